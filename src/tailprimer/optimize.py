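"""Per-gene panel selection: greedy set cover over isoforms.

Each candidate primer covers the set of its gene's isoforms on which
it has a usable perfect binding site. Multi-peak mode runs a greedy
set cover (candidates pooled across all peaks of the gene); single-peak
mode picks the one candidate with the largest coverage. Ties are always
broken toward the primer closest to the 3' end, then lexicographically,
so selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CoverageCandidate:
    primer_id: str
    covered_isoforms: frozenset[str]
    dist_to_3prime: int

    def __post_init__(self) -> None:
        if self.dist_to_3prime < 0:
            raise ValueError("dist_to_3prime must be >= 0")


@dataclass
class CoverageInstance:
    gene_id: str
    candidates: list[CoverageCandidate]
    max_primers: int = 1

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"gene {self.gene_id}: no candidates to optimize")
        if self.max_primers < 1:
            raise ValueError("max_primers must be >= 1")

    @property
    def reachable_isoforms(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.candidates:
            out |= c.covered_isoforms
        return frozenset(out)


@dataclass
class PanelSelection:
    gene_id: str
    chosen: list[str]
    covered: frozenset[str]
    iterations: list[tuple[str, int]] = field(default_factory=list)


def _pick(candidates, already_covered):
    """Best candidate by (new isoforms desc, dist asc, primer_id asc)."""
    def key(c: CoverageCandidate):
        gain = len(c.covered_isoforms - already_covered)
        return (-gain, c.dist_to_3prime, c.primer_id)

    best = min(candidates, key=key)
    return best, len(best.covered_isoforms - already_covered)


def greedy_set_cover(inst: CoverageInstance) -> PanelSelection:
    """Iteratively pick the primer adding the most uncovered isoforms.

    Stops at ``max_primers``, or as soon as the best remaining candidate
    adds no new isoform (zero-gain primers are never selected).
    """
    covered: set[str] = set()
    chosen: list[str] = []
    iterations: list[tuple[str, int]] = []
    pool = list(inst.candidates)
    while len(chosen) < inst.max_primers and pool:
        best, gain = _pick(pool, covered)
        if gain == 0:
            break
        chosen.append(best.primer_id)
        iterations.append((best.primer_id, gain))
        covered |= best.covered_isoforms
        pool = [c for c in pool if c.primer_id != best.primer_id]
    return PanelSelection(
        gene_id=inst.gene_id,
        chosen=chosen,
        covered=frozenset(covered),
        iterations=iterations,
    )


def single_peak_select(inst: CoverageInstance) -> PanelSelection:
    """One primer per gene maximizing distinct isoform coverage
    (equivalent to greedy set cover with max_primers = 1)."""
    best, gain = _pick(inst.candidates, set())
    if gain == 0:
        return PanelSelection(inst.gene_id, [], frozenset(), [])
    return PanelSelection(
        gene_id=inst.gene_id,
        chosen=[best.primer_id],
        covered=best.covered_isoforms,
        iterations=[(best.primer_id, gain)],
    )
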