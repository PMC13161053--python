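"""Lowest-common-ancestor reconciliation of reference lineages.

When a MAG's closest references carry only the less curated NCBI taxonomy,
classification should not rest on a single hit: the three closest hits must
agree — their LCA must reach at least a configurable rank (family by
default) — before a genome-based description is attempted. Absent ranks
never match anything, including other absent ranks, so two unclassified
lineages cannot appear congruent.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel

from magtriage.io_formats import CANONICAL_RANKS, RANK_DEPTH, Lineage
from magtriage.novelty import best_hit
from magtriage.io_formats import ReferenceHit

#: Sentinel rank returned when the lineages share no named rank at all.
ROOT_RANK = "root"

DEFAULT_MIN_RANK = "family"


class LcaResult(BaseModel):
    lca_rank: str
    lca_name: Optional[str] = None
    congruent: bool
    contributing_lineages: int


def compute_lca(lineages: Sequence[Lineage]) -> tuple[str, Optional[str]]:
    """Deepest rank at which every lineage carries the same non-absent name.

    Returns ``(ROOT_RANK, None)`` when not even the domain is shared.
    """
    if not lineages:
        raise ValueError("compute_lca requires at least one lineage")
    lca_rank, lca_name = ROOT_RANK, None
    for rank in CANONICAL_RANKS:
        names = {lin.name_at(rank) for lin in lineages}
        if len(names) == 1 and None not in names:
            lca_rank, lca_name = rank, names.pop()
        else:
            break
    return lca_rank, lca_name


def congruence_check(
    top3: Sequence[Lineage],
    min_rank: str = DEFAULT_MIN_RANK,
    allow_fewer: bool = False,
) -> LcaResult:
    """Do the top hits agree deeply enough to support a description?

    Congruent iff the LCA of the lineages sits at ``min_rank`` or deeper.
    Exactly three lineages are expected; fewer are accepted only with
    ``allow_fewer=True`` (the check is then made on what is available).
    """
    if min_rank not in RANK_DEPTH:
        raise ValueError(f"min_rank {min_rank!r} is not a canonical rank")
    if len(top3) < 3 and not allow_fewer:
        raise ValueError(f"congruence check expects 3 lineages, got {len(top3)} (set allow_fewer to proceed)")
    rank, name = compute_lca(top3)
    congruent = rank != ROOT_RANK and RANK_DEPTH[rank] >= RANK_DEPTH[min_rank]
    return LcaResult(
        lca_rank=rank,
        lca_name=name,
        congruent=congruent,
        contributing_lineages=len(top3),
    )


def select_top_lineages(
    aai_hits: Sequence[ReferenceHit],
    lineages: dict[str, Lineage],
    n: int = 3,
) -> list[Lineage]:
    """Lineages of the ``n`` best AAI hits that have a lineage on record.

    Hits are ranked with the same deterministic key as best-hit selection
    (value, then mapped fragments, then reference id).
    """
    ranked: list[ReferenceHit] = []
    pool = [h for h in aai_hits if h.reference_id in lineages]
    while pool and len(ranked) < n:
        top = best_hit(pool)
        assert top is not None
        ranked.append(top)
        pool = [h for h in pool if h is not top]
    return [lineages[h.reference_id] for h in ranked]
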