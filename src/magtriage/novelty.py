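"""Species- and genus-level novelty calls from best-hit ANI and AAI values.

The species rule is the standard genomic criterion: a best ANI of at least
95% to an existing genome means the species is already sequenced; below it
the MAG is a candidate novel species. The genus rule uses a 65% AAI floor:
below the floor the MAG represents a novel genus; at or above it the genus
is taken from the hit's taxonomy when that taxonomy names a genus, and is
otherwise unresolved unless an external phylogenetic placement decides.
"""

from __future__ import annotations

from typing import Iterable, Literal, Optional

from pydantic import BaseModel

from magtriage.io_formats import Lineage, ReferenceHit

SPECIES_ANI_THRESHOLD = 95.0
GENUS_AAI_THRESHOLD = 65.0

SpeciesStatus = Literal["known_species", "novel_species", "no_hit"]
GenusStatus = Literal["existing_genus", "novel_genus", "unresolved"]
PlacementOverride = Literal["none", "within_named_genus", "outside_named_genera"]


class NoveltyCall(BaseModel):
    mag_id: str
    best_ani_hit: Optional[ReferenceHit] = None
    best_aai_hit: Optional[ReferenceHit] = None
    species_status: SpeciesStatus
    genus_status: GenusStatus


def best_hit(hits: Iterable[ReferenceHit]) -> Optional[ReferenceHit]:
    """The maximal-identity hit; ``None`` when the list is empty.

    Ties on identity are broken by larger mapped-fragment count, then by
    lexicographically smaller reference id, so the result is independent of
    input order.
    """
    hits = list(hits)
    if not hits:
        return None
    return sorted(
        hits,
        key=lambda h: (
            -h.value,
            -(h.mapped_fragments if h.mapped_fragments is not None else -1),
            h.reference_id,
        ),
    )[0]


def species_call(
    best_ani: Optional[float],
    threshold: float = SPECIES_ANI_THRESHOLD,
) -> SpeciesStatus:
    """Known species at ANI >= threshold (inclusive), novel below, no_hit when absent."""
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"threshold {threshold} outside (0, 100]")
    if best_ani is None:
        return "no_hit"
    return "known_species" if best_ani >= threshold else "novel_species"


def genus_call(
    best_aai: Optional[float],
    hit_lineage: Optional[Lineage] = None,
    placement_override: PlacementOverride = "none",
    threshold: float = GENUS_AAI_THRESHOLD,
) -> GenusStatus:
    """Genus status from the best AAI value and the hit's taxonomy.

    AAI below the floor (or no AAI hit at all) means a novel genus. At or
    above the floor the call follows the hit's lineage when it names a genus.
    A genus-unnamed lineage (hit classified only to order, say) leaves the
    genus unresolved unless a phylogenetic placement, supplied as an input
    flag, puts the MAG inside or outside the named genera.
    """
    if best_aai is None or best_aai < threshold:
        return "novel_genus"
    if hit_lineage is not None and hit_lineage.name_at("genus") is not None:
        return "existing_genus"
    if placement_override == "outside_named_genera":
        return "novel_genus"
    if placement_override == "within_named_genus":
        return "existing_genus"
    return "unresolved"


def call_novelty(
    mag_id: str,
    ani_hits: Iterable[ReferenceHit],
    aai_hits: Iterable[ReferenceHit],
    lineages: Optional[dict[str, Lineage]] = None,
    species_threshold: float = SPECIES_ANI_THRESHOLD,
    genus_threshold: float = GENUS_AAI_THRESHOLD,
    placement_override: PlacementOverride = "none",
) -> NoveltyCall:
    """Convenience wrapper: best hits plus both calls for one MAG."""
    ani = best_hit(ani_hits)
    aai = best_hit(aai_hits)
    aai_lineage = None
    if aai is not None and lineages:
        aai_lineage = lineages.get(aai.reference_id)
    return NoveltyCall(
        mag_id=mag_id,
        best_ani_hit=ani,
        best_aai_hit=aai,
        species_status=species_call(ani.value if ani else None, species_threshold),
        genus_status=genus_call(
            aai.value if aai else None,
            aai_lineage,
            placement_override,
            genus_threshold,
        ),
    )
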