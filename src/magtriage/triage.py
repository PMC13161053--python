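"""The material-aware decision tree assigning each MAG a SeqCode action.

Whether a genome-based description is appropriate depends on two axes: is
the MAG the same species as an existing genome (best ANI >= 95%), and what
kind of material does that closest genome represent? Five material
categories are distinguished: (1) a described type strain, (2) an
undescribed strain held in a public culture collection, (3) a cultivated
strain never deposited, (4) purely in-silico material with a GTDB
classification, and (5) in-silico material known only to NCBI. Same-species
MAGs get categories A1-A5 (A1: nothing to register; A2: defer to the
biological material; A3: describe and recommend a strain deposit; A4/A5:
genome-based description), novel-species MAGs get the mirrored B1-B5 (all
describable; hits on biological material carry no priority below the
species line). Categories 5 additionally require the three closest NCBI
hits to be taxonomically congruent; otherwise the MAG is rejected for
description. Part C dereplicates conspecific study MAGs so that exactly one
representative per cluster is proposed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import networkx as nx
from pydantic import BaseModel, Field, model_validator

from magtriage.io_formats import MagRecord, ParseError
from magtriage.novelty import NoveltyCall
from magtriage.quality_gate import QualityVerdict
from magtriage.taxonomy_lca import LcaResult

logger = logging.getLogger(__name__)

MaterialStatus = Literal[
    "type_strain",
    "public_collection_strain",
    "cultivated_undeposited",
    "in_silico",
]

#: Material status -> category index for statuses that decide it alone.
_STATUS_INDEX: dict[str, int] = {
    "type_strain": 1,
    "public_collection_strain": 2,
    "cultivated_undeposited": 3,
}

CATEGORIES = tuple(
    [f"A{i}" for i in range(1, 6)]
    + [f"B{i}" for i in range(1, 6)]
    + ["REJECT_INCONGRUENT", "FAIL_QUALITY"]
)

_A_ACTIONS = {
    1: "No SeqCode registration: the species already exists with a type strain.",
    2: (
        "Recommend a formal description via the public-collection strain; "
        "no SeqCode deposition (priority to biological material)."
    ),
    3: (
        "SeqCode description, with a recommendation to deposit the cultivated "
        "strain in a public culture collection."
    ),
    4: "SeqCode description of the species, anchored to the GTDB-classified reference.",
    5: "SeqCode description of the species, supported by three congruent NCBI hits.",
}

_B_ACTIONS = {
    1: (
        "Describe as a novel species under SeqCode; the related type-strain "
        "material below the species threshold implies no priority."
    ),
    2: (
        "Describe as a novel species under SeqCode; the related public-collection "
        "strain implies no priority."
    ),
    3: (
        "Describe as a novel species under SeqCode; note the related undeposited "
        "cultivated material."
    ),
    4: "Describe as a novel species under SeqCode (< 95% ANI; GTDB-classified closest reference).",
    5: "Describe as a novel species under SeqCode (< 95% ANI; three congruent NCBI hits).",
}

#: Categories for which a protologue should be drafted.
DESCRIBABLE = frozenset({"A3", "A4", "A5", "B1", "B2", "B3", "B4", "B5"})


class MaterialRecord(BaseModel):
    """Biological-material status of one reference genome."""

    reference_id: str
    status: MaterialStatus
    collection_ids: Optional[list[str]] = None
    named_under_code: Optional[Literal["ICNP", "ICN", "SeqCode", "none"]] = None

    @model_validator(mode="after")
    def _collection_backed(self) -> "MaterialRecord":
        if self.status == "public_collection_strain" and not self.collection_ids:
            raise ValueError("public_collection_strain requires at least one collection id")
        return self


class TriageResult(BaseModel):
    mag_id: str
    category: str
    action: str
    evidence: dict = Field(default_factory=dict)


class ClusterAssignment(BaseModel):
    cluster_id: str
    members: list[str]
    representative: str
    representative_score: float

    @model_validator(mode="after")
    def _rep_is_member(self) -> "ClusterAssignment":
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")
        return self


def parse_materials_table(path: str | Path) -> dict[str, MaterialRecord]:
    """Read a ``reference_id<TAB>status[<TAB>collection_ids[<TAB>code]]`` TSV.

    ``collection_ids`` is a comma-separated list; empty fields are allowed
    for statuses that do not require them.
    """
    path = Path(path)
    registry: dict[str, MaterialRecord] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least reference_id and status")
            ref, status = fields[0], fields[1]
            collections = [c for c in fields[2].split(",") if c] if len(fields) > 2 and fields[2] else None
            code = fields[3] if len(fields) > 3 and fields[3] else None
            registry[ref] = MaterialRecord(
                reference_id=ref,
                status=status,  # type: ignore[arg-type]
                collection_ids=collections,
                named_under_code=code,  # type: ignore[arg-type]
            )
    return registry


def material_category(
    best_hit_ref: Optional[str],
    registry: Mapping[str, MaterialRecord],
    gtdb_hit_available: bool,
) -> int:
    """Map the closest reference's material status to a category index 1-5.

    A reference missing from the registry is treated as in-silico material
    (with a warning): the safe default, since nothing vouches for a culture.
    """
    record = registry.get(best_hit_ref) if best_hit_ref is not None else None
    if record is None:
        if best_hit_ref is not None:
            logger.warning("reference %s not in material registry; assuming in_silico", best_hit_ref)
        status: str = "in_silico"
    else:
        status = record.status
    if status in _STATUS_INDEX:
        return _STATUS_INDEX[status]
    return 4 if gtdb_hit_available else 5


def triage_mag(
    novelty: NoveltyCall,
    material_index: int,
    lca: Optional[LcaResult],
    quality: QualityVerdict,
) -> TriageResult:
    """Assign one MAG its decision-tree category and recommended action.

    Quality failure short-circuits everything. A MAG with no ANI hit at all
    is trivially below the species threshold and follows the novel-species
    branch. Index-5 material (NCBI-only taxonomy) demands a congruent LCA of
    the three closest hits; without one the MAG is rejected for description.
    """
    evidence = {
        "best_ani": novelty.best_ani_hit.model_dump() if novelty.best_ani_hit else None,
        "best_aai": novelty.best_aai_hit.model_dump() if novelty.best_aai_hit else None,
        "species_status": novelty.species_status,
        "genus_status": novelty.genus_status,
        "material_index": material_index,
        "lca": lca.model_dump() if lca is not None else None,
        "quality_reasons": quality.reasons,
    }
    if not quality.passed:
        return TriageResult(
            mag_id=novelty.mag_id,
            category="FAIL_QUALITY",
            action="Fails the SeqCode type-genome quality screen: " + ", ".join(quality.reasons) + ".",
            evidence=evidence,
        )
    if material_index not in range(1, 6):
        raise ValueError(f"material_index {material_index} outside 1..5")
    if novelty.species_status == "known_species":
        if novelty.best_ani_hit is None:
            raise ValueError(f"{novelty.mag_id}: known_species without a best ANI hit")
        side, actions = "A", _A_ACTIONS
    else:
        # novel_species, or no hit at all (vacuously below the species threshold)
        side, actions = "B", _B_ACTIONS
    if material_index == 5 and (lca is None or not lca.congruent):
        return TriageResult(
            mag_id=novelty.mag_id,
            category="REJECT_INCONGRUENT",
            action=(
                "No GTDB hit and the taxonomies of the closest NCBI hits are not "
                "congruent; a SeqCode description is not supported."
            ),
            evidence=evidence,
        )
    return TriageResult(
        mag_id=novelty.mag_id,
        category=f"{side}{material_index}",
        action=actions[material_index],
        evidence=evidence,
    )


def representative_score(record: MagRecord) -> float:
    """Dereplication score: completeness − 5 × contamination."""
    return record.completeness - 5.0 * record.contamination


def dereplicate(
    members: Sequence[str],
    pairwise_ani: Mapping[tuple[str, str], float],
    records: Mapping[str, MagRecord],
    link_threshold: float = 95.0,
) -> list[ClusterAssignment]:
    """Single-linkage clustering of conspecific study MAGs with one representative each.

    Pairs at ANI >= ``link_threshold`` are linked; missing pairs count as
    below threshold. The representative maximises completeness − 5 ×
    contamination, with ties broken by larger N50, then larger genome size,
    then lexicographically smaller id. Cluster ids are ``C1``, ``C2``, ... in
    order of each cluster's smallest member id, so output is deterministic
    under input permutation.
    """
    missing = [m for m in members if m not in records]
    if missing:
        raise ValueError(f"members without a MagRecord: {missing}")
    graph = nx.Graph()
    graph.add_nodes_from(members)
    member_set = set(members)
    for (a, b), value in pairwise_ani.items():
        if a in member_set and b in member_set and a != b and value >= link_threshold:
            graph.add_edge(a, b)
    clusters = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    assignments: list[ClusterAssignment] = []
    for i, cluster in enumerate(clusters, start=1):
        rep = min(
            cluster,
            key=lambda m: (
                -representative_score(records[m]),
                -(records[m].n50 or 0),
                -(records[m].genome_size or 0),
                m,
            ),
        )
        assignments.append(
            ClusterAssignment(
                cluster_id=f"C{i}",
                members=cluster,
                representative=rep,
                representative_score=representative_score(records[rep]),
            )
        )
    return assignments
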