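"""Rendering of SeqCode-style protologues (formal taxonomic descriptions).

A protologue pairs a hand-authored name and etymology with machine-filled
evidence: type-genome statistics, the closest reference with its ANI/AAI,
a gene-panel summary, the higher-rank placement, the type accession and the
registry line. Rendering is a pure function of its inputs — the same record
always produces byte-identical text — and every number is echoed from the
source record (genome size in Mb to two decimals; completeness and
contamination at input precision).
"""

from __future__ import annotations

import re
from typing import Literal, Optional

from pydantic import BaseModel, Field

from magtriage.io_formats import Lineage

_LATIN_NAME = re.compile(r"^[A-Za-z]+$")


class EtymologyRecord(BaseModel):
    """Structured etymology of a proposed epithet or genus name.

    Only structure is validated (elements present, legal gender tag); no
    Latin morphology is checked.
    """

    epithet: str
    derivation: list[tuple[str, str, str]] = Field(min_length=1)  # (language, element, gloss)
    gender_agreement: Literal["masc", "fem", "neut", "masc_fem"]
    formed_as: Literal["adjective", "genitive_noun", "nominative_noun"]


class ProtologueRecord(BaseModel):
    proposed_name: str
    rank: Literal["genus", "species"]
    type_genome_id: str
    accession: str
    stats: Optional[tuple[float, float, float]] = None  # (size_mb, completeness, contamination)
    closest_reference: Optional[tuple[str, float, float]] = None  # (reference_id, ani, aai)
    placement: Optional[Lineage] = None
    gene_summary: Optional[tuple[int, int, list[str]]] = None  # (present, panel_size, notable absences)
    provenance_text: Optional[str] = None
    registry_url: str = "seqco.de/r:pending"

    model_config = {"arbitrary_types_allowed": True}


def validate_name(name: str, rank: Literal["genus", "species"]) -> list[str]:
    """Structural violations of a proposed name; empty list when compliant.

    A species name must be a binomial (capitalised genus + lowercase
    epithet); a genus name a single capitalised word; both restricted to the
    Latin alphabet. Violations are data, not exceptions.
    """
    violations: list[str] = []
    tokens = name.split()
    if rank == "species":
        if len(tokens) != 2:
            violations.append(f"species name must be a two-word binomial, got {len(tokens)} token(s)")
            return violations
        genus, epithet = tokens
        if not _LATIN_NAME.match(genus):
            violations.append(f"genus part {genus!r} contains non-Latin-alphabet characters")
        elif not genus[0].isupper():
            violations.append("genus part must be capitalized")
        if not _LATIN_NAME.match(epithet):
            violations.append(f"epithet {epithet!r} contains non-Latin-alphabet characters")
        elif not epithet.islower():
            violations.append("species epithet must be lowercase")
    else:
        if len(tokens) != 1:
            violations.append(f"genus name must be a single word, got {len(tokens)} token(s)")
            return violations
        if not _LATIN_NAME.match(tokens[0]):
            violations.append(f"genus name {tokens[0]!r} contains non-Latin-alphabet characters")
        elif not tokens[0][0].isupper():
            violations.append("genus name must be capitalized")
    return violations


def _fmt(value: float) -> str:
    """Echo a numeric field at its input precision (no trailing zeros added)."""
    return f"{value:g}"


_SPECIES_MANDATORY = (
    "stats",
    "closest_reference",
    "placement",
    "provenance_text",
)


def render_protologue(rec: ProtologueRecord, ety: EtymologyRecord) -> str:
    """Render one protologue as deterministic plain text.

    Section order: name and etymology, provenance, genome statistics,
    closest reference with ANI/AAI, gene summary, accession with type-genome
    marker, higher-rank placement (family to phylum), registry line. A genus
    protologue carries only name, etymology and registry. Missing mandatory
    fields raise a ``ValueError`` listing all of them.
    """
    problems = validate_name(rec.proposed_name, rec.rank)
    if not ety.epithet:
        problems.append("etymology epithet is empty")
    if rec.rank == "species":
        missing = [f for f in _SPECIES_MANDATORY if getattr(rec, f) in (None, "")]
        problems.extend(f"missing mandatory field: {f}" for f in missing)
    if problems:
        raise ValueError("invalid protologue record: " + "; ".join(problems))

    derivation = "; ".join(f"{lang} {element}, {gloss}" for lang, element, gloss in ety.derivation)
    nov = "gen. nov." if rec.rank == "genus" else "sp. nov."
    lines = [
        f"Description of {rec.proposed_name} {nov}",
        "",
        f"{rec.proposed_name} ({ety.epithet}: {derivation}; {ety.gender_agreement}, {ety.formed_as}).",
    ]
    if rec.rank == "species":
        assert rec.stats and rec.closest_reference and rec.placement  # narrowed above
        size_mb, completeness, contamination = rec.stats
        ref_id, ani, aai = rec.closest_reference
        lines.append(rec.provenance_text or "")
        lines.append(
            f"The type genome ({rec.type_genome_id}) has a size of {size_mb:.2f} Mb, "
            f"completeness of {_fmt(completeness)}%, and contamination of {_fmt(contamination)}%."
        )
        lines.append(
            f"The closest reference genome is {ref_id} (ANI: {_fmt(ani)}%; AAI: {_fmt(aai)}%)."
        )
        if rec.gene_summary is not None:
            present, total, absences = rec.gene_summary
            sentence = (
                f"In total, this genome encodes {present} of the {total} screened "
                "phycobilisome, photosynthesis, and respiratory genes"
            )
            if absences:
                sentence += " (notably lacking " + ", ".join(absences) + ")"
            lines.append(sentence + ".")
        lines.append(
            f"The type genome has been deposited with the accession number {rec.accession}."
        )
        placement_parts = [
            f"{rank} {rec.placement.name_at(rank)}"
            for rank in ("family", "order", "class", "phylum")
            if rec.placement.name_at(rank) is not None
        ]
        if placement_parts:
            lines.append(f"{rec.proposed_name} belongs to the " + ", ".join(placement_parts) + ".")
    lines.append(f"The name has been registered under SeqCode: {rec.registry_url}.")
    return "\n".join(line for line in lines if line != "") + "\n"
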