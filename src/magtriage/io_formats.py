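"""Parsers and writers for the tabular and sequence formats the triage consumes.

Everything external comes in as plain TSV or FASTA: fastANI's five-column
output, FastAAI-style best-hit tables (normalised to the same shape), CheckM
quality tables, GTDB rank-prefixed lineage strings and NCBI semicolon
lineages, and the gene-panel definition. ANI/AAI values are kept on the
0-100 percentage scale throughout, matching how the tools print them.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

#: Canonical taxonomy ranks from shallowest to deepest.
CANONICAL_RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: GTDB-style rank prefixes.
GTDB_PREFIXES: dict[str, str] = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

RANK_DEPTH: dict[str, int] = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}


class ParseError(ValueError):
    """Malformed content in an input file; message carries the line number."""


class MagRecord(BaseModel):
    """One genome bin with its quality and assembly statistics."""

    mag_id: str
    completeness: float = Field(ge=0.0, le=100.0)
    contamination: float = Field(ge=0.0)
    genome_size: Optional[int] = Field(default=None, ge=0)
    n_contigs: Optional[int] = Field(default=None, ge=1)
    gunc_css: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    gunc_contamination: Optional[float] = Field(default=None, ge=0.0)
    n50: Optional[int] = Field(default=None, ge=1)


class ReferenceHit(BaseModel):
    """An ANI or AAI comparison of one query genome against one reference."""

    query_id: str
    reference_id: str
    metric: Literal["ANI", "AAI"]
    value: float = Field(ge=0.0, le=100.0)
    mapped_fragments: Optional[int] = Field(default=None, ge=0)
    total_fragments: Optional[int] = Field(default=None, ge=1)

    @model_validator(mode="after")
    def _fragments_consistent(self) -> "ReferenceHit":
        if self.mapped_fragments is not None and self.total_fragments is not None:
            if self.mapped_fragments > self.total_fragments:
                raise ValueError(
                    f"mapped_fragments ({self.mapped_fragments}) exceeds "
                    f"total_fragments ({self.total_fragments})"
                )
        return self


class Lineage:
    """An ordered, rank-labelled taxonomy path over the canonical seven ranks.

    Names may be absent at any rank; parsed GTDB strings with only a species
    token (``s__Kovacikia sp034541955``) are legal and leave the shallower
    ranks unnamed.
    """

    __slots__ = ("names", "source")

    def __init__(
        self,
        names: dict[str, Optional[str]] | None = None,
        source: Literal["GTDB", "NCBI"] = "NCBI",
    ) -> None:
        self.names: dict[str, Optional[str]] = {rank: None for rank in CANONICAL_RANKS}
        if names:
            for rank, name in names.items():
                if rank not in RANK_DEPTH:
                    raise ValueError(f"unknown rank {rank!r}")
                self.names[rank] = name
        self.source = source

    def name_at(self, rank: str) -> Optional[str]:
        return self.names[rank]

    @property
    def deepest_named_rank(self) -> Optional[str]:
        deepest = None
        for rank in CANONICAL_RANKS:
            if self.names[rank] is not None:
                deepest = rank
        return deepest

    def named_items(self) -> list[tuple[str, str]]:
        return [(r, n) for r, n in self.names.items() if n is not None]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Lineage) and self.names == other.names and self.source == other.source

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ";".join(f"{r[0]}__{n}" for r, n in self.named_items())
        return f"Lineage({self.source}:{parts})"

    def to_gtdb_string(self) -> str:
        return ";".join(f"{rank[0]}__{name}" for rank, name in self.named_items())


class GenePanelEntry(BaseModel):
    """One gene of the photosynthesis/respiration panel."""

    gene_symbol: str
    category: Literal["phycobilisome", "photosystem", "electron_transport_respiration"]
    model_id: str
    eukaryote_specific: bool = False


def parse_ani_table(path: str | Path, metric: Literal["ANI", "AAI"] = "ANI") -> list[ReferenceHit]:
    """Parse a fastANI-style TSV into :class:`ReferenceHit` records.

    Rows are ``query<TAB>reference<TAB>value[<TAB>mapped<TAB>total]``; the
    same dialect is used for FastAAI-style tables with ``metric="AAI"``.
    Columns beyond the fifth are ignored with a warning. Values must lie on
    the 0-100 percentage scale.
    """
    path = Path(path)
    hits: list[ReferenceHit] = []
    warned_extra = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}")
            if len(fields) > 5 and not warned_extra:
                logger.warning("%s:%d: ignoring columns beyond the fifth", path, lineno)
                warned_extra = True
            query, reference, value_s = fields[0], fields[1], fields[2]
            try:
                value = float(value_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric identity value {value_s!r}") from exc
            mapped = total = None
            if len(fields) >= 5 and fields[3] != "" and fields[4] != "":
                try:
                    mapped, total = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer fragment counts") from exc
            if not 0.0 <= value <= 100.0:
                raise ParseError(f"{path}:{lineno}: identity {value} outside [0, 100]")
            hits.append(
                ReferenceHit(
                    query_id=query,
                    reference_id=reference,
                    metric=metric,
                    value=value,
                    mapped_fragments=mapped,
                    total_fragments=total,
                )
            )
    return hits


def write_ani_table(hits: Iterable[ReferenceHit], path: str | Path) -> None:
    """Write hits back to the five-column dialect read by :func:`parse_ani_table`."""
    with Path(path).open("w") as fh:
        for h in hits:
            row = [h.query_id, h.reference_id, repr(h.value)]
            if h.mapped_fragments is not None and h.total_fragments is not None:
                row += [str(h.mapped_fragments), str(h.total_fragments)]
            fh.write("\t".join(row) + "\n")


def parse_lineage(
    raw: str,
    source: Literal["GTDB", "NCBI"],
    rank_template: Sequence[str] = CANONICAL_RANKS,
) -> Lineage:
    """Parse a lineage string into a :class:`Lineage`.

    GTDB strings use rank-prefixed tokens (``d__``, ``p__``, ... ``s__``)
    separated by semicolons, and any subset of ranks may be present (a lone
    ``s__X`` is common in best-hit tables). NCBI strings are semicolon-
    separated bare names whose ranks are read positionally from
    ``rank_template`` (canonical seven ranks by default), so a trailing
    informal token such as ``Synechococcus_B`` lands on genus.
    """
    if not raw or not raw.strip():
        raise ParseError("empty lineage string")
    tokens = [t.strip() for t in raw.split(";") if t.strip()]
    names: dict[str, Optional[str]] = {}
    if source == "GTDB":
        for tok in tokens:
            if len(tok) < 3 or tok[1:3] != "__":
                raise ParseError(f"token {tok!r} lacks a GTDB rank prefix")
            prefix, name = tok[0], tok[3:]
            rank = GTDB_PREFIXES.get(prefix)
            if rank is None:
                raise ParseError(f"unknown rank prefix {prefix!r} in token {tok!r}")
            if name:
                names[rank] = name
    elif source == "NCBI":
        if len(tokens) > len(rank_template):
            raise ParseError(
                f"{len(tokens)} lineage tokens exceed the {len(rank_template)}-rank template"
            )
        for rank, name in zip(rank_template, tokens):
            names[rank] = name
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown lineage source {source!r}")
    return Lineage(names, source=source)


def parse_lineage_table(path: str | Path) -> dict[str, Lineage]:
    """Read a ``reference_id<TAB>source<TAB>lineage`` TSV into a lookup table.

    A reference may appear once per source; when both a GTDB and an NCBI
    lineage are given, the GTDB one wins the single-slot lookup (it is the
    more curated taxonomy) and the NCBI one is retrievable from the returned
    mapping under ``reference_id + "|NCBI"``.
    """
    path = Path(path)
    table: dict[str, Lineage] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields (reference, source, lineage)")
            ref, source, lin = fields
            if source not in ("GTDB", "NCBI"):
                raise ParseError(f"{path}:{lineno}: unknown source {source!r}")
            lineage = parse_lineage(lin, source)  # type: ignore[arg-type]
            table[f"{ref}|{source}"] = lineage
            if ref not in table or source == "GTDB":
                table[ref] = lineage
    return table


def parse_quality_table(path: str | Path) -> list[MagRecord]:
    """Read a headered CheckM-style quality TSV into :class:`MagRecord` rows.

    Mandatory columns: ``mag_id``, ``completeness``, ``contamination``;
    recognised optional columns: ``genome_size``, ``n_contigs``, ``gunc_css``,
    ``gunc_contamination``, ``n50``. Duplicate mag_ids are rejected.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"mag_id": str})
    for col in ("mag_id", "completeness", "contamination"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing mandatory column {col!r}")
    if frame["mag_id"].duplicated().any():
        dupes = sorted(frame.loc[frame["mag_id"].duplicated(), "mag_id"])
        raise ParseError(f"{path}: duplicate mag_id values {dupes}")
    optional = ("genome_size", "n_contigs", "gunc_css", "gunc_contamination", "n50")
    records = []
    for _, row in frame.iterrows():
        kwargs = {
            "mag_id": row["mag_id"],
            "completeness": float(row["completeness"]),
            "contamination": float(row["contamination"]),
        }
        for col in optional:
            if col in frame.columns and pd.notna(row[col]):
                value = row[col]
                kwargs[col] = int(value) if col in ("genome_size", "n_contigs", "n50") else float(value)
        records.append(MagRecord(**kwargs))
    return records


def assembly_stats(fasta: str | Path) -> tuple[int, int, int]:
    """Total assembly size, contig count and N50 of a FASTA assembly.

    N50 is the largest contig length L such that contigs of length >= L sum
    to at least half of the assembly size. Only lengths are used, so no
    alphabet validation is performed.
    """
    lengths = [len(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")]
    if not lengths:
        raise ParseError(f"{fasta}: no sequences found")
    if any(n == 0 for n in lengths):
        raise ParseError(f"{fasta}: zero-length record")
    genome_size = sum(lengths)
    half = genome_size / 2
    running = 0
    n50 = lengths[0]
    for length in sorted(lengths, reverse=True):
        running += length
        n50 = length
        if running >= half:
            break
    return genome_size, len(lengths), n50
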