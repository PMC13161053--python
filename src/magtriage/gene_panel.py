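"""Presence/absence profiling of the photosynthesis gene panel from HMMER output.

The panel covers 115 genes of the phycobilisome (allophycocyanin apcABCDEF,
phycocyanin cpcABCDEFG, phycoerythrin cpeABCDERSTUYZ), the photosystems and
the respiratory chain (cytochrome bd cydABX, cytochrome b6f petABCDLM+GN,
cytochrome c oxidase ctaCDE+F, succinate dehydrogenase sdhCD, hydrogenase
hoxE, F-type ATPase / NADH dehydrogenase / electron transport). A gene is
called present in a MAG when at least one hmmsearch hit to its model passes
the e-value (or, optionally, bitscore) cutoff. Eukaryote-specific subunits
(psaGHNO, psbQRW) are tracked separately: their absence from a
cyanobacterial genome is expected and annotated as such rather than counted
as a gap.

The exact roster of a lab's panel varies, so the panel is an external TSV;
the bundled default contains every gene symbol listed above, with the slots
whose symbols are not individually enumerated shipped as clearly marked
placeholders (``photosystem_slot_NN`` etc.) to keep category totals honest.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from pydantic import BaseModel, Field

from magtriage.io_formats import GenePanelEntry, ParseError

logger = logging.getLogger(__name__)

DEFAULT_MAX_EVALUE = 1e-5


class TbloutRecord(NamedTuple):
    """One non-comment line of HMMER per-target (``--tblout``) output."""

    target_model: str
    query_protein: str
    full_seq_evalue: float
    full_seq_score: float


class GeneProfile(BaseModel):
    mag_id: str
    presence: dict[str, bool]
    present_count: int
    panel_size: int
    category_counts: dict[str, tuple[int, int]] = Field(default_factory=dict)
    missing_expected: list[str] = Field(default_factory=list)


def load_panel(path: str | Path | None = None) -> list[GenePanelEntry]:
    """Load a panel TSV (gene_symbol, category, model_id, eukaryote_specific).

    With no path the bundled 115-gene default panel is used. Gene symbols
    must be unique within the panel.
    """
    if path is None:
        text = resources.files("magtriage").joinpath("data/default_panel.tsv").read_text()
    else:
        text = Path(path).read_text()
    entries: list[GenePanelEntry] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "gene_symbol":
            continue
        if len(fields) < 4:
            raise ParseError(f"panel line {lineno}: expected 4 fields, got {len(fields)}")
        symbol, category, model_id, euk = fields[:4]
        if symbol in seen:
            raise ParseError(f"panel line {lineno}: duplicate gene symbol {symbol!r}")
        seen.add(symbol)
        entries.append(
            GenePanelEntry(
                gene_symbol=symbol,
                category=category,  # type: ignore[arg-type]
                model_id=model_id,
                eukaryote_specific=euk.strip().lower() in ("1", "true", "yes"),
            )
        )
    return entries


def parse_tblout(path: str | Path) -> list[TbloutRecord]:
    """Parse HMMER per-target tabular output into records.

    Comment lines start with ``#``. Data lines are whitespace-delimited with
    at least 19 fields (the trailing description may contain spaces); the
    target name, query name, full-sequence e-value and score are kept.
    """
    path = Path(path)
    records: list[TbloutRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 18)
            if len(fields) < 19:
                raise ParseError(f"{path}:{lineno}: truncated tblout line ({len(fields)} fields)")
            try:
                evalue = float(fields[4])
                score = float(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric e-value/score") from exc
            records.append(TbloutRecord(fields[0], fields[2], evalue, score))
    return records


def profile_genes(
    hits: Iterable[TbloutRecord],
    panel: Sequence[GenePanelEntry],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    mag_id: str = "",
    min_bitscore: Optional[float] = None,
) -> GeneProfile:
    """Presence/absence of every panel gene from parsed hmmsearch hits.

    A gene is present iff at least one hit to its model passes the filter
    (full-sequence e-value <= ``max_evalue``, or full-sequence score >=
    ``min_bitscore`` when a bitscore mode is requested). Hits to models
    outside the panel are ignored. The model id may appear in either the
    target or the query column, so both hmmsearch (proteome as target) and
    hmmscan (models as target) orientations are accepted; the target column
    wins when both match.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    by_model = {entry.model_id: entry.gene_symbol for entry in panel}
    presence = {entry.gene_symbol: False for entry in panel}
    for hit in hits:
        symbol = by_model.get(hit.target_model) or by_model.get(hit.query_protein)
        if symbol is None:
            logger.debug("hit to model %s/%s outside the panel; ignored", hit.target_model, hit.query_protein)
            continue
        if min_bitscore is not None:
            passing = hit.full_seq_score >= min_bitscore
        else:
            passing = hit.full_seq_evalue <= max_evalue
        if passing:
            presence[symbol] = True
    category_counts: dict[str, tuple[int, int]] = {}
    for entry in panel:
        present, total = category_counts.get(entry.category, (0, 0))
        category_counts[entry.category] = (present + int(presence[entry.gene_symbol]), total + 1)
    missing_expected = sorted(
        entry.gene_symbol
        for entry in panel
        if entry.eukaryote_specific and not presence[entry.gene_symbol]
    )
    return GeneProfile(
        mag_id=mag_id,
        presence=presence,
        present_count=sum(presence.values()),
        panel_size=len(panel),
        category_counts=category_counts,
        missing_expected=missing_expected,
    )


def presence_matrix(profiles: Sequence[GeneProfile]):
    """Genes x MAGs boolean presence matrix as a pandas DataFrame."""
    import pandas as pd

    if not profiles:
        return pd.DataFrame()
    genes = list(profiles[0].presence)
    return pd.DataFrame(
        {p.mag_id: [p.presence[g] for g in genes] for p in profiles},
        index=genes,
    )
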