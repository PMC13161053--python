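"""SeqCode type-genome quality screen.

The screen keeps bins with completeness above and contamination below
configurable bounds (strict inequalities: the defaults encode the
">90% completeness and <5% contamination" type-genome requirement), with an
optional GUNC chimerism criterion and contig cap. A separate exclusion step
removes bins flagged on other grounds (e.g. non-photosynthetic
Vampirovibrionophyceae relatives caught by phylogenomics).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

from magtriage.io_formats import MagRecord

logger = logging.getLogger(__name__)


class QualityPolicy(BaseModel):
    """Quality bounds applied to each MAG. Bounds are strict inequalities."""

    min_completeness: float = Field(default=90.0, gt=0.0, le=100.0)
    max_contamination: float = Field(default=5.0, gt=0.0)
    require_gunc_pass: bool = False
    max_gunc_css: float = Field(default=0.45, ge=0.0, le=1.0)
    max_contigs: Optional[int] = Field(default=None, ge=1)

    @classmethod
    def strict(cls) -> "QualityPolicy":
        """Preset with the stricter 95% completeness floor some selections use."""
        return cls(min_completeness=95.0)


class QualityVerdict(BaseModel):
    mag_id: str
    passed: bool
    reasons: list[str] = Field(default_factory=list)


def evaluate_quality(mag: MagRecord, policy: QualityPolicy | None = None) -> QualityVerdict:
    """Apply the quality policy to one MAG and report every violated criterion.

    Raises ``ValueError`` naming the missing field when an enabled criterion
    needs a statistic the record does not carry.
    """
    policy = policy or QualityPolicy()
    reasons: list[str] = []
    if not mag.completeness > policy.min_completeness:
        reasons.append("completeness")
    if not mag.contamination < policy.max_contamination:
        reasons.append("contamination")
    if policy.require_gunc_pass:
        if mag.gunc_css is None:
            raise ValueError(f"{mag.mag_id}: GUNC criterion enabled but field 'gunc_css' is missing")
        if mag.gunc_css > policy.max_gunc_css:
            reasons.append("gunc_css")
    if policy.max_contigs is not None:
        if mag.n_contigs is None:
            raise ValueError(f"{mag.mag_id}: contig cap enabled but field 'n_contigs' is missing")
        if mag.n_contigs > policy.max_contigs:
            reasons.append("n_contigs")
    return QualityVerdict(mag_id=mag.mag_id, passed=not reasons, reasons=reasons)


def apply_exclusions(
    passing: Sequence[str],
    excluded: Iterable[tuple[str, str]],
) -> list[str]:
    """Remove flagged bins from the quality-passing list, preserving order.

    An exclusion id not present in ``passing`` is a warning, not an error,
    so an exclusion list can be shared across runs.
    """
    drop: dict[str, str] = {}
    passing_set = set(passing)
    for mag_id, reason in excluded:
        if mag_id not in passing_set:
            logger.warning("exclusion %s (%s) not in the passing set; ignored", mag_id, reason)
            continue
        drop[mag_id] = reason
        logger.info("excluding %s: %s", mag_id, reason)
    return [m for m in passing if m not in drop]
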