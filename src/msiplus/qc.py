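"""Sample-level QC gates, the dilution/purification salvage flag, and the
borderline-score repeat-testing policy.

A sample passes QC when its median MSI-marker read depth is at least 100
and every mutation hotspot position has at least 250 reads.  A median
hotspot-to-marker depth ratio of 5 or more marks selective inhibition of
marker amplification: such samples are flagged for dilution or bead
purification before repeat testing.  MSI scores strictly inside (-5, 5)
require a repeat assay; the classification is accepted if the repeat agrees
and the sample fails QC if it disagrees.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

from .classifier import MsiResult
from .counts import SampleCounts

logger = logging.getLogger(__name__)

__all__ = ["QcThresholds", "QcVerdict", "RepeatDecision", "evaluate_qc", "resolve_repeat"]


@dataclass(frozen=True)
class QcThresholds:
    min_median_msi_depth: float = 100.0
    min_hotspot_depth: int = 250
    salvage_ratio: float = 5.0
    repeat_band: float = 5.0

    def __post_init__(self) -> None:
        if min(self.min_median_msi_depth, self.min_hotspot_depth,
               self.salvage_ratio, self.repeat_band) <= 0:
            raise ValueError("all QC thresholds must be positive")


@dataclass(frozen=True)
class QcVerdict:
    sample_id: str
    passed: bool
    median_msi_depth: float
    min_hotspot_depth_observed: int
    depth_ratio: float  # median hotspot depth / median marker depth; inf if marker median 0
    salvage_flag: bool
    reasons: tuple[str, ...]


def evaluate_qc(sample: SampleCounts, thresholds: QcThresholds = QcThresholds()) -> QcVerdict:
    """Apply the depth gates and compute the salvage flag for one sample."""
    marker_depths = [mc.total_reads for mc in sample.marker_counts.values()]
    hotspot_depths = [hc.depth for hc in sample.hotspot_counts.values()]
    median_msi = statistics.median(marker_depths) if marker_depths else 0.0
    median_hot = statistics.median(hotspot_depths) if hotspot_depths else 0.0
    min_hot = min(hotspot_depths) if hotspot_depths else 0
    reasons: list[str] = []
    if median_msi < thresholds.min_median_msi_depth:
        reasons.append(
            f"median MSI depth < {thresholds.min_median_msi_depth:g} "
            f"(observed {median_msi:g})"
        )
    if min_hot < thresholds.min_hotspot_depth:
        reasons.append(
            f"hotspot depth < {thresholds.min_hotspot_depth} "
            f"(minimum observed {min_hot})"
        )
    ratio = math.inf if median_msi == 0 else median_hot / median_msi
    return QcVerdict(
        sample_id=sample.sample_id,
        passed=not reasons,
        median_msi_depth=float(median_msi),
        min_hotspot_depth_observed=min_hot,
        depth_ratio=ratio,
        salvage_flag=ratio >= thresholds.salvage_ratio,
        reasons=tuple(reasons),
    )


@dataclass(frozen=True)
class RepeatDecision:
    """Outcome of the borderline-score repeat policy.

    ``kind`` is one of ``accept`` (with the accepted ``status``),
    ``needs_repeat`` (borderline first score, no repeat supplied yet), or
    ``qc_fail`` (discordant or inconclusive repeats).
    """

    kind: str
    status: str | None = None


def resolve_repeat(
    first: MsiResult,
    second: MsiResult | None = None,
    repeat_band: float = 5.0,
) -> RepeatDecision:
    """Apply the borderline-score repeat policy.

    Scores with magnitude at or beyond ``repeat_band`` are accepted
    outright (a supplied repeat is ignored with a warning).  Borderline
    scores need a repeat; concordant non-inconclusive statuses are
    accepted, anything else fails QC.  Unscorable first results fail QC.
    """
    if first.score is None:
        return RepeatDecision("qc_fail")
    if abs(first.score) >= repeat_band:
        if second is not None:
            logger.warning(
                "sample %s: repeat result ignored (first score %.2f outside "
                "the +/-%g repeat band)", first.sample_id, first.score, repeat_band,
            )
        return RepeatDecision("accept", first.status)
    if second is None:
        return RepeatDecision("needs_repeat")
    if (
        first.status == second.status
        and first.status in ("MSI-H", "MSS")
    ):
        return RepeatDecision("accept", first.status)
    return RepeatDecision("qc_fail")
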