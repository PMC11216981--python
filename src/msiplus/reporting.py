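"""Clinical report assembly: recommendation flags and serialisation.

A report combines the QC verdict, the final (post repeat-policy) MSI
result, and the reported hotspot variants into three recommendation flags:

* ``ls_risk`` — the patient is at risk of Lynch syndrome: the tumour is
  MSI-H and carries no reported BRAF p.V600E (which would mark a sporadic
  MMR-deficient tumour);
* ``ici_eligible`` — immune checkpoint inhibitor therapy is indicated for
  MMR-deficient (MSI-H) tumours;
* ``anti_egfr_contraindicated`` — a reported KRAS/NRAS variant or BRAF
  p.V600E contraindicates anti-EGFR therapy.

Only *reported* variants (VAF >= 0.04) drive the flags, so low-frequency
calls of uncertain relevance cannot deny a patient germline testing or
therapy.  When the sample fails QC, all flags are withheld and the
narrative code ``QC_FAIL`` is emitted.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from . import __version__ as _pipeline_version
from .classifier import MsiResult
from .hotspots import VariantCall
from .panel import BRAF_V600E
from .qc import QcVerdict, RepeatDecision

__all__ = ["ClinicalReport", "make_report", "report_to_json", "report_from_json", "render_text"]


@dataclass(frozen=True)
class ClinicalReport:
    sample_id: str
    qc: QcVerdict
    decision: RepeatDecision
    msi: MsiResult
    reported_variants: tuple[VariantCall, ...]
    ls_risk: bool
    ici_eligible: bool
    anti_egfr_contraindicated: bool
    narrative_codes: tuple[str, ...]
    pipeline_version: str = _pipeline_version


def _gene_of(call: VariantCall) -> str:
    return call.position_id.split("_", 1)[0]


def _is_braf_v600e(call: VariantCall) -> bool:
    return (call.position_id, call.substitution) == BRAF_V600E


def make_report(
    msi: MsiResult,
    calls: Sequence[VariantCall],
    decision: RepeatDecision,
    qc: QcVerdict,
) -> ClinicalReport:
    """Assemble the clinical report from the finalised analysis results.

    ``msi`` must be the final result after the repeat policy; ``decision``
    is the repeat-policy outcome.  Recommendation flags are set only when
    the decision is ``accept``.
    """
    reported = tuple(c for c in calls if c.reported)
    narrative: list[str] = []
    ls_risk = ici = anti_egfr = False
    if decision.kind != "accept":
        narrative.append("QC_FAIL" if decision.kind == "qc_fail" else "NEEDS_REPEAT")
    else:
        status = decision.status
        has_v600e = any(_is_braf_v600e(c) for c in reported)
        has_ras = any(_gene_of(c) in ("KRAS", "NRAS") for c in reported)
        ls_risk = status == "MSI-H" and not has_v600e
        ici = status == "MSI-H"
        anti_egfr = has_ras or has_v600e
        if ls_risk:
            narrative.append("LS_RISK_REFER_GERMLINE")
        if ici:
            narrative.append("ICI_ELIGIBLE")
        if anti_egfr:
            narrative.append("ANTI_EGFR_CONTRAINDICATED")
        if not qc.passed:
            narrative.append("SAMPLE_QC_FLAG")
    return ClinicalReport(
        sample_id=msi.sample_id,
        qc=qc,
        decision=decision,
        msi=msi,
        reported_variants=reported,
        ls_risk=ls_risk,
        ici_eligible=ici,
        anti_egfr_contraindicated=anti_egfr,
        narrative_codes=tuple(narrative),
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _qc_dict(qc: QcVerdict) -> dict:
    d = dataclasses.asdict(qc)
    d["reasons"] = list(qc.reasons)
    if math.isinf(d["depth_ratio"]):
        d["depth_ratio"] = "inf"
    return d


def report_to_json(report: ClinicalReport) -> str:
    d = {
        "report_format": 1,
        "sample_id": report.sample_id,
        "pipeline_version": report.pipeline_version,
        "qc": _qc_dict(report.qc),
        "decision": dataclasses.asdict(report.decision),
        "msi": dataclasses.asdict(report.msi),
        "reported_variants": [dataclasses.asdict(v) for v in report.reported_variants],
        "flags": {
            "ls_risk": report.ls_risk,
            "ici_eligible": report.ici_eligible,
            "anti_egfr_contraindicated": report.anti_egfr_contraindicated,
        },
        "narrative_codes": list(report.narrative_codes),
    }
    return json.dumps(d, indent=2, sort_keys=True)


def report_from_json(text: str) -> ClinicalReport:
    d = json.loads(text)
    if d.get("report_format") != 1:
        raise ValueError(f"unsupported report_format {d.get('report_format')!r}")
    qc_d = dict(d["qc"])
    if qc_d["depth_ratio"] == "inf":
        qc_d["depth_ratio"] = math.inf
    qc_d["reasons"] = tuple(qc_d["reasons"])
    msi_d = dict(d["msi"])
    msi_d["markers_used"] = tuple(msi_d["markers_used"])
    msi_d["markers_excluded"] = tuple(msi_d["markers_excluded"])
    return ClinicalReport(
        sample_id=d["sample_id"],
        qc=QcVerdict(**qc_d),
        decision=RepeatDecision(**d["decision"]),
        msi=MsiResult(**msi_d),
        reported_variants=tuple(VariantCall(**v) for v in d["reported_variants"]),
        ls_risk=d["flags"]["ls_risk"],
        ici_eligible=d["flags"]["ici_eligible"],
        anti_egfr_contraindicated=d["flags"]["anti_egfr_contraindicated"],
        narrative_codes=tuple(d["narrative_codes"]),
        pipeline_version=d["pipeline_version"],
    )


def render_text(report: ClinicalReport) -> str:
    """Human-readable rendering of a clinical report."""
    lines = [
        f"MSI-Plus report — sample {report.sample_id} (pipeline {report.pipeline_version})",
        f"QC: {'PASS' if report.qc.passed else 'FAIL'}"
        + (f" ({'; '.join(report.qc.reasons)})" if report.qc.reasons else ""),
        f"  median MSI marker depth: {report.qc.median_msi_depth:g}",
        f"  minimum hotspot depth:   {report.qc.min_hotspot_depth_observed}",
        f"  hotspot/marker depth ratio: {report.qc.depth_ratio:.2f}"
        + ("  ** salvage: dilute or purify before repeat **" if report.qc.salvage_flag else ""),
    ]
    if report.msi.score is not None:
        lines.append(f"MSI score: {report.msi.score:+.2f} ({report.msi.status})")
    else:
        lines.append("MSI score: unscorable (no marker with sufficient reads)")
    lines.append(f"Decision: {report.decision.kind}"
                 + (f" ({report.decision.status})" if report.decision.status else ""))
    if report.reported_variants:
        lines.append("Reported variants:")
        for v in report.reported_variants:
            lines.append(
                f"  {v.position_id} {v.substitution}  VAF {v.vaf:.3f}  depth {v.depth}"
            )
    else:
        lines.append("Reported variants: none")
    lines.append(
        "Recommendations: "
        f"LS risk={'yes' if report.ls_risk else 'no'}; "
        f"ICI eligible={'yes' if report.ici_eligible else 'no'}; "
        f"anti-EGFR contraindicated={'yes' if report.anti_egfr_contraindicated else 'no'}"
    )
    if report.narrative_codes:
        lines.append("Codes: " + ", ".join(report.narrative_codes))
    return "\n".join(lines) + "\n"


def write_report(report: ClinicalReport, path: Union[str, Path]) -> None:
    Path(path).write_text(report_to_json(report) + "\n", encoding="utf-8")
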