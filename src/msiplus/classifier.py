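"""Naive Bayes MSI classification from per-marker deletion features.

The MSI score of a test sample is the decadic log of the posterior odds that
the sample is MSI-H versus MSS:

    score = log10[ P(MSI-H | data) / P(MSS | data) ]

under a naive Bayes model.  Each usable marker contributes two features —
the deletion allele frequency (fraction of spanning reads carrying a net
deletion in the repeat tract) and the deletion allelic bias (share of
deletion reads on the single modal deletion length) — modelled as
class-conditional Beta distributions fitted by method of moments on a
training cohort of known MSI-H and MSS tumours.  Class priors default to
0.15 (MSI-H) and 0.85 (MSS).  Markers with fewer than 50 reads are excluded
from scoring.  A positive score classifies the sample MSI-H, a negative
score MSS, and a score of zero is inconclusive.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy import stats

from .counts import MarkerCount, SampleCounts
from .panel import Panel

__all__ = [
    "MarkerFeatures",
    "MarkerClassModel",
    "TrainedClassifier",
    "MsiResult",
    "TrainingError",
    "marker_features",
    "fit_beta_moments",
    "train",
    "msi_score",
    "classify",
    "save_classifier",
    "load_classifier",
]

CLASSES = ("MSI-H", "MSS")

DEFAULT_PRIOR_MSIH = 0.15
DEFAULT_PRIOR_MSS = 0.85
DEFAULT_MIN_READS = 50
DEFAULT_CLAMP_EPS = 1e-4
DEFAULT_VARIANCE_FLOOR = 1e-6
DEFAULT_INCONCLUSIVE_EPS = 1e-9

CLASSIFIER_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Raised when a training cohort cannot support a model fit."""


@dataclass(frozen=True)
class MarkerFeatures:
    """Scoring features extracted from one marker's length spectrum."""

    marker_id: str
    n_reads: int
    deletion_af: float | None
    allelic_bias: float | None
    excluded: bool


@dataclass(frozen=True)
class MarkerClassModel:
    """Class-conditional Beta models for one marker.

    ``af_beta[c]`` are the (alpha, beta) shapes of the deletion-AF model for
    class ``c``; ``bias_beta[c]`` may be absent when the class contributed
    too few deletion-bearing samples to fit the bias feature.
    """

    marker_id: str
    af_beta: dict[str, tuple[float, float]]
    bias_beta: dict[str, tuple[float, float]]
    n_train: dict[str, int]


@dataclass
class TrainedClassifier:
    panel_name: str
    models: dict[str, MarkerClassModel]
    prior_msih: float = DEFAULT_PRIOR_MSIH
    prior_mss: float = DEFAULT_PRIOR_MSS
    min_reads: int = DEFAULT_MIN_READS
    clamp_eps: float = DEFAULT_CLAMP_EPS
    inconclusive_eps: float = DEFAULT_INCONCLUSIVE_EPS

    def __post_init__(self) -> None:
        if not math.isclose(self.prior_msih + self.prior_mss, 1.0):
            raise ValueError("class priors must sum to 1")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass(frozen=True)
class MsiResult:
    """MSI score and status for one sample.

    ``score`` is the decadic-log posterior odds MSI-H : MSS, or ``None``
    when no marker was usable (``status == "unscorable"``).
    """

    sample_id: str
    score: float | None
    status: str
    markers_used: tuple[str, ...]
    markers_excluded: tuple[str, ...]


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def marker_features(count: MarkerCount, min_reads: int = DEFAULT_MIN_READS) -> MarkerFeatures:
    """Extract (deletion AF, allelic bias) from one marker's spectrum.

    Markers with fewer than ``min_reads`` total reads are excluded from MSI
    scoring.  The allelic bias is the share of deletion reads on the single
    most frequent deletion length; it is undefined (``None``) when the
    marker has no deletion reads.
    """
    total = count.total_reads
    if total < min_reads:
        return MarkerFeatures(count.marker_id, total, None, None, excluded=True)
    del_counts = {k: c for k, c in count.length_spectrum.items() if k < 0}
    n_del = sum(del_counts.values())
    deletion_af = n_del / total
    bias = max(del_counts.values()) / n_del if n_del > 0 else None
    return MarkerFeatures(count.marker_id, total, deletion_af, bias, excluded=False)


def _clamp(x: float, eps: float) -> float:
    return min(max(x, eps), 1.0 - eps)


# ---------------------------------------------------------------------------
# Beta fitting
# ---------------------------------------------------------------------------

def fit_beta_moments(
    values: Sequence[float],
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> tuple[float, float]:
    """Method-of-moments Beta fit of proportions.

    With sample mean m and variance v (unbiased, floored at
    ``variance_floor`` so degenerate training sets still yield a proper
    density): s = m(1-m)/v - 1, alpha = m*s, beta = (1-m)*s.  Input values
    are clamped into [clamp_eps, 1 - clamp_eps] first.
    """
    if len(values) < 2:
        raise TrainingError("need at least 2 values to fit a Beta distribution")
    x = np.clip(np.asarray(values, dtype=float), clamp_eps, 1.0 - clamp_eps)
    m = float(x.mean())
    v = max(float(x.var(ddof=1)), variance_floor)
    # a proper Beta requires v < m(1-m); cap v just below that bound
    v = min(v, 0.999 * m * (1.0 - m))
    s = m * (1.0 - m) / v - 1.0
    alpha, beta = m * s, (1.0 - m) * s
    assert alpha > 0 and beta > 0
    return alpha, beta


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    cohort: Sequence[SampleCounts],
    labels: Mapping[str, str],
    panel: Panel,
    min_reads: int = DEFAULT_MIN_READS,
    prior_msih: float = DEFAULT_PRIOR_MSIH,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> TrainedClassifier:
    """Fit per-marker class-conditional Beta models from a labelled cohort.

    Every cohort sample must carry a label in {"MSI-H", "MSS"}.  For each
    marker and class, the deletion-AF Beta is fitted on the non-excluded
    feature values; the bias Beta on the non-missing bias values.  A marker
    is dropped from the model (with a warning) when either class has fewer
    than two usable AF values; a class-specific bias model is dropped the
    same way, in which case the bias feature is simply uninformative for
    that marker.
    """
    import logging

    logger = logging.getLogger(__name__)

    for sample in cohort:
        if sample.sample_id not in labels:
            raise TrainingError(f"sample {sample.sample_id!r} has no label")
        lab = labels[sample.sample_id]
        if lab not in CLASSES:
            raise TrainingError(
                f"sample {sample.sample_id!r}: label {lab!r} not in {CLASSES}"
            )
    by_class = {c: [s for s in cohort if labels[s.sample_id] == c] for c in CLASSES}
    for c, members in by_class.items():
        if len(members) < 2:
            raise TrainingError(f"class {c} has {len(members)} sample(s); need >= 2")

    models: dict[str, MarkerClassModel] = {}
    for marker_id in panel.marker_ids:
        af_vals: dict[str, list[float]] = {c: [] for c in CLASSES}
        bias_vals: dict[str, list[float]] = {c: [] for c in CLASSES}
        for c, members in by_class.items():
            for sample in members:
                mc = sample.marker_counts.get(marker_id)
                if mc is None:
                    continue
                feats = marker_features(mc, min_reads)
                if feats.excluded:
                    continue
                af_vals[c].append(feats.deletion_af)
                if feats.allelic_bias is not None:
                    bias_vals[c].append(feats.allelic_bias)
        if any(len(af_vals[c]) < 2 for c in CLASSES):
            logger.warning(
                "marker %s dropped from classifier: fewer than 2 usable "
                "training samples in a class", marker_id,
            )
            continue
        af_beta = {
            c: fit_beta_moments(af_vals[c], variance_floor, clamp_eps) for c in CLASSES
        }
        bias_beta = {
            c: fit_beta_moments(bias_vals[c], variance_floor, clamp_eps)
            for c in CLASSES
            if len(bias_vals[c]) >= 2
        }
        models[marker_id] = MarkerClassModel(
            marker_id=marker_id,
            af_beta=af_beta,
            bias_beta=bias_beta,
            n_train={c: len(af_vals[c]) for c in CLASSES},
        )
    if not models:
        raise TrainingError("no marker had enough usable training data")
    return TrainedClassifier(
        panel_name=panel.name,
        models=models,
        prior_msih=prior_msih,
        prior_mss=1.0 - prior_msih,
        min_reads=min_reads,
        clamp_eps=clamp_eps,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

_LN10 = math.log(10.0)


def _marker_loglik(
    feats: MarkerFeatures, model: MarkerClassModel, cls: str, clamp_eps: float
) -> float:
    """Natural-log likelihood of one marker's features under one class."""
    a, b = model.af_beta[cls]
    ll = stats.beta.logpdf(_clamp(feats.deletion_af, clamp_eps), a, b)
    if feats.allelic_bias is not None and cls in model.bias_beta:
        a2, b2 = model.bias_beta[cls]
        ll += stats.beta.logpdf(_clamp(feats.allelic_bias, clamp_eps), a2, b2)
    return float(ll)


def msi_score(sample: SampleCounts, clf: TrainedClassifier) -> MsiResult:
    """Score one sample: decadic-log posterior odds MSI-H : MSS.

    Likelihoods multiply naively across usable markers; the computation is
    done entirely in log space.  Markers below the read threshold (or
    absent from the trained model) are listed in ``markers_excluded``; with
    zero usable markers the sample is unscorable.
    """
    if sample.panel_name != clf.panel_name:
        raise ValueError(
            f"sample panel {sample.panel_name!r} does not match "
            f"classifier panel {clf.panel_name!r}"
        )
    used: list[str] = []
    excluded: list[str] = []
    log_ratio = math.log(clf.prior_msih) - math.log(clf.prior_mss)
    for marker_id in sorted(sample.marker_counts):
        mc = sample.marker_counts[marker_id]
        model = clf.models.get(marker_id)
        feats = marker_features(mc, clf.min_reads)
        if feats.excluded or model is None:
            excluded.append(marker_id)
            continue
        log_ratio += _marker_loglik(feats, model, "MSI-H", clf.clamp_eps)
        log_ratio -= _marker_loglik(feats, model, "MSS", clf.clamp_eps)
        used.append(marker_id)
    if not used:
        return MsiResult(sample.sample_id, None, "unscorable", (), tuple(excluded))
    score = log_ratio / _LN10
    return MsiResult(
        sample.sample_id,
        score,
        classify(score, clf.inconclusive_eps),
        tuple(used),
        tuple(excluded),
    )


def classify(score: float | None, inconclusive_eps: float = DEFAULT_INCONCLUSIVE_EPS) -> str:
    """Sign-based status: positive score MSI-H, negative MSS, zero inconclusive."""
    if score is None:
        return "unscorable"
    if score > inconclusive_eps:
        return "MSI-H"
    if score < -inconclusive_eps:
        return "MSS"
    return "inconclusive"


# ---------------------------------------------------------------------------
# Persistence (classifier_format: 1)
# ---------------------------------------------------------------------------

def save_classifier(clf: TrainedClassifier, path: Union[str, Path]) -> None:
    buf = io.StringIO()
    buf.write(f"classifier_format: {CLASSIFIER_FORMAT_VERSION}\n")
    buf.write(f"panel_name: {clf.panel_name}\n")
    buf.write(f"prior_msih: {clf.prior_msih!r}\n")
    buf.write(f"min_reads: {clf.min_reads}\n")
    buf.write(f"clamp_eps: {clf.clamp_eps!r}\n")
    buf.write(f"inconclusive_eps: {clf.inconclusive_eps!r}\n")
    for marker_id in sorted(clf.models):
        m = clf.models[marker_id]
        buf.write(f"\n[model {marker_id}]\n")
        for c in CLASSES:
            a, b = m.af_beta[c]
            buf.write(f"af_{c} = {a!r} {b!r}\n")
            if c in m.bias_beta:
                a2, b2 = m.bias_beta[c]
                buf.write(f"bias_{c} = {a2!r} {b2!r}\n")
            buf.write(f"n_train_{c} = {m.n_train[c]}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def load_classifier(path: Union[str, Path]) -> TrainedClassifier:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: dict[str, str] = {}
    sections: list[tuple[str, dict[str, str]]] = []
    current: dict[str, str] | None = None
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[model ") and line.endswith("]"):
            current = {}
            sections.append((line[len("[model "):-1], current))
        elif current is None:
            k, v = line.split(":", 1)
            header[k.strip()] = v.strip()
        else:
            k, v = line.split("=", 1)
            current[k.strip()] = v.strip()
    if header.get("classifier_format") != str(CLASSIFIER_FORMAT_VERSION):
        raise ValueError(
            f"unsupported classifier_format {header.get('classifier_format')!r}"
        )
    models: dict[str, MarkerClassModel] = {}
    for marker_id, fields in sections:
        af_beta, bias_beta, n_train = {}, {}, {}
        for c in CLASSES:
            a, b = fields[f"af_{c}"].split()
            af_beta[c] = (float(a), float(b))
            if f"bias_{c}" in fields:
                a2, b2 = fields[f"bias_{c}"].split()
                bias_beta[c] = (float(a2), float(b2))
            n_train[c] = int(fields[f"n_train_{c}"])
        models[marker_id] = MarkerClassModel(marker_id, af_beta, bias_beta, n_train)
    prior_msih = float(header["prior_msih"])
    return TrainedClassifier(
        panel_name=header["panel_name"],
        models=models,
        prior_msih=prior_msih,
        prior_mss=1.0 - prior_msih,
        min_reads=int(header["min_reads"]),
        clamp_eps=float(header["clamp_eps"]),
        inconclusive_eps=float(header["inconclusive_eps"]),
    )
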