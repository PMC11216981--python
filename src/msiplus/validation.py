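"""End-to-end validation studies: the experiments that characterise the
assay's analytical performance, run on synthetic data.

Each function regenerates its inputs from a seed and runs the relevant
pipeline stages from scratch:

* training-cohort recovery (sensitivity/specificity of re-scoring the
  cohort the classifier was trained on),
* reference-standard calling and observed-vs-expected VAF correlation,
* the read-depth downsampling FP/FN study,
* the tumour-content detection limit on mixture series,
* repeat-assay MSI-score reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .classifier import TrainedClassifier, msi_score, train
from .hotspots import DownsampleErrorRow, call_variants, downsampling_study
from .panel import Panel
from .synth import (
    GeneratorParams,
    draw_latents,
    realise_counts,
    simulate_cohort,
    simulate_mixture_series,
    simulate_reference_standard,
)

__all__ = [
    "training_recovery",
    "reference_standard_triplicate",
    "downsampling_error",
    "tumour_content_limit",
    "repeat_reproducibility",
]


def training_recovery(
    panel: Panel,
    params: GeneratorParams = GeneratorParams(),
    n_msih: int = 50,
    n_mss: int = 50,
    seed: int = 1,
) -> tuple[float, float, TrainedClassifier]:
    """Train on a synthetic cohort and re-score it.

    Returns (sensitivity, specificity, classifier): sensitivity is the
    fraction of MSI-H training samples with score > 0, specificity the
    fraction of MSS training samples with score < 0.
    """
    cohort, labels = simulate_cohort(n_msih, n_mss, panel, params, seed=seed)
    clf = train(cohort, labels, panel)
    tp = fp = 0
    for sample in cohort:
        result = msi_score(sample, clf)
        if labels[sample.sample_id] == "MSI-H":
            tp += result.score is not None and result.score > 0
        else:
            fp += result.score is not None and result.score < 0
    return tp / n_msih, fp / n_mss, clf


def reference_standard_triplicate(
    panel: Panel,
    params: GeneratorParams = GeneratorParams(),
    seeds: Sequence[int] = (21, 22, 23),
) -> tuple[list[int], float]:
    """Assay the synthetic reference standard in replicate.

    Returns the number of called variants per replicate and the Pearson
    correlation between observed and expected VAF over the injected
    variants pooled across replicates (7 variants x replicates points).
    """
    n_called: list[int] = []
    observed: list[float] = []
    expected: list[float] = []
    for seed in seeds:
        sample, truth = simulate_reference_standard(panel, params, rng=seed)
        calls = call_variants(sample, panel)
        n_called.append(sum(c.called for c in calls))
        truth_subs = {
            (pid, sub): vaf for pid, d in truth.items() for sub, vaf in d.items()
        }
        for c in calls:
            key = (c.position_id, c.substitution)
            if key in truth_subs:
                observed.append(c.vaf)
                expected.append(truth_subs[key])
    r = float(_sps.pearsonr(observed, expected)[0])
    return n_called, r


@dataclass(frozen=True)
class DownsamplingSummary:
    fn_rate: float
    fp_rate: float
    fn_events: int
    fp_events: int
    replicate_rows: tuple[tuple[DownsampleErrorRow, ...], ...]


def downsampling_error(
    panel: Panel,
    params: GeneratorParams = GeneratorParams(),
    n_replicates: int = 3,
    n_sims: int = 1000,
    depths: Sequence[int] = tuple(range(50, 401, 50)),
    aggregate_min_depth: int = 250,
    seed: int = 11,
) -> DownsamplingSummary:
    """Pooled FP/FN rates at depths >= 250 over replicate parent assays.

    Each replicate simulates a fresh reference-standard parent at ~2500x
    and runs the downsampling study on it; FP and FN event counts are
    pooled across replicates over the aggregate depths.
    """
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    fn = fn_n = fp = fp_n = 0
    all_rows: list[tuple[DownsampleErrorRow, ...]] = []
    agg_depths = [d for d in depths if d >= aggregate_min_depth]
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sample, truth = simulate_reference_standard(panel, params, rng=rng)
        rows = downsampling_study(
            sample, panel, truth,
            depths=depths, n_sims=n_sims,
            aggregate_min_depth=aggregate_min_depth,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        all_rows.append(tuple(rows))
        agg = rows[-1]
        n_truth_pos_05 = sum(
            1 for d in truth.values() for v in d.values() if v == 0.05
        )
        n_truth_neg = 3 * len(panel.hotspots) - sum(len(d) for d in truth.values())
        rep_fn_n = n_truth_pos_05 * len(agg_depths) * n_sims
        rep_fp_n = n_truth_neg * len(agg_depths) * n_sims
        fn += round(agg.fn_rate * rep_fn_n)
        fp += round(agg.fp_rate * rep_fp_n)
        fn_n += rep_fn_n
        fp_n += rep_fp_n
    return DownsamplingSummary(
        fn_rate=fn / fn_n,
        fp_rate=fp / fp_n,
        fn_events=fn_n,
        fp_events=fp_n,
        replicate_rows=tuple(all_rows),
    )


def tumour_content_limit(
    clf: TrainedClassifier,
    panel: Panel,
    params: GeneratorParams = GeneratorParams(),
    fractions: Sequence[float] = (0.025, 0.05, 0.10, 0.20, 0.40),
    reps: int = 50,
    seed: int = 3,
) -> tuple[float | None, dict[float, int]]:
    """Smallest mixture fraction at which every replicate scores MSI-H.

    Returns (limit_fraction or None, per-fraction MSI-H replicate counts).
    """
    mixtures = simulate_mixture_series(list(fractions), reps, panel, params, seed=seed)
    hits: dict[float, int] = {f: 0 for f in fractions}
    for mx in mixtures:
        result = msi_score(mx.sample, clf)
        hits[mx.tumour_fraction] += result.status == "MSI-H"
    for f in sorted(fractions):
        if hits[f] == reps:
            return f, hits
    return None, hits


def repeat_reproducibility(
    clf: TrainedClassifier,
    panel: Panel,
    params: GeneratorParams = GeneratorParams(),
    n_msih: int = 6,
    n_mss: int = 19,
    seed: int = 5,
) -> tuple[float, list[tuple[float, float]]]:
    """Pearson r between MSI scores of original and repeat assays.

    Fixes per-specimen latent parameters, draws two independent count
    realisations per specimen, scores both, and correlates the score pairs.
    """
    root = np.random.SeedSequence(seed)
    latent_streams = root.spawn(n_msih + n_mss)
    pairs: list[tuple[float, float]] = []
    for i, ss in enumerate(latent_streams):
        rng = np.random.default_rng(ss)
        label = "MSI-H" if i < n_msih else "MSS"
        tf = float(rng.uniform(0.3, 0.9)) if label == "MSI-H" else 0.0
        latents = draw_latents(f"REP{i:02d}", label, panel, params, rng, tf)
        scores = []
        for assay in (1, 2):
            assay_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(1000 + i, assay))
            )
            counts = realise_counts(latents, panel, params, assay_rng)
            scores.append(msi_score(counts, clf).score)
        pairs.append((scores[0], scores[1]))
    r = float(_sps.pearsonr([a for a, _ in pairs], [b for _, b in pairs])[0])
    return r, pairs
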