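import math

import numpy as np
import pytest
from scipy import stats

from msiplus.classifier import (
    MarkerClassModel,
    TrainedClassifier,
    TrainingError,
    classify,
    fit_beta_moments,
    load_classifier,
    marker_features,
    msi_score,
    save_classifier,
    train,
)
from msiplus.counts import MarkerCount, SampleCounts
from msiplus.synth import simulate_cohort

PRIOR_RATIO = math.log10(0.15 / 0.85)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def test_marker_below_read_threshold_is_excluded():
    mc = MarkerCount("m", {0: 40, -1: 9})  # 49 reads, one short of the gate
    f = marker_features(mc, min_reads=50)
    assert f.excluded and f.deletion_af is None
    f50 = marker_features(MarkerCount("m", {0: 40, -1: 10}), min_reads=50)
    assert not f50.excluded


def test_deletion_af_and_modal_bias_arithmetic():
    f = marker_features(MarkerCount("m", {-1: 20, -2: 10, 0: 70}), 50)
    assert f.deletion_af == pytest.approx(0.30)
    assert f.allelic_bias == pytest.approx(20 / 30)
    assert f.n_reads == 100


def test_no_deletion_reads_gives_zero_af_and_missing_bias():
    f = marker_features(MarkerCount("m", {0: 100}), 50)
    assert f.deletion_af == 0.0
    assert f.allelic_bias is None


def test_insertions_do_not_count_as_deletions():
    f = marker_features(MarkerCount("m", {0: 60, 2: 20, -1: 20}), 50)
    assert f.deletion_af == pytest.approx(0.20)


# ---------------------------------------------------------------------------
# Beta fitting
# ---------------------------------------------------------------------------

def test_beta_moments_closed_form():
    # m = 0.4, unbiased v = 0.04 -> s = 5, alpha = 2, beta = 3
    a, b = fit_beta_moments([0.2, 0.4, 0.6])
    assert a == pytest.approx(2.0)
    assert b == pytest.approx(3.0)


def test_beta_moments_matches_moments_on_random_inputs(rng):
    vals = rng.uniform(0.05, 0.95, size=30)
    a, b = fit_beta_moments(list(vals))
    assert a / (a + b) == pytest.approx(vals.mean(), abs=1e-9)
    assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(
        vals.var(ddof=1), rel=1e-6
    )


def test_beta_moments_degenerate_and_boundary_inputs():
    a, b = fit_beta_moments([0.3, 0.3, 0.3])  # variance floor engages
    assert a > 0 and b > 0 and np.isfinite([a, b]).all()
    a0, b0 = fit_beta_moments([0.0, 0.5])  # 0.0 clamped before fitting
    assert a0 > 0 and b0 > 0
    with pytest.raises(TrainingError):
        fit_beta_moments([0.5])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def test_train_rejects_unknown_label(panel):
    cohort, labels = simulate_cohort(2, 2, panel, seed=7)
    labels[cohort[0].sample_id] = "MSI-LOW"
    with pytest.raises(TrainingError, match=cohort[0].sample_id):
        train(cohort, labels, panel)


def test_train_rejects_insufficient_class(panel):
    cohort, labels = simulate_cohort(1, 3, panel, seed=7)
    with pytest.raises(TrainingError, match="MSI-H"):
        train(cohort, labels, panel)


def test_training_separates_class_means(panel, trained):
    # fitted MSI-H deletion-AF mean exceeds the MSS mean at every marker
    for m in trained.models.values():
        mean = {c: ab[0] / (ab[0] + ab[1]) for c, ab in m.af_beta.items()}
        assert mean["MSI-H"] > mean["MSS"]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _toy_classifier(panel_name, marker_models):
    return TrainedClassifier(panel_name=panel_name, models=marker_models)


def _model(mid, af_h, af_s, bias_h=None, bias_s=None):
    bias = {}
    if bias_h is not None:
        bias["MSI-H"] = bias_h
    if bias_s is not None:
        bias["MSS"] = bias_s
    return MarkerClassModel(mid, {"MSI-H": af_h, "MSS": af_s}, bias,
                            {"MSI-H": 10, "MSS": 10})


def _sample(panel_name, spectra):
    s = SampleCounts("T1", panel_name)
    for mid, spec in spectra.items():
        s.marker_counts[mid] = MarkerCount(mid, spec)
    return s


def test_identical_class_models_recover_prior_ratio(panel):
    models = {
        mid: _model(mid, (2.0, 8.0), (2.0, 8.0), (5.0, 2.0), (5.0, 2.0))
        for mid in list(panel.marker_ids)[:3]
    }
    clf = _toy_classifier(panel.name, models)
    s = _sample(panel.name, {mid: {0: 80, -1: 15, -2: 5} for mid in models})
    res = msi_score(s, clf)
    assert res.score == pytest.approx(PRIOR_RATIO, abs=1e-12)


def test_score_matches_brute_force_oracle(panel, rng):
    """Naive Bayes score equals direct density evaluation on small instances."""
    for _ in range(25):
        n_markers = rng.integers(1, 4)
        mids = list(panel.marker_ids)[: n_markers]
        models, spectra = {}, {}
        for mid in mids:
            models[mid] = _model(
                mid,
                tuple(rng.uniform(0.5, 8.0, 2)),
                tuple(rng.uniform(0.5, 8.0, 2)),
                tuple(rng.uniform(0.5, 8.0, 2)),
                tuple(rng.uniform(0.5, 8.0, 2)),
            )
            nd = int(rng.integers(0, 60))
            n1 = int(rng.integers(0, nd + 1))
            spectra[mid] = {0: 100 - nd, -1: n1, -2: nd - n1}
        clf = _toy_classifier(panel.name, models)
        res = msi_score(_sample(panel.name, spectra), clf)

        # independent oracle: direct product of Beta densities, no logs
        num, den = 0.15, 0.85
        for mid in mids:
            f = marker_features(MarkerCount(mid, spectra[mid]), 50)
            af = min(max(f.deletion_af, 1e-4), 1 - 1e-4)
            num *= stats.beta.pdf(af, *models[mid].af_beta["MSI-H"])
            den *= stats.beta.pdf(af, *models[mid].af_beta["MSS"])
            if f.allelic_bias is not None:
                bias = min(max(f.allelic_bias, 1e-4), 1 - 1e-4)
                num *= stats.beta.pdf(bias, *models[mid].bias_beta["MSI-H"])
                den *= stats.beta.pdf(bias, *models[mid].bias_beta["MSS"])
        assert res.score == pytest.approx(math.log10(num / den), abs=1e-9)


def test_all_markers_below_threshold_is_unscorable(panel, trained):
    s = _sample(panel.name, {mid: {0: 30, -1: 10} for mid in panel.marker_ids})
    res = msi_score(s, trained)
    assert res.status == "unscorable" and res.score is None
    assert set(res.markers_excluded) == set(panel.marker_ids)
    assert classify(None) == "unscorable"


def test_score_invariant_to_marker_order_and_count_scaling(panel, trained):
    spectra = {mid: {0: 90, -1: 8, -2: 2} for mid in panel.marker_ids}
    s1 = _sample(panel.name, spectra)
    s2 = _sample(panel.name, dict(reversed(list(spectra.items()))))
    s3 = _sample(
        panel.name, {m: {k: 10 * v for k, v in sp.items()} for m, sp in spectra.items()}
    )
    r1, r2, r3 = (msi_score(s, trained) for s in (s1, s2, s3))
    assert r1.score == pytest.approx(r2.score, abs=1e-12)
    assert r1.score == pytest.approx(r3.score, abs=1e-12)


def test_score_monotone_in_deletion_af_under_dominance(panel, trained):
    """Raising a marker's deletion AF never lowers the score when the MSI-H
    AF model stochastically dominates the MSS one."""
    for mid, model in trained.models.items():
        ah, bh = model.af_beta["MSI-H"]
        as_, bs = model.af_beta["MSS"]
        if not (ah >= as_ and bh <= bs):  # sufficient dominance condition
            continue
        scores = []
        for k in range(50, 951, 100):
            s = _sample(panel.name, {mid: {0: 1000 - k, -1: k}})
            scores.append(msi_score(s, trained).score)
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))


def test_panel_mismatch_rejected(panel, trained):
    s = _sample("other_panel", {"MSI01": {0: 100}})
    with pytest.raises(ValueError, match="panel"):
        msi_score(s, trained)


# ---------------------------------------------------------------------------
# Status thresholds
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "score, status",
    [(-3.1, "MSS"), (0.0, "inconclusive"), (8.2, "MSI-H"),
     (1e-12, "inconclusive"), (-1e-12, "inconclusive"), (1e-6, "MSI-H")],
)
def test_classify_sign_rule(score, status):
    assert classify(score) == status


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def test_classifier_save_load_round_trip(panel, trained, tmp_path):
    path = tmp_path / "clf.txt"
    save_classifier(trained, path)
    back = load_classifier(path)
    assert back.panel_name == trained.panel_name
    assert back.models == trained.models
    assert back.prior_msih == trained.prior_msih
    cohort, _ = simulate_cohort(1, 1, panel, seed=55)
    for s in cohort:
        assert msi_score(s, back).score == pytest.approx(
            msi_score(s, trained).score, abs=1e-12
        )
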