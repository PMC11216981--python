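import numpy as np
import pytest

from msiplus.classifier import marker_features
from msiplus.counts import HotspotCount
from msiplus.hotspots import call_variants
from msiplus.synth import (
    GeneratorParams,
    MixtureSpec,
    draw_latents,
    estimate_purity_from_snps,
    marker_background_rates,
    realise_counts,
    simulate_cohort,
    simulate_mixture_series,
    simulate_reference_standard,
    simulate_sample,
)


def test_same_seed_reproduces_identical_counts(panel, params):
    a, _ = simulate_sample("X", "MSI-H", panel, params, rng=7, tumour_fraction=0.5)
    b, _ = simulate_sample("X", "MSI-H", panel, params, rng=7, tumour_fraction=0.5)
    assert a == b
    c, _ = simulate_sample("X", "MSI-H", panel, params, rng=8, tumour_fraction=0.5)
    assert a != c


def test_background_rates_are_a_fixed_marker_property(panel, params):
    r1 = marker_background_rates(panel, params)
    r2 = marker_background_rates(panel, params)
    assert r1 == r2
    assert all(0.0 < v < 0.2 for v in r1.values())
    # rates differ across markers (drawn from the across-marker Beta)
    assert len(set(r1.values())) == len(r1)


def test_zero_tumour_fraction_matches_mss_in_law(panel, params):
    bg = marker_background_rates(panel, params)
    lat = draw_latents("X", "MSI-H", panel, params, np.random.default_rng(3),
                       tumour_fraction=0.0)
    assert lat.del_prob == bg
    assert all(b == params.mss_bias_mean for b in lat.bias.values())


def test_pure_tumour_deletion_af_in_clonal_range(panel, params):
    s, lat = simulate_sample("X", "MSI-H", panel, params, rng=5, tumour_fraction=1.0)
    for mid in panel.marker_ids:
        f = marker_features(s.marker_counts[mid], 50)
        assert 0.45 <= f.deletion_af <= 0.95  # U[0.5, 0.9] up to sampling noise


def test_expected_deletion_af_is_affine_in_tumour_fraction(panel, params):
    def mean_af(frac, n=30):
        streams = np.random.SeedSequence(17).spawn(n)
        vals = []
        for ss in streams:
            rng = np.random.default_rng(ss)
            s, _ = simulate_sample("X", "MSI-H", panel, params, rng,
                                   tumour_fraction=frac)
            vals.append(np.mean([
                marker_features(s.marker_counts[m], 50).deletion_af
                for m in panel.marker_ids
            ]))
        return float(np.mean(vals))

    lo, mid, hi = mean_af(0.0), mean_af(0.5), mean_af(1.0)
    assert mid == pytest.approx((lo + hi) / 2, abs=0.02)


def test_cohort_sizes_labels_and_errors(panel, params):
    samples, labels = simulate_cohort(3, 4, panel, params, seed=9)
    assert len(samples) == 7
    assert sorted(labels.values()).count("MSI-H") == 3
    with pytest.raises(ValueError):
        simulate_cohort(0, 0, panel, params)


def test_mixture_tracer_alt_fraction_tracks_content(panel, params):
    mixtures = simulate_mixture_series([0.4], 30, panel, params, seed=12)
    fracs = []
    for mx in mixtures:
        for tid, tc in mx.tracers.items():
            fracs.append(tc.base_counts[mx.tracer_alt[tid]] / tc.depth)
    # expected alt fraction = 0.4 * 0.5 = 0.20
    assert np.mean(fracs) == pytest.approx(0.20, abs=0.01)


@pytest.mark.parametrize(
    "alt_fracs, expected",
    [((0.25, 0.25), 0.50), ((0.0, 0.0), 0.0), ((0.20, 0.30), 0.50)],
)
def test_purity_estimator_examples(alt_fracs, expected):
    tracers, alts = {}, {}
    for i, f in enumerate(alt_fracs):
        depth = 1000
        tid = f"rs{i}"
        tracers[tid] = HotspotCount(
            tid, {"A": int(f * depth), "C": 0, "G": depth - int(f * depth), "T": 0}
        )
        alts[tid] = "A"
    assert estimate_purity_from_snps(tracers, alts) == pytest.approx(expected)


def test_purity_estimator_recovers_truth_within_binomial_error(panel, params):
    spec = MixtureSpec()
    true_frac = 0.6
    mixtures = simulate_mixture_series([true_frac], 20, panel, params, spec, seed=4)
    for mx in mixtures:
        est = estimate_purity_from_snps(mx.tracers, mx.tracer_alt,
                                        spec.expected_pure_fraction)
        depth = min(t.depth for t in mx.tracers.values())
        se = np.sqrt(0.3 * 0.7 / depth) / 0.5 / np.sqrt(2)
        assert abs(est - true_frac) < 3 * se + 1e-9


def test_purity_estimator_requires_covered_tracer():
    with pytest.raises(ValueError, match="tracer"):
        estimate_purity_from_snps({"rs1": HotspotCount("rs1")}, {"rs1": "A"})


def test_reference_standard_calls_exactly_seven_variants(panel, params):
    sample, truth = simulate_reference_standard(panel, params, rng=1)
    calls = call_variants(sample, panel)
    called = [c for c in calls if c.called]
    assert len(called) == 7
    truth_subs = {(p, s) for p, d in truth.items() for s in d}
    assert {(c.position_id, c.substitution) for c in called} == truth_subs
    # the four detection-limit variants sit near VAF 0.05
    low = [c for c in called
           if truth[c.position_id][c.substitution] == 0.05]
    assert len(low) == 4
    assert all(abs(c.vaf - 0.05) <= 0.02 for c in low)
    # background error never reaches the reporting threshold
    assert all(not c.reported for c in calls
               if (c.position_id, c.substitution) not in truth_subs)


def test_params_validation():
    with pytest.raises(ValueError):
        GeneratorParams(mss_af_mean=1.5)
    with pytest.raises(ValueError):
        MixtureSpec(tumour_fraction=1.2)


def test_latents_fixed_realisations_vary(panel, params):
    lat = draw_latents("X", "MSI-H", panel, params, np.random.default_rng(2), 0.5)
    c1 = realise_counts(lat, panel, params, np.random.default_rng(10))
    c2 = realise_counts(lat, panel, params, np.random.default_rng(11))
    assert c1 != c2  # new assay, new reads
    afs1 = [marker_features(c1.marker_counts[m], 50).deletion_af
            for m in panel.marker_ids]
    afs2 = [marker_features(c2.marker_counts[m], 50).deletion_af
            for m in panel.marker_ids]
    # but the same specimen: per-marker AFs agree closely
    assert np.allclose(afs1, afs2, atol=0.05)
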