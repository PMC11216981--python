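"""Synthetic count generation with the statistical structure the classifier
and caller assume.

Each synthetic sample is generated in two stages that can be separated by
the caller:

1. *latent parameters* — per-marker deletion probability and allelic bias
   for the underlying tumour/normal mixture (biology of the specimen);
2. *count realisation* — read depths and multinomial read draws (a single
   assay of that specimen).

Repeat assays of the same specimen re-run stage 2 with fresh randomness on
fixed latents.  MSS samples show only background polymerase-stutter
deletions, at a fixed per-marker rate (around 5%) that is a property of
the repeat tract and chemistry rather than of the specimen; MSI-H tumour
cells carry clonal deletions at 50-90% allele fraction per marker, diluted
by the sample's tumour-cell fraction.  Hotspot positions see a small substitution error
rate per non-reference base, plus any injected true variants.  Mixture
series carry two tracer SNPs heterozygous in the tumour line and absent
from normal DNA, from which tumour content can be estimated.  A Tru-Q-like
multi-variant reference standard (seven injected hotspot variants, four at
5% VAF) exercises the caller's detection limits.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .counts import HotspotCount, MarkerCount, SampleCounts
from .panel import Panel

__all__ = [
    "GeneratorParams",
    "MixtureSpec",
    "MixtureSample",
    "SampleLatents",
    "TRACER_SNP_IDS",
    "marker_background_rates",
    "draw_latents",
    "realise_counts",
    "simulate_sample",
    "simulate_cohort",
    "simulate_mixture_series",
    "estimate_purity_from_snps",
    "simulate_reference_standard",
]

_BASES = ("A", "C", "G", "T")

#: the two tracer SNPs used for empirical tumour-content estimation
TRACER_SNP_IDS = ("rs2283006", "rs7905384")

#: deletion lengths modelled in synthetic spectra (modal length -1)
_DEL_LENGTHS = (-1, -2, -3)


@dataclass(frozen=True)
class GeneratorParams:
    """Defaults describe the study conditions the pipeline is validated under.

    The background deletion (polymerase stutter) rate is a fixed per-marker
    property of the synthetic assay — stutter depends on the repeat tract
    and the PCR chemistry, not on the specimen — drawn once per marker from
    a Beta with mean ``mss_af_mean`` and concentration
    ``mss_af_concentration`` (reproducibly from the marker id; see
    :func:`marker_background_rates`).  The MSI-H tumour-cell deletion
    allele fraction is Uniform[``msih_af_low``, ``msih_af_high``], drawn
    per marker per sample.  The allelic bias (modal-length share of the
    deletion read mass) is ``mss_bias_mean`` for stutter and
    ``msih_bias_mean`` for clonal tumour deletions; a mixture's bias is
    the deletion-mass-weighted combination of the two.  Read depths are
    log-normal around a 2500x target.  Each non-reference base at a
    hotspot carries a background substitution error VAF of 3e-4.
    """

    mss_af_mean: float = 0.05
    mss_af_concentration: float = 100.0
    msih_af_low: float = 0.5
    msih_af_high: float = 0.9
    mss_bias_mean: float = 0.5
    msih_bias_mean: float = 0.9
    marker_depth_median: float = 2500.0
    marker_depth_sigma: float = 0.25
    hotspot_depth_median: float = 2500.0
    hotspot_depth_sigma: float = 0.25
    background_error_vaf: float = 3e-4

    def __post_init__(self) -> None:
        for name in ("mss_af_mean", "msih_af_low", "msih_af_high",
                     "mss_bias_mean", "msih_bias_mean", "background_error_vaf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.marker_depth_median < 1 or self.hotspot_depth_median < 1:
            raise ValueError("depth medians must be >= 1")


@dataclass(frozen=True)
class MixtureSpec:
    """Tumour-line / normal mixture with tracer SNPs.

    The tracer SNPs are heterozygous in the tumour line and absent from the
    normal DNA, so a pure tumour sample shows them at allele fraction
    ``expected_pure_fraction`` (0.5).
    """

    tumour_fraction: float = 1.0
    tracer_ids: tuple[str, ...] = TRACER_SNP_IDS
    expected_pure_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumour_fraction <= 1.0:
            raise ValueError("tumour_fraction must be in [0, 1]")
        if not 0.0 < self.expected_pure_fraction <= 1.0:
            raise ValueError("expected_pure_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SampleLatents:
    """Per-specimen latent parameters, fixed across repeat assays."""

    sample_id: str
    label: str
    tumour_fraction: float
    del_prob: dict[str, float]  # marker_id -> observed deletion probability
    bias: dict[str, float]      # marker_id -> modal-length share of deletions


@dataclass(frozen=True)
class MixtureSample:
    sample: SampleCounts
    tracers: dict[str, HotspotCount]
    tracer_alt: dict[str, str]
    tumour_fraction: float


def _as_rng(seed_or_rng: Union[int, np.random.Generator, np.random.SeedSequence]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _depth(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(round(rng.lognormal(math.log(median), sigma))))


def marker_background_rates(panel: Panel, params: GeneratorParams) -> dict[str, float]:
    """Fixed per-marker background stutter deletion rates.

    Each marker's rate is a Beta(mean, concentration) draw seeded from a
    CRC32 of the marker id, so rates are a reproducible property of the
    synthetic assay — identical across samples, cohorts and user seeds —
    while still spreading realistically across markers.
    """
    a = params.mss_af_mean * params.mss_af_concentration
    b = (1.0 - params.mss_af_mean) * params.mss_af_concentration
    rates = {}
    for marker_id in panel.marker_ids:
        rng = np.random.default_rng(
            np.random.SeedSequence(zlib.crc32(marker_id.encode()))
        )
        rates[marker_id] = float(rng.beta(a, b))
    return rates


# ---------------------------------------------------------------------------
# Latents and realisation
# ---------------------------------------------------------------------------

def draw_latents(
    sample_id: str,
    label: str,
    panel: Panel,
    params: GeneratorParams,
    rng,
    tumour_fraction: float = 1.0,
) -> SampleLatents:
    """Draw per-marker latent deletion probabilities and biases.

    For an MSI-H specimen at tumour fraction t, the observed deletion
    probability at a marker is t * af_tumour + (1 - t) * background, with
    af_tumour ~ Uniform[0.5, 0.9]; the allelic bias is the deletion-mass-
    weighted mixture of the clonal (0.9) and stutter (0.5) bias means.  MSS
    specimens show background stutter only.
    """
    if label not in ("MSI-H", "MSS"):
        raise ValueError(f"label must be MSI-H or MSS, got {label!r}")
    rng = _as_rng(rng)
    background = marker_background_rates(panel, params)
    del_prob: dict[str, float] = {}
    bias: dict[str, float] = {}
    for marker_id in panel.marker_ids:
        bg = background[marker_id]
        if label == "MSI-H":
            t = tumour_fraction
            af_tum = float(rng.uniform(params.msih_af_low, params.msih_af_high))
            p = t * af_tum + (1.0 - t) * bg
            # modal-length share of the mixed deletion mass: clonal tumour
            # deletions carry bias msih_bias_mean, stutter mss_bias_mean
            b = (
                (t * af_tum * params.msih_bias_mean
                 + (1.0 - t) * bg * params.mss_bias_mean) / p
                if p > 0 else params.mss_bias_mean
            )
        else:
            p, b = bg, params.mss_bias_mean
        del_prob[marker_id] = p
        bias[marker_id] = b
    return SampleLatents(sample_id, label, tumour_fraction, del_prob, bias)


def realise_counts(
    latents: SampleLatents,
    panel: Panel,
    params: GeneratorParams,
    rng,
    variants: Mapping[str, Mapping[str, float]] | None = None,
) -> SampleCounts:
    """Draw one assay's read counts from fixed latent parameters.

    ``variants`` optionally maps position_id -> {alt_base: expected VAF} of
    true hotspot variants to inject on top of the background error rate.
    """
    rng = _as_rng(rng)
    sample = SampleCounts(latents.sample_id, panel.name)
    for marker_id in panel.marker_ids:
        depth = _depth(rng, params.marker_depth_median, params.marker_depth_sigma)
        p, b = latents.del_prob[marker_id], latents.bias[marker_id]
        # modal deletion length -1 carries share b of the deletion mass,
        # the remaining mass splits evenly over -2 and -3
        probs = [1.0 - p, p * b, p * (1.0 - b) / 2.0, p * (1.0 - b) / 2.0]
        draw = rng.multinomial(depth, probs)
        spectrum = {0: int(draw[0])}
        for i, length in enumerate(_DEL_LENGTHS):
            if draw[i + 1]:
                spectrum[length] = int(draw[i + 1])
        sample.marker_counts[marker_id] = MarkerCount(marker_id, spectrum)
    variants = variants or {}
    for hs in panel.hotspots:
        depth = _depth(rng, params.hotspot_depth_median, params.hotspot_depth_sigma)
        injected = variants.get(hs.position_id, {})
        probs = []
        for base in _BASES:
            if base == hs.ref_base:
                probs.append(0.0)  # remainder, filled below
            else:
                probs.append(params.background_error_vaf + injected.get(base, 0.0))
        ref_i = _BASES.index(hs.ref_base)
        probs[ref_i] = 1.0 - sum(probs)
        draw = rng.multinomial(depth, probs)
        sample.hotspot_counts[hs.position_id] = HotspotCount(
            hs.position_id, {b: int(draw[i]) for i, b in enumerate(_BASES)}
        )
    return sample


def simulate_sample(
    sample_id: str,
    label: str,
    panel: Panel,
    params: GeneratorParams,
    rng,
    tumour_fraction: float = 1.0,
    variants: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[SampleCounts, SampleLatents]:
    """Draw latents then counts; returns (counts, truth latents)."""
    rng = _as_rng(rng)
    latents = draw_latents(sample_id, label, panel, params, rng, tumour_fraction)
    return realise_counts(latents, panel, params, rng, variants), latents


# ---------------------------------------------------------------------------
# Cohorts, mixtures, reference standard
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_msih: int,
    n_mss: int,
    panel: Panel,
    params: GeneratorParams = GeneratorParams(),
    seed: int = 0,
    msih_tumour_fraction_range: tuple[float, float] = (0.3, 0.9),
) -> tuple[list[SampleCounts], dict[str, str]]:
    """Simulate an independent labelled cohort.

    MSI-H samples draw a tumour-cell fraction uniformly from
    ``msih_tumour_fraction_range`` (clinical specimens vary in tumour
    content); MSS samples have no tumour deletion signal.  Each sample uses
    an independent substream of the master seed.
    """
    if n_msih + n_mss == 0:
        raise ValueError("cohort must contain at least one sample")
    if n_msih < 0 or n_mss < 0:
        raise ValueError("cohort sizes must be non-negative")
    labels_seq = ["MSI-H"] * n_msih + ["MSS"] * n_mss
    streams = np.random.SeedSequence(seed).spawn(len(labels_seq))
    samples: list[SampleCounts] = []
    labels: dict[str, str] = {}
    for i, (label, ss) in enumerate(zip(labels_seq, streams)):
        rng = np.random.default_rng(ss)
        tf = (
            float(rng.uniform(*msih_tumour_fraction_range))
            if label == "MSI-H" else 0.0
        )
        sid = f"SYN{i:04d}_{'H' if label == 'MSI-H' else 'S'}"
        counts, _ = simulate_sample(sid, label, panel, params, rng, tf)
        samples.append(counts)
        labels[sid] = label
    return samples, labels


def simulate_mixture_series(
    fractions: Sequence[float],
    reps: int,
    panel: Panel,
    params: GeneratorParams = GeneratorParams(),
    spec: MixtureSpec = MixtureSpec(),
    seed: int = 0,
) -> list[MixtureSample]:
    """Simulate tumour-line / normal DNA mixtures with tracer SNPs.

    Each sample is an MSI-H specimen at the given tumour fraction plus
    tracer-SNP counts whose expected alternate-allele fraction is
    fraction * 0.5 (heterozygous tracer alleles absent from normal DNA).
    """
    streams = np.random.SeedSequence(seed).spawn(len(fractions) * max(reps, 1))
    out: list[MixtureSample] = []
    k = 0
    for frac in fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"tumour fraction {frac} outside [0, 1]")
        for rep in range(reps):
            rng = np.random.default_rng(streams[k])
            k += 1
            sid = f"MIX_f{frac:g}_r{rep:02d}"
            counts, _ = simulate_sample(sid, "MSI-H", panel, params, rng, frac)
            tracers: dict[str, HotspotCount] = {}
            tracer_alt: dict[str, str] = {}
            for tid in spec.tracer_ids:
                depth = _depth(rng, params.hotspot_depth_median,
                               params.hotspot_depth_sigma)
                p_alt = frac * spec.expected_pure_fraction
                n_alt = int(rng.binomial(depth, p_alt))
                tracers[tid] = HotspotCount(
                    tid, {"A": n_alt, "C": 0, "G": depth - n_alt, "T": 0}
                )
                tracer_alt[tid] = "A"
            out.append(MixtureSample(counts, tracers, tracer_alt, frac))
    return out


def estimate_purity_from_snps(
    tracers: Mapping[str, HotspotCount],
    tracer_alt: Mapping[str, str],
    expected_pure_fraction: float = 0.5,
) -> float:
    """Estimate tumour content from tracer-SNP allele fractions.

    Purity = mean over tracers of (observed alt fraction / expected
    pure-line fraction), clipped to [0, 1].  Tracers with zero depth are
    skipped; all-zero depth is an error.
    """
    ratios = []
    for tid, hc in tracers.items():
        if hc.depth == 0:
            continue
        alt = hc.base_counts.get(tracer_alt[tid], 0)
        ratios.append((alt / hc.depth) / expected_pure_fraction)
    if not ratios:
        raise ValueError("no tracer SNP with non-zero depth")
    return float(np.clip(np.mean(ratios), 0.0, 1.0))


#: injected variants of the synthetic multi-variant reference standard:
#: seven hotspot substitutions, four at the 5% detection-limit tier
#: (identities and the non-5% levels are documented placeholder choices).
REFERENCE_STANDARD_VARIANTS: dict[str, tuple[str, float]] = {
    "KRAS_c.35": ("A", 0.05),
    "KRAS_c.38": ("A", 0.05),
    "KRAS_c.183": ("C", 0.05),
    "NRAS_c.35": ("A", 0.05),
    "BRAF_c.1799": ("A", 0.10),
    "NRAS_c.181": ("A", 0.20),
    "KRAS_c.436": ("A", 0.30),
}


def simulate_reference_standard(
    panel: Panel,
    params: GeneratorParams = GeneratorParams(),
    rng: Union[int, np.random.Generator] = 0,
    variants: Mapping[str, tuple[str, float]] | None = None,
) -> tuple[SampleCounts, dict[str, dict[str, float]]]:
    """Simulate a Tru-Q-like multi-variant control sample.

    Injects seven hotspot substitutions (four at 5% VAF, the rest at 10,
    20 and 30%) over microsatellite-stable marker counts and background
    substitution error; returns the counts and a truth map
    position_id -> {"REF>ALT": expected VAF}.
    """
    rng = _as_rng(rng)
    variants = dict(variants) if variants is not None else dict(REFERENCE_STANDARD_VARIANTS)
    injected = {pid: {alt: vaf} for pid, (alt, vaf) in variants.items()}
    counts, _ = simulate_sample(
        "REF_STANDARD", "MSS", panel, params, rng, 0.0, variants=injected
    )
    truth = {
        pid: {f"{panel.hotspot(pid).ref_base}>{alt}": vaf}
        for pid, (alt, vaf) in variants.items()
    }
    return counts, truth
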