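# Methods

This note documents the models, defaults and design choices behind
`msiplus`, in the spirit of a statistical-methods appendix: what is
computed, under which assumptions, and what the synthetic validation does
and does not demonstrate.

## MSI classification model

A sample's MSI status is inferred from 14 mononucleotide-repeat markers by
a naïve Bayes model over two per-marker features:

* **deletion allele frequency** `d_m` — reads whose net indel length
  inside the repeat tract is negative, divided by all tract-spanning
  reads. Only reads covering the tract plus one anchoring base on each
  side are counted (partial overlaps would truncate the spectrum);
  insertions and substitutions do not count towards `d_m`.
* **deletion allelic bias** `b_m` — the share of deletion reads carrying
  the single most frequent (modal) deletion length. Clonal tumour
  deletions concentrate on one length (high bias); polymerase stutter is
  dispersed (low bias). `b_m` is undefined when a marker has no deletion
  reads, in which case it contributes no likelihood term — absence of
  deletions is already fully expressed through `d_m`, so a missing bias is
  treated as uninformative rather than penalised.

For each marker and class *c* ∈ {MSI-H, MSS}, training fits Beta densities
to the observed features by method of moments: with sample mean *m* and
unbiased variance *v*, `s = m(1−m)/v − 1`, `α = ms`, `β = (1−m)s`.
Proportions are clamped to `[1e-4, 1 − 1e-4]` before fitting and scoring
(Beta densities are degenerate at the boundary), the variance is floored at
`1e-6` so a degenerate training column still yields a proper density, and
`v` is capped just below `m(1−m)` (the Beta feasibility bound). Markers
with fewer than 2 usable training values in either class are dropped from
the model with a warning; a class-specific bias model missing for the same
reason simply silences the bias term for that class pair.

Scoring multiplies likelihoods naively across markers (and across the two
features within a marker), entirely in log space:

```
score = log10(0.15/0.85) + Σ_m [ log10 f_H(d_m) − log10 f_S(d_m)
                               + log10 g_H(b_m) − log10 g_S(b_m) ]
```

Markers with fewer than 50 reads are excluded from the sum; with zero
usable markers the sample is *unscorable*. Score > 0 ⇒ MSI-H, < 0 ⇒ MSS;
"score = 0 is inconclusive" is implemented as |score| ≤ 1e-9 (an exact
floating-point zero is fragile; any |score| below this is far inside the
repeat-testing band anyway, so the tolerance has no clinical effect). The
Beta family was chosen because both features are proportions; it keeps the
model two-parameter per feature and makes the score reproducible by direct
density evaluation, which the test suite exploits as an independent oracle.

Two closed-form consequences are used as correctness anchors: when the two
classes share identical per-marker models the score equals
log₁₀(0.15/0.85) ≈ −0.753 exactly, and on any small instance the score
matches brute-force evaluation of the posterior ratio to 1e-9.

## Hotspot calling and the downsampling study

VAF is variant reads over total covering reads. The validated operating
point is **call at VAF ≥ 0.01 with ≥250 reads**, **report at VAF ≥ 0.04**;
both comparisons are inclusive. Reported ⊆ called by construction.

The downsampling study measures calling error versus depth. Each hotspot
of a deeply sequenced parent sample is resampled to a target depth by a
multinomial draw over the parent's five category frequencies (A/C/G/T/
other) — the count-level equivalent of resampling reads with replacement,
and depth-flexible. Per target depth (50–400x in steps of 50, 1000
simulations each):

* FP rate — fraction of (simulation × truth-negative substitution) events
  with VAF ≥ 0.01;
* FN rate — fraction of (simulation × truth-positive substitution with
  expected VAF 0.05) events with VAF < 0.01;
* vaf_sd — standard deviation of (observed − expected) VAF over all
  truth-positive events.

An aggregate row pools depths {250, 300, 350, 400}. Randomness derives
from a single master seed with an independent substream per depth, so
studies are reproducible and parallelisable. Because the parent is itself
a finite assay (~2500x), its realised background frequencies fluctuate
around the generator's 3×10⁻⁴ error rate; this parent-sampling tail is the
dominant source of run-to-run spread in the aggregate FP rate and is a
genuine feature of downsampling real assays, not an artefact.

## Synthetic data generator

The generator emulates the study conditions the pipeline is validated
under, at the count level (no read-level simulation):

| parameter | default | meaning |
|---|---|---|
| `mss_af_mean`, `mss_af_concentration` | 0.05, 100 | across-marker Beta for background stutter deletion rates |
| `msih_af_low..high` | 0.5–0.9 | per-marker, per-sample tumour-cell deletion allele fraction (uniform) |
| `mss_bias_mean`, `msih_bias_mean` | 0.5, 0.9 | modal-length share of stutter vs clonal deletion mass |
| `marker/hotspot_depth_median`, `sigma` | 2500, 0.25 | log-normal read depths around the 2000–3000x target |
| `background_error_vaf` | 3×10⁻⁴ | per non-ref base substitution error at hotspots |

Background stutter is modelled as a **fixed per-marker property**: each
marker's rate is one Beta(mean 0.05, concentration 100) draw seeded
reproducibly from the marker id. Stutter depends on the repeat tract and
the PCR chemistry, not on the specimen, so specimens differ at a marker
only through read sampling. Deletion lengths are restricted to
{−1, −2, −3} with modal length −1: sufficient to exercise both features
without modelling stutter physics.

A specimen is two-staged: *latents* (per-marker deletion probability and
bias — the biology) then *realisation* (depths and multinomial read draws —
one assay). Repeat assays redraw stage two on fixed latents. An MSI-H
specimen at tumour fraction *t* has per-marker deletion probability
`t·a + (1−t)·bg` with `a ~ U[0.5, 0.9]`, and bias equal to the
deletion-mass-weighted share `(t·a·0.9 + (1−t)·bg·0.5)/(t·a + (1−t)·bg)` —
the exact modal share of the mixed spectrum, which reduces to the MSS law
at *t* = 0 and the clonal value at *t* = 1. Cohort MSI-H samples draw
`t ~ U[0.3, 0.9]` (clinical specimens vary in tumour content; referral
requires ≥20%).

Mixture series add two tracer SNPs (heterozygous in the tumour line,
absent from normal DNA) with expected alternate fraction `t/2`; the purity
estimator inverts this as the mean over tracers of (observed alt
fraction)/0.5, clipped to [0, 1]. The synthetic reference standard injects
seven hotspot substitutions — four at VAF 0.05 (the detection-limit tier)
and one each at 0.10/0.20/0.30 — over microsatellite-stable marker counts;
the identities and the non-0.05 levels are documented placeholders chosen
from the default panel.

**What the generator does not model:** FFPE fragmentation and deamination
artefacts, per-sample stutter-rate variation from DNA quality, PCR
competition between amplicons, strand effects, and realistic stutter
length spectra. Synthetic class separation is therefore cleaner than
clinical data — MSI scores reach thousands where clinical scores span
roughly ±40 — so passing the synthetic validation demonstrates the
*correctness of the computations and decision rules*, not clinical
sensitivity/specificity, which require accredited validation on tissue.

## QC, repeat policy, reporting

QC gates: median MSI-marker depth ≥100 and ≥250 reads at every hotspot.
The hotspot/marker median depth ratio (∞ when the marker median is 0)
flags selective inhibition of marker amplification at ≥5: such samples are
diluted or bead-purified before repeat testing. The ratio flag is
independent of pass/fail. QC pass is monotone in depth: adding reads never
flips pass to fail.

Repeat policy: "between 5 and −5" is the **open** interval (−5, 5) —
boundary scores are accepted without repeat (the boundary convention is
undocumented in the service description; inclusive acceptance was chosen
and is configurable). Concordance means identical sign-based status, not
numeric closeness; a discordant or inconclusive repeat is a terminal QC
failure. An unscorable first result is likewise a QC failure.

Report flags are a pure function of (final status, reported variant set,
QC decision): LS risk = MSI-H without reported BRAF p.V600E; ICI
eligibility = MSI-H; anti-EGFR contraindication = any reported *KRAS*/
*NRAS* variant or BRAF p.V600E (including V600E alongside *RAS* is the
clinically standard rule; it is a documented, configurable choice). Only
*reported* (VAF ≥ 0.04) variants drive flags, so a low-frequency call
cannot deny a patient germline testing or therapy. On QC failure all flags
are withheld.

## Validation studies and problem sizes

`msiplus.validation` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) re-runs the analytical validation end-to-end:

* training recovery — 50 MSI-H + 50 MSS synthetic cohort, trained and
  re-scored (expected 100%/100% at these noise levels);
* reference standard — triplicate assays, exactly 7 calls each, Pearson r
  between observed and expected VAF over the 21 points;
* downsampling — 3 replicate parents × 8 depths × 1000 simulations,
  FP/FN pooled over depths ≥250;
* tumour-content limit — mixtures at {2.5, 5, 10, 20, 40}% × 50
  replicates, smallest fraction with every replicate MSI-H (10% under
  defaults: 5% mixtures fail, 10% mixtures all score positive);
* reproducibility — 25 specimens (6 MSI-H, 19 MSS), two independent
  realisations each, Pearson r between score pairs.

These sizes run in seconds while keeping Monte-Carlo error well inside
the asserted tolerances. All seeds derive from a single master seed via
`numpy` `SeedSequence` substreams.

## Known limitations

* The default panel's marker/hotspot identities and coordinates are
  representative placeholders; deploying labs must supply their production
  panel config.
* The KRAS c.37G>A artefact signature shipped with the default panel is a
  placeholder; the definitive chimera sequence is laboratory-specific.
* The classifier extrapolates poorly below the tumour-content range seen
  in training (a property of tight class-conditional densities); mixtures
  below ~10% content score MSS rather than borderline.
* Alignment ingestion assumes well-formed CIGARs against the panel's
  reference coordinates and skips MAPQ-0 reads by default (configurable);
  it does not deduplicate reads.
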