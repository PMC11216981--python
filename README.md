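# msiplus

Analysis pipeline for a one-step multiplex PCR, amplicon-sequencing
colorectal-cancer (CRC) test that combines microsatellite instability (MSI)
classification with *BRAF*/*KRAS*/*NRAS* hotspot variant calling — the two
tumour results needed for Lynch syndrome (LS) screening, immune checkpoint
inhibitor (ICI) eligibility, and anti-EGFR therapy decisions. It is written
for clinical-bioinformatics and assay-validation use: every stage, from
allele counts to the final recommendation flags, is a tested, reusable
library function, and a built-in synthetic count generator makes the whole
pipeline verifiable without patient data.

## What it computes

**MSI score (naïve Bayes).** The assay sequences 14 mononucleotide-repeat
markers to ~2500x. For each marker *m* with ≥50 reads, two features are
extracted from the indel-length spectrum: the deletion allele frequency
*d<sub>m</sub>* (fraction of tract-spanning reads with a net deletion) and
the deletion allelic bias *b<sub>m</sub>* (share of deletion reads on the
single modal deletion length — high for clonal tumour deletions, low for
dispersed polymerase stutter). A training cohort of known MSI-H and MSS
tumours fixes class-conditional Beta densities per marker (method-of-moments
fit), and a test sample's MSI score is the decadic-log posterior odds

> score = log₁₀ [ P(MSI-H | d, b) / P(MSS | d, b) ]
> = log₁₀ (0.15/0.85) + Σ<sub>m</sub> log₁₀ [ f<sub>H</sub>(d<sub>m</sub>) g<sub>H</sub>(b<sub>m</sub>) / f<sub>S</sub>(d<sub>m</sub>) g<sub>S</sub>(b<sub>m</sub>) ]

with priors 0.15 (MSI-H) and 0.85 (MSS). Score > 0 ⇒ MSI-H, score < 0 ⇒
MSS, score = 0 ⇒ inconclusive.

**Hotspot variants.** At each of 22 *BRAF*/*KRAS*/*NRAS* hotspot positions,
VAF = variant reads / total reads. A substitution is *called* when
VAF ≥ 0.01 with ≥250 reads, and *reported* clinically only when VAF ≥ 0.04.
A multinomial read-downsampling study quantifies false-positive /
false-negative calling rates versus depth (50–400x, 1000 simulations per
depth).

**QC and reporting.** Samples pass QC with median MSI-marker depth ≥100 and
≥250 reads per hotspot; a hotspot/marker depth ratio ≥5 flags the sample
for dilution or purification before repeat testing. Scores inside (−5, 5)
require a repeat assay (accepted if concordant, QC-failed if discordant).
The report sets three flags: **LS risk** (MSI-H and no reported BRAF
p.V600E), **ICI eligible** (MSI-H), and **anti-EGFR contraindicated**
(reported *RAS* variant or BRAF p.V600E).

The shipped default panel uses representative marker identities and
hg19-style coordinates (the true production panel is laboratory-specific);
the documented panel-config format lets a lab substitute its own.

## Worked example

Simulate a training cohort, train the classifier, and report one sample:

```sh
msiplus simulate --n-msih 50 --n-mss 50 --seed 1 --out-dir train
msiplus train train/labels.tsv train/*.counts.tsv --out clf.txt
msiplus simulate --n-msih 2 --n-mss 2 --seed 42 --out-dir cohort
msiplus report cohort/SYN0000_H.counts.tsv --classifier clf.txt
```

prints

```
MSI-Plus report — sample SYN0000_H (pipeline 0.1.0)
QC: PASS
  median MSI marker depth: 2662.5
  minimum hotspot depth:   1660
  hotspot/marker depth ratio: 0.99
MSI score: +13469.31 (MSI-H)
Decision: accept (MSI-H)
Reported variants: none
Recommendations: LS risk=yes; ICI eligible=yes; anti-EGFR contraindicated=no
Codes: LS_RISK_REFER_GERMLINE, ICI_ELIGIBLE
```

The sample passes both depth gates (median marker depth 2662 ≥ 100, all
hotspots ≥ 250 reads; ratio 0.99 — no salvage flag). Its MSI score is far
above the +5 repeat band, so the MSI-H classification is accepted without a
repeat; with no reported BRAF p.V600E the patient is flagged at risk of
Lynch syndrome and eligible for ICI therapy. Synthetic scores are much more
extreme than clinical ones because the generator omits FFPE noise — see
`docs/methods.md`. Other subcommands: `panel validate`,
`counts from-alignment` (SAM/BAM → counts table), `score`, `call`, `qc`,
`resolve`, `downsample-study`.

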