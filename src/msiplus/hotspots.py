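"""Hotspot variant calling and read-depth downsampling error analysis.

A substitution's variant allele frequency (VAF) is the number of reads
carrying the alternate base divided by total reads over the position.  A
variant is *called* when VAF >= 0.01 and the position is supported by >= 250
reads, thresholds validated against a multi-variant reference standard; it
is *reported* clinically only when VAF >= 0.04, to avoid acting on
low-frequency variants of uncertain relevance.

The downsampling study resamples a deeply sequenced parent sample to lower
target depths (multinomial over the parent's allele frequencies) and
measures false-positive / false-negative calling rates and VAF spread as a
function of depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .counts import HotspotCount, SampleCounts

__all__ = [
    "VariantCall",
    "DownsampleErrorRow",
    "DEFAULT_CALL_VAF",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_REPORT_VAF",
    "compute_vafs",
    "call_variants",
    "downsample_hotspot",
    "downsampling_study",
    "write_study_table",
]

DEFAULT_CALL_VAF = 0.01
DEFAULT_MIN_DEPTH = 250
DEFAULT_REPORT_VAF = 0.04

_BASES = ("A", "C", "G", "T")
_CATEGORIES = _BASES + ("OTHER",)


@dataclass(frozen=True)
class VariantCall:
    """One possible substitution at a hotspot, with call/report status."""

    position_id: str
    substitution: str  # "REF>ALT"
    vaf: float
    depth: int
    called: bool
    reported: bool


@dataclass(frozen=True)
class DownsampleErrorRow:
    """Error rates at one simulated target depth (or the >=250 aggregate)."""

    target_depth: int | None  # None for the aggregate row
    n_sims: int
    fp_rate: float
    fn_rate: float
    vaf_sd: float

    @property
    def label(self) -> str:
        return "AGG_GE250" if self.target_depth is None else str(self.target_depth)


def compute_vafs(count: HotspotCount, ref_base: str) -> dict[str, float]:
    """VAF of each non-reference substitution at one position."""
    depth = count.depth
    if depth == 0:
        raise ValueError(
            f"hotspot {count.position_id}: VAF undefined at zero depth"
        )
    return {
        f"{ref_base}>{b}": count.base_counts.get(b, 0) / depth
        for b in _BASES
        if b != ref_base
    }


def call_variants(
    sample: SampleCounts,
    panel,
    call_vaf: float = DEFAULT_CALL_VAF,
    min_depth: int = DEFAULT_MIN_DEPTH,
    report_vaf: float = DEFAULT_REPORT_VAF,
) -> list[VariantCall]:
    """Apply the call / report thresholds at every panel hotspot.

    Returns one :class:`VariantCall` per (position, non-ref base), including
    uncalled ones with ``called=False``; zero-depth positions yield three
    zero-VAF uncalled entries.
    """
    if not (0.0 < call_vaf <= 1.0 and 0.0 < report_vaf <= 1.0):
        raise ValueError("VAF thresholds must be in (0, 1]")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    calls: list[VariantCall] = []
    for hs in panel.hotspots:
        hc = sample.hotspot_counts.get(hs.position_id)
        if hc is None:
            continue
        depth = hc.depth
        if depth == 0:
            vafs = {f"{hs.ref_base}>{b}": 0.0 for b in hs.alt_bases}
        else:
            vafs = compute_vafs(hc, hs.ref_base)
        for sub, vaf in vafs.items():
            called = vaf >= call_vaf and depth >= min_depth
            calls.append(
                VariantCall(
                    position_id=hs.position_id,
                    substitution=sub,
                    vaf=vaf,
                    depth=depth,
                    called=called,
                    reported=called and vaf >= report_vaf,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def _category_probs(parent: HotspotCount) -> np.ndarray:
    counts = np.array(
        [parent.base_counts.get(b, 0) for b in _BASES] + [parent.other_count],
        dtype=float,
    )
    total = counts.sum()
    if total < 1:
        raise ValueError(f"hotspot {parent.position_id}: empty parent counts")
    return counts / total


def downsample_hotspot(
    parent: HotspotCount, target_depth: int, rng: np.random.Generator
) -> HotspotCount:
    """Resample one position to ``target_depth`` reads.

    Counts are drawn multinomially with category probabilities equal to the
    parent allele frequencies (with-replacement resampling at count level),
    so the expected frequency of every allele equals its parent frequency
    at any target depth.
    """
    if target_depth < 1:
        raise ValueError("target_depth must be >= 1")
    draw = rng.multinomial(target_depth, _category_probs(parent))
    return HotspotCount(
        position_id=parent.position_id,
        base_counts={b: int(draw[i]) for i, b in enumerate(_BASES)},
        other_count=int(draw[4]),
    )


def downsampling_study(
    sample: SampleCounts,
    panel,
    truth: Mapping[str, Mapping[str, float]],
    depths: Sequence[int] = tuple(range(50, 401, 50)),
    n_sims: int = 1000,
    call_vaf: float = DEFAULT_CALL_VAF,
    fn_expected_vaf: float = 0.05,
    aggregate_min_depth: int = 250,
    seed: int = 0,
) -> list[DownsampleErrorRow]:
    """Measure FP/FN rates and VAF spread versus simulated read depth.

    ``truth`` maps position_id -> {substitution: expected VAF} for the
    truth-positive variants; every other (position, non-ref base) pair is
    truth-negative.  Per depth, each of ``n_sims`` simulations downsamples
    every hotspot and applies the VAF call threshold:

    * FP rate: fraction of (simulation x truth-negative substitution)
      events with observed VAF >= ``call_vaf``;
    * FN rate: fraction of (simulation x truth-positive substitution with
      expected VAF == ``fn_expected_vaf``) events with VAF < ``call_vaf``;
    * vaf_sd: standard deviation of (observed - expected) VAF over all
      truth-positive events.

    Returns one row per depth plus an aggregate row pooling depths >=
    ``aggregate_min_depth``.  Randomness derives deterministically from
    ``seed`` with an independent substream per depth.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    hotspot_index = {h.position_id: h for h in panel.hotspots}
    for pid in truth:
        if pid not in hotspot_index:
            raise ValueError(f"truth position {pid!r} not in panel")

    rows: list[DownsampleErrorRow] = []
    agg = {"fp": 0, "fp_n": 0, "fn": 0, "fn_n": 0, "dev": []}
    for depth_i, depth in enumerate(depths):
        rng = np.random.default_rng(np.random.SeedSequence([seed, depth_i]))
        fp = fp_n = fn = fn_n = 0
        deviations: list[np.ndarray] = []
        for hs in panel.hotspots:
            parent = sample.hotspot_counts.get(hs.position_id)
            if parent is None or parent.depth == 0:
                continue
            probs = _category_probs(parent)
            draws = rng.multinomial(depth, probs, size=n_sims)  # (n_sims, 5)
            pos_truth = truth.get(hs.position_id, {})
            for alt_i, base in enumerate(_BASES):
                if base == hs.ref_base:
                    continue
                sub = f"{hs.ref_base}>{base}"
                vafs = draws[:, alt_i] / depth
                if sub in pos_truth:
                    expected = pos_truth[sub]
                    deviations.append(vafs - expected)
                    if expected == fn_expected_vaf:
                        fn += int(np.count_nonzero(vafs < call_vaf))
                        fn_n += n_sims
                else:
                    fp += int(np.count_nonzero(vafs >= call_vaf))
                    fp_n += n_sims
        all_dev = np.concatenate(deviations) if deviations else np.array([0.0])
        rows.append(
            DownsampleErrorRow(
                target_depth=depth,
                n_sims=n_sims,
                fp_rate=fp / fp_n if fp_n else 0.0,
                fn_rate=fn / fn_n if fn_n else 0.0,
                vaf_sd=float(all_dev.std(ddof=1)) if all_dev.size > 1 else 0.0,
            )
        )
        if depth >= aggregate_min_depth:
            agg["fp"] += fp
            agg["fp_n"] += fp_n
            agg["fn"] += fn
            agg["fn_n"] += fn_n
            agg["dev"].append(all_dev)
    if agg["dev"]:
        pooled = np.concatenate(agg["dev"])
        rows.append(
            DownsampleErrorRow(
                target_depth=None,
                n_sims=sum(r.n_sims for r in rows if r.target_depth is not None
                           and r.target_depth >= aggregate_min_depth),
                fp_rate=agg["fp"] / agg["fp_n"] if agg["fp_n"] else 0.0,
                fn_rate=agg["fn"] / agg["fn_n"] if agg["fn_n"] else 0.0,
                vaf_sd=float(pooled.std(ddof=1)),
            )
        )
    return rows


def write_study_table(rows: Sequence[DownsampleErrorRow], path: Union[str, Path]) -> None:
    """Write study rows as TSV (one row per depth plus the AGG_GE250 row)."""
    lines = ["depth\tn_sims\tfp_rate\tfn_rate\tvaf_sd"]
    for r in rows:
        lines.append(
            f"{r.label}\t{r.n_sims}\t{r.fp_rate:.6g}\t{r.fn_rate:.6g}\t{r.vaf_sd:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
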