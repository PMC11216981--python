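"""Per-sample allele counts and their production from alignments.

The canonical interchange object for the whole pipeline is the counts table:
an indel-length spectrum per MSI marker (net insertion-deletion length inside
the repeat tract, negative = deletion) and per-base read counts at each
hotspot position.  Alignment ingestion is a thin optional reader over SAM/BAM
via pysam, so the downstream classifier, caller, QC and reporting stages are
all testable without alignment files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .panel import Panel, PanelError

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerCount",
    "HotspotCount",
    "SampleCounts",
    "CountsFormatError",
    "filter_artefact_reads",
    "summarise_alignment",
    "read_counts_table",
    "write_counts_table",
]

_DNA = frozenset("ACGT")
_BASES = ("A", "C", "G", "T")

COUNTS_HEADER = "#msiplus_counts v1"


class CountsFormatError(ValueError):
    """Raised for malformed or panel-inconsistent count tables."""


@dataclass
class MarkerCount:
    """Indel-length spectrum at one MSI marker.

    ``length_spectrum`` maps net indel length in bp (negative = net deletion,
    0 = reference length, positive = net insertion) to the number of spanning
    reads observed with that length.
    """

    marker_id: str
    length_spectrum: dict[int, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.length_spectrum.values())

    @property
    def deletion_reads(self) -> int:
        return sum(c for k, c in self.length_spectrum.items() if k < 0)

    def validate(self) -> None:
        if any(c < 0 for c in self.length_spectrum.values()):
            raise CountsFormatError(f"marker {self.marker_id}: negative count")


@dataclass
class HotspotCount:
    """Base counts at one hotspot position.

    ``other_count`` holds reads aligned over the position with none of the
    four bases (e.g. a spanning deletion).
    """

    position_id: str
    base_counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(_BASES, 0))
    other_count: int = 0

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.other_count

    def validate(self) -> None:
        if set(self.base_counts) - set(_BASES):
            raise CountsFormatError(
                f"hotspot {self.position_id}: non-ACGT base key"
            )
        if self.other_count < 0 or any(c < 0 for c in self.base_counts.values()):
            raise CountsFormatError(f"hotspot {self.position_id}: negative count")


@dataclass
class SampleCounts:
    """All counts for one sample over one panel."""

    sample_id: str
    panel_name: str
    marker_counts: dict[str, MarkerCount] = field(default_factory=dict)
    hotspot_counts: dict[str, HotspotCount] = field(default_factory=dict)

    def validate(self, panel: Panel | None = None) -> None:
        for mid, mc in self.marker_counts.items():
            if mid != mc.marker_id:
                raise CountsFormatError(f"marker key {mid} != record id {mc.marker_id}")
            mc.validate()
        for pid, hc in self.hotspot_counts.items():
            if pid != hc.position_id:
                raise CountsFormatError(f"hotspot key {pid} != record id {hc.position_id}")
            hc.validate()
        if panel is not None:
            known_m = set(panel.marker_ids)
            known_h = set(panel.hotspot_ids)
            for mid in self.marker_counts:
                if mid not in known_m:
                    raise CountsFormatError(f"marker id {mid!r} not in panel {panel.name}")
            for pid in self.hotspot_counts:
                if pid not in known_h:
                    raise CountsFormatError(f"hotspot id {pid!r} not in panel {panel.name}")


# ---------------------------------------------------------------------------
# Artefact-read filtering
# ---------------------------------------------------------------------------

def _read_sequence(read) -> str:
    seq = getattr(read, "query_sequence", None)
    if seq is None:
        seq = str(read)
    return seq


def filter_artefact_reads(
    reads: Iterable, signatures: Sequence[str]
) -> tuple[list, int]:
    """Drop reads whose sequence contains any artefact signature.

    A signature is an exact-match DNA substring that identifies a PCR chimera
    (the assay's known case is a KRAS/NRAS homology artefact producing false
    KRAS c.37G>A calls).  Returns ``(retained_reads, removed_count)``.
    """
    for sig in signatures:
        if not sig or not set(sig) <= _DNA:
            raise PanelError(f"artefact signature {sig!r} is not a DNA string")
    if not signatures:
        retained = list(reads)
        return retained, 0
    retained, removed = [], 0
    for read in reads:
        seq = _read_sequence(read)
        if any(sig in seq for sig in signatures):
            removed += 1
        else:
            retained.append(read)
    return retained, removed


# ---------------------------------------------------------------------------
# Alignment summarisation
# ---------------------------------------------------------------------------

# CIGAR op codes that consume reference / query (SAM spec).
_REF_OPS = {0, 2, 3, 7, 8}    # M, D, N, =, X
_QRY_OPS = {0, 1, 4, 7, 8}    # M, I, S, =, X


def _net_indel_in_tract(read, tract_start: int, tract_end: int) -> int | None:
    """Net insertion-deletion length of one read inside a tract window.

    The read must span ``[tract_start - 1, tract_end + 1]`` (1-based,
    flanked by one anchoring base on each side); returns ``None`` otherwise.
    Walks the CIGAR: insertions anchored inside the tract add their length,
    deleted reference bases overlapping the tract subtract theirs.
    Substitutions are ignored.
    """
    ref = read.reference_start + 1  # 1-based position of next ref base
    if ref > tract_start - 1 or read.reference_end < tract_end + 1:
        return None
    net = 0
    for op, length in read.cigartuples:
        if op == 1:  # insertion, anchored between ref-1 and ref
            if tract_start <= ref <= tract_end + 1:
                net += length
        elif op in (2, 3):  # deletion / skip over [ref, ref+length-1]
            overlap = min(tract_end, ref + length - 1) - max(tract_start, ref) + 1
            if overlap > 0 and op == 2:
                net -= overlap
            ref += length
        elif op in _REF_OPS:
            ref += length
    return net


def _base_at(read, pos: int) -> str | None:
    """Aligned query base at 1-based reference position ``pos``.

    Returns the base, ``"OTHER"`` when the position falls in a deletion, or
    ``None`` when the read does not cover the position.
    """
    if read.reference_start + 1 > pos or read.reference_end < pos:
        return None
    ref = read.reference_start + 1
    q = 0
    seq = read.query_sequence
    for op, length in read.cigartuples:
        consumes_ref = op in _REF_OPS
        consumes_qry = op in _QRY_OPS
        if consumes_ref and ref <= pos < ref + length:
            if consumes_qry:
                return seq[q + (pos - ref)]
            return "OTHER"
        if consumes_ref:
            ref += length
        if consumes_qry:
            q += length
    return None


def summarise_alignment(
    reads: Union[str, Path, Iterable],
    panel: Panel,
    sample_id: str,
    min_mapping_quality: int = 1,
    apply_artefact_filter: bool = True,
) -> SampleCounts:
    """Summarise aligned reads into a :class:`SampleCounts`.

    ``reads`` may be a SAM/BAM path or an iterable of pysam
    ``AlignedSegment``.  A read contributes to a marker only when it fully
    spans the repeat tract plus one base of flank on each side; it then
    increments the spectrum key equal to its net indel length inside the
    tract.  At hotspots the aligned base at the position is counted.  Reads
    below ``min_mapping_quality`` (default: MAPQ 0 excluded) and unmapped
    reads are skipped; reads on contigs absent from the panel are skipped
    with a logged warning.
    """
    import pysam

    if isinstance(reads, (str, Path)):
        with pysam.AlignmentFile(str(reads), check_sq=False) as fh:
            return summarise_alignment(
                list(fh), panel, sample_id, min_mapping_quality, apply_artefact_filter
            )

    reads = list(reads)
    if apply_artefact_filter:
        signatures = [
            sig for amp in panel.amplicons for sig in amp.artefact_signatures
        ]
        if signatures:
            reads, removed = filter_artefact_reads(reads, signatures)
            if removed:
                logger.info("removed %d artefact read(s)", removed)

    by_chrom_markers: dict[str, list] = {}
    for m in panel.markers:
        by_chrom_markers.setdefault(m.chrom, []).append(m)
    by_chrom_hotspots: dict[str, list] = {}
    for h in panel.hotspots:
        by_chrom_hotspots.setdefault(h.chrom, []).append(h)
    known_contigs = set(by_chrom_markers) | set(by_chrom_hotspots)

    sample = SampleCounts(sample_id=sample_id, panel_name=panel.name)
    for m in panel.markers:
        sample.marker_counts[m.marker_id] = MarkerCount(m.marker_id)
    for h in panel.hotspots:
        sample.hotspot_counts[h.position_id] = HotspotCount(h.position_id)

    warned_contigs: set[str] = set()
    for read in reads:
        if read.is_unmapped or read.mapping_quality < min_mapping_quality:
            continue
        contig = read.reference_name
        if contig not in known_contigs:
            if contig not in warned_contigs:
                logger.warning("skipping reads on contig %s absent from panel", contig)
                warned_contigs.add(contig)
            continue
        for m in by_chrom_markers.get(contig, ()):
            net = _net_indel_in_tract(read, m.tract_start, m.tract_end)
            if net is not None:
                spec = sample.marker_counts[m.marker_id].length_spectrum
                spec[net] = spec.get(net, 0) + 1
        for h in by_chrom_hotspots.get(contig, ()):
            base = _base_at(read, h.pos)
            if base is None:
                continue
            hc = sample.hotspot_counts[h.position_id]
            if base in _DNA:
                hc.base_counts[base] += 1
            else:
                hc.other_count += 1
    return sample


# ---------------------------------------------------------------------------
# Counts table I/O (TSV dialect, header "#msiplus_counts v1")
# ---------------------------------------------------------------------------

def write_counts_table(sample: SampleCounts, path: Union[str, Path]) -> None:
    """Write one sample's counts in the versioned TSV dialect.

    Rows: ``M <sample> <marker> <indel_len> <count>`` and
    ``H <sample> <position> <base|OTHER> <count>``.
    """
    lines = [COUNTS_HEADER, f"#panel\t{sample.panel_name}"]
    for mid in sorted(sample.marker_counts):
        mc = sample.marker_counts[mid]
        if not mc.length_spectrum:
            # explicit zero row so a zero-depth marker survives the round trip
            lines.append(f"M\t{sample.sample_id}\t{mid}\t0\t0")
            continue
        for length in sorted(mc.length_spectrum):
            lines.append(
                f"M\t{sample.sample_id}\t{mid}\t{length}\t{mc.length_spectrum[length]}"
            )
    for pid in sorted(sample.hotspot_counts):
        hc = sample.hotspot_counts[pid]
        for base in _BASES:
            lines.append(f"H\t{sample.sample_id}\t{pid}\t{base}\t{hc.base_counts.get(base, 0)}")
        if hc.other_count:
            lines.append(f"H\t{sample.sample_id}\t{pid}\tOTHER\t{hc.other_count}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_counts_table(
    path: Union[str, Path], panel: Panel | None = None
) -> SampleCounts:
    """Read a single-sample counts table; validates against ``panel`` if given."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != COUNTS_HEADER:
        raise CountsFormatError(f"missing header line {COUNTS_HEADER!r}")
    panel_name = ""
    sample: SampleCounts | None = None
    seen_keys: set[tuple] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#panel\t"):
            panel_name = line.split("\t", 1)[1]
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise CountsFormatError(f"line {lineno}: expected 5 tab-separated fields")
        kind, sample_id, target_id, key, count_str = fields
        try:
            count = int(count_str)
        except ValueError as exc:
            raise CountsFormatError(f"line {lineno}: non-integer count {count_str!r}") from exc
        if count < 0:
            raise CountsFormatError(f"line {lineno}: negative count {count}")
        if sample is None:
            sample = SampleCounts(sample_id=sample_id, panel_name=panel_name)
        elif sample.sample_id != sample_id:
            raise CountsFormatError(
                f"line {lineno}: multiple sample ids in one table "
                f"({sample.sample_id!r} vs {sample_id!r})"
            )
        row_key = (kind, target_id, key)
        if row_key in seen_keys:
            raise CountsFormatError(f"line {lineno}: duplicate row key {row_key}")
        seen_keys.add(row_key)
        if kind == "M":
            try:
                length = int(key)
            except ValueError as exc:
                raise CountsFormatError(f"line {lineno}: bad indel length {key!r}") from exc
            mc = sample.marker_counts.setdefault(target_id, MarkerCount(target_id))
            mc.length_spectrum[length] = count
        elif kind == "H":
            if key not in _BASES and key != "OTHER":
                raise CountsFormatError(f"line {lineno}: bad base {key!r}")
            hc = sample.hotspot_counts.setdefault(target_id, HotspotCount(target_id))
            if key == "OTHER":
                hc.other_count = count
            else:
                hc.base_counts[key] = count
        else:
            raise CountsFormatError(f"line {lineno}: unknown row kind {kind!r}")
    if sample is None:
        raise CountsFormatError("counts table contains no rows")
    sample.validate(panel)
    return sample
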