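import pytest

from msiplus.counts import (
    CountsFormatError,
    HotspotCount,
    MarkerCount,
    SampleCounts,
    filter_artefact_reads,
    read_counts_table,
    summarise_alignment,
    write_counts_table,
)
from msiplus.panel import PanelError


def make_sample(panel):
    s = SampleCounts("S1", panel.name)
    s.marker_counts["MSI01"] = MarkerCount("MSI01", {0: 70, -1: 20, -2: 10})
    s.marker_counts["MSI02"] = MarkerCount("MSI02", {})  # zero-depth marker
    s.hotspot_counts["KRAS_c.35"] = HotspotCount(
        "KRAS_c.35", {"A": 10, "C": 0, "G": 990, "T": 0}
    )
    return s


# ---------------------------------------------------------------------------
# Counts table I/O
# ---------------------------------------------------------------------------

def test_counts_table_round_trip(panel, tmp_path):
    s = make_sample(panel)
    path = tmp_path / "s1.tsv"
    write_counts_table(s, path)
    back = read_counts_table(path, panel)
    assert back.sample_id == "S1"
    assert back.marker_counts["MSI01"].length_spectrum == {0: 70, -1: 20, -2: 10}
    assert back.marker_counts["MSI02"].total_reads == 0
    assert back.hotspot_counts["KRAS_c.35"].base_counts["A"] == 10
    # a second write/read cycle is bit-identical
    path2 = tmp_path / "s1b.tsv"
    write_counts_table(back, path2)
    assert path2.read_text() == path.read_text()


@pytest.mark.parametrize(
    "row, needle",
    [
        ("M\tS1\tMSI01\t-1\t-3", "negative count"),
        ("M\tS1\tMSI01\t0\t5\nM\tS1\tMSI01\t0\t5", "duplicate row"),
        ("H\tS1\tKRAS_c.35\tZ\t5", "bad base"),
        ("M\tS1\tMSI01\tx\t5", "bad indel length"),
        ("Q\tS1\tMSI01\t0\t5", "unknown row kind"),
        ("M\tS1\tMSI01\t0", "5 tab-separated fields"),
    ],
)
def test_counts_table_rejects_malformed_rows(tmp_path, row, needle):
    path = tmp_path / "bad.tsv"
    path.write_text(f"#msiplus_counts v1\n{row}\n")
    with pytest.raises(CountsFormatError, match=needle):
        read_counts_table(path)


def test_counts_table_rejects_unknown_marker_id(panel, tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("#msiplus_counts v1\nM\tS1\tNOT_A_MARKER\t0\t5\n")
    with pytest.raises(CountsFormatError, match="NOT_A_MARKER"):
        read_counts_table(path, panel)


def test_counts_table_requires_header(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("M\tS1\tMSI01\t0\t5\n")
    with pytest.raises(CountsFormatError, match="header"):
        read_counts_table(path)


# ---------------------------------------------------------------------------
# Artefact filter
# ---------------------------------------------------------------------------

def test_filter_artefact_reads_removes_exact_substring_matches():
    reads = ["ACGTACGT", "TTTTAAAA", "GGACGTGG", "CCCCCCCC"]
    kept, removed = filter_artefact_reads(reads, ["ACGT"])
    assert kept == ["TTTTAAAA", "CCCCCCCC"]
    assert removed == 2


def test_filter_artefact_reads_identity_without_signatures():
    reads = ["AAAA", "CCCC"]
    kept, removed = filter_artefact_reads(reads, [])
    assert kept == reads and removed == 0


def test_filter_artefact_reads_can_remove_everything():
    kept, removed = filter_artefact_reads(["AAA", "TAAAT"], ["AAA"])
    assert kept == [] and removed == 2


def test_filter_artefact_reads_rejects_non_dna_signature():
    with pytest.raises(PanelError, match="DNA"):
        filter_artefact_reads(["AAAA"], ["ACGX"])


# ---------------------------------------------------------------------------
# Alignment summarisation (constructed SAM)
# ---------------------------------------------------------------------------
# MSI01 tract: chr1:16215000-16215022 (23 bp); NRAS_c.34 at chr1:115258748
# (ref G).  Reads are hand-constructed so net indel lengths are known.

SAM_HEADER = (
    "@HD\tVN:1.6\tSO:coordinate\n"
    "@SQ\tSN:chr1\tLN:249250621\n"
    "@SQ\tSN:chrUn\tLN:10000\n"
)


def _sam_line(name, chrom, pos, mapq, cigar, seq):
    return f"{name}\t0\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*\n"


@pytest.fixture
def sam_path(tmp_path):
    lines = [
        # spans tract with flanks, no indel -> net 0
        _sam_line("match", "chr1", 16214990, 60, "45M", "A" * 45),
        # 2 bp deletion wholly inside the tract -> net -2
        _sam_line("del2", "chr1", 16214990, 60, "15M2D28M", "A" * 43),
        # 3 bp insertion anchored inside the tract -> net +3
        _sam_line("ins3", "chr1", 16214990, 60, "15M3I25M", "A" * 43),
        # ends inside the tract -> not counted
        _sam_line("short", "chr1", 16214990, 60, "20M", "A" * 20),
        # mapping quality 0 -> skipped
        _sam_line("mapq0", "chr1", 16214990, 0, "45M", "A" * 45),
        # contig not in the panel -> skipped with a warning
        _sam_line("offpanel", "chrUn", 100, 60, "45M", "A" * 45),
        # covers NRAS_c.34 with a T at the hotspot (offset 8 from POS)
        _sam_line("hotspotT", "chr1", 115258740, 60, "20M",
                  "AAAAAAAA" + "T" + "A" * 11),
    ]
    path = tmp_path / "reads.sam"
    path.write_text(SAM_HEADER + "".join(lines))
    return path


def test_summarise_alignment_indel_spectrum_and_hotspot_bases(panel, sam_path):
    sample = summarise_alignment(sam_path, panel, "S1")
    spec = sample.marker_counts["MSI01"].length_spectrum
    assert spec == {0: 1, -2: 1, 3: 1}
    assert sample.marker_counts["MSI01"].total_reads == 3
    hc = sample.hotspot_counts["NRAS_c.34"]
    assert hc.base_counts["T"] == 1
    assert hc.depth == 1


def test_summarise_alignment_counts_each_read_once(panel, sam_path):
    sample = summarise_alignment(sam_path, panel, "S1")
    # conservation: marker totals equal the number of retained spanning reads
    assert sum(mc.total_reads for mc in sample.marker_counts.values()) == 3
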