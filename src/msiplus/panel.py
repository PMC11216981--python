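"""Assay panel definition: MSI markers, mutation hotspot positions, amplicons.

The assay interrogates 14 mononucleotide-repeat microsatellite markers and
22 hotspot positions in *BRAF*, *KRAS*, and *NRAS*, amplified as 21 amplicons
(one per MSI marker, seven multi-position hotspot amplicons).  The shipped
default panel uses representative marker identities and hg19-style
coordinates; a laboratory deploying the assay substitutes its own panel
config file (same text format) with the true primer targets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "MsiMarker",
    "HotspotPosition",
    "Amplicon",
    "Panel",
    "PanelError",
    "load_panel",
    "validate_panel",
    "write_panel",
    "default_panel",
    "BRAF_V600E",
]

_DNA = frozenset("ACGT")

PANEL_FORMAT_VERSION = 1

#: position id and substitution of the BRAF p.V600E variant used by the
#: Lynch-syndrome triage logic (sporadic MMR-deficient CRC exclusion).
BRAF_V600E = ("BRAF_c.1799", "T>A")


class PanelError(ValueError):
    """Raised for malformed or unresolvable panel configuration."""


@dataclass(frozen=True)
class MsiMarker:
    """A mononucleotide repeat tract scored for instability.

    Coordinates are 1-based inclusive genomic positions of the repeat tract.
    """

    marker_id: str
    chrom: str
    tract_start: int
    tract_end: int
    repeat_unit: str

    @property
    def reference_tract_length(self) -> int:
        return self.tract_end - self.tract_start + 1


@dataclass(frozen=True)
class HotspotPosition:
    """A single recurrently mutated genomic position (1-based).

    The three possible substitutions at the position are implicitly the
    three non-reference bases.
    """

    position_id: str
    gene: str
    chrom: str
    pos: int
    ref_base: str
    hgvs_label: str

    @property
    def alt_bases(self) -> tuple[str, ...]:
        return tuple(b for b in "ACGT" if b != self.ref_base)


@dataclass(frozen=True)
class Amplicon:
    """A PCR amplicon covering one marker or a group of hotspot positions."""

    amplicon_id: str
    target_ids: tuple[str, ...]
    relative_primer_concentration: float = 1.0
    artefact_signatures: tuple[str, ...] = ()


@dataclass(frozen=True)
class Panel:
    name: str
    version: str
    markers: tuple[MsiMarker, ...]
    hotspots: tuple[HotspotPosition, ...]
    amplicons: tuple[Amplicon, ...]

    def marker(self, marker_id: str) -> MsiMarker:
        return self._marker_index[marker_id]

    def hotspot(self, position_id: str) -> HotspotPosition:
        return self._hotspot_index[position_id]

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(m.marker_id for m in self.markers)

    @property
    def hotspot_ids(self) -> tuple[str, ...]:
        return tuple(h.position_id for h in self.hotspots)

    @property
    def _marker_index(self) -> dict[str, MsiMarker]:
        return {m.marker_id: m for m in self.markers}

    @property
    def _hotspot_index(self) -> dict[str, HotspotPosition]:
        return {h.position_id: h for h in self.hotspots}


# ---------------------------------------------------------------------------
# Default panel
# ---------------------------------------------------------------------------

def _default_markers() -> tuple[MsiMarker, ...]:
    # Representative mononucleotide tracts (placeholder identities and
    # hg19-style coordinates); tract lengths span the 10-27 bp range typical
    # of highly unstable markers.
    spec = [
        ("MSI01", "chr1", 16_215_000, 23, "A"),
        ("MSI02", "chr2", 47_641_400, 27, "A"),
        ("MSI03", "chr2", 95_849_300, 21, "T"),
        ("MSI04", "chr4", 55_598_200, 25, "T"),
        ("MSI05", "chr6", 31_830_700, 18, "A"),
        ("MSI06", "chr7", 116_409_600, 22, "T"),
        ("MSI07", "chr8", 7_679_700, 16, "A"),
        ("MSI08", "chr9", 139_418_200, 20, "A"),
        ("MSI09", "chr11", 108_188_700, 24, "T"),
        ("MSI10", "chr13", 31_722_600, 14, "A"),
        ("MSI11", "chr14", 23_652_300, 19, "T"),
        ("MSI12", "chr15", 89_803_900, 26, "A"),
        ("MSI13", "chr17", 56_492_800, 12, "T"),
        ("MSI14", "chr19", 13_051_100, 17, "A"),
    ]
    return tuple(
        MsiMarker(mid, chrom, start, start + length - 1, unit)
        for mid, chrom, start, length, unit in spec
    )


def _default_hotspots() -> tuple[HotspotPosition, ...]:
    # BRAF codon 600; KRAS codons 12, 13, 59, 61, 117, 146; NRAS codons
    # 12, 13, 59, 61.  Coordinates are hg19-style placeholders; ref bases
    # are coding-strand conventions for the canonical substitutions.
    spec = [
        ("BRAF_c.1799", "BRAF", "chr7", 140_453_136, "T", "BRAF c.1799 (p.V600)"),
        ("KRAS_c.34", "KRAS", "chr12", 25_398_285, "G", "KRAS c.34 (p.G12)"),
        ("KRAS_c.35", "KRAS", "chr12", 25_398_284, "G", "KRAS c.35 (p.G12)"),
        ("KRAS_c.37", "KRAS", "chr12", 25_398_282, "G", "KRAS c.37 (p.G13)"),
        ("KRAS_c.38", "KRAS", "chr12", 25_398_281, "G", "KRAS c.38 (p.G13)"),
        ("KRAS_c.175", "KRAS", "chr12", 25_380_283, "G", "KRAS c.175 (p.A59)"),
        ("KRAS_c.176", "KRAS", "chr12", 25_380_282, "C", "KRAS c.176 (p.A59)"),
        ("KRAS_c.181", "KRAS", "chr12", 25_380_277, "C", "KRAS c.181 (p.Q61)"),
        ("KRAS_c.182", "KRAS", "chr12", 25_380_276, "A", "KRAS c.182 (p.Q61)"),
        ("KRAS_c.183", "KRAS", "chr12", 25_380_275, "A", "KRAS c.183 (p.Q61)"),
        ("KRAS_c.351", "KRAS", "chr12", 25_378_647, "A", "KRAS c.351 (p.K117)"),
        ("KRAS_c.436", "KRAS", "chr12", 25_378_562, "G", "KRAS c.436 (p.A146)"),
        ("KRAS_c.437", "KRAS", "chr12", 25_378_561, "C", "KRAS c.437 (p.A146)"),
        ("NRAS_c.34", "NRAS", "chr1", 115_258_748, "G", "NRAS c.34 (p.G12)"),
        ("NRAS_c.35", "NRAS", "chr1", 115_258_747, "G", "NRAS c.35 (p.G12)"),
        ("NRAS_c.37", "NRAS", "chr1", 115_258_745, "G", "NRAS c.37 (p.G13)"),
        ("NRAS_c.38", "NRAS", "chr1", 115_258_744, "G", "NRAS c.38 (p.G13)"),
        ("NRAS_c.175", "NRAS", "chr1", 115_256_536, "G", "NRAS c.175 (p.A59)"),
        ("NRAS_c.176", "NRAS", "chr1", 115_256_535, "C", "NRAS c.176 (p.A59)"),
        ("NRAS_c.181", "NRAS", "chr1", 115_256_531, "C", "NRAS c.181 (p.Q61)"),
        ("NRAS_c.182", "NRAS", "chr1", 115_256_530, "A", "NRAS c.182 (p.Q61)"),
        ("NRAS_c.183", "NRAS", "chr1", 115_256_529, "A", "NRAS c.183 (p.Q61)"),
    ]
    return tuple(HotspotPosition(*row) for row in spec)


# Placeholder for the definitive artefact sequence removed before KRAS
# codon 13 counting (a KRAS/NRAS homology PCR chimera causing false
# KRAS c.37G>A calls); the deployed sequence is lab-specific.
_KRAS_ARTEFACT_SIGNATURE = "TTGGAGCTAGTGGCGTAGGC"


def _default_amplicons(
    markers: Iterable[MsiMarker], hotspots: Iterable[HotspotPosition]
) -> tuple[Amplicon, ...]:
    amps = [
        Amplicon(f"AMP_{m.marker_id}", (m.marker_id,)) for m in markers
    ]
    groups = {
        "AMP_BRAF_600": (["BRAF_c.1799"], 1.5, ()),
        "AMP_KRAS_12_13": (
            ["KRAS_c.34", "KRAS_c.35", "KRAS_c.37", "KRAS_c.38"],
            1.0,
            (_KRAS_ARTEFACT_SIGNATURE,),
        ),
        "AMP_KRAS_59_61": (
            ["KRAS_c.175", "KRAS_c.176", "KRAS_c.181", "KRAS_c.182", "KRAS_c.183"],
            1.0,
            (),
        ),
        "AMP_KRAS_117": (["KRAS_c.351"], 1.0, ()),
        "AMP_KRAS_146": (["KRAS_c.436", "KRAS_c.437"], 1.0, ()),
        "AMP_NRAS_12_13": (
            ["NRAS_c.34", "NRAS_c.35", "NRAS_c.37", "NRAS_c.38"],
            1.0,
            (),
        ),
        "AMP_NRAS_59_61": (
            ["NRAS_c.175", "NRAS_c.176", "NRAS_c.181", "NRAS_c.182", "NRAS_c.183"],
            1.0,
            (),
        ),
    }
    for amp_id, (targets, conc, sigs) in groups.items():
        amps.append(Amplicon(amp_id, tuple(targets), conc, tuple(sigs)))
    return tuple(amps)


def default_panel() -> Panel:
    """Return the shipped default panel (14 markers, 22 hotspots, 21 amplicons)."""
    markers = _default_markers()
    hotspots = _default_hotspots()
    return Panel(
        name="msiplus_default",
        version="1.0",
        markers=markers,
        hotspots=hotspots,
        amplicons=_default_amplicons(markers, hotspots),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_panel(panel: Panel) -> list[str]:
    """Check every panel invariant; return diagnostics (empty means valid)."""
    diags: list[str] = []
    seen: set[str] = set()
    for m in panel.markers:
        if m.marker_id in seen:
            diags.append(f"marker {m.marker_id}: duplicate id")
        seen.add(m.marker_id)
        if m.tract_end < m.tract_start:
            diags.append(f"marker {m.marker_id}: inverted tract (end < start)")
        if not m.repeat_unit or not set(m.repeat_unit) <= _DNA:
            diags.append(f"marker {m.marker_id}: repeat_unit not a DNA string")
    for h in panel.hotspots:
        if h.position_id in seen:
            diags.append(f"hotspot {h.position_id}: duplicate id")
        seen.add(h.position_id)
        if h.ref_base not in _DNA:
            diags.append(f"hotspot {h.position_id}: ref_base {h.ref_base!r} not in ACGT")
        if h.pos < 1:
            diags.append(f"hotspot {h.position_id}: non-positive coordinate")
    target_ids = {m.marker_id for m in panel.markers} | {
        h.position_id for h in panel.hotspots
    }
    for a in panel.amplicons:
        if a.amplicon_id in seen:
            diags.append(f"amplicon {a.amplicon_id}: duplicate id")
        seen.add(a.amplicon_id)
        if a.relative_primer_concentration <= 0:
            diags.append(
                f"amplicon {a.amplicon_id}: non-positive primer concentration"
            )
        for t in a.target_ids:
            if t not in target_ids:
                diags.append(f"amplicon {a.amplicon_id}: unknown target {t}")
        for s in a.artefact_signatures:
            if not s or not set(s) <= _DNA:
                diags.append(
                    f"amplicon {a.amplicon_id}: artefact signature not a DNA string"
                )
    return diags


# ---------------------------------------------------------------------------
# Text config format (panel_format: 1)
# ---------------------------------------------------------------------------
#
#   panel_format: 1
#   name: <panel name>
#   version: <panel version>
#
#   [marker <id>]
#   chrom = chr1
#   tract_start = 100
#   tract_end = 120
#   repeat_unit = A
#
#   [hotspot <id>]
#   gene = KRAS
#   chrom = chr12
#   pos = 25398284
#   ref_base = G
#   hgvs = KRAS c.35 (p.G12)
#
#   [amplicon <id>]
#   targets = ID1, ID2
#   primer_concentration = 1.0
#   artefact_signatures = SEQ1, SEQ2        (optional)

_MARKER_FIELDS = {"chrom", "tract_start", "tract_end", "repeat_unit"}
_HOTSPOT_FIELDS = {"gene", "chrom", "pos", "ref_base", "hgvs"}
_AMPLICON_FIELDS = {"targets", "primer_concentration", "artefact_signatures"}


def write_panel(panel: Panel, path: Union[str, Path]) -> None:
    """Serialise a panel to the versioned text config format."""
    buf = io.StringIO()
    buf.write(f"panel_format: {PANEL_FORMAT_VERSION}\n")
    buf.write(f"name: {panel.name}\n")
    buf.write(f"version: {panel.version}\n")
    for m in panel.markers:
        buf.write(f"\n[marker {m.marker_id}]\n")
        buf.write(f"chrom = {m.chrom}\n")
        buf.write(f"tract_start = {m.tract_start}\n")
        buf.write(f"tract_end = {m.tract_end}\n")
        buf.write(f"repeat_unit = {m.repeat_unit}\n")
    for h in panel.hotspots:
        buf.write(f"\n[hotspot {h.position_id}]\n")
        buf.write(f"gene = {h.gene}\n")
        buf.write(f"chrom = {h.chrom}\n")
        buf.write(f"pos = {h.pos}\n")
        buf.write(f"ref_base = {h.ref_base}\n")
        buf.write(f"hgvs = {h.hgvs_label}\n")
    for a in panel.amplicons:
        buf.write(f"\n[amplicon {a.amplicon_id}]\n")
        buf.write(f"targets = {', '.join(a.target_ids)}\n")
        buf.write(f"primer_concentration = {a.relative_primer_concentration}\n")
        if a.artefact_signatures:
            buf.write(f"artefact_signatures = {', '.join(a.artefact_signatures)}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _parse_sections(text: str) -> tuple[dict[str, str], list[tuple[str, str, dict[str, str]]]]:
    header: dict[str, str] = {}
    sections: list[tuple[str, str, dict[str, str]]] = []
    current: dict[str, str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            parts = line[1:-1].split(None, 1)
            if len(parts) != 2:
                raise PanelError(f"line {lineno}: malformed section header {line!r}")
            kind, entity_id = parts
            if kind not in ("marker", "hotspot", "amplicon"):
                raise PanelError(f"line {lineno}: unknown section kind {kind!r}")
            current = {}
            sections.append((kind, entity_id, current))
        elif current is None:
            if ":" not in line:
                raise PanelError(f"line {lineno}: expected 'key: value' in header")
            k, v = line.split(":", 1)
            header[k.strip()] = v.strip()
        else:
            if "=" not in line:
                raise PanelError(f"line {lineno}: expected 'key = value'")
            k, v = line.split("=", 1)
            current[k.strip()] = v.strip()
    return header, sections


def _require(fields: dict[str, str], key: str, entity: str) -> str:
    if key not in fields:
        raise PanelError(f"{entity}: missing required field {key!r}")
    return fields[key]


def load_panel(source: Union[str, Path]) -> Panel:
    """Load a panel from a config file, or by built-in name.

    ``load_panel("msiplus_default")`` returns the shipped default panel.
    """
    if isinstance(source, str) and source == "msiplus_default":
        return default_panel()
    path = Path(source)
    if not path.exists():
        raise PanelError(f"unknown built-in panel or missing file: {source}")
    header, sections = _parse_sections(path.read_text(encoding="utf-8"))
    if header.get("panel_format") != str(PANEL_FORMAT_VERSION):
        raise PanelError(
            f"unsupported panel_format {header.get('panel_format')!r} "
            f"(expected {PANEL_FORMAT_VERSION})"
        )
    markers: list[MsiMarker] = []
    hotspots: list[HotspotPosition] = []
    amplicons: list[Amplicon] = []
    for kind, entity_id, fields in sections:
        entity = f"{kind} {entity_id}"
        try:
            if kind == "marker":
                unknown = set(fields) - _MARKER_FIELDS
                if unknown:
                    raise PanelError(f"{entity}: unknown field(s) {sorted(unknown)}")
                markers.append(
                    MsiMarker(
                        marker_id=entity_id,
                        chrom=_require(fields, "chrom", entity),
                        tract_start=int(_require(fields, "tract_start", entity)),
                        tract_end=int(_require(fields, "tract_end", entity)),
                        repeat_unit=_require(fields, "repeat_unit", entity),
                    )
                )
            elif kind == "hotspot":
                unknown = set(fields) - _HOTSPOT_FIELDS
                if unknown:
                    raise PanelError(f"{entity}: unknown field(s) {sorted(unknown)}")
                hotspots.append(
                    HotspotPosition(
                        position_id=entity_id,
                        gene=_require(fields, "gene", entity),
                        chrom=_require(fields, "chrom", entity),
                        pos=int(_require(fields, "pos", entity)),
                        ref_base=_require(fields, "ref_base", entity),
                        hgvs_label=_require(fields, "hgvs", entity),
                    )
                )
            else:
                unknown = set(fields) - _AMPLICON_FIELDS
                if unknown:
                    raise PanelError(f"{entity}: unknown field(s) {sorted(unknown)}")
                targets = tuple(
                    t.strip()
                    for t in _require(fields, "targets", entity).split(",")
                    if t.strip()
                )
                sigs_raw = fields.get("artefact_signatures", "")
                sigs = tuple(s.strip() for s in sigs_raw.split(",") if s.strip())
                amplicons.append(
                    Amplicon(
                        amplicon_id=entity_id,
                        target_ids=targets,
                        relative_primer_concentration=float(
                            fields.get("primer_concentration", "1.0")
                        ),
                        artefact_signatures=sigs,
                    )
                )
        except ValueError as exc:
            if isinstance(exc, PanelError):
                raise
            raise PanelError(f"{entity}: {exc}") from exc
    panel = Panel(
        name=header.get("name", path.stem),
        version=header.get("version", "0"),
        markers=tuple(markers),
        hotspots=tuple(hotspots),
        amplicons=tuple(amplicons),
    )
    diags = validate_panel(panel)
    if diags:
        raise PanelError("invalid panel: " + "; ".join(diags))
    return panel
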