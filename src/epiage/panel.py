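"""Amplicon panel model: markers, target CpG sites, and bisulfite-space references.

The panel describes a multiplex bisulfite PCR assay: eight age-informative
methylation markers whose amplicons together cover 44 CpG sites.  Genomic
coordinates are 1-based, fully closed (GRCh38); offsets into an amplicon are
0-based in sequencing orientation.  For minus-strand markers the stored
reference sequence is the amplicon as sequenced, so ``genomic_pos = end -
amplicon_offset``; for plus-strand markers ``genomic_pos = start +
amplicon_offset``.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Marker",
    "CpGSite",
    "PanelDefinition",
    "PanelError",
    "ValidationCheck",
    "load_panel",
    "load_default_panel",
    "validate_panel",
    "cpg_census",
    "collapse_reference",
    "write_collapsed_fasta",
    "write_cpg_bed",
]

_COMPLEMENT = str.maketrans("ACGTYRN", "TGCARYN")


class PanelError(ValueError):
    """Raised when a panel file or definition is malformed."""


@dataclass(frozen=True)
class Marker:
    """One amplicon of the multiplex: genomic span, primers, reference."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    amplicon_size: int
    fwd_primer: str
    rev_primer: str
    primer_conc_uM: float = 0.0
    reference_seq: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise PanelError(f"marker {self.name}: end {self.end} < start {self.start}")
        if self.strand not in {"+", "-"}:
            raise PanelError(f"marker {self.name}: strand must be + or -")
        if self.reference_seq is not None and len(self.reference_seq) != self.amplicon_size:
            raise PanelError(
                f"marker {self.name}: reference length {len(self.reference_seq)} "
                f"!= amplicon size {self.amplicon_size}"
            )

    @property
    def span_length(self) -> int:
        """Length of the genomic span under the 1-based closed convention."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class CpGSite:
    """A target CpG within one amplicon.

    ``label`` follows the assay's per-marker C1..Cn naming, which does not
    always run in genomic coordinate order.  ``synthetic`` flags sites whose
    coordinates are fixture stand-ins rather than published positions.
    """

    marker: str
    label: str
    genomic_pos: int
    amplicon_offset: int
    array_id: str = ""
    synthetic: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.marker}_{self.label}"


@dataclass
class PanelDefinition:
    markers: list[Marker]
    cpgs: list[CpGSite]

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate marker name(s): {', '.join(dup)}")
        by_name = set(names)
        for c in self.cpgs:
            if c.marker not in by_name:
                raise PanelError(f"CpG {c.site_id} references unknown marker {c.marker}")

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def cpgs_for(self, marker: str) -> list[CpGSite]:
        return [c for c in self.cpgs if c.marker == marker]

    def site_ids(self) -> list[str]:
        return [c.site_id for c in self.cpgs]

    def cpg_offsets(self, marker: str) -> dict[str, int]:
        return {c.label: c.amplicon_offset for c in self.cpgs_for(marker)}

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)

    def checksum(self) -> str:
        """Stable content hash used to detect model/panel mismatches."""
        import hashlib

        h = hashlib.sha256()
        for m in self.markers:
            h.update(f"{m.name}|{m.chrom}|{m.start}|{m.end}|{m.strand}|{m.amplicon_size}".encode())
        for c in self.cpgs:
            h.update(f"{c.site_id}|{c.genomic_pos}|{c.amplicon_offset}".encode())
        return h.hexdigest()[:16]


_MARKER_COLS = [
    "marker", "chrom", "start", "end", "strand", "amplicon_size",
    "fwd_primer", "rev_primer", "primer_conc_uM", "reference_seq",
]
_CPG_COLS = ["marker", "label", "genomic_pos", "amplicon_offset", "array_id"]


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise PanelError(f"{path}: empty file, no markers")
        return list(reader)


def load_panel(marker_path: str | Path, cpg_path: str | Path | None = None) -> PanelDefinition:
    """Load a panel from its marker TSV and (optionally) a companion CpG TSV.

    When ``cpg_path`` is omitted, a file named ``*_cpgs.tsv`` next to the
    marker table is used if present; otherwise the panel has no CpG records.
    """
    marker_path = Path(marker_path)
    rows = _read_tsv(marker_path)
    if not rows:
        raise PanelError(f"{marker_path}: no markers")
    missing = [c for c in _MARKER_COLS[:8] if c not in rows[0]]
    if missing:
        raise PanelError(f"{marker_path}: missing column(s) {', '.join(missing)}")

    markers: list[Marker] = []
    for i, row in enumerate(rows, start=2):
        name = row["marker"]
        try:
            start, end = int(row["start"]), int(row["end"])
            size = int(row["amplicon_size"])
        except (TypeError, ValueError) as exc:
            raise PanelError(f"{marker_path} line {i} (marker {name}): malformed coordinate") from exc
        ref = (row.get("reference_seq") or "").strip() or None
        markers.append(
            Marker(
                name=name, chrom=row["chrom"], start=start, end=end,
                strand=row["strand"], amplicon_size=size,
                fwd_primer=row["fwd_primer"], rev_primer=row["rev_primer"],
                primer_conc_uM=float(row.get("primer_conc_uM") or 0.0),
                reference_seq=ref,
            )
        )

    cpgs: list[CpGSite] = []
    if cpg_path is None:
        guess = marker_path.with_name(marker_path.name.replace("markers", "cpgs"))
        cpg_path = guess if guess != marker_path and guess.exists() else None
    if cpg_path is not None:
        crows = _read_tsv(Path(cpg_path))
        if crows:
            missing = [c for c in _CPG_COLS[:4] if c not in crows[0]]
            if missing:
                raise PanelError(f"{cpg_path}: missing column(s) {', '.join(missing)}")
        for i, row in enumerate(crows, start=2):
            try:
                pos = int(row["genomic_pos"])
                off = int(row["amplicon_offset"])
            except (TypeError, ValueError) as exc:
                raise PanelError(
                    f"{cpg_path} line {i} ({row.get('marker')} {row.get('label')}): malformed position"
                ) from exc
            cpgs.append(
                CpGSite(
                    marker=row["marker"], label=row["label"], genomic_pos=pos,
                    amplicon_offset=off, array_id=row.get("array_id") or "",
                    synthetic=bool(int(row.get("synthetic") or 0)),
                )
            )
    return PanelDefinition(markers=markers, cpgs=cpgs)


def load_default_panel() -> PanelDefinition:
    """The bundled eight-marker / 44-CpG panel fixture.

    Marker geometry, primers and the 15 published CpG coordinates are real;
    reference sequences and the remaining CpG offsets are synthetic
    stand-ins (flagged per site) with the correct lengths and counts.
    """
    data = resources.files("epiage.data")
    with resources.as_file(data / "panel_markers.tsv") as mp, \
            resources.as_file(data / "panel_cpgs.tsv") as cp:
        return load_panel(mp, cp)


@dataclass(frozen=True)
class ValidationCheck:
    marker: str
    check: str
    passed: bool
    detail: str = ""


def validate_panel(panel: PanelDefinition) -> list[ValidationCheck]:
    """Consistency checks per marker; failures are report rows, not errors."""
    report: list[ValidationCheck] = []
    for m in panel.markers:
        report.append(
            ValidationCheck(
                m.name, "span_matches_size", m.span_length == m.amplicon_size,
                f"span {m.span_length} vs declared {m.amplicon_size}",
            )
        )
        primer_ok = (
            len(m.fwd_primer) <= m.amplicon_size
            and len(m.rev_primer) <= m.amplicon_size
            and len(m.fwd_primer) + len(m.rev_primer) <= m.amplicon_size
        )
        report.append(ValidationCheck(m.name, "primer_lengths", primer_ok))
        sites = panel.cpgs_for(m.name)
        contained = all(
            m.start <= c.genomic_pos <= m.end and 0 <= c.amplicon_offset < m.amplicon_size
            for c in sites
        )
        report.append(ValidationCheck(m.name, "cpg_containment", contained))
        labels = [c.label for c in sites]
        report.append(ValidationCheck(m.name, "cpg_labels_unique", len(set(labels)) == len(labels)))
        if m.reference_seq is not None:
            ok = all(
                m.reference_seq[c.amplicon_offset : c.amplicon_offset + 2] == "CG"
                for c in sites
            )
            report.append(ValidationCheck(m.name, "reference_cpg_dinucleotides", ok))
    return report


def cpg_census(panel: PanelDefinition) -> tuple[dict[str, int], int]:
    """Per-marker target CpG counts and their total."""
    counts = {m.name: 0 for m in panel.markers}
    for c in panel.cpgs:
        counts[c.marker] += 1
    return counts, sum(counts.values())


def collapse_reference(seq: str, cpg_offsets: Iterable[int]) -> str:
    """Collapse a reference into bisulfite space over the alphabet {A,G,T,Y}.

    Cytosines at CpG offsets become the ambiguity code Y (methylated C reads
    as C, unmethylated as T); every other C becomes T (assumed unmethylated
    and fully converted); A/G/T pass through.
    """
    offsets = set(cpg_offsets)
    out = []
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(f"non-ACGT base {base!r} at position {i}")
        if base == "C":
            out.append("Y" if i in offsets else "T")
        else:
            out.append(base)
    return "".join(out)


def collapsed_references(panel: PanelDefinition) -> dict[str, str]:
    """Bisulfite-collapsed reference per marker (markers with a sequence)."""
    refs: dict[str, str] = {}
    for m in panel.markers:
        if m.reference_seq is None:
            continue
        offsets = [c.amplicon_offset for c in panel.cpgs_for(m.name)]
        refs[m.name] = collapse_reference(m.reference_seq, offsets)
    return refs


def write_collapsed_fasta(panel: PanelDefinition, path: str | Path) -> None:
    """Export collapsed references as FASTA, one record per marker."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="bisulfite-collapsed amplicon")
        for name, seq in collapsed_references(panel).items()
    ]
    seqio_write(records, str(path), "fasta")


def write_cpg_bed(panel: PanelDefinition, path: str | Path) -> None:
    """Export CpG positions as BED (0-based half-open) in panel order."""
    with open(path, "w") as fh:
        for c in panel.cpgs:
            fh.write(f"{panel.marker(c.marker).chrom}\t{c.genomic_pos - 1}\t{c.genomic_pos + 1}\t{c.site_id}\n")
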