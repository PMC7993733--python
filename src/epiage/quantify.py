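"""Beta-value quantification from bisulfite amplicon reads or count tables.

Reads are assigned to amplicons by end-anchored, ungapped matching against
bisulfite-collapsed references (alphabet {A,G,T,Y}): a read T matches
reference T or Y, a read C matches Y only, all other bases must be equal.
A read pair goes to the marker with the fewest mismatches over both mates,
trying both mate/orientation pairings; ties or mismatch fractions above the
threshold leave the pair unassigned.  This mismatch-fraction rule plus the
unique-best-hit requirement stands in for a mapping-quality >= 30 filter.

At target CpGs, methylation is the percent beta value 100*C/(C+T); bases
other than C/T are excluded from the denominator but counted toward the
misincorporation rate.  Both mates of an overlapping pair are counted
("paired reads" depth units), with an optional fragment-level mode.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import PanelDefinition
from .simulate import ReadPairBatch

__all__ = [
    "AssignedReads",
    "MethylationCallSet",
    "FastqParseError",
    "parse_fastq_pairs",
    "assign_reads",
    "count_cpg_bases",
    "call_methylation",
    "qc_metrics",
    "coverage_summary",
    "compare_measurements",
    "within_amplicon_spread",
    "load_counts_tsv",
    "quantify_sample",
]

DEFAULT_MIN_READS = 1000
DEFAULT_MIN_BASE_QUAL = 30
DEFAULT_MAX_MISMATCH_FRAC = 0.05

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNYR", b"TGCANRY"):
    _COMP[_a] = _b


class FastqParseError(ValueError):
    pass


def parse_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (id, seq1, qual1, seq2, qual2) from paired FASTQ files."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(r1_path) as f1, open(r2_path) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        i = 0
        while True:
            try:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ near record {i} ({r1_path}): {exc}") from exc
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise FastqParseError(f"paired FASTQ files differ in length at record {i}")
            (id1, s1, q1), (_, s2, q2) = rec1, rec2
            yield id1.split()[0].rstrip("/12"), s1.upper(), q1, s2.upper(), q2
            i += 1


@dataclass
class AssignedReads:
    """Reads assigned to one amplicon, orientation-normalized.

    ``fwd`` mates align to the reference 5' end in reference orientation;
    ``rev`` mates are reverse-complement reads anchored at the 3' end.
    Qualities are Phred scores (uint8), same shape as the base matrices.
    """

    marker: str
    fwd: np.ndarray
    rev: np.ndarray
    fwd_qual: np.ndarray
    rev_qual: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.fwd.shape[0]


@dataclass
class MethylationCallSet:
    """Per-CpG beta calls plus the run's QC metrics."""

    calls: pd.DataFrame  # sample, cpg, c_reads, t_reads, other_reads, depth, beta, pass_depth
    conversion_efficiency: dict[str, float] = field(default_factory=dict)  # per sample, percent
    misincorporation: pd.DataFrame | None = None  # sample, cpg, misincorporation_pct
    coverage: pd.DataFrame | None = None  # sample, marker, read_depth, normalized_depth

    def beta_matrix(self) -> pd.DataFrame:
        """Samples x CpGs matrix of beta values (NaN where undefined)."""
        return self.calls.pivot(index="sample", columns="cpg", values="beta")

    def write_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)


def _as_matrices(
    reads: Iterable[tuple[str, str, str, str, str]] | Sequence[ReadPairBatch] | tuple[str | Path, str | Path],
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Group read pairs into (r1, r2, q1, q2) uint8 matrices by read lengths."""
    if isinstance(reads, tuple) and len(reads) == 2 and isinstance(reads[0], (str, Path)):
        reads = list(parse_fastq_pairs(*reads))
    groups: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    if reads and isinstance(reads[0] if isinstance(reads, Sequence) else None, ReadPairBatch):
        for batch in reads:  # type: ignore[union-attr]
            q = np.full(batch.r1.shape, 37, dtype=np.uint8)
            q2 = np.full(batch.r2.shape, 37, dtype=np.uint8)
            groups.append((batch.r1, batch.r2, q, q2))
        return groups
    buckets: dict[tuple[int, int], list[tuple[bytes, bytes, bytes, bytes]]] = {}
    for _rid, s1, q1, s2, q2 in reads:  # type: ignore[misc]
        buckets.setdefault((len(s1), len(s2)), []).append(
            (s1.encode(), s2.encode(), q1.encode(), q2.encode())
        )
    for (l1, l2), rows in buckets.items():
        r1 = np.frombuffer(b"".join(r[0] for r in rows), dtype=np.uint8).reshape(-1, l1)
        r2 = np.frombuffer(b"".join(r[1] for r in rows), dtype=np.uint8).reshape(-1, l2)
        q1 = np.frombuffer(b"".join(r[2] for r in rows), dtype=np.uint8).reshape(-1, l1) - 33
        q2 = np.frombuffer(b"".join(r[3] for r in rows), dtype=np.uint8).reshape(-1, l2) - 33
        groups.append((r1, r2, q1, q2))
    return groups


def _allowed_tables(ref: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position allowed-byte lookup tables for head (fwd) and tail (rev).

    Head table: collapsed reference orientation (Y accepts C/T, T accepts T).
    Tail table: reverse complement, Y -> R (R accepts A/G, A accepts A).
    """
    n = len(ref)
    head = np.zeros((n, 256), dtype=bool)
    tail = np.zeros((n, 256), dtype=bool)
    for i, b in enumerate(ref):
        if b == "Y":
            head[i, [ord("C"), ord("T")]] = True
        else:
            head[i, ord(b)] = True
    rc = bytes(_COMP[np.frombuffer(ref.encode(), dtype=np.uint8)][::-1]).decode()
    for i, b in enumerate(rc):
        if b == "R":
            tail[i, [ord("A"), ord("G")]] = True
        else:
            tail[i, ord(b)] = True
    return head, tail


def _mismatches(reads: np.ndarray, table: np.ndarray, offset: int) -> np.ndarray:
    """Mismatch count of each read against table rows [offset, offset+rl)."""
    rl = reads.shape[1]
    sub = table[offset : offset + rl]
    ok = sub[np.arange(rl)[None, :], reads]
    return rl - ok.sum(axis=1)


def assign_reads(
    reads,
    collapsed_refs: Mapping[str, str],
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[dict[str, AssignedReads], int]:
    """Assign read pairs to amplicons; returns per-marker groups + unassigned.

    Accepts a ``(r1.fastq, r2.fastq)`` path pair, an iterable of
    ``(id, seq1, qual1, seq2, qual2)`` tuples, or simulated
    :class:`~epiage.simulate.ReadPairBatch` objects.
    """
    markers = list(collapsed_refs)
    tables = {m: _allowed_tables(collapsed_refs[m]) for m in markers}
    lengths = {m: len(collapsed_refs[m]) for m in markers}
    out: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]] = {m: [] for m in markers}
    unassigned = 0

    for r1, r2, q1, q2 in _as_matrices(reads):
        n, (l1, l2) = r1.shape[0], (r1.shape[1], r2.shape[1])
        if n == 0:
            continue
        big = l1 + l2 + 1
        mm = np.full((len(markers), n), big, dtype=np.int64)
        swap = np.zeros((len(markers), n), dtype=bool)
        frac_ok = np.zeros((len(markers), n), dtype=bool)
        for k, m in enumerate(markers):
            length = lengths[m]
            head, tail = tables[m]
            if l1 <= length and l2 <= length:
                a1, a2 = _mismatches(r1, head, 0), _mismatches(r2, tail, 0)
                b1, b2 = _mismatches(r2, head, 0), _mismatches(r1, tail, 0)
                use_b = (b1 + b2) < (a1 + a2)
                mm[k] = np.where(use_b, b1 + b2, a1 + a2)
                swap[k] = use_b
                # the mismatch-fraction filter applies per mate (MAPQ proxy)
                frac_ok[k] = np.where(
                    use_b,
                    (b1 <= max_mismatch_frac * l2) & (b2 <= max_mismatch_frac * l1),
                    (a1 <= max_mismatch_frac * l1) & (a2 <= max_mismatch_frac * l2),
                )
        order = np.argsort(mm, axis=0, kind="stable")
        best = order[0]
        idx = np.arange(n)
        best_mm = mm[best, idx]
        second_mm = mm[order[1], idx] if len(markers) > 1 else np.full(n, big)
        ok = frac_ok[best, idx] & (best_mm < second_mm)
        unassigned += int((~ok).sum())
        for k, m in enumerate(markers):
            sel = ok & (best == k)
            if not sel.any():
                continue
            sw = swap[k] & sel
            fw = sel & ~swap[k]
            fwd = np.concatenate([r1[fw], r2[sw]]) if sw.any() else r1[fw]
            rev = np.concatenate([r2[fw], r1[sw]]) if sw.any() else r2[fw]
            fq = np.concatenate([q1[fw], q2[sw]]) if sw.any() else q1[fw]
            rq = np.concatenate([q2[fw], q1[sw]]) if sw.any() else q2[fw]
            out[m].append((fwd, rev, fq, rq))

    groups: dict[str, AssignedReads] = {}
    for m in markers:
        if not out[m]:
            continue
        fwd = np.concatenate([g[0] for g in out[m]])
        rev = np.concatenate([g[1] for g in out[m]])
        fq = np.concatenate([g[2] for g in out[m]])
        rq = np.concatenate([g[3] for g in out[m]])
        groups[m] = AssignedReads(marker=m, fwd=fwd, rev=rev, fwd_qual=fq, rev_qual=rq)
    return groups, unassigned


def _position_tally(
    group: AssignedReads,
    ref_length: int,
    offsets: Sequence[int],
    min_base_qual: int,
    paired_counting: bool = True,
) -> dict[int, tuple[int, int, int]]:
    """(C, T, other) counts at the given reference offsets.

    Reverse-mate bases are complemented back to reference orientation before
    tallying.  With ``paired_counting`` both mates of an overlapping pair
    contribute; otherwise the forward mate wins where both cover a position.
    """
    lf, lr = group.fwd.shape[1], group.rev.shape[1]
    res: dict[int, tuple[int, int, int]] = {}
    for o in offsets:
        c = t = other = 0
        fwd_covers = o < lf
        if fwd_covers:
            base = group.fwd[:, o]
            qual_ok = group.fwd_qual[:, o] >= min_base_qual
            c += int(((base == ord("C")) & qual_ok).sum())
            t += int(((base == ord("T")) & qual_ok).sum())
            other += int((qual_ok & (base != ord("C")) & (base != ord("T"))).sum())
        if o >= ref_length - lr and (paired_counting or not fwd_covers):
            raw = group.rev[:, ref_length - 1 - o]
            base = _COMP[raw]
            qual_ok = group.rev_qual[:, ref_length - 1 - o] >= min_base_qual
            c += int(((base == ord("C")) & qual_ok).sum())
            t += int(((base == ord("T")) & qual_ok).sum())
            other += int((qual_ok & (base != ord("C")) & (base != ord("T"))).sum())
        res[o] = (c, t, other)
    return res


def count_cpg_bases(
    groups: Mapping[str, AssignedReads],
    panel: PanelDefinition,
    min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
    sample_id: str = "S1",
    paired_counting: bool = True,
) -> pd.DataFrame:
    """Tally C/T/other bases at every target CpG into a count table."""
    rows = []
    for marker in panel.markers:
        sites = panel.cpgs_for(marker.name)
        group = groups.get(marker.name)
        if group is None:
            for cpg in sites:
                rows.append((sample_id, cpg.site_id, 0, 0, 0))
            continue
        tally = _position_tally(
            group, marker.amplicon_size, [c.amplicon_offset for c in sites],
            min_base_qual, paired_counting,
        )
        for cpg in sites:
            c, t, o = tally[cpg.amplicon_offset]
            rows.append((sample_id, cpg.site_id, c, t, o))
    df = pd.DataFrame(rows, columns=["sample", "cpg", "c_reads", "t_reads", "other_reads"])
    df["depth"] = df[["c_reads", "t_reads", "other_reads"]].sum(axis=1)
    return df


def call_methylation(counts: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Beta values (percent) with a depth pass flag.

    beta = 100*C/(C+T); other bases are excluded from the denominator.  The
    depth threshold applies to the total depth (C+T+other); failing sites
    keep their beta and are flagged rather than suppressed.
    """
    df = counts.copy()
    ct = df["c_reads"] + df["t_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["beta"] = np.where(ct > 0, 100.0 * df["c_reads"] / ct, np.nan)
    df["pass_depth"] = df["depth"] >= min_reads
    return df


def qc_metrics(
    groups: Mapping[str, AssignedReads],
    panel: PanelDefinition,
    min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
    sample_id: str = "S1",
) -> tuple[float, pd.DataFrame]:
    """Bisulfite conversion efficiency and per-CpG misincorporation rates.

    Conversion efficiency is 100 x the mean, over all non-CpG cytosine
    reference positions with coverage, of T/(C+T) — the "reversed beta" at
    sites that are unmethylated by construction.  Misincorporation at a CpG
    is 100 x other/depth.
    """
    reversed_betas: list[float] = []
    rows = []
    for marker in panel.markers:
        if marker.reference_seq is None:
            continue
        group = groups.get(marker.name)
        cpg_offsets = {c.amplicon_offset for c in panel.cpgs_for(marker.name)}
        non_cpg_c = [i for i, b in enumerate(marker.reference_seq) if b == "C" and i not in cpg_offsets]
        if group is not None and non_cpg_c:
            tally = _position_tally(group, marker.amplicon_size, non_cpg_c, min_base_qual)
            for o in non_cpg_c:
                c, t, _ = tally[o]
                if c + t > 0:
                    reversed_betas.append(t / (c + t))
        if group is not None:
            sites = panel.cpgs_for(marker.name)
            tally = _position_tally(
                group, marker.amplicon_size, [c.amplicon_offset for c in sites], min_base_qual
            )
            for cpg in sites:
                c, t, o = tally[cpg.amplicon_offset]
                depth = c + t + o
                rate = 100.0 * o / depth if depth > 0 else np.nan
                rows.append((sample_id, cpg.site_id, rate))
    efficiency = 100.0 * float(np.mean(reversed_betas)) if reversed_betas else float("nan")
    mis = pd.DataFrame(rows, columns=["sample", "cpg", "misincorporation_pct"])
    return efficiency, mis


def coverage_summary(
    counts: pd.DataFrame,
    panel: PanelDefinition,
    representative: Mapping[str, str] | str = "C1",
) -> pd.DataFrame:
    """Total coverage and normalized per-amplicon read depth.

    One representative CpG per amplicon (default its C1) carries the
    amplicon's depth; normalized depth divides by the sample's total
    coverage and sums to 1.  With zero total coverage normalized depths are
    NaN and flagged undefined.
    """
    rows = []
    for sample, sub in counts.groupby("sample"):
        depth_by_cpg = dict(zip(sub["cpg"], sub["depth"]))
        depths = {}
        for m in panel.marker_names():
            label = representative if isinstance(representative, str) else representative.get(m, "C1")
            depths[m] = int(depth_by_cpg.get(f"{m}_{label}", 0))
        total = sum(depths.values())
        for m, d in depths.items():
            norm = d / total if total > 0 else np.nan
            rows.append((sample, m, d, norm, total))
    return pd.DataFrame(rows, columns=["sample", "marker", "read_depth", "normalized_depth", "total_coverage"])


def _marker_of(cpg: str) -> str:
    return cpg.rsplit("_", 1)[0]


def compare_measurements(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    scope: str = "duplicates",
) -> pd.DataFrame:
    """Per-marker mean absolute beta difference (+/- sd) between two call sets.

    ``duplicates``: |beta_a - beta_b| per CpG averaged within marker.
    ``to_reference``: set_a is treated as the measurement (e.g. duplicate
    mean) and set_b as the reference; the arithmetic is the same, the scope
    label records the comparison design.
    Inputs are call tables (``cpg``/``beta`` columns) or beta matrices.
    """
    def _series(df: pd.DataFrame) -> pd.Series:
        if "cpg" in df.columns and "beta" in df.columns:
            return df.groupby("cpg")["beta"].mean()
        return df.mean(axis=0)

    a, b = _series(set_a), _series(set_b)
    common = a.index.intersection(b.index)
    common = [c for c in common if np.isfinite(a[c]) and np.isfinite(b[c])]
    if not common:
        raise ValueError("no overlapping CpGs with defined beta values")
    diff = (a[common] - b[common]).abs()
    marker = pd.Series({c: _marker_of(c) for c in common})
    out = diff.groupby(marker).agg(["mean", "std", "count"])
    out.columns = ["mean_abs_diff", "sd_abs_diff", "n_cpgs"]
    out.index.name = "marker"
    out["scope"] = scope
    return out.reset_index()


def within_amplicon_spread(calls: pd.DataFrame, panel: PanelDefinition) -> pd.DataFrame:
    """Max - min beta across the CpGs of one marker within one sample."""
    df = calls.copy()
    df["marker"] = df["cpg"].map(_marker_of)
    rows = []
    for (sample, marker), sub in df.groupby(["sample", "marker"]):
        betas = sub["beta"].dropna()
        if len(betas):
            rows.append((sample, marker, float(betas.max() - betas.min()), len(betas)))
    return pd.DataFrame(rows, columns=["sample", "marker", "spread", "n_cpgs"])


def load_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pre-tabulated per-CpG count table."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "cpg", "c_reads", "t_reads", "other_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    if "depth" not in df.columns:
        df["depth"] = df[["c_reads", "t_reads", "other_reads"]].sum(axis=1)
    return df


def quantify_sample(
    reads,
    panel: PanelDefinition,
    sample_id: str = "S1",
    min_reads: int = DEFAULT_MIN_READS,
    min_base_qual: int = DEFAULT_MIN_BASE_QUAL,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> MethylationCallSet:
    """End-to-end assign -> count -> call -> QC for one sample's reads."""
    from .panel import collapsed_references

    groups, _unassigned = assign_reads(reads, collapsed_references(panel), max_mismatch_frac)
    counts = count_cpg_bases(groups, panel, min_base_qual, sample_id)
    calls = call_methylation(counts, min_reads)
    efficiency, mis = qc_metrics(groups, panel, min_base_qual, sample_id)
    coverage = coverage_summary(counts, panel)
    return MethylationCallSet(
        calls=calls,
        conversion_efficiency={sample_id: efficiency},
        misincorporation=mis,
        coverage=coverage,
    )
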