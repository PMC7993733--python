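"""Generate the bundled panel fixture TSVs (markers + CpGs) deterministically.

Real geometry (coordinates, sizes, strands, primers, per-marker CpG counts)
and the 15 CpG coordinates with printed positions are hard-coded; reference
sequences and the remaining 29 CpG offsets are synthetic, generated with a
fixed seed and flagged synthetic=1 in the CpG table.
"""
import numpy as np

MARKERS = [
    # name, chrom, start, end, strand, size, fwd, rev, conc, n_cpgs
    ("FHL2", "chr2", 105399250, 105399416, "+", 167,
     "TGTTTTTAGGGTTTTGGGAGTATAG", "ACACCTCCTAAAACTTCTCCAATCTCC", 0.2, 10),
    ("KLF14", "chr7", 130734307, 130734434, "+", 128,
     "GGTTTTAGGTTAAGTTATGTTTAATAGT", "ACTACTACAACCCAAAAATTCC", 0.2, 4),
    ("TRIM59", "chr3", 160450140, 160450280, "+", 141,
     "TATAGGTGGTTTGGGGGAGAG", "AAAAAACACTACCCTCCACAACATAAC", 0.2, 8),
    ("ELOVL2", "chr6", 11044500, 11044766, "+", 267,
     "AGGGGAGTAGGGTAAGTGAG", "AAACCCAACTATAAACAAAACCAA", 0.2, 9),
    ("MIR29B2CHG", "chr1", 207823605, 207823750, "+", 146,
     "GTAAATATATAAGTGGGGGAAGAAGGG", "TTAATAAAACCAAATTCTAAAACATTC", 0.4, 3),
    ("EDARADD", "chr1", 236394309, 236394501, "-", 193,
     "TTGGTGATTAGGAGTTTTAGTGTTTT", "CCACCTACAAATTCCCCAAA", 0.4, 2),
    ("ASPA", "chr17", 3476207, 3476314, "+", 108,
     "TTTTGGAGGAATTTATGGGAA", "ATAAATAATTTTACCTCCAACCCTA", 0.4, 1),
    ("PDE4C", "chr19", 18232953, 18233167, "+", 215,
     "TTGTAGGAGGAAAAGGGTTAG", "AAAACAAAAACTTACAACAAATTAAA", 1.0, 7),
]

# (marker, label, genomic_pos, array_id) for CpGs with printed coordinates
REAL_CPGS = [
    ("ELOVL2", "C2", 11044655, "cg24724428"),
    ("ELOVL2", "C7", 11044634, ""),
    ("ELOVL2", "C9", 11044628, ""),
    ("PDE4C", "C4", 18233105, ""),
    ("PDE4C", "C5", 18233127, ""),
    ("PDE4C", "C6", 18233131, "cg01481989"),
    ("MIR29B2CHG", "C1", 207823681, ""),
    ("MIR29B2CHG", "C3", 207823672, ""),
    ("KLF14", "C1", 130734355, "cg14361627"),
    ("KLF14", "C3", 130734372, ""),
    ("KLF14", "C4", 130734375, ""),
    ("TRIM59", "C8", 160450202, ""),
    ("FHL2", "C1", 105399282, "cg06639320"),
    ("EDARADD", "C1", 236394383, "cg09809672"),
    ("ASPA", "C1", 3476273, "cg02228185"),
]

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


rng = np.random.default_rng(20210311)

real_by_marker = {}
for m, lab, pos, aid in REAL_CPGS:
    real_by_marker.setdefault(m, {})[lab] = (pos, aid)

marker_rows = []
cpg_rows = []
for name, chrom, start, end, strand, size, fwd, rev, conc, n_cpgs in MARKERS:
    assert end - start + 1 == size
    tail = revcomp(rev)
    # offsets of CpGs with printed coordinates
    real = real_by_marker.get(name, {})
    real_offsets = {}
    for lab, (pos, aid) in real.items():
        off = (pos - start) if strand == "+" else (end - pos)
        assert len(fwd) <= off <= size - len(rev) - 2, (name, lab, off)
        real_offsets[lab] = off
    # synthetic offsets for remaining labels, spread through the insert
    labels = [f"C{i}" for i in range(1, n_cpgs + 1)]
    need = [lab for lab in labels if lab not in real_offsets]
    lo, hi = len(fwd) + 2, size - len(rev) - 3
    taken = set()
    for off in real_offsets.values():
        taken.update(range(off - 2, off + 3))
    syn_offsets = {}
    candidates = [o for o in range(lo, hi) if o not in taken]
    if need:
        picks = []
        stride = max(1, len(candidates) // (len(need) + 1))
        i = stride // 2
        while len(picks) < len(need) and i < len(candidates):
            o = candidates[i]
            if all(abs(o - p) > 2 for p in picks):
                picks.append(o)
            i += stride
        # fallback fill
        j = 0
        while len(picks) < len(need):
            o = candidates[j]
            if all(abs(o - p) > 2 for p in picks):
                picks.append(o)
            j += 1
        picks.sort()
        for lab, o in zip(need, picks):
            syn_offsets[lab] = o
    all_offsets = {**real_offsets, **syn_offsets}
    assert len(set(all_offsets.values())) == n_cpgs

    # build reference: fwd primer + random insert + revcomp(rev primer)
    seq = list(fwd) + [str(b) for b in rng.choice(list("AGT"), size=size - len(fwd) - len(rev))] + list(tail)
    assert len(seq) == size
    for off in all_offsets.values():
        seq[off] = "C"
        seq[off + 1] = "G"
    # sprinkle non-CpG cytosines in the insert (needed for conversion QC)
    cpg_zone = set()
    for off in all_offsets.values():
        cpg_zone.update((off - 1, off, off + 1))
    spots = [i for i in range(lo, hi) if i not in cpg_zone and seq[i + 1] != "G" and seq[i] != "C"]
    n_extra = min(12, len(spots))
    for i in sorted(rng.choice(len(spots), size=n_extra, replace=False)):
        seq[spots[i]] = "C"
    ref = "".join(seq)
    # no accidental CpG outside the designated offsets
    cg_positions = {i for i in range(size - 1) if ref[i:i + 2] == "CG"}
    assert cg_positions == set(all_offsets.values()), name

    marker_rows.append((name, chrom, start, end, strand, size, fwd, rev, conc, ref))
    for lab in labels:
        off = all_offsets[lab]
        if lab in real_offsets:
            pos, aid = real[lab]
            syn = 0
        else:
            pos = (start + off) if strand == "+" else (end - off)
            aid, syn = "", 1
        cpg_rows.append((name, lab, pos, off, aid, syn))

with open("src/epiage/data/panel_markers.tsv", "w") as fh:
    fh.write("marker\tchrom\tstart\tend\tstrand\tamplicon_size\tfwd_primer\trev_primer\tprimer_conc_uM\treference_seq\n")
    for r in marker_rows:
        fh.write("\t".join(map(str, r)) + "\n")

with open("src/epiage/data/panel_cpgs.tsv", "w") as fh:
    fh.write("marker\tlabel\tgenomic_pos\tamplicon_offset\tarray_id\tsynthetic\n")
    for r in cpg_rows:
        fh.write("\t".join(map(str, r)) + "\n")

print("markers:", len(marker_rows), "cpgs:", len(cpg_rows))
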