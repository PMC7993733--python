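"""Synthetic cohorts, methylation standards, and bisulfite amplicon reads.

The generator emulates what a targeted bisulfite amplicon sequencing run of
an age panel produces, with the measurement artifacts such assays show:

* age-dependent per-CpG methylation trajectories per tissue (hyper- or
  hypomethylation, linear or power-shaped),
* marker-specific PCR amplification bias that vanishes at 0% and 100%
  methylation,
* duplicate (run-to-run) measurement noise,
* incomplete bisulfite conversion and sequencing error,
* per-amplicon depth imbalance, and
* the template-molecule bottleneck that makes low-input reactions noisy.

All randomness flows through ``numpy.random.default_rng`` seeded explicitly;
per-sample streams are spawned from the seed so cohorts are reproducible and
samples independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import PanelDefinition

__all__ = [
    "AgeMethylationFunction",
    "AssayDistortion",
    "SampleRecord",
    "ReadPairBatch",
    "default_age_functions",
    "simulate_cohort",
    "true_methylation",
    "apply_assay_distortion",
    "simulate_counts",
    "simulate_reads",
    "simulate_standard_series",
    "SCENARIOS",
]

TISSUES = ("blood", "buccal", "bone", "cartilage", "muscle", "standard")

PHRED_QUAL = 37  # constant base quality emitted for simulated reads
_QUAL_CHAR = chr(PHRED_QUAL + 33)


@dataclass(frozen=True)
class AgeMethylationFunction:
    """Mean methylation (percent) at one CpG as a function of age.

    ``linear``: intercept + slope * age.  ``power``: intercept +
    scale * age ** exponent.  Output is clamped to [0, 100]; ``direction``
    records whether the site hyper- or hypomethylates with age and is
    enforced by sign conventions on slope/scale.
    """

    cpg: str
    form: str = "linear"  # {linear, power}
    intercept: float = 0.0
    slope: float = 0.0
    scale: float = 0.0
    exponent: float = 1.0
    direction: str = "hyper"  # {hyper, hypo}
    sd_biological: float = 2.5  # between-individual sd, percent

    def mean_at(self, age: float | np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if self.form == "linear":
            val = self.intercept + self.slope * age
        elif self.form == "power":
            val = self.intercept + self.scale * np.power(age, self.exponent)
        else:
            raise ValueError(f"unknown form {self.form!r}")
        return np.clip(val, 0.0, 100.0)

    @property
    def lifespan_range(self) -> float:
        """Percent span of the (noise-free) trajectory over ages 1-93."""
        grid = self.mean_at(np.linspace(1, 93, 93))
        return float(grid.max() - grid.min())


# qualitative per-marker calibration: wide spans for ELOVL2/PDE4C/MIR29B2CHG,
# narrowest span for KLF14; ELOVL2 is the non-linear (power) marker; ELOVL2,
# PDE4C, FHL2, TRIM59, KLF14 hypermethylate with age, MIR29B2CHG, EDARADD
# and ASPA hypomethylate.
_MARKER_SHAPES: dict[str, dict] = {
    "ELOVL2": dict(form="power", intercept=5.0, scale=3.95, exponent=0.6, direction="hyper"),
    "PDE4C": dict(form="linear", intercept=10.0, slope=0.55, direction="hyper"),
    "MIR29B2CHG": dict(form="linear", intercept=78.0, slope=-0.55, direction="hypo"),
    "FHL2": dict(form="linear", intercept=15.0, slope=0.38, direction="hyper"),
    "TRIM59": dict(form="linear", intercept=12.0, slope=0.42, direction="hyper"),
    "KLF14": dict(form="linear", intercept=4.0, slope=0.12, direction="hyper"),
    "EDARADD": dict(form="linear", intercept=68.0, slope=-0.30, direction="hypo"),
    "ASPA": dict(form="linear", intercept=62.0, slope=-0.26, direction="hypo"),
}

# mild tissue-specific attenuation of age trajectories
_TISSUE_SLOPE_FACTOR = {"blood": 1.0, "buccal": 0.95, "bone": 0.90, "cartilage": 0.6, "muscle": 0.6}


def default_age_functions(panel: PanelDefinition, tissue: str = "blood") -> dict[str, AgeMethylationFunction]:
    """Default age trajectory for every CpG of the panel in one tissue."""
    factor = _TISSUE_SLOPE_FACTOR.get(tissue, 1.0)
    funcs: dict[str, AgeMethylationFunction] = {}
    for marker in panel.marker_names():
        shape = _MARKER_SHAPES.get(marker, dict(form="linear", intercept=30.0, slope=0.3, direction="hyper"))
        for j, cpg in enumerate(panel.cpgs_for(marker)):
            # small per-CpG intercept offset so sites within a marker differ
            kw = dict(shape)
            kw["intercept"] = float(kw["intercept"]) + 0.8 * j
            if kw["form"] == "linear":
                kw["slope"] = float(kw["slope"]) * factor
            else:
                kw["scale"] = float(kw["scale"]) * factor
            funcs[cpg.site_id] = AgeMethylationFunction(cpg=cpg.site_id, **kw)
    return funcs


@dataclass(frozen=True)
class AssayDistortion:
    """Measurement artifacts applied between true methylation and reads.

    ``bias_amplitude`` is the signed per-marker PCR bias in percent at 50%
    true methylation (the bias vanishes at 0% and 100%); ``duplicate_sd`` is
    the per-measurement noise sd in percent, calibrated so the expected
    absolute difference between duplicates (2*sd/sqrt(pi)) is 1.9%.
    """

    bias_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"MIR29B2CHG": 3.0, "EDARADD": 3.0, "ELOVL2": -3.0}
    )
    duplicate_sd: float = 1.684  # percent; E|dup1-dup2| = 2*sd/sqrt(pi) ~= 1.9
    conversion_prob: float = 0.998
    seq_error: float = 0.001
    amplicon_weights: Mapping[str, float] = field(default_factory=dict)
    depth_mean: float = 2000.0  # pairs per amplicon
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    template_molecules_per_ng: float = 300.0
    bisulfite_recovery: float = 0.6  # fraction of template surviving conversion

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_prob <= 1.0:
            raise ValueError("conversion_prob must be in [0,1]")
        if not 0.0 <= self.seq_error <= 1.0:
            raise ValueError("seq_error must be in [0,1]")
        if any(w <= 0 for w in self.amplicon_weights.values()):
            raise ValueError("amplicon weights must be positive")

    def bias_for(self, marker: str) -> float:
        return float(self.bias_amplitude.get(marker, 0.0))

    def weight_for(self, marker: str) -> float:
        return float(self.amplicon_weights.get(marker, 1.0))

    @classmethod
    def none(cls) -> "AssayDistortion":
        """Identity assay: no bias, no noise, perfect conversion, no error."""
        return cls(bias_amplitude={}, duplicate_sd=0.0, conversion_prob=1.0, seq_error=0.0)


@dataclass
class SampleRecord:
    sample_id: str
    age: float
    sex: str
    tissue: str
    true_methylation: np.ndarray | None = None
    split: str = "none"  # {train, test, none}

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be nonnegative")


def simulate_cohort(
    n: int,
    age_range: tuple[float, float],
    sex_ratio: float = 0.5,
    tissue: str = "blood",
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[SampleRecord]:
    """Draw a cohort of ``n`` samples with uniform ages over ``age_range``.

    ``sex_ratio`` is the fraction of males; the male count is round(n*ratio)
    exactly, the assignment order is shuffled.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    lo, hi = age_range
    if lo > hi:
        raise ValueError("empty age range")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n)
    n_m = int(round(n * sex_ratio))
    sexes = np.array(["M"] * n_m + ["F"] * (n - n_m))
    rng.shuffle(sexes)
    prefix = id_prefix or tissue[:2].upper()
    return [
        SampleRecord(sample_id=f"{prefix}{i + 1:04d}", age=float(a), sex=str(s), tissue=tissue)
        for i, (a, s) in enumerate(zip(ages, sexes))
    ]


def true_methylation(
    age: float,
    tissue: str,
    functions: Mapping[str, AgeMethylationFunction],
    panel: PanelDefinition,
    seed: int | np.random.Generator = 0,
    noise: bool = True,
) -> np.ndarray:
    """True per-CpG methylation (percent, panel order) for one individual.

    Evaluates each CpG's age trajectory, adds between-individual biological
    noise, clamps to [0, 100].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(panel.n_cpgs)
    for i, site in enumerate(panel.site_ids()):
        if site not in functions:
            raise KeyError(f"no age function for CpG {site} ({tissue})")
        f = functions[site]
        val = float(f.mean_at(age))
        if noise and f.sd_biological > 0:
            val += rng.normal(0.0, f.sd_biological)
        out[i] = val
    return np.clip(out, 0.0, 100.0)


def apply_assay_distortion(
    true_vec: np.ndarray,
    distortion: AssayDistortion,
    panel: PanelDefinition,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Observed (assay-level) methylation: PCR bias plus duplicate noise.

    observed = clamp(true + b_m * 4 * p * (1-p) + eps), p = true/100,
    eps ~ Normal(0, duplicate_sd).  The logistic-shaped bias term is the
    simplest form that vanishes at both endpoints and peaks at 50%.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_vec = np.asarray(true_vec, dtype=float)
    p = true_vec / 100.0
    bias = np.array([distortion.bias_for(c.marker) for c in panel.cpgs])
    out = true_vec + bias * 4.0 * p * (1.0 - p)
    if distortion.duplicate_sd > 0:
        out = out + rng.normal(0.0, distortion.duplicate_sd, size=out.shape)
    return np.clip(out, 0.0, 100.0)


def _template_fraction(
    observed_vec: np.ndarray,
    distortion: AssayDistortion,
    input_ng: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Template-bottleneck resampling of per-CpG methylated fractions."""
    m_templates = int(round(input_ng * distortion.template_molecules_per_ng * distortion.bisulfite_recovery))
    m_templates = max(m_templates, 1)
    p = np.asarray(observed_vec, dtype=float) / 100.0
    k = rng.binomial(m_templates, p)
    return k / m_templates


def _read_base_probs(p_meth: np.ndarray, conv: float, err: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P[C], P[T], P[other]) at a CpG given methylated template fraction."""
    p_c0 = p_meth + (1.0 - p_meth) * (1.0 - conv)
    p_t0 = 1.0 - p_c0
    p_c = p_c0 * (1.0 - err) + p_t0 * (err / 3.0)
    p_t = p_t0 * (1.0 - err) + p_c0 * (err / 3.0)
    return p_c, p_t, 1.0 - p_c - p_t


def simulate_counts(
    observed_vec: np.ndarray,
    distortion: AssayDistortion,
    panel: PanelDefinition,
    input_ng: float = 200.0,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Per-CpG C/T/other read counts for one sample.

    The template bottleneck (binomial resampling over the number of
    converted input molecules) acts before sequencing depth, so low-input
    reactions are noisy even at high coverage.  Depth per amplicon is
    negative-binomial around ``depth_mean`` scaled by the amplicon weight.
    """
    if input_ng <= 0:
        raise ValueError("input_ng must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_meth = _template_fraction(observed_vec, distortion, input_ng, rng)
    rows = []
    site_index = {s: i for i, s in enumerate(panel.site_ids())}
    for marker in panel.marker_names():
        mean = distortion.depth_mean * distortion.weight_for(marker)
        size = distortion.depth_dispersion
        depth = int(rng.negative_binomial(size, size / (size + mean))) if mean > 0 else 0
        for cpg in panel.cpgs_for(marker):
            i = site_index[cpg.site_id]
            p_c, p_t, p_o = _read_base_probs(p_meth[i], distortion.conversion_prob, distortion.seq_error)
            c, t, o = rng.multinomial(depth, [p_c, p_t, max(p_o, 0.0)])
            rows.append((sample_id, cpg.site_id, int(c), int(t), int(o)))
    df = pd.DataFrame(rows, columns=["sample", "cpg", "c_reads", "t_reads", "other_reads"])
    df["depth"] = df[["c_reads", "t_reads", "other_reads"]].sum(axis=1)
    return df


_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_a] = _b


@dataclass
class ReadPairBatch:
    """Paired reads from one amplicon as byte matrices (fast pipeline form).

    ``r1``/``r2`` are (n, read_len) uint8 arrays of ASCII bases in read
    orientation (r2 is the reverse complement of the template 3' end).
    Base qualities are constant Phred ``PHRED_QUAL``.
    """

    marker: str
    r1: np.ndarray
    r2: np.ndarray
    id_prefix: str = "read"

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def to_pairs(self) -> Iterator[tuple[str, str, str, str, str]]:
        q1 = _QUAL_CHAR * self.r1.shape[1]
        q2 = _QUAL_CHAR * self.r2.shape[1]
        for i in range(self.n_pairs):
            yield (
                f"{self.id_prefix}:{self.marker}:{i}",
                self.r1[i].tobytes().decode("ascii"),
                q1,
                self.r2[i].tobytes().decode("ascii"),
                q2,
            )


def write_fastq(batches: Iterable[ReadPairBatch], r1_path: str | Path, r2_path: str | Path) -> int:
    """Write paired batches as Phred+33 FASTQ (_R1/_R2); returns pair count."""
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for batch in batches:
            for rid, s1, q1, s2, q2 in batch.to_pairs():
                f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
                n += 1
    return n


def simulate_reads(
    observed_vec: np.ndarray,
    panel: PanelDefinition,
    distortion: AssayDistortion,
    read_length: int = 150,
    n_pairs: int | Mapping[str, int] | None = None,
    input_ng: float = 200.0,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
) -> list[ReadPairBatch]:
    """Simulate primer-anchored paired reads for every amplicon of the panel.

    Each read pair is a bisulfite-converted copy of the amplicon: R1 covers
    the first ``read_length`` bases, R2 the reverse complement of the last
    ``read_length`` bases, so interior positions of amplicons longer than
    2*read_length - overlap are covered by one mate only (the 2x150 vs 2x200
    kit geometry).  ``n_pairs`` overrides the depth model (int for all
    markers or a per-marker mapping).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    longest_primer = max(max(len(m.fwd_primer), len(m.rev_primer)) for m in panel.markers)
    if read_length < longest_primer:
        raise ValueError("read_length shorter than the longest primer")
    p_meth = _template_fraction(observed_vec, distortion, input_ng, rng)
    site_index = {s: i for i, s in enumerate(panel.site_ids())}
    conv = distortion.conversion_prob
    err = distortion.seq_error

    batches: list[ReadPairBatch] = []
    for marker in panel.markers:
        if marker.reference_seq is None:
            raise ValueError(f"marker {marker.name} has no reference sequence")
        if isinstance(n_pairs, Mapping):
            n = int(n_pairs.get(marker.name, 0))
        elif n_pairs is not None:
            n = int(n_pairs)
        else:
            mean = distortion.depth_mean * distortion.weight_for(marker.name)
            size = distortion.depth_dispersion
            n = int(rng.negative_binomial(size, size / (size + mean)))
        ref = np.frombuffer(marker.reference_seq.encode("ascii"), dtype=np.uint8)
        length = ref.size
        cpg_offsets = {c.amplicon_offset: site_index[c.site_id] for c in panel.cpgs_for(marker.name)}
        template = np.tile(ref, (n, 1))
        c_cols = np.flatnonzero(ref == ord("C"))
        for col in c_cols:
            if col in cpg_offsets:
                methylated = rng.random(n) < p_meth[cpg_offsets[col]]
                converted = rng.random(n) < conv
                template[~methylated & converted, col] = ord("T")
            else:
                template[rng.random(n) < conv, col] = ord("T")
        rl = min(read_length, length)
        r1 = template[:, :rl].copy()
        r2 = _COMP_TABLE[template[:, length - rl :]][:, ::-1].copy()
        if err > 0:
            for mat in (r1, r2):
                hit = np.argwhere(rng.random(mat.shape) < err)
                if hit.size:
                    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
                    repl = bases[rng.integers(0, 4, size=hit.shape[0])]
                    same = repl == mat[hit[:, 0], hit[:, 1]]
                    repl[same] = _COMP_TABLE[repl[same]]  # force a substitution
                    mat[hit[:, 0], hit[:, 1]] = repl
        batches.append(ReadPairBatch(marker=marker.name, r1=r1, r2=r2, id_prefix=sample_id))
    return batches


def simulate_standard_series(
    ratios: Sequence[float],
    replicates: int = 2,
    singles: Sequence[float] = (),
    panel: PanelDefinition | None = None,
    n_cpgs: int | None = None,
    seed: int = 0,
) -> list[SampleRecord]:
    """Artificially methylated DNA standards: constant truth across all CpGs.

    ``ratios`` are run in ``replicates`` copies each, ``singles`` once
    (mirrors runs of duplicated 5-75% standards plus single 0%/100%
    controls).
    """
    if n_cpgs is None:
        n_cpgs = panel.n_cpgs if panel is not None else 44
    records = []
    for r in list(ratios) + list(singles):
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"standard ratio {r} outside [0,100]")
    i = 0
    for r in ratios:
        for rep in range(replicates):
            i += 1
            records.append(
                SampleRecord(
                    sample_id=f"STD{int(round(r)):03d}_{rep + 1}",
                    age=0.0,
                    sex="F",
                    tissue="standard",
                    true_methylation=np.full(n_cpgs, float(r)),
                )
            )
    for r in singles:
        i += 1
        records.append(
            SampleRecord(
                sample_id=f"STD{int(round(r)):03d}_1",
                age=0.0,
                sex="F",
                tissue="standard",
                true_methylation=np.full(n_cpgs, float(r)),
            )
        )
    return records


def cohort_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.age, r.sex, r.tissue, r.split) for r in records],
        columns=["sample_id", "age", "sex", "tissue", "split"],
    )


def truth_to_frame(records: Sequence[SampleRecord], panel: PanelDefinition) -> pd.DataFrame:
    rows = {}
    for r in records:
        if r.true_methylation is not None:
            rows[r.sample_id] = r.true_methylation
    return pd.DataFrame.from_dict(rows, orient="index", columns=panel.site_ids())


# Scenario presets mirroring the assay's development stages: the first
# design on the 2x150 kit (unbalanced PDE4C), the re-optimized design on the
# 2x200 kit, the input-DNA dilution series, and the standards series.
SCENARIOS: dict[str, dict] = {
    "design1_v2": dict(
        read_length=150,
        ratios=(0.0, 25.0, 50.0, 75.0, 100.0),
        replicates=2,
        singles=(),
        input_ng=200.0,
        amplicon_weights={"PDE4C": 0.08},
    ),
    "design2_v3": dict(
        read_length=200,
        ratios=(5.0, 10.0, 25.0, 50.0, 75.0),
        replicates=2,
        singles=(0.0, 100.0),
        input_ng=200.0,
        amplicon_weights={"PDE4C": 0.5, "MIR29B2CHG": 0.6},
    ),
    "dilution_series": dict(
        read_length=200,
        ratios=(50.0,),
        replicates=2,
        singles=(),
        input_ng=(200.0, 100.0, 50.0, 20.0, 10.0, 1.0),
        amplicon_weights={"PDE4C": 0.5},
    ),
    "standards": dict(
        read_length=200,
        ratios=(0.0, 5.0, 10.0, 25.0, 50.0, 75.0, 100.0),
        replicates=2,
        singles=(),
        input_ng=200.0,
        amplicon_weights={},
    ),
}
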