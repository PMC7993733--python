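"""Tissue-specific epigenetic age regression models.

The modelling layer follows the classic small-panel forensic age-clock
recipe: per-CpG curve estimation (identity vs power transformation of the
methylation predictor), univariate screening by standardized regression
coefficient, stepwise multivariable selection driven by partial-F p-values
(probability-of-F entry/removal), and an ordinary least squares fit of
chronological age on the transformed beta values.  Accuracy is summarized
as mean absolute error overall and within 20-year age categories, plus the
correlation of absolute error with age.

The public surface is statsmodels-shaped: :class:`AgeRegression` is built
from data and its ``fit``/``fit_stepwise`` return an
:class:`AgeRegressionResults` carrying coefficients, their uncertainties,
standardized effects, adjusted R^2 and a ``summary()`` table; prediction,
serialization and evaluation hang off the results object.  Module-level
functions wrap the same operations for pipeline use.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import SampleRecord

__all__ = [
    "TransformSpec",
    "StepwiseConfig",
    "AgeRegression",
    "AgeRegressionResults",
    "EvaluationReport",
    "DEFAULT_CATEGORY_BOUNDS",
    "split_train_test",
    "fit_power_transform",
    "univariate_screen",
    "stepwise_select",
    "fit_model",
    "predict_age",
    "evaluate_predictions",
    "test_assay_equivalence",
]

DEFAULT_EXPONENT_GRID = tuple(np.round(np.arange(0.5, 3.01, 0.1), 10))
# categories 3 (41-60) and 4 (>60) are fixed by convention; 1 and 2 are the
# preceding 20-year bins
DEFAULT_CATEGORY_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 20.0), (20.0, 40.0), (40.0, 60.0), (60.0, float("inf")),
)


@dataclass(frozen=True)
class TransformSpec:
    """Predictor transformation: identity, or meth**exponent (percent scale)."""

    cpg: str
    form: str = "identity"  # {identity, power}
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in {"identity", "power"}:
            raise ValueError(f"unknown transform form {self.form!r}")
        if self.form == "power" and self.exponent <= 0:
            raise ValueError("power exponent must be positive")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "identity":
            return x
        if np.any(x[np.isfinite(x)] < 0):
            raise ValueError(f"negative methylation under power transform at {self.cpg}")
        return np.power(x, self.exponent)


@dataclass(frozen=True)
class StepwiseConfig:
    p_enter: float = 0.05
    p_remove: float = 0.10
    max_steps: int = 100

    def __post_init__(self) -> None:
        if self.p_enter > self.p_remove:
            raise ValueError("p_enter must be <= p_remove (termination guarantee)")


@dataclass
class EvaluationReport:
    mae_overall: float
    mae_by_category: dict[int, float | None]
    n_by_category: dict[int, int]
    category_bounds: tuple[tuple[float, float], ...]
    pearson_r_abs_error_vs_age: float
    pearson_p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mae_overall": self.mae_overall,
            "mae_by_category": {str(k): v for k, v in self.mae_by_category.items()},
            "n_by_category": {str(k): v for k, v in self.n_by_category.items()},
            "category_bounds": [list(b) for b in self.category_bounds],
            "pearson_r_abs_error_vs_age": self.pearson_r_abs_error_vs_age,
            "pearson_p": self.pearson_p,
            "n": self.n,
        }


class AgeRegression:
    """Age-on-methylation linear model built from a training table.

    Parameters
    ----------
    age : array of chronological ages in years.
    meth : DataFrame of percent beta values, one column per CpG.
    transforms : optional per-CpG :class:`TransformSpec`; unlisted CpGs use
        the identity.
    tissue : label recorded on fitted results.
    """

    def __init__(
        self,
        age: np.ndarray,
        meth: pd.DataFrame,
        transforms: Mapping[str, TransformSpec] | None = None,
        tissue: str = "unspecified",
    ) -> None:
        self.age = np.asarray(age, dtype=float)
        self.meth = meth.reset_index(drop=True)
        if len(self.age) != len(self.meth):
            raise ValueError("age and methylation table differ in length")
        self.transforms = dict(transforms or {})
        self.tissue = tissue

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        age_col: str = "age",
        cpg_cols: Sequence[str] | None = None,
        **kwargs,
    ) -> "AgeRegression":
        if cpg_cols is None:
            cpg_cols = [c for c in df.columns if c not in {age_col, "sample_id", "sex", "tissue", "split"}]
        return cls(df[age_col].to_numpy(), df[list(cpg_cols)], **kwargs)

    def transform_for(self, cpg: str) -> TransformSpec:
        return self.transforms.get(cpg, TransformSpec(cpg=cpg))

    def _design(self, predictors: Sequence[str]) -> np.ndarray:
        cols = [self.transform_for(c).apply(self.meth[c].to_numpy()) for c in predictors]
        return np.column_stack(cols) if cols else np.empty((len(self.age), 0))

    def select_transforms(
        self,
        cpgs: Sequence[str] | None = None,
        exponent_grid: Sequence[float] = DEFAULT_EXPONENT_GRID,
    ) -> dict[str, TransformSpec]:
        """Curve estimation: per CpG pick identity vs the best power exponent."""
        chosen = {}
        for cpg in cpgs if cpgs is not None else self.meth.columns:
            x = self.meth[cpg].to_numpy(dtype=float)
            if np.any(x[np.isfinite(x)] <= 0):
                # sites touching 0% cannot carry a power form; keep identity
                chosen[cpg] = TransformSpec(cpg=cpg)
                continue
            chosen[cpg] = fit_power_transform(x, self.age, exponent_grid, cpg=cpg)
        self.transforms.update(chosen)
        return chosen

    def univariate_screen(self) -> pd.DataFrame:
        return univariate_screen(self.age, self.meth, self.transforms)

    def fit(self, predictors: Sequence[str] | None = None) -> "AgeRegressionResults":
        """OLS fit of age on the (transformed) given predictors (default all)."""
        predictors = list(predictors if predictors is not None else self.meth.columns)
        return self._fit_ols(predictors)

    def _fit_ols(self, predictors: list[str]) -> "AgeRegressionResults":
        y = self.age
        if not predictors:
            return AgeRegressionResults(
                tissue=self.tissue, predictors=[], transforms={},
                intercept=float(np.mean(y)), coefficients={}, std_errors={},
                t_values={}, p_values={}, std_beta={}, adjusted_r2=0.0,
                r2=0.0, training_n=len(y),
            )
        x = self._design(predictors)
        if len(y) <= x.shape[1] + 1:
            raise ValueError("need n > number of predictors + 1")
        # collinearity guard: name the offending pair
        if x.shape[1] > 1:
            cc = np.corrcoef(x, rowvar=False)
            for i in range(len(predictors)):
                for j in range(i + 1, len(predictors)):
                    if abs(cc[i, j]) > 1 - 1e-10:
                        raise ValueError(
                            f"collinear predictors: {predictors[i]} and {predictors[j]}"
                        )
        res = sm.OLS(y, sm.add_constant(x)).fit()
        sy = float(np.std(y, ddof=1))
        std_beta = {
            c: float(res.params[i + 1] * np.std(x[:, i], ddof=1) / sy)
            for i, c in enumerate(predictors)
        }
        return AgeRegressionResults(
            tissue=self.tissue,
            predictors=predictors,
            transforms={c: self.transform_for(c) for c in predictors},
            intercept=float(res.params[0]),
            coefficients={c: float(res.params[i + 1]) for i, c in enumerate(predictors)},
            std_errors={c: float(res.bse[i + 1]) for i, c in enumerate(predictors)},
            t_values={c: float(res.tvalues[i + 1]) for i, c in enumerate(predictors)},
            p_values={c: float(res.pvalues[i + 1]) for i, c in enumerate(predictors)},
            std_beta=std_beta,
            adjusted_r2=float(res.rsquared_adj),
            r2=float(res.rsquared),
            training_n=int(res.nobs),
        )

    def fit_stepwise(
        self,
        candidates: Sequence[str] | None = None,
        config: StepwiseConfig | None = None,
    ) -> "AgeRegressionResults":
        """Stepwise selection by probability of the partial F statistic.

        At each step the candidate whose addition has the smallest
        partial-F p-value enters if p < p_enter; any included predictor
        whose partial-F p exceeds p_remove is then removed.  For a single
        coefficient the partial F equals the squared t statistic, so the
        entry/removal tests use the coefficient t-test p-values.  Stops when
        a pass changes nothing; if nothing ever enters, an empty model
        (intercept = mean age) is returned.
        """
        config = config or StepwiseConfig()
        candidates = list(candidates if candidates is not None else self.meth.columns)
        included: list[str] = []
        for _step in range(config.max_steps):
            changed = False
            best_p, best_c = None, None
            for c in candidates:
                if c in included:
                    continue
                try:
                    trial = self._fit_ols(included + [c])
                except ValueError:
                    continue
                p = trial.p_values[c]
                if np.isfinite(p) and (best_p is None or p < best_p):
                    best_p, best_c = p, c
            if best_c is not None and best_p < config.p_enter:
                included.append(best_c)
                changed = True
            if included:
                res = self._fit_ols(included)
                worst = max(included, key=lambda c: res.p_values[c])
                if res.p_values[worst] > config.p_remove:
                    included.remove(worst)
                    changed = True
            if not changed:
                break
        return self._fit_ols(included)


@dataclass
class AgeRegressionResults:
    """Fitted age model: estimates, uncertainties, diagnostics."""

    tissue: str
    predictors: list[str]
    transforms: dict[str, TransformSpec]
    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    std_beta: dict[str, float]
    adjusted_r2: float
    r2: float
    training_n: int
    panel_checksum: str = ""

    @property
    def is_empty(self) -> bool:
        return not self.predictors

    def summary(self) -> str:
        lines = [
            f"Age regression model ({self.tissue})",
            f"  n = {self.training_n}, predictors = {len(self.predictors)}, "
            f"R2 = {self.r2:.3f}, adj. R2 = {self.adjusted_r2:.3f}",
            f"  intercept = {self.intercept:.3f} years",
            f"  {'CpG':<18}{'transform':<12}{'coef':>10}{'std beta':>10}{'t':>9}{'P':>12}",
        ]
        for c in self.predictors:
            t = self.transforms[c]
            tf = "identity" if t.form == "identity" else f"x^{t.exponent:g}"
            lines.append(
                f"  {c:<18}{tf:<12}{self.coefficients[c]:>10.4f}{self.std_beta[c]:>10.3f}"
                f"{self.t_values[c]:>9.2f}{self.p_values[c]:>12.3g}"
            )
        return "\n".join(lines)

    def predict(self, meth: pd.DataFrame, pass_depth: pd.DataFrame | None = None) -> pd.DataFrame:
        """Predict age from a samples x CpGs beta matrix (percent).

        Samples with a missing or depth-failing predictor get NaN with the
        reason recorded; predictions are not clamped to a plausible range.
        """
        missing_cols = [c for c in self.predictors if c not in meth.columns]
        if missing_cols:
            raise ValueError(f"calls lack model predictor(s): {', '.join(missing_cols)}")
        pred = np.full(len(meth), self.intercept, dtype=float)
        for c in self.predictors:
            pred = pred + self.coefficients[c] * self.transforms[c].apply(meth[c].to_numpy())
        notes = []
        for i, sample in enumerate(meth.index):
            reason = ""
            for c in self.predictors:
                if not np.isfinite(meth[c].iloc[i]):
                    reason = f"missing beta at {c}"
                    break
                if pass_depth is not None and c in pass_depth.columns and not bool(pass_depth[c].iloc[i]):
                    reason = f"depth QC failure at {c}"
                    break
            if reason:
                pred[i] = np.nan
            notes.append(reason)
        return pd.DataFrame(
            {"sample": meth.index, "predicted_age": pred, "note": notes}
        ).set_index("sample")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "tissue": self.tissue,
            "predictors": [
                {
                    "cpg": c,
                    "transform": {"form": self.transforms[c].form, "exponent": self.transforms[c].exponent},
                    "coefficient": self.coefficients[c],
                    "std_beta": self.std_beta[c],
                    "std_error": self.std_errors.get(c),
                    "t_value": self.t_values.get(c),
                    "p_value": self.p_values.get(c),
                }
                for c in self.predictors
            ],
            "intercept": self.intercept,
            "adjusted_r2": self.adjusted_r2,
            "r2": self.r2,
            "training_n": self.training_n,
            "panel_checksum": self.panel_checksum,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AgeRegressionResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        preds = doc["predictors"]
        return cls(
            tissue=doc["tissue"],
            predictors=[p["cpg"] for p in preds],
            transforms={
                p["cpg"]: TransformSpec(
                    cpg=p["cpg"], form=p["transform"]["form"], exponent=p["transform"]["exponent"]
                )
                for p in preds
            },
            intercept=doc["intercept"],
            coefficients={p["cpg"]: p["coefficient"] for p in preds},
            std_errors={p["cpg"]: p.get("std_error", float("nan")) for p in preds},
            t_values={p["cpg"]: p.get("t_value", float("nan")) for p in preds},
            p_values={p["cpg"]: p.get("p_value", float("nan")) for p in preds},
            std_beta={p["cpg"]: p["std_beta"] for p in preds},
            adjusted_r2=doc["adjusted_r2"],
            r2=doc.get("r2", float("nan")),
            training_n=doc["training_n"],
            panel_checksum=doc.get("panel_checksum", ""),
        )


# ---------------------------------------------------------------------------
# pipeline-level functions


def split_train_test(
    cohort: Sequence[SampleRecord] | pd.DataFrame,
    train_n: int,
    seed: int = 0,
    stratify_on: Sequence[str] = ("age", "sex"),
) -> Sequence[SampleRecord] | pd.DataFrame:
    """Random train/test split preserving age-quartile x sex proportions.

    Strata are the cross of age quartile and sex; each stratum contributes
    its proportional share of the training set (largest-remainder rounding,
    so within +/-1 sample per stratum).
    """
    is_frame = isinstance(cohort, pd.DataFrame)
    df = cohort.copy() if is_frame else pd.DataFrame(
        {"age": [r.age for r in cohort], "sex": [r.sex for r in cohort]}
    )
    n = len(df)
    if train_n >= n:
        raise ValueError(f"train_n {train_n} must be smaller than cohort size {n}")
    rng = np.random.default_rng(seed)
    key = pd.Series("", index=df.index)
    if "age" in stratify_on:
        key = key + pd.qcut(df["age"], 4, labels=False, duplicates="drop").astype(str)
    if "sex" in stratify_on and "sex" in df.columns:
        key = key + "|" + df["sex"].astype(str)
    strata = df.groupby(key.to_numpy()).indices
    quotas = {k: train_n * len(idx) / n for k, idx in strata.items()}
    base = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = train_n - sum(base.values())
    order = sorted(quotas, key=lambda k: quotas[k] - base[k], reverse=True)
    for k in order[:leftover]:
        base[k] += 1
    train_idx: list[int] = []
    for k, idx in strata.items():
        idx = np.asarray(idx)
        take = min(base[k], len(idx))
        train_idx.extend(rng.choice(idx, size=take, replace=False))
    train_set = set(train_idx)
    labels = ["train" if i in train_set else "test" for i in range(n)]
    if is_frame:
        df["split"] = labels
        return df
    for r, lab in zip(cohort, labels):
        r.split = lab
    return cohort


def fit_power_transform(
    meth: np.ndarray,
    age: np.ndarray,
    exponent_grid: Sequence[float] = DEFAULT_EXPONENT_GRID,
    cpg: str = "",
) -> TransformSpec:
    """Pick identity vs the R^2-maximizing power exponent for one CpG.

    Compares the linear-fit R^2 of age against raw methylation with the fit
    against meth**k over the grid; ties favor the identity.
    """
    meth = np.asarray(meth, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(meth) < 10:
        raise ValueError("need at least 10 observations for curve estimation")
    if np.any(meth <= 0):
        raise ValueError(f"nonpositive methylation: power transform undefined for {cpg or 'CpG'}")

    def _r2(x: np.ndarray) -> float:
        if np.std(x) == 0:
            return -np.inf
        r = np.corrcoef(x, age)[0, 1]
        return float(r * r)

    base = _r2(meth)
    best_form, best_exp, best_r2 = "identity", 1.0, base
    for k in exponent_grid:
        r2 = _r2(np.power(meth, k))
        if r2 > best_r2 + 1e-12:
            best_form, best_exp, best_r2 = "power", float(k), r2
    return TransformSpec(cpg=cpg, form=best_form, exponent=best_exp)


def univariate_screen(
    age: np.ndarray,
    meth: pd.DataFrame,
    transforms: Mapping[str, TransformSpec] | None = None,
) -> pd.DataFrame:
    """Simple regression of age on each (transformed) CpG.

    The standardized coefficient equals the Pearson correlation in simple
    regression; zero-variance predictors are flagged excluded.
    """
    age = np.asarray(age, dtype=float)
    transforms = transforms or {}
    rows = []
    n = len(age)
    for cpg in meth.columns:
        x = meth[cpg].to_numpy(dtype=float)
        spec = transforms.get(cpg)
        if spec is not None:
            x = spec.apply(x)
        ok = np.isfinite(x) & np.isfinite(age)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            rows.append((cpg, np.nan, np.nan, np.nan, np.nan, int(ok.sum()), True))
            continue
        r = float(np.corrcoef(x[ok], age[ok])[0, 1])
        dof = int(ok.sum()) - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(dof / (1.0 - r * r)) if abs(r) < 1 else np.inf * np.sign(r)
        p = float(2 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
        rows.append((cpg, r, float(t), p, r * r, int(ok.sum()), False))
    return pd.DataFrame(
        rows, columns=["cpg", "std_beta", "t_stat", "p_value", "r_squared", "n", "excluded"]
    ).set_index("cpg")


def stepwise_select(
    age: np.ndarray,
    meth: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    config: StepwiseConfig | None = None,
    transforms: Mapping[str, TransformSpec] | None = None,
    tissue: str = "unspecified",
) -> AgeRegressionResults:
    model = AgeRegression(age, meth, transforms=transforms, tissue=tissue)
    return model.fit_stepwise(candidates, config)


def fit_model(
    age: np.ndarray,
    meth: pd.DataFrame,
    predictors: Sequence[str],
    transforms: Mapping[str, TransformSpec] | None = None,
    tissue: str = "unspecified",
) -> AgeRegressionResults:
    model = AgeRegression(age, meth, transforms=transforms, tissue=tissue)
    return model.fit(predictors)


def predict_age(results: AgeRegressionResults, calls) -> pd.DataFrame:
    """Apply a fitted model to a call set or beta matrix."""
    from .quantify import MethylationCallSet

    if isinstance(calls, MethylationCallSet):
        beta = calls.beta_matrix()
        pass_depth = calls.calls.pivot(index="sample", columns="cpg", values="pass_depth")
        return results.predict(beta, pass_depth)
    return results.predict(calls)


def evaluate_predictions(
    predicted: np.ndarray,
    truth: np.ndarray,
    category_bounds: Sequence[tuple[float, float]] = DEFAULT_CATEGORY_BOUNDS,
) -> EvaluationReport:
    """MAE overall and per age category, plus corr(|error|, age).

    Categories are (lo, hi] intervals of chronological age; an empty
    category reports MAE None.  The per-category MAEs, weighted by their n,
    average exactly to the overall MAE.
    """
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape or len(truth) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    ok = np.isfinite(predicted) & np.isfinite(truth)
    err = np.abs(predicted[ok] - truth[ok])
    ages = truth[ok]
    mae_by, n_by = {}, {}
    for i, (lo, hi) in enumerate(category_bounds, start=1):
        sel = (ages > lo) & (ages <= hi)
        n_by[i] = int(sel.sum())
        mae_by[i] = float(err[sel].mean()) if sel.any() else None
    if np.std(err) == 0 or np.std(ages) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(err, ages)
    return EvaluationReport(
        mae_overall=float(err.mean()),
        mae_by_category=mae_by,
        n_by_category=n_by,
        category_bounds=tuple(tuple(b) for b in category_bounds),
        pearson_r_abs_error_vs_age=float(r),
        pearson_p=float(p),
        n=int(ok.sum()),
    )


def test_assay_equivalence(
    measurements_a: Mapping[str, np.ndarray],
    measurements_b: Mapping[str, np.ndarray],
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Joint (intercept, slope) = (0, 1) equivalence test per marker.

    Regresses assay B on assay A and F-tests the joint hypothesis that the
    calibration line is the identity; p-values are Bonferroni-adjusted by
    the number of tests (capped at 1).
    """
    markers = [m for m in measurements_a if m in measurements_b]
    if n_tests is None:
        n_tests = len(markers)
    rows = []
    for m in markers:
        a = np.asarray(measurements_a[m], dtype=float)
        b = np.asarray(measurements_b[m], dtype=float)
        if len(a) != len(b) or len(a) < 3:
            raise ValueError(f"marker {m}: need >= 3 paired observations")
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError(f"marker {m}: degenerate variance")
        x = sm.add_constant(a)
        res = sm.OLS(b, x).fit()
        intercept, slope = float(res.params[0]), float(res.params[1])
        n = len(a)
        rss_full = float(res.ssr)
        rss_restricted = float(np.sum((b - a) ** 2))  # identity line
        df_den = n - 2
        if rss_full <= 1e-12 * max(rss_restricted, 1.0):
            p = 1.0 if rss_restricted <= 1e-12 else 0.0
            fstat = 0.0 if p == 1.0 else np.inf
        else:
            fstat = (rss_restricted - rss_full) / 2.0 / (rss_full / df_den)
            fstat = max(fstat, 0.0)
            p = float(stats.f.sf(fstat, 2, df_den))
        rows.append((m, slope, intercept, float(fstat), p, min(1.0, n_tests * p), n))
    return pd.DataFrame(
        rows,
        columns=["marker", "slope", "intercept", "f_stat", "p_value", "p_bonferroni", "n"],
    ).set_index("marker")
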