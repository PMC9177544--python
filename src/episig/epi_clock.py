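"""Epigenetic-clock age estimation, age acceleration, and group tests.

A methylation clock is a penalized linear model on a fixed CpG panel:
the linear predictor ``intercept + sum(w_i * beta_i)`` estimates a
*transformed* age, where the transform is logarithmic through childhood
and linear in adulthood,

    T(age) = log(age + 1) - log(adult_age + 1)   if age <= adult_age
           = (age - adult_age) / (adult_age + 1) otherwise

with ``adult_age`` = 20 years by default. DNAm age is the inverse
transform of the predictor. Age acceleration is DNAm age minus
chronological age; the "DNAm age residual" is the residual from an
ordinary least-squares regression of DNAm age on chronological age over
a fitting set, and is the clock covariate used by the differential
model.

Group comparisons mirror common practice with small cohorts: a paired
Wilcoxon signed-rank test of DNAm vs chronological age within a group,
and a Mann-Whitney U test of age acceleration between groups. Exact
p-values are used at small n, normal approximations (with continuity
and tie corrections) otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, EpisigError, SampleSheet

#: sample-size cutoffs below which exact test distributions are used
WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_MIN_N = 8


@dataclass
class ClockModel:
    """Clock coefficients: intercept plus CpG weights, and the transform knot."""

    intercept: float
    coefficients: dict[str, float]
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise EpisigError("clock model needs at least one coefficient")
        if self.adult_age <= -1:
            raise EpisigError("adult_age must be > -1")

    @property
    def cpgs(self) -> list[str]:
        return list(self.coefficients)


def read_clock_model(path: str | Path) -> ClockModel:
    """Read a clock CSV: ``# adult_age: <x>`` header, then cpg,weight rows.

    The intercept is the row whose cpg field is ``(Intercept)``.
    """
    adult_age = 20.0
    lines = Path(path).read_text().splitlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "adult_age":
                adult_age = float(val)
            continue
        data_lines.append(line)
    df = pd.read_csv(pd.io.common.StringIO("\n".join(data_lines)))
    intercept = 0.0
    coefs: dict[str, float] = {}
    for cpg, w in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if cpg == "(Intercept)":
            intercept = float(w)
        else:
            coefs[str(cpg)] = float(w)
    return ClockModel(intercept=intercept, coefficients=coefs, adult_age=adult_age)


def write_clock_model(clock: ClockModel, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# adult_age: {clock.adult_age}\n")
        fh.write("cpg,weight\n")
        fh.write(f"(Intercept),{clock.intercept!r}\n")
        for cpg, w in clock.coefficients.items():
            fh.write(f"{cpg},{w!r}\n")


# ---------------------------------------------------------------------------
# Age transform
# ---------------------------------------------------------------------------


def transform_age(age, adult_age: float = 20.0):
    """Log-linear age transform; continuous and strictly increasing."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise EpisigError("age must be > -1")
    young = np.log(age + 1) - np.log(adult_age + 1)
    old = (age - adult_age) / (adult_age + 1)
    out = np.where(age <= adult_age, young, old)
    return float(out) if out.ndim == 0 else out


def inverse_transform_age(x, adult_age: float = 20.0):
    """Exact inverse of :func:`transform_age`."""
    x = np.asarray(x, dtype=float)
    young = np.exp(x + np.log(adult_age + 1)) - 1
    old = x * (adult_age + 1) + adult_age
    out = np.where(x <= 0, young, old)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_dnam_age(
    beta: BetaMatrix, clock: ClockModel, max_missing_fraction: float = 0.05
) -> pd.Series:
    """DNAm age (years) per sample from the clock's linear predictor.

    Clock CpGs absent from the matrix are tolerated up to
    ``max_missing_fraction`` of the panel; missing values (absent probes
    or NaN cells) are imputed with the cohort mean of that CpG, with a
    warning. More missing than that is an error.
    """
    cpgs = clock.cpgs
    present = [c for c in cpgs if c in beta.values.index]
    n_absent = len(cpgs) - len(present)
    if n_absent / len(cpgs) > max_missing_fraction:
        raise EpisigError(
            f"{n_absent}/{len(cpgs)} clock CpGs missing from beta matrix "
            f"(> {max_missing_fraction:.0%} allowed)"
        )
    sub = beta.values.reindex(cpgs)
    arr = sub.to_numpy(dtype=float)
    if np.isnan(arr).any():
        warnings.warn(
            f"imputing {int(np.isnan(arr).any(axis=1).sum())} clock CpGs "
            "with cohort means"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            row_means = np.nanmean(arr, axis=1, keepdims=True)
        row_means = np.where(np.isnan(row_means), 0.5, row_means)
        arr = np.where(np.isnan(arr), row_means, arr)
    w = np.array([clock.coefficients[c] for c in cpgs])
    predictor = clock.intercept + w @ arr
    ages = inverse_transform_age(predictor, clock.adult_age)
    return pd.Series(ages, index=beta.sample_ids, name="dnam_age")


def age_acceleration(dnam_ages: pd.Series, chrono_ages: pd.Series) -> pd.Series:
    """DNAm age minus chronological age, per sample."""
    chrono = chrono_ages.reindex(dnam_ages.index)
    if chrono.isna().any():
        missing = list(chrono.index[chrono.isna()])
        raise EpisigError(f"missing chronological age for samples: {missing[:5]}")
    return (dnam_ages - chrono).rename("acceleration")


def dnam_age_residual(
    dnam_ages: pd.Series,
    chrono_ages: pd.Series,
    fitting_set: list[str] | None = None,
) -> pd.Series:
    """Residual of DNAm age regressed on chronological age (OLS).

    The line is fitted over ``fitting_set`` (default: all samples) and
    residuals are returned for every sample.
    """
    chrono = chrono_ages.reindex(dnam_ages.index)
    if chrono.isna().any():
        raise EpisigError("missing chronological ages")
    fit_idx = list(fitting_set) if fitting_set is not None else list(dnam_ages.index)
    if len(fit_idx) < 3:
        raise EpisigError("need >= 3 samples in the residual fitting set")
    x = chrono.loc[fit_idx].to_numpy(dtype=float)
    y = dnam_ages.loc[fit_idx].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise EpisigError("constant chronological ages: residual line undefined")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * chrono.to_numpy(dtype=float)
    return pd.Series(
        dnam_ages.to_numpy(dtype=float) - fitted,
        index=dnam_ages.index,
        name="dnam_age_residual",
    )


@dataclass
class ClockResult:
    """Per-sample clock outputs plus the residual-regression bookkeeping."""

    table: pd.DataFrame  # columns: dnam_age, chrono_age, acceleration, residual
    fitting_set: list[str] = field(default_factory=list)


def run_clock(
    beta: BetaMatrix,
    sheet: SampleSheet,
    clock: ClockModel,
    residual_fitting_roles: tuple[str, ...] = ("discovery_case", "discovery_control"),
) -> ClockResult:
    """Predict DNAm age for all samples; residual line fit on modeled samples."""
    from .core_io import align

    aligned = align(beta, sheet)
    sub_sheet = sheet.subset(list(aligned.sample_ids))
    dnam = predict_dnam_age(aligned, clock)
    chrono = pd.Series(
        sub_sheet.table["age_years"].to_numpy(),
        index=sub_sheet.sample_ids,
        name="chrono_age",
    )
    fitting = [
        s
        for s, r in zip(sub_sheet.sample_ids, sub_sheet.table["role"])
        if r in residual_fitting_roles
    ]
    if len(fitting) < 3:
        fitting = list(dnam.index)
    accel = age_acceleration(dnam, chrono)
    resid = dnam_age_residual(dnam, chrono, fitting)
    table = pd.DataFrame(
        {
            "dnam_age": dnam,
            "chrono_age": chrono,
            "acceleration": accel,
            "residual": resid,
        }
    )
    return ClockResult(table=table, fitting_set=fitting)


# ---------------------------------------------------------------------------
# Nonparametric group tests
# ---------------------------------------------------------------------------


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped. Exact null distribution when the
    number of non-zero pairs is <= 25 and there are no tied ranks;
    otherwise the normal approximation with continuity correction.
    Returns (signed-rank statistic W, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EpisigError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if d.size < 3:
        raise EpisigError("need >= 3 non-zero paired differences")
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(ranks)) < len(ranks)
    method = "exact" if (d.size <= WILCOXON_EXACT_MAX_N and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two independent groups.

    Exact when min(n, m) <= 8 and there are no ties; otherwise the
    normal approximation with continuity and tie corrections. Returns
    (U for the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EpisigError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) == 1:
        # degenerate: every observation identical; U at its null mean
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(x.size, y.size) <= MANNWHITNEY_EXACT_MAX_MIN_N and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)
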