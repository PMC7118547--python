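"""Regression and ANCOVA analyses of pattern metrics against SF-36 scores.

Each SF-36 score is regressed on a single pattern-metric exposure plus a
fixed covariate set; four covariate families are supported, named by what
they adjust for:

* ``base`` — age, total body fat %, occupational status, analgesic use,
  antidepressant use, and accelerometer wear time;
* ``base_mvpa`` — base plus moderate-to-vigorous physical activity;
* ``base_st`` — base plus total sedentary time (used when the exposure is a
  bout frequency, so the association is independent of sedentary volume);
* ``base_st_mvpa`` — base plus sedentary time and MVPA.

The combined analysis median-splits participants on weekly sedentary time and
on mean prolonged (≥30 min) bout duration — ties go to the low group — and
compares the four joint groups by ANCOVA: adjusted means at the sample
covariate means with all six pairwise contrasts. No multiplicity adjustment
is applied; the grid output annotates how many tests were run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, InsufficientDataError, ValidationError

BASE_COVARIATES = (
    "age",
    "body_fat_pct",
    "occupational_status",
    "analgesic_use",
    "antidepressant_use",
    "wear_minutes_per_day",
)

MODEL_FAMILIES: dict[str, tuple[str, ...]] = {
    "base": BASE_COVARIATES,
    "base_mvpa": BASE_COVARIATES + ("mvpa_minutes_per_day",),
    "base_st": BASE_COVARIATES + ("st_minutes_per_day",),
    "base_st_mvpa": BASE_COVARIATES + ("st_minutes_per_day", "mvpa_minutes_per_day"),
}

GROUP_LEVELS = ("low_low", "low_high", "high_low", "high_high")


@dataclass(frozen=True)
class ModelSpec:
    """One regression cell: outcome, exposure, covariate family, alpha."""

    outcome: str
    exposure: str
    family: str = "base"
    covariates: tuple[str, ...] | None = None  # override the family set
    alpha: float = 0.05

    def covariate_names(self) -> tuple[str, ...]:
        if self.covariates is not None:
            return tuple(self.covariates)
        if self.family not in MODEL_FAMILIES:
            raise ValidationError(
                f"unknown model family {self.family!r}; known: {sorted(MODEL_FAMILIES)}"
            )
        return MODEL_FAMILIES[self.family]


@dataclass(frozen=True)
class ModelResult:
    """Exposure-term estimates from one fitted model."""

    B: float  # unstandardized coefficient, outcome units per exposure unit
    SE: float
    beta: float  # standardized: B × sd(exposure)/sd(outcome) on the analysis sample
    p: float
    n: int
    ci95: tuple[float, float]


def _design(data: pd.DataFrame, cols: list[str]):
    """Complete-case design matrix with intercept; rejects rank deficiency."""
    sub = data[cols].dropna()
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in cols[1:]])
    names = ["const"] + cols[1:]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns whose R diagonal collapses are the dependent ones
        _, R, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise CollinearityError(f"rank-deficient design; collinear columns: {bad}")
    return sub, X, names


def fit_linear_model(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """OLS of the outcome on exposure + covariates; exposure-term estimates.

    Listwise deletion on outcome, exposure, and covariates. Standardized beta
    uses the post-deletion sample SDs; the CI is ``B ± t(n−k−1, 1−alpha/2)·SE``
    with k predictors.
    """
    covs = list(spec.covariate_names())
    cols = [spec.outcome, spec.exposure, *covs]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"analysis table missing columns {missing}")
    sub, X, _ = _design(data, cols)
    y = sub[spec.outcome].to_numpy(dtype=float)
    k = X.shape[1] - 1  # predictors excluding intercept
    n = len(sub)
    if n <= k + 1:
        raise InsufficientDataError(
            f"{spec.outcome} ~ {spec.exposure}: n={n} too small for {k} predictors"
        )
    res = sm.OLS(y, X).fit()
    B = float(res.params[1])
    SE = float(res.bse[1])
    sd_x = float(sub[spec.exposure].std(ddof=1))
    sd_y = float(y.std(ddof=1))
    beta = B * sd_x / sd_y if sd_y > 0 else float("nan")
    tcrit = stats.t.ppf(1 - spec.alpha / 2, res.df_resid)
    return ModelResult(
        B=B,
        SE=SE,
        beta=beta,
        p=float(res.pvalues[1]),
        n=n,
        ci95=(B - tcrit * SE, B + tcrit * SE),
    )


def run_model_grid(
    data: pd.DataFrame,
    outcomes: list[str],
    exposures: list[str],
    families: list[str],
) -> pd.DataFrame:
    """One model per (outcome, exposure, family), long format.

    A failing cell (degenerate exposure, too few cases) yields a flagged row
    with the error message; remaining cells are unaffected. The attribute
    ``df.attrs['n_tests']`` records how many models were attempted, since no
    multiplicity adjustment is applied.
    """
    rows = []
    for outcome, exposure, family in itertools.product(outcomes, exposures, families):
        row = {"outcome": outcome, "exposure": exposure, "family": family}
        try:
            r = fit_linear_model(data, ModelSpec(outcome, exposure, family))
            row.update(
                B=r.B, SE=r.SE, beta=r.beta, p=r.p, n=r.n,
                ci_low=r.ci95[0], ci_high=r.ci95[1], error="",
            )
        except (CollinearityError, InsufficientDataError, ValidationError) as exc:
            row.update(
                B=np.nan, SE=np.nan, beta=np.nan, p=np.nan, n=0,
                ci_low=np.nan, ci_high=np.nan, error=str(exc),
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(rows)
    return out


def assign_groups(
    data: pd.DataFrame,
    st_col: str = "st_minutes_per_week",
    dur_col: str = "mean_bout_duration_30",
    zero_bout_policy: str = "zero",
) -> pd.DataFrame:
    """Median-split on total weekly sedentary time and prolonged-bout duration.

    Values at or below the sample median go to the low group. Participants
    with no prolonged (≥30 min) bout have an undefined mean bout duration;
    under ``zero_bout_policy='zero'`` they enter with duration 0 (hence low),
    under ``'exclude'`` they are dropped. The returned frame carries the
    medians and the count of such participants in ``attrs``.
    """
    if zero_bout_policy not in ("zero", "exclude"):
        raise ValidationError("zero_bout_policy must be 'zero' or 'exclude'")
    sub = data[["participant_id", st_col, dur_col]].copy()
    sub = sub.dropna(subset=[st_col])
    n_zero_bout = int(sub[dur_col].isna().sum())
    if zero_bout_policy == "zero":
        sub[dur_col] = sub[dur_col].fillna(0.0)
    else:
        sub = sub.dropna(subset=[dur_col])
    st_median = float(sub[st_col].median())
    dur_median = float(sub[dur_col].median())
    out = pd.DataFrame(
        {
            "participant_id": sub["participant_id"],
            "st_group": np.where(sub[st_col] <= st_median, "low", "high"),
            "bout_group": np.where(sub[dur_col] <= dur_median, "low", "high"),
        }
    )
    out["joint_group"] = out["st_group"] + "_" + out["bout_group"]
    out.attrs.update(
        st_median=st_median, dur_median=dur_median, n_zero_bout=n_zero_bout
    )
    return out.reset_index(drop=True)


@dataclass
class AncovaResult:
    """Adjusted group means at covariate means, plus all pairwise contrasts."""

    adjusted_means: dict[str, float]
    contrasts: pd.DataFrame = field(repr=False)  # group1, group2, diff, se, ci_low, ci_high, p
    group_sizes: dict[str, int] = field(default_factory=dict)
    n: int = 0


def fit_ancova(
    data: pd.DataFrame,
    groups: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = BASE_COVARIATES,
    include_mvpa: bool = False,
    alpha: float = 0.05,
) -> AncovaResult:
    """ANCOVA of the outcome on the four joint groups plus covariates.

    Fits OLS with three group indicators (reference ``low_low``) and the
    covariates; adjusted means are model predictions at the sample covariate
    means, and the six pairwise group differences carry t-based CIs and
    p-values, unadjusted for multiplicity.
    """
    covs = list(covariates) + (["mvpa_minutes_per_day"] if include_mvpa else [])
    merged = data.merge(groups[["participant_id", "joint_group"]], on="participant_id")
    cols = [outcome, *covs, "joint_group"]
    sub = merged[cols].dropna()
    sizes = {g: int((sub["joint_group"] == g).sum()) for g in GROUP_LEVELS}
    empty = [g for g, s in sizes.items() if s == 0]
    if empty:
        raise InsufficientDataError(f"empty ANCOVA groups {empty}; sizes {sizes}")

    n = len(sub)
    dummies = np.column_stack(
        [(sub["joint_group"] == g).to_numpy(dtype=float) for g in GROUP_LEVELS[1:]]
    )
    C = np.column_stack([sub[c].to_numpy(dtype=float) for c in covs]) if covs else np.empty((n, 0))
    X = np.column_stack([np.ones(n), dummies, C])
    y = sub[outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient ANCOVA design (group dummies + covariates)")
    res = sm.OLS(y, X).fit()

    cbar = C.mean(axis=0) if covs else np.empty(0)
    base_vec = np.concatenate([[1.0], np.zeros(3), cbar])
    means = {}
    group_vecs = {}
    for i, g in enumerate(GROUP_LEVELS):
        v = base_vec.copy()
        if i > 0:
            v[i] = 1.0
        group_vecs[g] = v
        means[g] = float(v @ res.params)

    tcrit = stats.t.ppf(1 - alpha / 2, res.df_resid)
    cov_params = res.cov_params()
    rows = []
    for g1, g2 in itertools.combinations(GROUP_LEVELS, 2):
        c = group_vecs[g1] - group_vecs[g2]
        diff = float(c @ res.params)
        se = float(np.sqrt(c @ cov_params @ c))
        tval = diff / se
        p = float(2 * stats.t.sf(abs(tval), res.df_resid))
        rows.append(
            {
                "group1": g1, "group2": g2, "diff": diff, "se": se,
                "ci_low": diff - tcrit * se, "ci_high": diff + tcrit * se, "p": p,
            }
        )
    return AncovaResult(
        adjusted_means=means,
        contrasts=pd.DataFrame(rows),
        group_sizes=sizes,
        n=n,
    )
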