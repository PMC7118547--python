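"""Independent reference implementations used as oracles by the test suite.

Each oracle recomputes a pipeline quantity by a deliberately different route
(literal window enumeration, per-epoch scanning, normal equations,
group-mean-centering algebra) and never calls the code path it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


# -- nonwear: literal window enumeration ------------------------------------

def _rle(mask):
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        runs.append((bool(mask[i]), i, j))
        i = j
    return runs


def _window_qualifies(zero, lo, hi, min_len, tol, flank):
    """Apply the sustained-zero rules literally to the slice [lo, hi)."""
    w = zero[lo:hi]
    if hi - lo < min_len:
        return False
    nonzero = ~w
    if nonzero.sum() > tol:
        return False
    # every maximal nonzero run inside must be flanked by >= flank zeros
    for is_zero, s, e in _rle(w):
        if is_zero:
            continue
        if s < flank or not w[s - flank : s].all():
            return False
        if len(w) - e < flank or not w[e : e + flank].all():
            return False
    return True


def nonwear_reference(zero: np.ndarray, min_len: int, tol: int, flank: int) -> np.ndarray:
    """Union of all qualifying windows; windows are enumerated explicitly.

    Qualifying windows start and end on zero epochs (a boundary spike can
    never be flanked), so enumeration over zero-run-aligned windows is
    exhaustive; extension stops once the spike budget is exceeded because
    adding epochs can only add nonzero minutes.
    """
    zero = np.asarray(zero, dtype=bool)
    flags = np.zeros(len(zero), dtype=bool)
    runs = _rle(zero)
    zruns = [i for i, r in enumerate(runs) if r[0]]
    for a in zruns:
        spikes = 0
        for b in range(a, len(runs)):
            if not runs[b][0]:
                spikes += runs[b][2] - runs[b][1]
                if spikes > tol:
                    break
                continue
            lo, hi = runs[a][1], runs[b][2]
            if _window_qualifies(zero, lo, hi, min_len, tol, flank):
                flags[lo:hi] = True
    return flags


def zero_run_reference(zero: np.ndarray, min_len: int) -> np.ndarray:
    """Pure zero-run scanner (the spike_tolerance=0 degenerate case)."""
    flags = np.zeros(len(zero), dtype=bool)
    for is_zero, s, e in _rle(np.asarray(zero, dtype=bool)):
        if is_zero and e - s >= min_len:
            flags[s:e] = True
    return flags


# -- bouts: per-epoch scanner ------------------------------------------------

def bout_scan(sedentary: np.ndarray, day: np.ndarray) -> list[tuple[int, int]]:
    """(start index, duration) of every maximal sedentary run within a day."""
    out = []
    n = len(sedentary)
    i = 0
    while i < n:
        if sedentary[i]:
            j = i
            while j < n and sedentary[j] and day[j] == day[i]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def summary_from_bouts(durations, st_min, n_valid_days, categories=(10, 20, 30, 60)):
    """Recompute the pattern ratios directly from a bout-duration list."""
    durations = np.asarray(durations, dtype=float)
    out = {}
    for L in categories:
        sel = durations[durations >= L]
        out[f"pct_st_in_bouts_{L}"] = 100.0 * sel.sum() / st_min
        out[f"bouts_per_sed_hour_{L}"] = len(sel) / (st_min / 60.0)
        out[f"bouts_per_week_{L}"] = 7.0 * len(sel) / n_valid_days
    sel30 = durations[durations >= 30]
    out["mean_bout_duration_30"] = sel30.mean() if len(sel30) else float("nan")
    return out


# -- intensity: interval bisection lookup ------------------------------------

def intensity_lookup(vm: np.ndarray, edges=(200.0, 2690.0, 6167.0)) -> np.ndarray:
    """Classify by bisecting the cut-point edges (0=sed,1=light,2=mod,3=vig)."""
    return np.searchsorted(np.asarray(edges), np.asarray(vm, dtype=float), side="right")


# -- regression: normal equations + t distribution ---------------------------

def ols_reference(y: np.ndarray, X: np.ndarray):
    """OLS by pseudo-inverse normal equations; returns per-term estimates.

    ``X`` excludes the intercept; one is prepended. Returns (coef, se, p,
    ci_low, ci_high) arrays over [const, predictors...].
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xd = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
    p = Xd.shape[1]
    coef = np.linalg.pinv(Xd) @ y
    resid = y - Xd @ coef
    df = n - p
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    tcrit = stats.t.ppf(0.975, df)
    return coef, se, pvals, coef - tcrit * se, coef + tcrit * se


# -- ANCOVA: group-mean-centering algebra ------------------------------------

def ancova_reference(y, covariates, group_labels, levels):
    """Adjusted means via the within-group (pooled) covariate slope.

    Regress group-demeaned y on group-demeaned covariates to get the pooled
    slopes b, then adjusted mean of group g = ybar_g − b·(cbar_g − cbar).
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    g = np.asarray(group_labels)
    yc = y.copy()
    Cc = C.copy()
    for lev in levels:
        m = g == lev
        yc[m] -= y[m].mean()
        Cc[m] -= C[m].mean(axis=0)
    b = np.linalg.lstsq(Cc, yc, rcond=None)[0]
    cbar = C.mean(axis=0)
    means = {
        lev: y[g == lev].mean() - b @ (C[g == lev].mean(axis=0) - cbar)
        for lev in levels
    }
    return means, b
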