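"""Differential iModulon activity (DiMA), explained variance, trendlines.

DiMA compares an iModulon's mean activity between two sample groups against
a log-normal null fitted to the absolute activity differences between
biological replicates — the natural scale of "no biological change".  A
difference is called significant when it clears both an absolute activity
threshold (default 5) and a Benjamini–Hochberg FDR (default 0.1).

Explained variance attributes fractions of the centered compendium's
squared Frobenius norm to subsets of iModulons via the reconstruction
M_S·A_S; because components are not orthogonal, cumulative curves use
nested-union reconstruction rather than sums of singleton values.

Trendline fits (linear or logarithmic) and signed distances to them support
phase-plane analysis of two iModulons' activities across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DimaNull",
    "TrendFit",
    "fit_dima_null",
    "dima",
    "explained_variance",
    "rank_by_explained_variance",
    "fit_trendline",
    "distance_to_trendline",
]


@dataclass
class DimaNull:
    """Per-iModulon log-normal null of replicate activity differences.

    params holds columns mu and sigma: the MLE of the log-normal fitted to
    log(|difference| + epsilon) over all within-replicate-group sample
    pairs.
    """

    params: pd.DataFrame        # index: imodulon; columns: mu, sigma
    n_pairs: int
    epsilon: float = 1e-6

    def survival(self, imodulon: str, abs_diff: float) -> float:
        mu = self.params.loc[imodulon, "mu"]
        sigma = self.params.loc[imodulon, "sigma"]
        z = (np.log(abs_diff + self.epsilon) - mu) / sigma
        return float(norm.sf(z))


def fit_dima_null(A: pd.DataFrame, design, epsilon: float = 1e-6) -> DimaNull:
    """Fit the replicate-difference null, one log-normal per iModulon.

    For each iModulon, |aᵢ − aⱼ| is collected over every within-group
    sample pair; the log-normal MLE is the mean and (population) SD of
    log(|d| + epsilon).  Degenerate nulls — no pairs, or differences with
    zero spread — cannot calibrate a test and raise.
    """
    pairs: list[tuple[str, str]] = []
    for grp in design.replicate_groups:
        present = [s for s in grp if s in A.columns]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                pairs.append((present[i], present[j]))
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 replicate pairs, found {len(pairs)}")
    diffs = np.column_stack(
        [np.abs(A[a].to_numpy() - A[b].to_numpy()) for a, b in pairs]
    )  # (imodulons, pairs)
    if not diffs.any():
        raise ValueError("degenerate null: all replicate differences are zero")
    logs = np.log(diffs + epsilon)
    mu = logs.mean(axis=1)
    sigma = logs.std(axis=1)  # MLE (ddof=0)
    if np.any(sigma == 0):
        bad = list(A.index[sigma == 0])
        raise ValueError(f"degenerate null for iModulons {bad}: zero spread")
    params = pd.DataFrame({"mu": mu, "sigma": sigma}, index=A.index)
    return DimaNull(params=params, n_pairs=len(pairs), epsilon=epsilon)


def dima(
    A: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    null: DimaNull,
    diff_threshold: float = 5.0,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Differential activity test between two sample groups.

    Per iModulon the observed statistic is the absolute difference of group
    mean activities; its p-value is the fitted log-normal's survival there,
    and q-values are Benjamini–Hochberg across iModulons.  Significance
    requires q < `fdr_threshold` AND |difference| > `diff_threshold`.
    Groups of size one are permitted (their mean is the single value) with
    a logged warning.
    """
    if not group1 or not group2:
        raise ValueError("both groups must be nonempty")
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")
    unknown = [s for s in [*group1, *group2] if s not in A.columns]
    if unknown:
        raise ValueError(f"unknown sample identifiers: {unknown}")
    for name, grp in (("group1", group1), ("group2", group2)):
        if len(grp) == 1:
            logger.warning("%s has a single sample; its mean is that sample", name)

    mean1 = A[list(group1)].mean(axis=1)
    mean2 = A[list(group2)].mean(axis=1)
    diff = mean2 - mean1
    pvals = np.array(
        [null.survival(im, abs(d)) for im, d in diff.items()], dtype=float
    )
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "imodulon": A.index,
            "mean_group1": mean1.to_numpy(),
            "mean_group2": mean2.to_numpy(),
            "difference": diff.to_numpy(),
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )
    out["significant"] = (out["qvalue"] < fdr_threshold) & (
        out["difference"].abs() > diff_threshold
    )
    return out


def _as_matrices(X, M, A):
    Xv = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X)
    Mv = M.to_numpy() if isinstance(M, pd.DataFrame) else np.asarray(M)
    Av = A.to_numpy() if isinstance(A, pd.DataFrame) else np.asarray(A)
    return Xv, Mv, Av


def explained_variance(
    X,
    M,
    A,
    imodulon_subset: list | None = None,
    sample_subset: list | None = None,
    clamp: bool = False,
    refit_A: bool = False,
) -> float:
    """Fraction of ||X||²_F captured by reconstructing from an iModulon subset.

    EV = 1 − ||X_T − M_S·A_{S,T}||²_F / ||X_T||²_F, restricted to sample
    subset T and iModulon subset S.  An empty S is a zero reconstruction
    (EV = 0 on any centered X with variance).  A badly mismatched single
    component can give a slightly negative EV; `clamp=True` floors it at 0.

    With `refit_A=True` the activities are re-estimated by least squares on
    the subset (A_S = M_S⁺·X_T), so the reconstruction is the orthogonal
    projection of X onto the subset's column span — the natural choice for
    cumulative curves over non-orthogonal components, and invariant to
    listing a component twice.
    """
    Xv, Mv, Av = _as_matrices(X, M, A)
    if sample_subset is not None:
        cols = (
            [list(X.data.columns).index(s) for s in sample_subset]
            if hasattr(X, "data")
            else list(sample_subset)
        )
        if not cols:
            raise ValueError("sample subset is empty")
        Xv, Av = Xv[:, cols], Av[:, cols]
    if imodulon_subset is not None:
        idx = (
            [list(M.columns).index(i) if isinstance(i, str) else i
             for i in imodulon_subset]
            if isinstance(M, pd.DataFrame)
            else list(imodulon_subset)
        )
        Mv, Av = Mv[:, idx], Av[idx, :]
    denom = np.linalg.norm(Xv) ** 2
    if denom == 0:
        raise ValueError("undefined explained variance: ||X|| is zero")
    if Mv.shape[1] == 0:
        ev = 0.0
    else:
        if refit_A:
            Av = np.linalg.pinv(Mv) @ Xv
        ev = 1.0 - np.linalg.norm(Xv - Mv @ Av) ** 2 / denom
    return max(ev, 0.0) if clamp else float(ev)


def rank_by_explained_variance(
    X, M: pd.DataFrame, A: pd.DataFrame, sample_subset: list | None = None
) -> pd.DataFrame:
    """iModulons ordered by singleton EV, with nested cumulative EV.

    Cumulative values reconstruct from the union of the prefix by
    projecting X onto the prefix's column span (not by summing singleton
    values), so they are nondecreasing, bounded by 1, and unchanged by a
    duplicated component, even for correlated components.
    """
    singles = {
        im: explained_variance(X, M, A, imodulon_subset=[im],
                               sample_subset=sample_subset)
        for im in M.columns
    }
    order = sorted(singles, key=lambda im: -singles[im])
    rows, prefix = [], []
    for im in order:
        prefix.append(im)
        rows.append(
            {
                "imodulon": im,
                "singleton_ev": singles[im],
                "cumulative_ev": explained_variance(
                    X, M, A, imodulon_subset=list(prefix),
                    sample_subset=sample_subset, refit_A=True,
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    """A linear or logarithmic background trend y(x) on a phase plane."""

    model: str                   # "linear" | "logarithmic"
    slope: float
    intercept: float
    x_shift: float               # log model: abscissa is ln(x − x_shift + 1)
    residual_scale: float
    fit_x: np.ndarray = field(repr=False, default=None)
    fit_y: np.ndarray = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            t = x
        else:
            t = np.log(x - self.x_shift + 1.0)
        return self.slope * t + self.intercept


def fit_trendline(
    x,
    y,
    model: str = "linear",
    fit_mask=None,
) -> TrendFit:
    """Least-squares trend of y on x (linear) or on ln(x − min(x) + 1) (log).

    `fit_mask` selects the background samples the trend is fitted to
    (deviating samples are then scored by `distance_to_trendline`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if model not in ("linear", "logarithmic"):
        raise ValueError(f"unknown trend model {model!r}")
    if fit_mask is not None:
        mask = np.asarray(fit_mask)
        xf, yf = x[mask], y[mask]
    else:
        xf, yf = x, y
    if xf.size < 3:
        raise ValueError(f"need at least 3 fit points, got {xf.size}")
    if np.ptp(xf) == 0:
        raise ValueError("degenerate abscissa: x is constant on the fit set")
    shift = float(xf.min()) if model == "logarithmic" else 0.0
    t = xf if model == "linear" else np.log(xf - shift + 1.0)
    slope, intercept = np.polyfit(t, yf, 1)
    resid = yf - (slope * t + intercept)
    return TrendFit(
        model=model,
        slope=float(slope),
        intercept=float(intercept),
        x_shift=shift,
        residual_scale=float(np.sqrt(np.mean(resid**2))),
        fit_x=xf,
        fit_y=yf,
    )


def distance_to_trendline(x, y, fit: TrendFit) -> np.ndarray:
    """Signed vertical residual y − ŷ(x); points above the line positive."""
    return np.asarray(y, dtype=float) - fit.predict(x)
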