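"""Drug-sensitivity filtering and prediction.

The response stage emulates the contract of expression-based drug-response
prediction: discard drugs missing in more than 20% of cell lines, impute the
remaining gaps by k-nearest-neighbor averaging over cell lines, fit a ridge
regression from expression to log IC50, threshold predicted sensitivity at
10 uM, and keep only drugs that qualify in every screen (GDSC1&2-style
co-occurrence).

Response matrices are cell-line x drug DataFrames of IC50 values in uM with
NaN marking missing entries.  Expression matrices are gene x sample frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def validate_response_matrix(m: pd.DataFrame) -> pd.DataFrame:
    if m.index.duplicated().any() or m.columns.duplicated().any():
        raise ValueError("cell-line and drug identifiers must be unique")
    observed = m.to_numpy(dtype=float)
    if np.any(observed[~np.isnan(observed)] <= 0):
        raise ValueError("observed IC50 values must be strictly positive")
    return m


def drop_missing_drugs(m: pd.DataFrame, max_na_frac: float = 0.20) -> pd.DataFrame:
    """Remove drugs missing in strictly more than ``max_na_frac`` of lines."""
    validate_response_matrix(m)
    frac = m.isna().mean(axis=0)
    keep = frac.index[(frac <= max_na_frac).to_numpy()]
    return m.loc[:, keep]


def knn_impute(m: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing entries from the k nearest cell lines.

    Distance between lines is the root-mean-square difference over jointly
    observed drugs after dividing each drug column by its observed mean;
    lines sharing no observed drug are infinitely far.  A missing
    (line, drug) entry becomes the unweighted mean of that drug's values over
    the k nearest lines that observe it (ties broken by line id) and is then
    clamped to the drug's observed range.
    """
    validate_response_matrix(m)
    if k < 1:
        raise ValueError("k must be >= 1")
    values = m.to_numpy(dtype=float)
    n_lines, n_drugs = values.shape
    fully_missing = np.isnan(values).all(axis=0)
    if fully_missing.any():
        bad = list(m.columns[fully_missing])
        raise ValueError(f"no line observes drug(s): {', '.join(map(str, bad))}")
    col_mean = np.nanmean(values, axis=0)
    scaled = values / col_mean
    observed = ~np.isnan(values)
    line_ids = [str(i) for i in m.index]

    out = values.copy()
    for i in range(n_lines):
        missing_cols = np.flatnonzero(~observed[i])
        if missing_cols.size == 0:
            continue
        dists = np.full(n_lines, np.inf)
        for j in range(n_lines):
            if j == i:
                continue
            both = observed[i] & observed[j]
            if not both.any():
                continue
            diff = scaled[i, both] - scaled[j, both]
            dists[j] = float(np.sqrt(np.mean(diff**2)))
        order = sorted(
            (j for j in range(n_lines) if j != i),
            key=lambda j: (dists[j], line_ids[j]),
        )
        for c in missing_cols:
            donors = [j for j in order if observed[j, c]][:k]
            if not donors:
                raise ValueError(
                    f"cannot impute ({line_ids[i]}, {m.columns[c]}): "
                    "no observing neighbor"
                )
            val = float(np.mean(values[donors, c]))
            lo = float(np.nanmin(values[:, c]))
            hi = float(np.nanmax(values[:, c]))
            out[i, c] = min(max(val, lo), hi)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


@dataclass
class RidgeModel:
    """Ridge fit from expression to log IC50 (natural log, uM)."""

    coef: pd.Series  # indexed by gene
    intercept: float
    lam: float


_DEFAULT_GRID = np.logspace(-3.0, 4.0, 15)


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> Tuple[np.ndarray, float]:
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    p = X.shape[1]
    coef = np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ yc)
    return coef, float(y_mean - x_mean @ coef)


def _gcv(X: np.ndarray, y: np.ndarray, lam: float) -> float:
    # LOO-GCV via SVD of the centered design: GCV = n*RSS / (n - edf)^2
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    shrink = s**2 / (s**2 + lam)
    fitted = U @ (shrink * (U.T @ yc))
    rss = float(np.sum((yc - fitted) ** 2))
    edf = float(np.sum(shrink)) + 1.0  # +1 for the unpenalized intercept
    return n * rss / (n - edf) ** 2 if n > edf else np.inf


def ridge_fit(
    expr: pd.DataFrame,
    y: pd.Series,
    lam: Optional[float] = None,
    grid: Sequence[float] = _DEFAULT_GRID,
) -> RidgeModel:
    """Penalized least squares of ln(IC50) on expression, intercept unpenalized.

    ``expr`` is genes x training lines; ``y`` holds positive IC50 values (uM)
    per line.  When ``lam`` is None it is chosen by leave-one-out generalized
    cross-validation over ``grid``.
    """
    if lam is not None and lam < 0:
        raise ValueError("lambda must be >= 0")
    lines = [l for l in expr.columns if l in set(y.index)]
    if len(lines) < 2:
        raise ValueError("need at least 2 training lines")
    X = expr[lines].to_numpy(dtype=float).T  # lines x genes
    yv = y.loc[lines].to_numpy(dtype=float)
    if np.any(yv <= 0):
        raise ValueError("IC50 responses must be strictly positive")
    y_log = np.log(yv)
    if np.ptp(y_log) == 0:  # constant response: intercept-only model
        coef = pd.Series(np.zeros(expr.shape[0]), index=expr.index)
        return RidgeModel(coef, float(y_log[0]), lam if lam is not None else 0.0)
    if lam is None:
        lam = float(min(grid, key=lambda g: _gcv(X, y_log, g)))
    beta, intercept = _ridge_solve(X, y_log, lam)
    return RidgeModel(pd.Series(beta, index=expr.index), intercept, float(lam))


def ridge_predict(model: RidgeModel, expr: pd.DataFrame) -> pd.Series:
    """Predicted IC50 (uM, back-transformed) for new samples (genes x samples)."""
    X = expr.loc[model.coef.index].to_numpy(dtype=float).T
    return pd.Series(
        np.exp(X @ model.coef.to_numpy() + model.intercept), index=expr.columns
    )


def sensitive_drugs(
    predictions: Mapping[str, pd.DataFrame],
    threshold_um: float = 10.0,
    group: Optional[Sequence[str]] = None,
) -> Set[str]:
    """Drugs with mean predicted IC50 < threshold in every screen.

    ``predictions`` maps screen label to a samples x drugs IC50 frame; the
    mean is taken over ``group`` rows (default: all rows, i.e. the BM group).
    The returned set is the intersection across screens (co-occurrence rule).
    """
    if len(predictions) == 0:
        raise ValueError("need at least one screen")
    qualifying = []
    for screen in sorted(predictions):
        frame = predictions[screen]
        sub = frame.loc[list(group)] if group is not None else frame
        if sub.isna().any().any():
            raise ValueError(f"screen {screen}: predictions must be complete")
        means = sub.mean(axis=0)
        qualifying.append({str(d) for d in means.index[(means < threshold_um).to_numpy()]})
    out = qualifying[0]
    for q in qualifying[1:]:
        out &= q
    return out


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    # exact permutation null when untied (matches an exhaustive enumeration);
    # tie-corrected normal approximation otherwise
    method = "asymptotic" if len(np.unique(np.concatenate([a, b]))) < len(a) + len(b) else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
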