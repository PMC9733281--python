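"""Between-array normalization of background-corrected intensities.

Four methods, mirroring what single-channel array studies usually compare:

* none — log2 transform only,
* scale — per-array median scaling on the linear scale (factors chosen so
  every post-scaling median equals the geometric mean of the input
  medians), then log2,
* quantile — rank-mean quantile normalization on the log2 scale; forces an
  identical intensity distribution on every array,
* fast cyclic loess — each array is adjusted by a robust loess fit of M on
  A against a reference array (the average of all arrays), iterated a few
  times; the least aggressive of the distribution-matching methods.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ArraySet, NormalizedSet, ValidationError


def _log2_missing(E: np.ndarray) -> np.ndarray:
    """log2 with non-positive values mapped to missing."""
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = np.where(E > 0, np.log2(np.maximum(E, np.finfo(float).tiny)), np.nan)
    return Y


def to_log2(arrayset: ArraySet) -> NormalizedSet:
    """log2-transform a background-corrected linear-state matrix; no
    normalization.  Non-positive entries become missing."""
    if arrayset.log_state != "linear":
        raise ValidationError("to_log2 expects a linear-state ArraySet")
    Y = _log2_missing(arrayset.E.to_numpy(dtype=float))
    return NormalizedSet(
        Y=pd.DataFrame(Y, columns=arrayset.E.columns, index=arrayset.E.index),
        method="none",
        probes=arrayset.probes,
        targets=arrayset.targets,
    )


def norm_scale(arrayset: ArraySet) -> NormalizedSet:
    """Median-scale each array on the linear scale, then log2.

    Array j is multiplied by f_j = g / median_j with g the geometric mean
    of the per-array medians (missing values excluded), so all post-scaling
    medians equal g.
    """
    if arrayset.log_state != "linear":
        raise ValidationError("scale normalization operates on the linear scale")
    E = arrayset.E.to_numpy(dtype=float)
    medians = np.nanmedian(E, axis=0)
    if np.any(~np.isfinite(medians)) or np.any(medians <= 0):
        raise ValidationError(
            f"scale normalization needs positive array medians, got {medians}"
        )
    g = float(stats.gmean(medians))
    factors = g / medians
    Y = _log2_missing(E * factors[np.newaxis, :])
    return NormalizedSet(
        Y=pd.DataFrame(Y, columns=arrayset.E.columns, index=arrayset.E.index),
        method="scale",
        parameters={"scale_factors": dict(zip(arrayset.sample_ids, factors))},
        probes=arrayset.probes,
        targets=arrayset.targets,
    )


def norm_quantile(Y, probes=None, targets=None) -> NormalizedSet:
    """Quantile normalization of a log2 matrix (classic rank-mean rule).

    The reference distribution is the across-array mean of the sorted
    values of complete rows.  Every value is then replaced by the reference
    quantile at its within-column rank; tied values receive the mean of
    their tied reference values, and rows with missing values are
    rank-interpolated onto the reference quantile function.
    """
    Y = pd.DataFrame(Y)
    V = Y.to_numpy(dtype=float)
    n, J = V.shape
    counts = np.isfinite(V).sum(axis=0)
    if np.any(counts == 0):
        bad = [Y.columns[j] for j in np.flatnonzero(counts == 0)]
        raise ValidationError(f"arrays entirely missing: {bad}")
    complete = np.all(np.isfinite(V), axis=1)
    m = int(complete.sum())
    if m < 2:
        raise ValidationError(
            f"quantile normalization needs >= 2 complete rows, got {m}"
        )
    ref = np.sort(V[complete], axis=0).mean(axis=1)  # length m, ascending
    ref_p = np.linspace(0.0, 1.0, m)

    out = np.full_like(V, np.nan)
    for j in range(J):
        col = V[:, j]
        finite = np.isfinite(col)
        k = int(finite.sum())
        # average ranks so ties get the mean of their tied reference values
        ranks = stats.rankdata(col[finite], method="average")
        p = (ranks - 1.0) / (k - 1.0) if k > 1 else np.array([0.5])
        out[finite, j] = np.interp(p, ref_p, ref)
    return NormalizedSet(
        Y=pd.DataFrame(out, columns=Y.columns, index=Y.index),
        method="quantile",
        parameters={"n_reference_rows": m},
        probes=probes,
        targets=targets,
    )


def norm_cyclicloess_fast(
    Y, span: float = 0.7, iterations: int = 3, probes=None, targets=None
) -> NormalizedSet:
    """Fast cyclic loess normalization of a log2 matrix.

    Per iteration the reference is the missing-aware row mean of all
    arrays; each array j is corrected by subtracting a robust local-linear
    loess fit (tricube weights, 2 robustness iterations) of
    M = Y_j - ref on A = (Y_j + ref)/2.  The reference is recomputed at the
    start of every pass.
    """
    Y = pd.DataFrame(Y)
    if Y.shape[1] < 2:
        raise ValidationError("cyclic loess needs at least 2 arrays")
    if not 0.0 < span <= 1.0:
        raise ValidationError(f"span must lie in (0, 1], got {span}")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    V = Y.to_numpy(dtype=float).copy()
    for _ in range(int(iterations)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            ref = np.nanmean(V, axis=1)
        for j in range(V.shape[1]):
            M = V[:, j] - ref
            A = 0.5 * (V[:, j] + ref)
            finite = np.isfinite(M) & np.isfinite(A)
            if finite.sum() < 10:
                raise ValidationError(
                    f"array {Y.columns[j]!r}: fewer than 10 complete points "
                    "for the loess smoother"
                )
            a = A[finite]
            delta = 0.01 * (a.max() - a.min())
            fitted = lowess(
                M[finite],
                a,
                frac=span,
                it=2,
                delta=delta,
                return_sorted=False,
            )
            V[finite, j] -= fitted
    return NormalizedSet(
        Y=pd.DataFrame(V, columns=Y.columns, index=Y.index),
        method="cyclicloess",
        parameters={"span": span, "iterations": int(iterations)},
        probes=probes,
        targets=targets,
    )


def normalize(arrayset: ArraySet, method: str, **kwargs) -> NormalizedSet:
    """Dispatch by method name: none, scale, quantile or cyclicloess."""
    if method == "none":
        return to_log2(arrayset)
    if method == "scale":
        return norm_scale(arrayset)
    if method == "quantile":
        base = to_log2(arrayset)
        return norm_quantile(base.Y, probes=arrayset.probes, targets=arrayset.targets)
    if method == "cyclicloess":
        base = to_log2(arrayset)
        return norm_cyclicloess_fast(
            base.Y, probes=arrayset.probes, targets=arrayset.targets, **kwargs
        )
    raise ValidationError(f"unknown normalization method {method!r}")
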