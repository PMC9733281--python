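"""Spot filtering and background correction.

Spot filtering flags "noisy" spots whose foreground falls below a per-array
noise threshold, median(bg) + 2*sd(bg); flagged values become missing (NA)
so the matrix keeps its shape.

Four background-correction methods are provided:

* ``none`` — foreground used as-is (background treated as zero),
* ``subtract`` — fg - bg; non-positive results go missing at the log2 step,
* ``movingmin`` — bg replaced by the 3x3 within-block neighbourhood minimum
  before subtraction, robust to local artefacts such as dust,
* ``normexp`` — model-based: the background-subtracted signal x = fg - bg
  is modelled as X = B + S with B ~ N(mu, sigma^2) and S ~ Exp(mean alpha);
  (mu, sigma, alpha) are estimated by exact maximum likelihood and each
  intensity is replaced by the posterior mean E[S | X = x], which is a
  smooth, strictly increasing transform with strictly positive output.

The normexp+offset variant adds a constant k after correction; k can be
chosen by maximizing the empirical-Bayes prior degrees of freedom over a
grid (a variance-stabilization criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .containers import ArraySet, FitError, NormexpParams, ValidationError

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class NoiseThresholds:
    """Per-array spot-filter thresholds T_j = median(bg) + 2 sd(bg) and the
    number of foreground values set missing on each array."""

    thresholds: pd.Series
    n_filtered: pd.Series


def filter_spots(arrayset: ArraySet) -> tuple[ArraySet, NoiseThresholds]:
    """Set foreground values below the per-array noise threshold missing.

    The threshold of array j is median(B_j) + 2*sd(B_j) over all spots of
    that array (sample sd); backgrounds are left untouched.  Idempotent.
    """
    if arrayset.log_state != "linear":
        raise ValidationError("spot filtering operates on linear intensities")
    if arrayset.n_spots < 3:
        raise ValidationError("need at least 3 spots per array to estimate sd")
    out = arrayset.copy()
    B = out.B.to_numpy(dtype=float)
    med = np.median(B, axis=0)
    sd = np.std(B, axis=0, ddof=1)
    T = med + 2.0 * sd
    E = out.E.to_numpy(dtype=float)
    mask = E < T[np.newaxis, :]
    E = np.where(mask, np.nan, E)
    out.E = pd.DataFrame(E, columns=out.E.columns, index=out.E.index)
    thr = NoiseThresholds(
        thresholds=pd.Series(T, index=out.sample_ids),
        n_filtered=pd.Series(mask.sum(axis=0), index=out.sample_ids),
    )
    out.log(
        "filter:2sd thresholds "
        + ", ".join(f"{s}={t:.4g}" for s, t in thr.thresholds.items())
    )
    return out, thr


def bgcorrect_none(arrayset: ArraySet) -> ArraySet:
    """No correction: background treated as zero, E unchanged."""
    out = arrayset.copy()
    out.log("background:none")
    return out


def bgcorrect_subtract(arrayset: ArraySet) -> ArraySet:
    """Plain local-background subtraction, E <- fg - bg.

    Non-positive corrected values are kept (they become missing at the
    subsequent log2 step); their count is recorded in the processing log.
    """
    out = arrayset.copy()
    E = out.E.to_numpy(dtype=float) - out.B.to_numpy(dtype=float)
    n_nonpos = int(np.sum(E <= 0))
    out.E = pd.DataFrame(E, columns=out.E.columns, index=out.E.index)
    out.log(f"background:subtract, {n_nonpos} non-positive corrected values")
    return out


def _movingmin_background(arrayset: ArraySet) -> np.ndarray:
    """3x3 within-block neighbourhood minimum of bg for every spot."""
    probes = arrayset.probes
    B = arrayset.B.to_numpy(dtype=float)
    out = np.empty_like(B)
    for block in probes["block"].unique():
        idx = np.flatnonzero((probes["block"] == block).to_numpy())
        rows = probes["row"].to_numpy()[idx]
        cols = probes["column"].to_numpy()[idx]
        r0, c0 = rows.min(), cols.min()
        grid_shape = (rows.max() - r0 + 1, cols.max() - c0 + 1)
        for j in range(B.shape[1]):
            grid = np.full(grid_shape, np.inf)
            grid[rows - r0, cols - c0] = B[idx, j]
            mins = ndimage.minimum_filter(
                grid, size=3, mode="constant", cval=np.inf
            )
            out[idx, j] = mins[rows - r0, cols - c0]
    return out


def bgcorrect_movingmin(arrayset: ArraySet) -> ArraySet:
    """Moving-minimum correction: subtract the 3x3 neighbourhood minimum
    background (within-block; edge spots use only existing neighbours)."""
    out = arrayset.copy()
    bgmin = _movingmin_background(out)
    E = out.E.to_numpy(dtype=float) - bgmin
    n_nonpos = int(np.sum(E <= 0))
    out.E = pd.DataFrame(E, columns=out.E.columns, index=out.E.index)
    out.log(f"background:movingminimum, {n_nonpos} non-positive corrected values")
    return out


# ---------------------------------------------------------------------------
# normexp convolution model


def normexp_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    """Negative log-likelihood of x under the normal+exponential model,
    parametrized as (mu, log sigma, log alpha)."""
    mu, lsigma, lalpha = theta
    sigma = np.exp(lsigma)
    alpha = np.exp(lalpha)
    z = (x - mu - sigma**2 / alpha) / sigma
    ll = (
        -lalpha
        + (mu - x) / alpha
        + sigma**2 / (2.0 * alpha**2)
        + special.log_ndtr(z)
    )
    return -float(np.sum(ll))


def normexp_fit(fg, bg=None) -> NormexpParams:
    """Fit the normal+exponential convolution model by maximum likelihood.

    Parameters
    ----------
    fg, bg : array-like
        Foreground and background intensities; the model is fitted to the
        background-subtracted signal x = fg - bg.  ``bg`` may be omitted if
        ``fg`` is already the corrected-scale vector.

    Returns
    -------
    NormexpParams
        (mu, sigma, alpha) at the optimum plus the achieved log-likelihood
        and a convergence flag.

    Notes
    -----
    Optimization is unconstrained Nelder-Mead over (mu, log sigma,
    log alpha) with moment-based starting values: mu0 = 5th percentile of
    x, sigma0 = sd of the mirrored lower tail, alpha0 = mean(x) - mu0.
    """
    x = np.asarray(fg, dtype=float)
    if bg is not None:
        x = x - np.asarray(bg, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise FitError(f"normexp fit needs >= 10 finite values, got {x.size}")
    if np.ptp(x) <= 0:
        raise FitError("normexp fit impossible: all values identical")

    mu0 = float(np.percentile(x, 5))
    lower = x[x < mu0] - mu0
    sigma0 = float(np.sqrt(np.mean(lower**2))) if lower.size else float(np.std(x)) / 10
    sigma0 = max(sigma0, 1e-6 * np.ptp(x))
    alpha0 = max(float(np.mean(x)) - mu0, 1e-6 * np.ptp(x))

    theta0 = np.array([mu0, np.log(sigma0), np.log(alpha0)])
    res = optimize.minimize(
        normexp_negloglik,
        theta0,
        args=(x,),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000, "maxfev": 5000},
    )
    mu, lsigma, lalpha = res.x
    return NormexpParams(
        mu=float(mu),
        sigma=float(np.exp(lsigma)),
        alpha=float(np.exp(lalpha)),
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
    )


def normexp_signal(x, params: NormexpParams):
    """Posterior mean E[S | X = x] of the true signal; strictly positive.

    With mu_sx = x - mu - sigma^2/alpha and t = mu_sx/sigma,

        E[S | X = x] = mu_sx + sigma * phi(t)/Phi(t) = sigma * (t + h(t)),

    evaluated through log phi - log Phi for stability; in the deep lower
    tail (t << 0) the Mills-ratio expansion sigma*(-1/t)(1 - 2/t^2) is used
    to avoid catastrophic cancellation.  The stored offset k is added
    afterwards by the caller.
    """
    for name, val in (("mu", params.mu), ("sigma", params.sigma), ("alpha", params.alpha)):
        if not np.isfinite(val):
            raise ValidationError(f"non-finite normexp parameter {name}={val}")
    x = np.asarray(x, dtype=float)
    sigma = params.sigma
    mu_sx = x - params.mu - sigma**2 / params.alpha
    t = mu_sx / sigma
    with np.errstate(over="ignore"):
        log_phi = -0.5 * t**2 - _LOG_SQRT_2PI
        h = np.exp(log_phi - special.log_ndtr(t))
    direct = sigma * (t + h)
    deep = np.errstate(divide="ignore", invalid="ignore")
    with deep:
        asymptotic = sigma * (-1.0 / t) * (1.0 - 2.0 / t**2)
    out = np.where(t < -1e4, asymptotic, direct)
    # guard against residual round-off at the positivity boundary
    tiny = np.finfo(float).tiny
    out = np.maximum(out, tiny)
    return out if out.ndim else float(out)


def bgcorrect_normexp(arrayset: ArraySet, offset: float = 0.0) -> ArraySet:
    """Normexp-correct every array: fit the convolution model to fg - bg
    per array, replace E by the posterior signal plus ``offset``.

    Fitted per-array parameters are stored on the result as
    ``normexp_params`` and summarized in the processing log.
    """
    if offset < 0:
        raise ValidationError("normexp offset must be >= 0")
    out = arrayset.copy()
    E = out.E.to_numpy(dtype=float)
    B = out.B.to_numpy(dtype=float)
    params_list = []
    corrected = np.empty_like(E)
    for j in range(E.shape[1]):
        x = E[:, j] - B[:, j]
        params = normexp_fit(x)
        params.offset = offset
        finite = np.isfinite(x)
        col = np.full_like(x, np.nan)
        col[finite] = normexp_signal(x[finite], params) + offset
        corrected[:, j] = col
        params_list.append(params)
    out.E = pd.DataFrame(corrected, columns=out.E.columns, index=out.E.index)
    out.normexp_params = params_list
    out.log(
        f"background:normexp(k={offset:g}) "
        + ", ".join(
            f"{s}:(mu={p.mu:.4g},sigma={p.sigma:.4g},alpha={p.alpha:.4g})"
            for s, p in zip(out.sample_ids, params_list)
        )
    )
    return out


BACKGROUND_METHODS = {
    "none": bgcorrect_none,
    "subtract": bgcorrect_subtract,
    "movingminimum": bgcorrect_movingmin,
    "normexp": bgcorrect_normexp,
}


def select_offset(arrayset: ArraySet, design, k_grid=None):
    """Choose the normexp offset k maximizing the prior degrees of freedom.

    For each k on the grid the set is normexp-corrected with offset k,
    log2-transformed, cyclic-loess normalized, consolidated and fitted
    probe-wise; the empirical-Bayes prior df d0 measures how stable the
    residual variances are.  Returns (best k, DataFrame of k vs d0); ties
    go to the first occurrence.
    """
    from .diffexp import ebayes, fit_probewise
    from .normalize import norm_cyclicloess_fast, to_log2
    from .summarize import consolidate

    if k_grid is None:
        k_grid = list(range(0, 55, 5))
    k_grid = list(k_grid)
    if not k_grid:
        raise ValidationError("offset grid is empty")
    if any(k < 0 for k in k_grid):
        raise ValidationError("offsets must be >= 0")

    records = []
    errors = []
    for k in k_grid:
        try:
            corrected = bgcorrect_normexp(arrayset, offset=float(k))
            nset = to_log2(corrected)
            if arrayset.n_arrays >= 2:
                nset = norm_cyclicloess_fast(nset.Y, probes=corrected.probes)
            expr = consolidate(
                nset.Y, corrected.probes, targets=corrected.targets, drop=()
            )
            fit = fit_probewise(expr.values, np.asarray(design, dtype=float))
            stats = ebayes(fit)
            records.append({"k": k, "df_prior": stats.d0})
        except Exception as exc:  # noqa: BLE001 - per-k failures are recorded
            errors.append((k, str(exc)))
    if not records:
        raise FitError(f"offset selection failed for every k: {errors}")
    table = pd.DataFrame(records)
    best = table.loc[table["df_prior"].idxmax(), "k"]
    return float(best), table
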