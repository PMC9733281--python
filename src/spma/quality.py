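"""Array quality weights from a heteroscedastic linear model (REML).

Model: for probe g, y_g = X b_g + e_g with Var(e_gj) = sigma_g^2 *
exp(z_j' gamma), where z_j encodes array indicators under a sum-to-zero
constraint, so the per-array variance factors multiply to one and the
weights w_j = exp(-gamma_j) act purely relatively.

gamma is estimated by Fisher scoring on the restricted (REML)
log-likelihood aggregated over probes, with the probe-level variances
sigma_g^2 profiled out.  At each step every probe is fitted by weighted
least squares with the current weights; writing d_j for the squared
standardized residual w_j r_j^2 / sigma_hat_g^2 and h_j for the weighted
hat leverage, the score is (1/2) Z' (d - (1 - h)) and the expected
information (1/2) Z' ((I - H)∘(I - H)) Z (elementwise square).  The
scoring fixed point is exactly the maximizer of the profiled REML
criterion exposed as :func:`reml_criterion`, which generic optimizers can
verify independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FitError, ValidationError


@dataclass
class ArrayWeightResult:
    """Per-array log-variance factors gamma (sum-to-zero) and weights
    w = exp(-gamma) (product one)."""

    gamma: pd.Series
    weights: pd.Series
    iterations: int
    converged: bool


def _sum_to_zero_basis(J: int) -> np.ndarray:
    """J x (J-1) basis C with columns summing to zero: gamma = C @ free."""
    C = np.zeros((J, J - 1))
    C[: J - 1, :] = np.eye(J - 1)
    C[J - 1, :] = -1.0
    return C


def _probe_groups(V: np.ndarray, p: int):
    """Group probe indices by identical finite-value pattern, keeping only
    probes with enough observations for a residual df >= 1."""
    finite = np.isfinite(V)
    enough = finite.sum(axis=1) >= p + 1
    groups = {}
    for g in np.flatnonzero(enough):
        key = tuple(np.flatnonzero(finite[g]))
        groups.setdefault(key, []).append(g)
    return groups


def reml_criterion(gamma: np.ndarray, V: np.ndarray, X: np.ndarray) -> float:
    """Profiled restricted log-likelihood of gamma (up to a constant).

    Sum over probes of -1/2 [ (n_g - p) log(RSS_w,g) + sum_j gamma_j
    + log|X' W X| ] with W = diag(exp(-gamma)) restricted to the probe's
    available arrays.  Probes need n_g >= p + 1 observations.
    """
    gamma = np.asarray(gamma, dtype=float)
    p = X.shape[1]
    total = 0.0
    for key, idx in _probe_groups(V, p).items():
        cols = np.array(key)
        Xs = X[cols]
        if np.linalg.matrix_rank(Xs) < p:
            continue
        w = np.exp(-gamma[cols])
        sw = np.sqrt(w)
        Xw = Xs * sw[:, None]
        Yg = V[np.ix_(idx, cols)]  # probes x arrays(avail)
        Yw = Yg * sw[None, :]
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ Yw.T)
        R = Yw.T - Xw @ beta
        rss = np.sum(R**2, axis=0)
        n_g = len(cols)
        sign, logdet = np.linalg.slogdet(XtX)
        ll = -0.5 * (
            (n_g - p) * np.log(np.maximum(rss, 1e-300))
            + np.sum(gamma[cols])
            + logdet
        )
        total += float(np.sum(ll))
    return total


def fit_array_weights(
    Y,
    design,
    max_iterations: int = 200,
    tol: float = 1e-6,
) -> ArrayWeightResult:
    """Estimate per-array quality weights by REML Fisher scoring.

    Parameters
    ----------
    Y : DataFrame or array, probes x arrays
        Normalized log2 expression values; missing entries allowed (probes
        contribute through their available arrays only).
    design : array, arrays x coefficients
        Full-rank design matrix of the mean model.

    Returns
    -------
    ArrayWeightResult
        gamma (sum-to-zero) and w = exp(-gamma) per array.
    """
    Y = pd.DataFrame(Y)
    V = Y.to_numpy(dtype=float)
    X = np.asarray(design, dtype=float)
    J, p = X.shape
    if V.shape[1] != J:
        raise ValidationError("design rows must match the number of arrays")
    if np.linalg.matrix_rank(X) < p:
        raise FitError("singular design matrix")
    if J < p + 2:
        raise ValidationError(
            f"need at least {p + 2} arrays for {p} design columns, got {J}"
        )
    groups = _probe_groups(V, p)
    if not groups:
        raise FitError("no probe has enough finite values to estimate weights")

    C = _sum_to_zero_basis(J)
    free = np.zeros(J - 1)
    converged = False
    crit = reml_criterion(C @ free, V, X)
    it = 0
    for it in range(1, max_iterations + 1):
        gamma = C @ free
        U = np.zeros(J - 1)
        info = np.zeros((J - 1, J - 1))
        for key, idx in groups.items():
            cols = np.array(key)
            Xs = X[cols]
            if np.linalg.matrix_rank(Xs) < p:
                continue
            w = np.exp(-gamma[cols])
            sw = np.sqrt(w)
            Xw = Xs * sw[:, None]
            XtX = Xw.T @ Xw
            Hw = Xw @ np.linalg.solve(XtX, Xw.T)
            h = np.diag(Hw)
            Mres = np.eye(len(cols)) - Hw
            Yg = V[np.ix_(idx, cols)]
            Yw = Yg * sw[None, :]
            Rw = Yw - (Xw @ np.linalg.solve(XtX, Xw.T @ Yw.T)).T
            rss = np.sum(Rw**2, axis=1)  # per probe
            df = len(cols) - p
            s2 = np.maximum(rss / df, 1e-300)
            d = Rw**2 / s2[:, None]  # squared standardized residuals
            q = d - (1.0 - h)[None, :]
            Cs = C[cols]
            U += 0.5 * Cs.T @ q.sum(axis=0)
            info += 0.5 * len(idx) * (Cs.T @ (Mres**2) @ Cs)
        try:
            delta = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular REML information matrix: {exc}") from exc
        # line search along the scoring direction: halve on failure and,
        # because the expected information over-damps steps far from the
        # optimum, expand while the criterion keeps improving
        step = 1.0
        new_crit = reml_criterion(C @ (free + step * delta), V, X)
        if new_crit < crit - 1e-10:
            for _ in range(20):
                step *= 0.5
                new_crit = reml_criterion(C @ (free + step * delta), V, X)
                if new_crit >= crit - 1e-10:
                    break
        else:
            while step < 64.0:
                wider = reml_criterion(C @ (free + 2.0 * step * delta), V, X)
                if wider <= new_crit:
                    break
                step *= 2.0
                new_crit = wider
        free = free + step * delta
        crit = new_crit
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break

    if not converged:
        # scoring can crawl when an array's variance factor is extreme
        # (the expected information misjudges the curvature there); polish
        # the surviving iterate by direct maximization of the criterion
        from scipy import optimize

        res = optimize.minimize(
            lambda f: -reml_criterion(C @ f, V, X),
            free,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 5000},
        )
        if -res.fun >= crit:
            free = res.x
            converged = bool(res.success)

    gamma = C @ free
    weights = np.exp(-gamma)
    return ArrayWeightResult(
        gamma=pd.Series(gamma, index=Y.columns),
        weights=pd.Series(weights, index=Y.columns),
        iterations=it,
        converged=converged,
    )


def drop_lowest_arrays(Y, weights: ArrayWeightResult, n_drop: int = 2):
    """Remove the ``n_drop`` lowest-weight arrays (ties broken by array
    order).  Returns (reduced matrix, kept column labels, dropped labels).
    """
    Y = pd.DataFrame(Y)
    J = Y.shape[1]
    if n_drop < 0:
        raise ValidationError("n_drop must be >= 0")
    if n_drop >= J:
        raise ValidationError(f"cannot drop {n_drop} of {J} arrays")
    w = weights.weights.reindex(Y.columns).to_numpy(dtype=float)
    order = np.argsort(w, kind="stable")
    dropped = [Y.columns[i] for i in sorted(order[:n_drop])]
    kept = [c for c in Y.columns if c not in set(dropped)]
    return Y[kept], kept, dropped


def write_weights(weights: ArrayWeightResult, path) -> None:
    """Two-column TSV (sample_id, weight)."""
    df = pd.DataFrame(
        {"sample_id": weights.weights.index, "weight": weights.weights.to_numpy()}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
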