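"""Weighted probe-wise linear models and empirical-Bayes moderated t.

The mean model uses a group-means parametrization (one coefficient per
condition level) with explicit contrast columns built from the metadata,
so two-group and multi-group designs are handled uniformly.  Array quality
weights enter as prior weights of the per-probe weighted least squares
fit.  Residual variances are then shrunk toward a common prior: the prior
degrees of freedom d0 and prior variance s0^2 are estimated by moment
matching on e_g = log s_g^2 - psi(d_g/2) + log(d_g/2) (psi the digamma
function), solving psi'(d0/2) = mean[(e - ebar)^2 n/(n-1) - psi'(d_g/2)]
by Newton inversion of the trigamma function; varying residual df d_g
(from missing values) are handled exactly.  The moderated t-statistic
divides each coefficient by its standard error computed from the posterior
variance s_tilde_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g) on d0 + d_g
degrees of freedom (the normal limit when d0 is infinite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import FitError, ValidationError


def make_design(targets: pd.DataFrame) -> pd.DataFrame:
    """Group-means design matrix: one indicator column per condition level,
    levels in order of first appearance."""
    cond = targets["Condition"].astype(str)
    levels = list(dict.fromkeys(cond))
    X = pd.DataFrame(
        {lev: (cond == lev).astype(float).to_numpy() for lev in levels},
        index=targets["SampleID"],
    )
    return X


def make_contrasts(targets: pd.DataFrame, comparisons: list[str]) -> pd.DataFrame:
    """Build a contrast matrix from "A-B" comparison strings.

    Each comparison maps the group-means parametrization to the difference
    mean(A) - mean(B).
    """
    cond = targets["Condition"].astype(str)
    levels = list(dict.fromkeys(cond))
    cols = {}
    for comp in comparisons:
        if comp.count("-") != 1:
            raise ValidationError(
                f"comparison {comp!r} must be of the form 'A-B'"
            )
        a, b = (s.strip() for s in comp.split("-"))
        for lev in (a, b):
            if lev not in levels:
                raise ValidationError(
                    f"comparison {comp!r} names unknown condition {lev!r}; "
                    f"available: {levels}"
                )
        if a == b:
            raise ValidationError(f"degenerate contrast {comp!r} (zero column)")
        vec = np.zeros(len(levels))
        vec[levels.index(a)] = 1.0
        vec[levels.index(b)] = -1.0
        cols[comp] = vec
    return pd.DataFrame(cols, index=levels)


@dataclass
class ProbeFit:
    """Per-probe weighted least-squares results."""

    coefficients: pd.DataFrame  # probes x coefficients (log2 units)
    stdev_unscaled: pd.DataFrame  # unscaled coefficient sd (dimensionless)
    sigma: pd.Series  # residual sd per probe
    df_residual: pd.Series  # residual df per probe
    cov_unscaled: np.ndarray  # probes x p x p unscaled covariance
    design_columns: list = field(default_factory=list)


def fit_probewise(E, design, weights=None) -> ProbeFit:
    """Weighted least squares per probe with prior array weights.

    Missing values reduce each probe's residual df; a probe observed on
    fewer arrays than the design rank gets coefficients where estimable
    and no variance estimate (df 0, inestimable entries NaN).
    """
    E = pd.DataFrame(E)
    V = E.to_numpy(dtype=float)
    X = np.asarray(design, dtype=float)
    design_cols = (
        list(design.columns) if isinstance(design, pd.DataFrame) else None
    ) or [f"coef{i + 1}" for i in range(X.shape[1])]
    G, J = V.shape
    p = X.shape[1]
    if X.shape[0] != J:
        raise ValidationError("design rows must match number of arrays")
    if weights is None:
        w_arr = np.ones(J)
    else:
        w_arr = np.asarray(
            weights.weights.reindex(E.columns)
            if hasattr(weights, "weights")
            else weights,
            dtype=float,
        )
        if w_arr.shape != (J,) or np.any(~np.isfinite(w_arr)) or np.any(w_arr <= 0):
            raise ValidationError("weights must be positive, one per array")

    coef = np.full((G, p), np.nan)
    u = np.full((G, p), np.nan)
    sigma = np.full(G, np.nan)
    df_res = np.zeros(G)
    cov = np.full((G, p, p), np.nan)

    finite = np.isfinite(V)
    patterns: dict = {}
    for g in range(G):
        patterns.setdefault(tuple(np.flatnonzero(finite[g])), []).append(g)

    for key, idx in patterns.items():
        cols = np.array(key, dtype=int)
        if cols.size == 0:
            continue
        Xs = X[cols]
        rank = np.linalg.matrix_rank(Xs)
        sw = np.sqrt(w_arr[cols])
        Xw = Xs * sw[:, None]
        idx = np.array(idx)
        Yw = V[np.ix_(idx, cols)] * sw[None, :]
        if rank < p:
            # estimate the estimable subset: keep columns with any support
            XtX = Xw.T @ Xw
            est = np.diag(XtX) > 0
            if est.sum() == 0 or np.linalg.matrix_rank(Xw[:, est]) < est.sum():
                continue
            sub = np.linalg.pinv(Xw[:, est].T @ Xw[:, est])
            beta = (sub @ Xw[:, est].T @ Yw.T).T
            coef[np.ix_(idx, np.flatnonzero(est))] = beta
            continue
        XtXinv = np.linalg.inv(Xw.T @ Xw)
        beta = (XtXinv @ Xw.T @ Yw.T).T
        coef[idx] = beta
        cov[idx] = XtXinv[None, :, :]
        u[idx] = np.sqrt(np.diag(XtXinv))[None, :]
        df = cols.size - p
        df_res[idx] = df
        if df > 0:
            R = Yw - beta @ Xw.T
            sigma[idx] = np.sqrt(np.sum(R**2, axis=1) / df)

    return ProbeFit(
        coefficients=pd.DataFrame(coef, index=E.index, columns=design_cols),
        stdev_unscaled=pd.DataFrame(u, index=E.index, columns=design_cols),
        sigma=pd.Series(sigma, index=E.index),
        df_residual=pd.Series(df_res, index=E.index),
        cov_unscaled=cov,
        design_columns=design_cols,
    )


def contrasts_fit(fit: ProbeFit, contrasts: pd.DataFrame) -> ProbeFit:
    """Re-express a fit in terms of contrast columns."""
    Cmat = contrasts.reindex(fit.design_columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(Cmat)):
        raise ValidationError(
            "contrast matrix rows do not match fitted coefficients"
        )
    coef = fit.coefficients.to_numpy() @ Cmat
    var = np.einsum("ik,gkl,lj->gij", Cmat.T, fit.cov_unscaled, Cmat)
    u = np.sqrt(np.einsum("gii->gi", var))
    names = list(contrasts.columns)
    return ProbeFit(
        coefficients=pd.DataFrame(coef, index=fit.coefficients.index, columns=names),
        stdev_unscaled=pd.DataFrame(u, index=fit.coefficients.index, columns=names),
        sigma=fit.sigma,
        df_residual=fit.df_residual,
        cov_unscaled=var,
        design_columns=names,
    )


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve psi'(y) = x for y > 0 by Newton iteration on 1/psi'."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < tol:
            break
    return float(y)


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics per contrast."""

    d0: float  # prior df (may be inf)
    s0_2: float  # prior variance
    s_tilde_2: pd.Series  # posterior variances
    df_total: pd.Series
    coefficients: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    adj_p: pd.DataFrame


def _squeeze_var(sigma2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching estimates of (d0, s0^2) from sample variances."""
    ok = (df > 0) & np.isfinite(sigma2) & (sigma2 > 0)
    n = int(ok.sum())
    if n < 3:
        raise FitError("need >= 3 probes with positive residual variance")
    d = df[ok]
    e = np.log(sigma2[ok]) - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(np.mean(e))
    rhs = float(
        np.mean((e - ebar) ** 2 * n / (n - 1.0) - special.polygamma(1, d / 2.0))
    )
    if rhs > 0:
        d0 = 2.0 * trigamma_inverse(rhs)
        s0_2 = float(
            np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        # infinite prior df: all probes share one variance; the arithmetic
        # mean is its natural estimate (no log-scale bias correction left)
        d0 = np.inf
        s0_2 = float(np.mean(sigma2[ok]))
    return d0, s0_2


def ebayes(fit: ProbeFit, d0: float | None = None, s0_2: float | None = None
           ) -> ModeratedStats:
    """Moderate the residual variances and compute moderated t-statistics.

    ``d0``/``s0_2`` may be forced (e.g. d0=0 recovers the classical t);
    when omitted they are estimated by moment matching.
    """
    sigma2 = fit.sigma.to_numpy(dtype=float) ** 2
    df = fit.df_residual.to_numpy(dtype=float)
    if not np.any(np.isfinite(sigma2) & (sigma2 > 0)):
        raise FitError("all residual variances are zero or undefined")
    if d0 is None or s0_2 is None:
        d0_est, s0_est = _squeeze_var(sigma2, df)
        d0 = d0_est if d0 is None else d0
        s0_2 = s0_est if s0_2 is None else s0_2

    s2 = np.where(np.isfinite(sigma2), sigma2, 0.0)
    if np.isinf(d0):
        s_tilde_2 = np.full_like(s2, s0_2)
    else:
        s_tilde_2 = (d0 * s0_2 + df * s2) / np.maximum(d0 + df, 1e-300)
        if d0 == 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                s_tilde_2 = np.where(df > 0, s2, np.nan)
    df_total = d0 + df

    coef = fit.coefficients.to_numpy(dtype=float)
    u = fit.stdev_unscaled.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = coef / (u * np.sqrt(s_tilde_2)[:, None])
    pvals = np.full_like(tstat, np.nan)
    finite = np.isfinite(tstat)
    dft = np.broadcast_to(df_total[:, None], tstat.shape)
    if np.isinf(d0):
        pvals[finite] = 2.0 * stats.norm.sf(np.abs(tstat[finite]))
    else:
        pvals[finite] = 2.0 * stats.t.sf(np.abs(tstat[finite]), dft[finite])

    adj = np.full_like(pvals, np.nan)
    for k in range(pvals.shape[1]):
        col = pvals[:, k]
        ok = np.isfinite(col)
        if ok.any():
            adj[ok, k] = bh_adjust(col[ok])

    index = fit.coefficients.index
    cols = fit.coefficients.columns
    return ModeratedStats(
        d0=float(d0),
        s0_2=float(s0_2),
        s_tilde_2=pd.Series(s_tilde_2, index=index),
        df_total=pd.Series(df_total, index=index),
        coefficients=fit.coefficients,
        t=pd.DataFrame(tstat, index=index, columns=cols),
        p=pd.DataFrame(pvals, index=index, columns=cols),
        adj_p=pd.DataFrame(adj, index=index, columns=cols),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def toptable(
    stats_: ModeratedStats, alpha: float = 0.05, contrast=None
) -> pd.DataFrame:
    """Ranked results for one contrast, sorted by raw p ascending.

    The significance flag uses the raw p-value at ``alpha`` (the
    probability-level default); BH-adjusted p-values are reported
    alongside for FDR-based selection.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if contrast is None:
        contrast = stats_.t.columns[0] if len(stats_.t.columns) else None
    if contrast is None:
        return pd.DataFrame(
            columns=["probe_id", "logFC", "t", "p", "adj_p", "significant"]
        )
    out = pd.DataFrame(
        {
            "probe_id": stats_.t.index,
            "logFC": stats_.coefficients[contrast].to_numpy(),
            "t": stats_.t[contrast].to_numpy(),
            "p": stats_.p[contrast].to_numpy(),
            "adj_p": stats_.adj_p[contrast].to_numpy(),
        }
    )
    out["significant"] = out["p"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)
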