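"""Method-comparison metrics: MA values, control CVs, variance trends and
array-filtering strategy comparisons.

These are the quantities used to rank background-correction methods (MA
spread and missing-value burden, residual-variance precision curves),
normalization methods (replicate control CVs, with one-way ANOVA and Tukey
HSD across methods), and array-filtering strategies (moderated-t and
FDR summaries under equal weights, estimated weights, or dropping the
lowest-weight arrays).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import ValidationError
from .diffexp import contrasts_fit, ebayes, fit_probewise
from .quality import ArrayWeightResult, drop_lowest_arrays


@dataclass
class MATable:
    """M/A values of one array against the mean of all other arrays."""

    table: pd.DataFrame  # columns: M, A
    array: object
    max_abs_m: float
    fraction_missing: float


def ma_versus_rest(Y, j: int) -> MATable:
    """M = Y_j - mean(rest), A = (Y_j + mean(rest))/2, missing-aware."""
    Y = pd.DataFrame(Y)
    J = Y.shape[1]
    if J < 2:
        raise ValidationError("MA comparison needs at least 2 arrays")
    if not 0 <= j < J:
        raise ValidationError(f"array index {j} out of range 0..{J - 1}")
    V = Y.to_numpy(dtype=float)
    x = V[:, j]
    rest = np.delete(V, j, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        y = np.nanmean(rest, axis=1)
    M = x - y
    A = 0.5 * (x + y)
    finite = np.isfinite(M)
    return MATable(
        table=pd.DataFrame({"M": M, "A": A}, index=Y.index),
        array=Y.columns[j],
        max_abs_m=float(np.nanmax(np.abs(M))) if finite.any() else np.nan,
        fraction_missing=float(1.0 - finite.mean()),
    )


def control_cv(
    values,
    probes: pd.DataFrame,
    controls=None,
    input_log2: bool = True,
    scale: str = "linear",
) -> pd.DataFrame:
    """Replicate-spot coefficient of variation per control probe per array.

    Parameters
    ----------
    values : DataFrame, spots x arrays
        Spot-level intensities aligned with ``probes``.
    controls : iterable of probe ids, optional
        Defaults to every probe with category 'control'.
    input_log2, scale :
        Whether ``values`` is on the log2 scale, and the scale on which CVs
        are computed (linear by default: CV of log values depends on the
        unit of the log and is rarely intended; a log2 option is exposed).

    Returns
    -------
    DataFrame
        Long table (probe_id, array, cv_pct); CV = sd/mean in percent,
        missing when a control has < 2 finite replicates or mean <= 0.
    """
    if scale not in ("linear", "log2"):
        raise ValidationError(f"unknown CV scale {scale!r}")
    values = pd.DataFrame(values)
    ids = probes["probe_id"].reset_index(drop=True)
    if controls is None:
        controls = probes.loc[probes["category"] == "control", "probe_id"].unique()
    controls = list(controls)
    known = set(ids)
    unknown = [c for c in controls if c not in known]
    if unknown:
        raise ValidationError(f"unknown control probes: {unknown}")
    V = values.to_numpy(dtype=float)
    if input_log2 and scale == "linear":
        V = 2.0**V
    elif not input_log2 and scale == "log2":
        with np.errstate(invalid="ignore", divide="ignore"):
            V = np.where(V > 0, np.log2(V), np.nan)
    rows = []
    for ctrl in controls:
        sub = V[(ids == ctrl).to_numpy()]
        for k, arr in enumerate(values.columns):
            col = sub[:, k]
            col = col[np.isfinite(col)]
            if col.size < 2 or np.mean(col) <= 0:
                cv = np.nan
            else:
                cv = 100.0 * np.std(col, ddof=1) / np.mean(col)
            rows.append({"probe_id": ctrl, "array": arr, "cv_pct": cv})
    return pd.DataFrame(rows)


def cv_anova(cv_tables: dict) -> dict:
    """One-way ANOVA F-test plus Tukey HSD comparing mean CVs across
    methods; ``cv_tables`` maps method name -> control_cv output."""
    groups, labels = [], []
    for method, table in cv_tables.items():
        vals = table["cv_pct"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        groups.append(vals)
        labels += [method] * vals.size
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 methods with >= 2 CVs each")
    f, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(np.concatenate(groups), np.array(labels))
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"F": float(f), "p": float(p), "tukey": tukey_df}


@dataclass
class VarianceTrend:
    """Residual variances against standardized mean intensity."""

    table: pd.DataFrame  # sigma2, log2_sigma2, A, A_std per probe
    curve: pd.DataFrame  # smoothed log2 sigma^2 over the A_std grid


def variance_trend(Y, design, span: float = 0.5) -> VarianceTrend:
    """Probe-wise residual variances and their intensity trend.

    sigma_g^2 comes from the probe-wise linear fit; A is the probe mean
    log2 intensity, rank-standardized to [0, 1] so curves from different
    correction methods share a common horizontal grid; the curve is a
    robust local-linear smooth of log2 sigma^2 on standardized A.
    """
    Y = pd.DataFrame(Y)
    fit = fit_probewise(Y, design)
    sigma2 = fit.sigma.to_numpy(dtype=float) ** 2
    ok = np.isfinite(sigma2) & (fit.df_residual.to_numpy() >= 1)
    if not ok.any():
        raise ValidationError("no probe has residual df >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        A = np.nanmean(Y.to_numpy(dtype=float), axis=1)
    keep = ok & np.isfinite(A)
    A_std = np.full_like(A, np.nan)
    ranks = stats.rankdata(A[keep], method="average")
    A_std[keep] = (ranks - 1.0) / max(len(ranks) - 1.0, 1.0)
    with np.errstate(divide="ignore"):
        log2_s2 = np.where(sigma2 > 0, np.log2(np.maximum(sigma2, 1e-300)), np.nan)
    table = pd.DataFrame(
        {"sigma2": sigma2, "log2_sigma2": log2_s2, "A": A, "A_std": A_std},
        index=Y.index,
    )
    smooth_ok = keep & np.isfinite(log2_s2)
    if smooth_ok.sum() >= 2:
        fitted = lowess(
            log2_s2[smooth_ok], A_std[smooth_ok], frac=span, it=2,
            return_sorted=True,
        )
        curve = pd.DataFrame(
            fitted, columns=["A_std", "log2_sigma2"]
        ).drop_duplicates("A_std")
    else:  # e.g. all probes constant: no finite log-variances to smooth
        curve = pd.DataFrame(columns=["A_std", "log2_sigma2"])
    return VarianceTrend(table=table, curve=curve)


def compare_filtering(
    E,
    design,
    weights: ArrayWeightResult,
    contrasts: pd.DataFrame | None = None,
    n_drop: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Run the differential analysis under three array-filtering strategies.

    Strategies: 'equal' (all arrays, unit weights), 'weighted' (all arrays,
    estimated weights), 'drop' (remove the ``n_drop`` lowest-weight arrays,
    unit weights).  Returns one block per strategy with the moderated
    statistics and summary counts.
    """
    E = pd.DataFrame(E)
    X = pd.DataFrame(design)
    report = {}

    def analyse(mat, dsg, w):
        fit = fit_probewise(mat, dsg, weights=w)
        if contrasts is not None:
            fit = contrasts_fit(fit, contrasts)
        st = ebayes(fit)
        t = st.t.iloc[:, 0]
        p = st.p.iloc[:, 0]
        adj = st.adj_p.iloc[:, 0]
        return {
            "stats": st,
            "mean_abs_t": float(np.nanmean(np.abs(t))),
            "n_sig_raw": int((p < alpha).sum()),
            "n_sig_adj": int((adj < alpha).sum()),
            "n_arrays": mat.shape[1],
        }

    report["equal"] = analyse(E, X, None)
    report["weighted"] = analyse(E, X, weights)
    reduced, kept, dropped = drop_lowest_arrays(E, weights, n_drop=n_drop)
    keep_idx = [list(E.columns).index(c) for c in kept]
    report["drop"] = analyse(reduced, X.iloc[keep_idx], None)
    report["drop"]["dropped_arrays"] = dropped
    return report
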