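"""Replicate-spot consolidation into a proteins x arrays matrix.

Replicate spots of the same probe are averaged (missing-aware) on the log2
scale, one row per retained probe per array; probes in dropped categories
(controls and empty spots by default) are removed.  Per-cell replicate
counts are reported so users can filter on support downstream; no minimum
replicate rule is imposed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError


def consolidate(
    Y,
    probes: pd.DataFrame,
    targets: pd.DataFrame | None = None,
    categories: dict | None = None,
    drop=("control", "empty"),
) -> ExpressionMatrix:
    """Average replicate spots per probe per array and drop categories.

    Parameters
    ----------
    Y : DataFrame, spots x arrays
        Normalized log2 spot matrix, aligned with ``probes``.
    probes : DataFrame
        Spot annotation with probe_id / probe_name / category columns.
    categories : dict, optional
        probe_id -> category overrides (e.g. from an annotated probe list).
    drop : iterable of categories
        Categories removed from the result; default control and empty.

    Returns
    -------
    ExpressionMatrix
        One row per retained distinct probe_id, in order of first
        appearance; values are means of the finite replicate values (all
        replicates missing -> missing); replicate counts per cell attached.
    """
    Y = pd.DataFrame(Y)
    if len(Y) != len(probes):
        raise ValidationError("Y and probe annotation row counts differ")
    ann = probes.reset_index(drop=True).copy()
    if categories:
        ann["category"] = (
            ann["probe_id"].map(categories).fillna(ann["category"])
        )
    drop = set(drop)
    keep = ~ann["category"].isin(drop)
    if not keep.any():
        raise ValidationError(
            f"no probes left after dropping categories {sorted(drop)}"
        )
    V = Y.to_numpy(dtype=float)[keep.to_numpy()]
    ann = ann[keep].reset_index(drop=True)

    order = ann["probe_id"].drop_duplicates().tolist()
    codes = ann["probe_id"].map({pid: i for i, pid in enumerate(order)}).to_numpy()
    n_probe, J = len(order), V.shape[1]
    sums = np.zeros((n_probe, J))
    counts = np.zeros((n_probe, J), dtype=int)
    finite = np.isfinite(V)
    np.add.at(sums, codes, np.where(finite, V, 0.0))
    np.add.at(counts, codes, finite.astype(int))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    annotation = (
        ann.drop_duplicates("probe_id")
        .set_index("probe_id")[["probe_name", "category"]]
        .loc[order]
        .reset_index()
    )
    values = pd.DataFrame(means, index=order, columns=Y.columns)
    values.index.name = "probe_id"
    return ExpressionMatrix(
        values=values,
        annotation=annotation,
        targets=targets if targets is not None else pd.DataFrame(),
        replicate_counts=pd.DataFrame(counts, index=order, columns=Y.columns),
    )
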