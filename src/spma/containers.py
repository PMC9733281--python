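"""Core in-memory containers shared across the pipeline.

The central object is :class:`ArraySet`: aligned probes x arrays foreground
and background matrices together with the spot annotation and the sample
targets (metadata) table.  Arrays are always aligned by spot geometry —
every file in a set must agree row-by-row on (block, row, column) and probe
identity, so that a matrix row means the same physical spot on every slide.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Valid probe categories.
CATEGORIES = ("sample", "control", "empty")

#: Columns of a spot annotation frame, in canonical order.
SPOT_COLUMNS = ["block", "row", "column", "probe_id", "probe_name", "category", "flag"]

#: Required headers of a targets (metadata) table.
TARGETS_COLUMNS = ["FileName", "SampleID", "Condition"]


class SpmaError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(SpmaError):
    """Input data violates a structural contract (geometry, labels, ranges)."""


class ConfigError(SpmaError):
    """A user-supplied option is missing, unknown or inconsistent."""


class ParseError(SpmaError):
    """A file could not be parsed; carries file/line context in the message."""


class FitError(SpmaError):
    """A model fit is impossible on the given data (degenerate input)."""


def default_category(probe_name: str) -> str:
    """Default category rule: blank or literal 'empty' names are empty spots."""
    name = str(probe_name).strip()
    if name == "" or name.lower() == "empty":
        return "empty"
    return "sample"


@dataclass
class SpotTable:
    """One array's spot-level records.

    ``spots`` is a DataFrame with columns ``block, row, column, probe_id,
    probe_name, category, flag, fg, bg``; (block, row, column) triples are
    unique and intensities are finite and non-negative.
    """

    array_id: str
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.spots
        missing = [c for c in SPOT_COLUMNS + ["fg", "bg"] if c not in df.columns]
        if missing:
            raise ValidationError(
                f"array {self.array_id!r}: spot table missing columns {missing}"
            )
        dup = df.duplicated(subset=["block", "row", "column"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["block", "row", "column"]].tolist()
            raise ValidationError(
                f"array {self.array_id!r}: duplicate spot coordinates "
                f"(block,row,column)={tuple(first)}"
            )
        for col in ("fg", "bg"):
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValidationError(
                    f"array {self.array_id!r}: non-finite {col} intensities"
                )
            if (vals < 0).any():
                raise ValidationError(
                    f"array {self.array_id!r}: negative {col} intensities"
                )
        bad = ~df["category"].isin(CATEGORIES)
        if bad.any():
            raise ValidationError(
                f"array {self.array_id!r}: unknown categories "
                f"{sorted(df.loc[bad, 'category'].unique())}"
            )

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def annotation(self) -> pd.DataFrame:
        """Spot annotation (everything except the intensities)."""
        return self.spots[SPOT_COLUMNS].reset_index(drop=True)


@dataclass
class ArraySet:
    """Aligned spot x array intensity matrices plus annotation and targets.

    E holds foreground intensities and B backgrounds; columns are sample ids
    in targets order.  ``log_state`` tracks whether E is on the linear
    fluorescence scale or log2 (B always stays linear).
    """

    probes: pd.DataFrame
    E: pd.DataFrame
    B: pd.DataFrame
    targets: pd.DataFrame
    log_state: str = "linear"
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.E.shape != self.B.shape:
            raise ValidationError(
                f"E {self.E.shape} and B {self.B.shape} dimensions differ"
            )
        if list(self.E.columns) != list(self.targets["SampleID"]):
            raise ValidationError("E column order does not match targets order")
        if len(self.probes) != len(self.E):
            raise ValidationError("probe annotation and E row counts differ")
        if self.log_state not in ("linear", "log2"):
            raise ValidationError(f"unknown log_state {self.log_state!r}")

    @property
    def n_arrays(self) -> int:
        return self.E.shape[1]

    @property
    def n_spots(self) -> int:
        return self.E.shape[0]

    @property
    def sample_ids(self) -> list:
        return list(self.E.columns)

    def log(self, message: str) -> None:
        self.processing_log.append(message)

    def copy(self) -> "ArraySet":
        return ArraySet(
            probes=self.probes.copy(),
            E=self.E.copy(),
            B=self.B.copy(),
            targets=self.targets.copy(),
            log_state=self.log_state,
            processing_log=list(self.processing_log),
        )

    def with_categories(self, mapping: dict) -> "ArraySet":
        """Return a copy whose probe categories follow ``mapping`` (probe_id
        -> category); unlisted probes keep their current category."""
        out = self.copy()
        cats = out.probes["probe_id"].map(mapping)
        out.probes["category"] = cats.fillna(out.probes["category"])
        out.log(f"categories:annotated {int(cats.notna().sum())} probes")
        return out


@dataclass
class NormalizedSet:
    """Log2 probes x arrays matrix after a normalization step."""

    Y: pd.DataFrame
    method: str
    parameters: dict = field(default_factory=dict)
    probes: pd.DataFrame | None = None
    targets: pd.DataFrame | None = None


@dataclass
class ExpressionMatrix:
    """Consolidated proteins x arrays mean log2 intensities."""

    values: pd.DataFrame
    annotation: pd.DataFrame
    targets: pd.DataFrame
    replicate_counts: pd.DataFrame | None = None


@dataclass
class NormexpParams:
    """Parameters of the normal+exponential convolution background model."""

    mu: float
    sigma: float
    alpha: float
    offset: float = 0.0
    log_likelihood: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.alpha > 0):
            raise ValidationError(
                f"normexp parameters need sigma>0 and alpha>0, "
                f"got sigma={self.sigma}, alpha={self.alpha}"
            )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
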