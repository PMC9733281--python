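"""Reading and writing array extractions, targets metadata and matrices.

Supported input dialects:

* GenePix GPR files in the ATF 1.0 layout: an ``ATF<TAB>1.0`` signature
  line, a line with the count of optional header records and data columns,
  that many (usually quoted) header records, a column-name line, then
  tab-delimited data rows.
* Generic single-header tab-delimited TXT (e.g. Mapix exports): the first
  line is the column-name line.

Any other dialect is rejected with a clear error.  Foreground/background
columns are auto-detected by the GenePix naming convention
(``F<wavelength> Median`` / ``B<wavelength> Median``); exports that use a
different scheme must name their columns explicitly.
"""

from __future__ import annotations

import io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    SPOT_COLUMNS,
    TARGETS_COLUMNS,
    ArraySet,
    ConfigError,
    ParseError,
    SpotTable,
    ValidationError,
    default_category,
)

FG_PATTERN = re.compile(r"^F(\d+) Median$")
BG_PATTERN = re.compile(r"^B(\d+) Median$")

# Column-name aliases for the spot annotation, checked case-insensitively.
_ANNOT_ALIASES = {
    "block": ["block"],
    "row": ["row"],
    "column": ["column", "col"],
    "probe_id": ["id"],
    "probe_name": ["name"],
    "flag": ["flags", "flag"],
}


def _strip_quotes(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        return token[1:-1]
    return token


def _read_text(path) -> list[str]:
    raw = Path(path).read_text()
    # dialect-insensitive to LF/CRLF
    return raw.replace("\r\n", "\n").replace("\r", "\n").split("\n")


def _locate_header(lines: list[str], path) -> int:
    """Return the 0-based index of the column-name line."""
    if not lines:
        raise ParseError(f"{path}: empty file")
    first = [_strip_quotes(t) for t in lines[0].split("\t")]
    if first and first[0].upper() == "ATF":
        if len(first) < 2 or first[1] not in ("1", "1.0"):
            raise ParseError(f"{path}: unsupported ATF version line {lines[0]!r}")
        if len(lines) < 2:
            raise ParseError(f"{path}: truncated ATF header")
        counts = lines[1].split("\t")
        try:
            n_records = int(_strip_quotes(counts[0]))
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: line 2: expected ATF header-count line, got {lines[1]!r}"
            ) from None
        return 2 + n_records
    # plain single-header dialect: first line must look like column names,
    # i.e. contain at least one non-numeric token and a tab
    if "\t" not in lines[0]:
        raise ParseError(
            f"{path}: not an ATF file and first line is not tab-delimited; "
            "only GPR/ATF and single-header tab-delimited files are supported"
        )
    return 0


def _pick_channel(columns: list[str], pattern: re.Pattern, kind: str, path) -> str:
    hits = [(int(pattern.match(c).group(1)), c) for c in columns if pattern.match(c)]
    if not hits:
        raise ConfigError(
            f"{path}: no {kind} intensity column matches {pattern.pattern!r}; "
            f"available columns: {columns}"
        )
    hits.sort()  # ties broken by lowest wavelength
    return hits[0][1]


def read_gpr(path, fg_column: str = "auto", bg_column: str = "auto") -> SpotTable:
    """Read one GPR/ATF or single-header tab-delimited extraction.

    Parameters
    ----------
    path : path-like
        File to read.
    fg_column, bg_column : str
        Intensity column names, or ``"auto"`` to pick the lowest-wavelength
        ``F<w> Median`` / ``B<w> Median`` pair.

    Returns
    -------
    SpotTable
        Validated spot records; the chosen column names are recorded on the
        table as ``fg_column`` / ``bg_column`` attributes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    lines = _read_text(path)
    header_idx = _locate_header(lines, path)
    if header_idx >= len(lines):
        raise ParseError(f"{path}: ATF header claims more records than file has")
    columns = [_strip_quotes(t) for t in lines[header_idx].split("\t")]
    body = "\n".join(lines[header_idx:])
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str, keep_default_na=False)
    df.columns = columns[: len(df.columns)]

    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canon, aliases in _ANNOT_ALIASES.items():
        for a in aliases:
            if a in lower:
                resolved[canon] = lower[a]
                break
    for required in ("block", "row", "column"):
        if required not in resolved:
            raise ParseError(f"{path}: missing required column {required!r}")
    if "probe_id" not in resolved and "probe_name" not in resolved:
        raise ParseError(f"{path}: neither ID nor Name column present")

    if fg_column == "auto":
        fg_column = _pick_channel(columns, FG_PATTERN, "foreground", path)
    if bg_column == "auto":
        wl = FG_PATTERN.match(fg_column)
        if wl and f"B{wl.group(1)} Median" in columns:
            bg_column = f"B{wl.group(1)} Median"
        else:
            bg_column = _pick_channel(columns, BG_PATTERN, "background", path)
    for col, kind in ((fg_column, "foreground"), (bg_column, "background")):
        if col not in df.columns:
            raise ConfigError(
                f"{path}: requested {kind} column {col!r} not present; "
                f"available columns: {columns}"
            )

    def numeric(col: str, name: str) -> np.ndarray:
        # float() per token: correctly-rounded parsing so that fixture
        # round-trips are bit-exact
        out = np.empty(len(df), dtype=float)
        for i, tok in enumerate(df[col]):
            tok = tok.strip()
            if tok in ("", "NA", "nan"):
                out[i] = np.nan
                continue
            try:
                out[i] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: line {header_idx + 2 + i}: non-numeric {name} "
                    f"value {tok!r}"
                ) from None
        return out

    out = pd.DataFrame(
        {
            "block": numeric(resolved["block"], "Block").astype(int),
            "row": numeric(resolved["row"], "Row").astype(int),
            "column": numeric(resolved["column"], "Column").astype(int),
        }
    )
    probe_id = df[resolved["probe_id"]] if "probe_id" in resolved else None
    probe_name = df[resolved["probe_name"]] if "probe_name" in resolved else None
    out["probe_id"] = (probe_id if probe_id is not None else probe_name).astype(str)
    out["probe_name"] = (probe_name if probe_name is not None else probe_id).astype(str)
    out["category"] = out["probe_name"].map(default_category)
    if "flag" in resolved:
        out["flag"] = numeric(resolved["flag"], "Flags").astype(int)
    else:
        out["flag"] = 0
    out["fg"] = numeric(fg_column, "foreground")
    out["bg"] = numeric(bg_column, "background")

    table = SpotTable(array_id=path.name, spots=out)
    table.fg_column = fg_column
    table.bg_column = bg_column
    return table


def read_targets(path) -> pd.DataFrame:
    """Read the targets (metadata) table: tab-delimited with required
    headers FileName, SampleID, Condition; extra columns are kept."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TARGETS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: targets file missing headers {missing}")
    if df["FileName"].duplicated().any():
        dups = df.loc[df["FileName"].duplicated(), "FileName"].tolist()
        raise ValidationError(f"{path}: duplicate FileName entries {dups}")
    return df.reset_index(drop=True)


def read_probe_annotations(path) -> dict:
    """Read an annotated probe list (tab-delimited, probe_id and category
    columns); returns probe_id -> category.  Unlisted probes keep the
    default category 'sample' downstream."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    id_col = lower.get("probe_id", lower.get("id"))
    cat_col = lower.get("category")
    if id_col is None or cat_col is None:
        raise ValidationError(f"{path}: need probe_id and category columns")
    mapping: dict = {}
    for pid, cat in zip(df[id_col], df[cat_col]):
        cat = str(cat).strip().lower()
        if pid in mapping and mapping[pid] != cat:
            raise ValidationError(
                f"{path}: probe {pid!r} listed with conflicting categories "
                f"{mapping[pid]!r} and {cat!r}"
            )
        mapping[pid] = cat
    return mapping


def assemble_arrayset(tables: list[SpotTable], targets: pd.DataFrame) -> ArraySet:
    """Align spot tables into a probes x arrays ArraySet.

    All tables must share identical spot geometry and probe annotation
    row-by-row; column j of the result corresponds to row j of ``targets``.
    """
    if len(tables) < 2:
        raise ValidationError("need at least 2 arrays to assemble a set")
    by_file = {t.array_id: t for t in tables}
    unmatched = [f for f in targets["FileName"] if f not in by_file]
    if unmatched:
        raise ValidationError(f"targets name files not loaded: {unmatched}")
    extra = [t.array_id for t in tables if t.array_id not in set(targets["FileName"])]
    if extra:
        raise ValidationError(f"loaded arrays missing from targets: {extra}")

    ordered = [by_file[f] for f in targets["FileName"]]
    ref = ordered[0].annotation()
    geom_cols = ["block", "row", "column", "probe_id", "probe_name"]
    for t in ordered[1:]:
        ann = t.annotation()
        if len(ann) != len(ref):
            raise ValidationError(
                f"array {t.array_id!r} has {len(ann)} spots, "
                f"expected {len(ref)} (geometry mismatch)"
            )
        neq = (ann[geom_cols].to_numpy() != ref[geom_cols].to_numpy()).any(axis=1)
        if neq.any():
            i = int(np.flatnonzero(neq)[0])
            raise ValidationError(
                f"array {t.array_id!r} disagrees with {ordered[0].array_id!r} "
                f"at spot {i} "
                f"(block,row,column)={tuple(ref.loc[i, ['block', 'row', 'column']])}"
            )

    sample_ids = list(targets["SampleID"])
    E = pd.DataFrame(
        np.column_stack([t.spots["fg"].to_numpy(dtype=float) for t in ordered]),
        columns=sample_ids,
    )
    B = pd.DataFrame(
        np.column_stack([t.spots["bg"].to_numpy(dtype=float) for t in ordered]),
        columns=sample_ids,
    )
    aset = ArraySet(
        probes=ref.copy(),
        E=E,
        B=B,
        targets=targets.reset_index(drop=True),
        log_state="linear",
    )
    fg = getattr(ordered[0], "fg_column", None)
    bg = getattr(ordered[0], "bg_column", None)
    aset.log(f"load:{len(ordered)} arrays, {len(ref)} spots, fg={fg}, bg={bg}")
    return aset


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    """Write a labelled matrix as tab-delimited text; missing values as NA.

    Uses 10 significant digits so that write -> read round-trips to well
    beyond 6 significant figures.
    """
    matrix.to_csv(
        path, sep="\t", na_rep="NA", index_label=index_label, float_format="%.10g"
    )


def read_matrix(path) -> pd.DataFrame:
    """Read back a matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
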