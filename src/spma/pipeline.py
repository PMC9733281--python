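"""End-to-end pipeline orchestration.

The default flow is: read arrays -> spot filtering (2-SD threshold) ->
normexp background correction (offset k = 0) -> log2 -> fast cyclic loess
normalization (span 0.7, 3 iterations) -> REML array weights ->
consolidation (drop controls and empty spots) -> optional weighted
differential expression.  Every stage appends to a processing log that is
written with the outputs, and identical inputs + config produce
byte-identical output files.
"""

from __future__ import annotations

import glob as globmod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arrayio, background, evaluate, quality, summarize
from .normalize import normalize as apply_normalization
from .containers import ConfigError, ValidationError
from .diffexp import contrasts_fit, ebayes, fit_probewise, make_contrasts, make_design

NORMALIZATION_METHODS = ("none", "scale", "quantile", "cyclicloess")
WEIGHT_STRATEGIES = ("weights", "equal")  # plus "drop:<n>"


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the recommended
    pipeline (normexp k=0, cyclic loess, REML array weights)."""

    inputs: list = field(default_factory=list)  # file paths or globs
    targets: str | None = None
    probe_annotations: str | None = None
    fg_column: str = "auto"
    bg_column: str = "auto"
    drop_categories: tuple = ("control", "empty")
    background: str = "normexp"
    offset: float = 0.0
    offset_grid: bool = False
    normalization: str = "cyclicloess"
    span: float = 0.7
    iterations: int = 3
    weight_strategy: str = "weights"
    comparisons: list = field(default_factory=list)
    alpha: float = 0.05
    output_dir: str = "spma_output"
    plots: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.background not in background.BACKGROUND_METHODS:
            raise ConfigError(
                f"unknown background method {self.background!r}; "
                f"choose from {sorted(background.BACKGROUND_METHODS)}"
            )
        if self.normalization not in NORMALIZATION_METHODS:
            raise ConfigError(
                f"unknown normalization method {self.normalization!r}; "
                f"choose from {NORMALIZATION_METHODS}"
            )
        ws = self.weight_strategy
        if ws not in WEIGHT_STRATEGIES and not ws.startswith("drop:"):
            raise ConfigError(
                f"unknown weight strategy {ws!r}; use 'weights', 'equal' "
                "or 'drop:<n>'"
            )
        if ws.startswith("drop:"):
            try:
                int(ws.split(":", 1)[1])
            except ValueError:
                raise ConfigError(f"bad drop strategy {ws!r}") from None
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.offset < 0:
            raise ConfigError("offset must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if "drop_categories" in data:
            data["drop_categories"] = tuple(data["drop_categories"])
        return cls(**data)


def _expand_inputs(patterns) -> list[str]:
    files: list[str] = []
    for pat in patterns:
        hits = sorted(globmod.glob(str(pat)))
        files.extend(hits if hits else [str(pat)])
    return files


def load_inputs(config: RunConfig):
    """Read GPR files, targets and optional probe annotations."""
    if not config.targets:
        raise ConfigError("a targets file is required")
    targets = arrayio.read_targets(config.targets)
    files = _expand_inputs(config.inputs)
    if not files:
        raise ConfigError("no input files given")
    tables = [
        arrayio.read_gpr(f, fg_column=config.fg_column, bg_column=config.bg_column)
        for f in files
    ]
    aset = arrayio.assemble_arrayset(tables, targets)
    if config.probe_annotations:
        mapping = arrayio.read_probe_annotations(config.probe_annotations)
        aset = aset.with_categories(mapping)
    return aset


def preprocess(arrayset, config: RunConfig):
    """Spot filter, background-correct and normalize one ArraySet.

    Returns (normalized set, stage report dict).
    """
    report: dict = {}
    filtered, thresholds = background.filter_spots(arrayset)
    report["noise_thresholds"] = {
        str(k): float(v) for k, v in thresholds.thresholds.items()
    }
    report["n_filtered"] = {
        str(k): int(v) for k, v in thresholds.n_filtered.items()
    }

    if config.background == "normexp":
        k = config.offset
        if config.offset_grid:
            design = make_design(filtered.targets)
            k, table = background.select_offset(filtered, design)
            report["offset_grid"] = table.to_dict("records")
        corrected = background.bgcorrect_normexp(filtered, offset=k)
        report["offset"] = float(k)
        report["normexp_params"] = {
            s: p.as_dict()
            for s, p in zip(corrected.sample_ids, corrected.normexp_params)
        }
    else:
        corrected = background.BACKGROUND_METHODS[config.background](filtered)
    report["background"] = config.background

    if config.normalization == "cyclicloess":
        nset = apply_normalization(
            corrected, "cyclicloess", span=config.span, iterations=config.iterations
        )
    else:
        nset = apply_normalization(corrected, config.normalization)
    report["normalization"] = {"method": nset.method, **nset.parameters}
    nset.probes = corrected.probes
    nset.targets = corrected.targets
    report["processing_log"] = list(corrected.processing_log)
    return nset, report


def run_pipeline(config: RunConfig, arrayset=None) -> dict:
    """Run the full pipeline and write all outputs to config.output_dir.

    ``arrayset`` may be supplied directly (e.g. from the simulator); it
    otherwise comes from the configured input files.  Returns a result
    dict with the consolidated matrix, weights, report and paths written.
    On any stage error, partial outputs are removed and the error re-raised.
    """
    config.validate()
    if arrayset is None:
        arrayset = load_inputs(config)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        nset, report = preprocess(arrayset, config)
        design = make_design(nset.targets)

        weights = quality.fit_array_weights(nset.Y, design.to_numpy())
        report["array_weights"] = {
            str(k): float(v) for k, v in weights.weights.items()
        }
        report["array_weights_converged"] = weights.converged

        expr = summarize.consolidate(
            nset.Y, nset.probes, targets=nset.targets, drop=config.drop_categories
        )
        report["n_proteins"] = int(expr.values.shape[0])

        expr_path = outdir / "expression.tsv"
        arrayio.write_matrix(expr.values, expr_path)
        written.append(expr_path)
        weights_path = outdir / "array_weights.tsv"
        quality.write_weights(weights, weights_path)
        written.append(weights_path)

        de_table = None
        if config.comparisons:
            strategy = config.weight_strategy
            contrasts = make_contrasts(nset.targets, list(config.comparisons))
            values, dsg, w = expr.values, design, None
            if strategy == "weights":
                w = weights
            elif strategy.startswith("drop:"):
                n_drop = int(strategy.split(":", 1)[1])
                values, kept, dropped = quality.drop_lowest_arrays(
                    values, weights, n_drop=n_drop
                )
                keep_idx = [list(expr.values.columns).index(c) for c in kept]
                dsg = design.iloc[keep_idx]
                report["dropped_arrays"] = dropped
            fit = fit_probewise(values, dsg, weights=w)
            fit = contrasts_fit(fit, contrasts)
            stats = ebayes(fit)
            report["d0"] = float(stats.d0)
            report["s0_2"] = float(stats.s0_2)
            frames = []
            for comp in contrasts.columns:
                from .diffexp import toptable

                tt = toptable(stats, alpha=config.alpha, contrast=comp)
                tt.insert(0, "contrast", comp)
                frames.append(tt)
            de_table = pd.concat(frames, ignore_index=True)
            de_path = outdir / "de_results.tsv"
            de_table.to_csv(de_path, sep="\t", index=False, float_format="%.10g")
            written.append(de_path)

        report_path = outdir / "run_report.yaml"
        with open(report_path, "w") as fh:
            yaml.safe_dump(
                {"config": {**config.__dict__,
                            "drop_categories": list(config.drop_categories),
                            "inputs": list(config.inputs),
                            "comparisons": list(config.comparisons)},
                 "report": report},
                fh,
                sort_keys=True,
            )
        written.append(report_path)
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise

    return {
        "expression": expr,
        "weights": weights,
        "normalized": nset,
        "report": report,
        "de": de_table,
        "paths": written,
    }


def run_compare(config: RunConfig, arrayset=None) -> dict:
    """Run the background x normalization grid and the filtering
    comparison, writing one report per cell.

    Grid cells that fail are recorded; the call raises only if every cell
    fails.
    """
    config.validate()
    if arrayset is None:
        arrayset = load_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    filtered, _ = background.filter_spots(arrayset)
    design = make_design(arrayset.targets)
    results: dict = {"cells": {}, "failures": {}, "filtering": None}

    for bg_name, bg_fun in background.BACKGROUND_METHODS.items():
        try:
            corrected = bg_fun(filtered)
        except Exception as exc:  # noqa: BLE001
            for nm in NORMALIZATION_METHODS:
                results["failures"][f"{bg_name}/{nm}"] = str(exc)
            continue
        for nm in NORMALIZATION_METHODS:
            cell = f"{bg_name}/{nm}"
            try:
                nset = apply_normalization(corrected, nm)
                trend = evaluate.variance_trend(nset.Y, design.to_numpy())
                ma = evaluate.ma_versus_rest(nset.Y, 0)
                cvs = evaluate.control_cv(nset.Y, arrayset.probes)
                cell_report = {
                    "median_sigma2": float(np.nanmedian(trend.table["sigma2"])),
                    "max_abs_m": ma.max_abs_m,
                    "fraction_missing_m": ma.fraction_missing,
                    "mean_control_cv_pct": float(np.nanmean(cvs["cv_pct"])),
                }
                results["cells"][cell] = cell_report
                pd.DataFrame([cell_report]).to_csv(
                    outdir / f"compare_{bg_name}_{nm}.tsv", sep="\t", index=False
                )
            except Exception as exc:  # noqa: BLE001
                results["failures"][cell] = str(exc)

    try:
        corrected = background.bgcorrect_normexp(filtered, offset=config.offset)
        nset = apply_normalization(
            corrected, "cyclicloess", span=config.span, iterations=config.iterations
        )
        expr = summarize.consolidate(
            nset.Y, arrayset.probes, targets=arrayset.targets,
            drop=config.drop_categories,
        )
        weights = quality.fit_array_weights(expr.values, design.to_numpy())
        levels = list(dict.fromkeys(arrayset.targets["Condition"]))
        contrasts = None
        if len(levels) >= 2:
            contrasts = make_contrasts(
                arrayset.targets, [f"{levels[0]}-{levels[1]}"]
            )
        filt = evaluate.compare_filtering(
            expr.values, design, weights, contrasts=contrasts, alpha=config.alpha
        )
        summary = pd.DataFrame(
            {
                strat: {
                    "mean_abs_t": block["mean_abs_t"],
                    "n_sig_raw": block["n_sig_raw"],
                    "n_sig_adj": block["n_sig_adj"],
                    "n_arrays": block["n_arrays"],
                }
                for strat, block in filt.items()
            }
        ).T
        summary.to_csv(outdir / "compare_filtering.tsv", sep="\t")
        results["filtering"] = filt
        if config.plots:
            from . import plots

            plots.plot_ma(
                evaluate.ma_versus_rest(nset.Y, 0), outdir / "ma_plot.png"
            )
            plots.plot_weights(weights, outdir / "array_weights.png")
    except Exception as exc:  # noqa: BLE001
        results["failures"]["filtering"] = str(exc)

    if not results["cells"] and results["filtering"] is None:
        raise ValidationError(
            f"every comparison cell failed: {results['failures']}"
        )
    return results
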