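"""Synthetic single-channel array sets with known ground truth.

Each spot intensity follows the additive model the background correction
assumes: observed foreground = normal background noise plus a positive
true signal,

    L_ij = mu_bg_j + N(0, bg_spatial_sd^2 * v_j)      local background,
    fg   = max(L + N(0, bg_meas_sd^2 * v_j), 0) + a_pc * 2^(b + eps),
    B    = max(L + N(0, bg_meas_sd^2), 0)             reported background,
    b ~ N(0, bio_log2_sd^2 * v_j)   per protein per array,
    eps ~ N(0, tech_log2_sd^2 * v_j)  per spot,

where L is the spot's true local background — wash deposits, dust and
optical gradients make it vary spot-to-spot — which contaminates the
foreground AND is what the image software's background column estimates
(up to independent measurement noise bg_meas_sd).  Local background
subtraction can therefore genuinely remove noise, exactly the situation
background-correction methods are designed for.
mu_bg_j = mu_bg + N(0, bg_array_sd^2) is the array's own background
level (slides differ in wash residue and scanner baseline),
a_pc is protein p's true signal level in condition c, b the individual
sample's biological deviation from the condition mean (shared by the
protein's replicate spots on one array; autoantibody levels vary widely
between individuals, default log2 sd 0.8; spiked control probes carry
none) and eps a small multiplicative spot-level technical noise (default
log2 sd 0.25, i.e. replicate CVs around 18%, the scale real replicate
spots show).  The
spread of the signal lives ACROSS proteins: a_p = alpha_sig * f_p with
abundance factors f_p log-normal (sd 1 on the log2 scale) by default, or
exactly exponential (so the within-array signal marginal is Exp(alpha_sig)
and the convolution-model fit can be checked for parameter recovery).
v_j is a per-array residual-variance multiplier acting on both noise
components; v_j > 1 emulates a "bad" array.

Per-array technical distortions are applied multiplicatively on the
linear scale as 2^(offset_j + curvature_j * (log2 fg - centre_j)), which
is what scale/loess normalization is meant to undo.  Differential proteins
are shifted by a known log2 fold change in one condition.

The default design emulates a 130-feature array: 123 sample proteins plus
2 negative and 5 positive controls (three of them a BSA dilution series),
each printed in triplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ArraySet, ValidationError


def default_controls() -> list[tuple[str, float, str]]:
    """Two negative controls plus five positives (BSA series and IgG)."""
    return [
        ("NegCtrl-1", 0.0, "control"),
        ("NegCtrl-2", 0.0, "control"),
        ("AF647-BSA-5ng", 0.5, "control"),
        ("AF647-BSA-10ng", 1.0, "control"),
        ("AF647-BSA-15ng", 1.5, "control"),
        ("IgG-1", 2.0, "control"),
        ("IgG-2", 2.0, "control"),
    ]


@dataclass
class SimDesign:
    """Parameters of a simulated array experiment.

    Defaults are the 130-feature triplicate design with 4 arrays in each of
    two conditions, background N(100, 15^2) fluorescence units and mean
    exponential signal 200 units.
    """

    n_proteins: int = 123
    n_replicate_spots: int = 3
    controls: list = field(default_factory=default_controls)
    n_arrays_per_condition: dict = field(
        default_factory=lambda: {"disease": 4, "healthy": 4}
    )
    bg_mean: float = 100.0
    bg_spatial_sd: float = 30.0
    bg_meas_sd: float = 10.0
    bg_array_sd: float = 10.0
    signal_mean: float = 200.0
    protein_log2_sd: float = 1.0
    protein_distribution: str = "lognormal"
    tech_log2_sd: float = 0.25
    bio_log2_sd: float = 0.8
    array_log2_offsets: list | None = None
    array_curvature: list | None = None
    array_variance_factors: list | None = None
    de_fraction: float = 0.0
    de_log2fc: float = 0.0
    de_condition: str | None = None
    seed: int = 0

    @property
    def n_arrays(self) -> int:
        return int(sum(self.n_arrays_per_condition.values()))

    @property
    def n_features(self) -> int:
        return self.n_proteins + len(self.controls)

    @property
    def n_spots(self) -> int:
        return self.n_features * self.n_replicate_spots

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ValidationError("n_proteins must be positive")
        if self.n_replicate_spots <= 0:
            raise ValidationError("n_replicate_spots must be positive")
        if not self.n_arrays_per_condition or any(
            n <= 0 for n in self.n_arrays_per_condition.values()
        ):
            raise ValidationError("array counts per condition must be positive")
        if self.bg_spatial_sd < 0 or self.bg_meas_sd < 0:
            raise ValidationError("background sds must be >= 0")
        if self.bg_spatial_sd + self.bg_meas_sd <= 0:
            raise ValidationError("background noise must have positive spread")
        if self.signal_mean <= 0:
            raise ValidationError("signal_mean must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.protein_distribution not in ("lognormal", "exponential"):
            raise ValidationError(
                f"unknown protein_distribution {self.protein_distribution!r}"
            )
        if self.tech_log2_sd < 0:
            raise ValidationError("tech_log2_sd must be >= 0")
        if self.bg_array_sd < 0:
            raise ValidationError("bg_array_sd must be >= 0")
        if self.bio_log2_sd < 0:
            raise ValidationError("bio_log2_sd must be >= 0")
        for name, vec in (
            ("array_log2_offsets", self.array_log2_offsets),
            ("array_curvature", self.array_curvature),
            ("array_variance_factors", self.array_variance_factors),
        ):
            if vec is not None and len(vec) != self.n_arrays:
                raise ValidationError(f"{name} must have one entry per array")
        if self.array_variance_factors is not None and any(
            v < 0 for v in self.array_variance_factors
        ):
            raise ValidationError("variance factors must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated set (kept out of any file on purpose)."""

    protein_means: pd.DataFrame  # feature x condition true exponential means
    de_labels: pd.Series  # bool per feature
    variance_factors: np.ndarray
    conditions: list


def _layout(design: SimDesign) -> pd.DataFrame:
    """Row-major single-block layout; replicate spots are adjacent."""
    names = [f"Prot{i + 1:03d}" for i in range(design.n_proteins)] + [
        c[0] for c in design.controls
    ]
    cats = ["sample"] * design.n_proteins + [c[2] for c in design.controls]
    rows = []
    n_cols = int(np.ceil(np.sqrt(design.n_spots)))
    k = 0
    for name, cat in zip(names, cats):
        for _ in range(design.n_replicate_spots):
            rows.append(
                {
                    "block": 1,
                    "row": k // n_cols + 1,
                    "column": k % n_cols + 1,
                    "probe_id": name,
                    "probe_name": name,
                    "category": cat,
                    "flag": 0,
                }
            )
            k += 1
    return pd.DataFrame(rows)


def simulate_arrayset(design: SimDesign) -> tuple[ArraySet, SimTruth]:
    """Draw one ArraySet (linear scale) plus its ground-truth record.

    Deterministic given ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    J = design.n_arrays
    conditions = []
    for cond, n in design.n_arrays_per_condition.items():
        conditions += [cond] * n
    cond_levels = list(design.n_arrays_per_condition)
    de_condition = design.de_condition or (
        cond_levels[1] if len(cond_levels) > 1 else cond_levels[0]
    )

    probes = _layout(design)
    n_feat = design.n_features
    spots_per = design.n_replicate_spots
    n_spots = design.n_spots

    # per-protein abundance factors: the signal spread lives across proteins
    if design.protein_distribution == "lognormal":
        factors = 2.0 ** rng.normal(
            0.0, design.protein_log2_sd, size=design.n_proteins
        )
    else:  # exponential marginal, mean 1
        factors = rng.exponential(1.0, size=design.n_proteins)
    rel = np.concatenate([factors, [c[1] for c in design.controls]])
    base_means = design.signal_mean * rel  # per feature

    n_de = int(round(design.de_fraction * design.n_proteins))
    de = np.zeros(n_feat, dtype=bool)
    if n_de > 0 and design.de_log2fc != 0.0:
        de[rng.choice(design.n_proteins, size=n_de, replace=False)] = True

    means = {}
    for cond in cond_levels:
        m = base_means.copy()
        if cond == de_condition:
            m = np.where(de, m * 2.0**design.de_log2fc, m)
        means[cond] = m

    v = np.asarray(
        design.array_variance_factors
        if design.array_variance_factors is not None
        else np.ones(J),
        dtype=float,
    )
    offsets = np.asarray(
        design.array_log2_offsets
        if design.array_log2_offsets is not None
        else np.zeros(J),
        dtype=float,
    )
    curv = np.asarray(
        design.array_curvature if design.array_curvature is not None else np.zeros(J),
        dtype=float,
    )

    E = np.empty((n_spots, J))
    B = np.empty((n_spots, J))
    # per-array background level (wash/scanner differences between slides)
    bg_centres = design.bg_mean + rng.normal(0.0, design.bg_array_sd, size=J)
    for j in range(J):
        feat_means = means[conditions[j]]
        spot_means = np.repeat(feat_means, spots_per)
        sv = np.sqrt(v[j])
        local_bg = bg_centres[j] + rng.normal(
            0.0, design.bg_spatial_sd * sv, size=n_spots
        )
        noise = local_bg + rng.normal(0.0, design.bg_meas_sd * sv, size=n_spots)
        # per-individual biological effect: one draw per sample protein per
        # array, shared by its replicate spots; controls are spiked
        # standards and carry none
        bio = rng.normal(0.0, design.bio_log2_sd * sv, size=n_feat)
        bio[design.n_proteins:] = 0.0
        log2_shift = np.repeat(bio, spots_per)
        if design.tech_log2_sd > 0:
            log2_shift = log2_shift + rng.normal(
                0.0, design.tech_log2_sd * sv, size=n_spots
            )
        signal = spot_means * 2.0**log2_shift
        fg = np.maximum(noise, 0.0) + signal
        if offsets[j] != 0.0 or curv[j] != 0.0:
            lf = np.log2(np.maximum(fg, 1e-12))
            centre = np.median(lf)
            fg = fg * 2.0 ** (offsets[j] + curv[j] * (lf - centre))
        E[:, j] = fg
        B[:, j] = np.maximum(
            local_bg + rng.normal(0.0, design.bg_meas_sd, n_spots), 0.0
        )

    sample_ids = [f"S{j + 1:02d}" for j in range(J)]
    targets = pd.DataFrame(
        {
            "FileName": [f"array_{j + 1:02d}.gpr" for j in range(J)],
            "SampleID": sample_ids,
            "Condition": conditions,
        }
    )
    aset = ArraySet(
        probes=probes,
        E=pd.DataFrame(E, columns=sample_ids),
        B=pd.DataFrame(B, columns=sample_ids),
        targets=targets,
        log_state="linear",
    )
    aset.log(
        f"simulate:seed={design.seed}, {n_feat} features x{spots_per} spots, "
        f"{J} arrays"
    )
    feature_ids = probes["probe_id"].unique()
    truth = SimTruth(
        protein_means=pd.DataFrame(means, index=feature_ids),
        de_labels=pd.Series(de, index=feature_ids),
        variance_factors=v,
        conditions=conditions,
    )
    return aset, truth


def write_fixture_gprs(arrayset: ArraySet, outdir) -> list[Path]:
    """Write one ATF-valid GPR per array plus targets.tsv.

    Intensities are written with 17 significant digits so that
    read_gpr + assemble_arrayset reproduces the ArraySet exactly.
    """
    if arrayset.log_state != "linear":
        raise ValidationError("fixture GPRs require a linear-state ArraySet")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    probes = arrayset.probes
    for j, fname in enumerate(arrayset.targets["FileName"]):
        path = outdir / fname
        with open(path, "w", newline="\n") as fh:
            fh.write("ATF\t1.0\n")
            fh.write("2\t8\n")
            fh.write('"Type=GenePix Results 3"\n')
            fh.write('"Origin=synthetic"\n')
            fh.write(
                '"Block"\t"Row"\t"Column"\t"ID"\t"Name"\t"Flags"\t'
                '"F635 Median"\t"B635 Median"\n'
            )
            fg = arrayset.E.iloc[:, j].to_numpy()
            bg = arrayset.B.iloc[:, j].to_numpy()
            for i in range(len(probes)):
                p = probes.iloc[i]
                fh.write(
                    f"{p['block']}\t{p['row']}\t{p['column']}\t"
                    f"\"{p['probe_id']}\"\t\"{p['probe_name']}\"\t{p['flag']}\t"
                    f"{fg[i]:.17g}\t{bg[i]:.17g}\n"
                )
        paths.append(path)
    tpath = outdir / "targets.tsv"
    arrayset.targets.to_csv(tpath, sep="\t", index=False)
    paths.append(tpath)
    # GPR files carry no category column, so emit the non-default categories
    # as an annotated probe list alongside the fixtures
    ann = probes.loc[probes["category"] != "sample", ["probe_id", "category"]]
    ann = ann.drop_duplicates()
    if len(ann):
        apath = outdir / "probe_categories.tsv"
        ann.to_csv(apath, sep="\t", index=False)
        paths.append(apath)
    return paths
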