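"""Linear models, contrasts, empirical-Bayes moderation and BH adjustment.

The BH oracle is an independent quadratic-time transcription of the
step-up definition; the moderated t is checked against the classical t in
the d0 -> 0 limit and against parameter recovery under the scaled-F prior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from spma import (
    ValidationError,
    bh_adjust,
    contrasts_fit,
    ebayes,
    fit_probewise,
    make_contrasts,
    make_design,
    toptable,
)
from spma.diffexp import trigamma_inverse
from tests.conftest import two_group_design


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Quadratic-time step-up rule, straight from the definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        candidates = [
            m * p[j] / (rank_j + 1)
            for rank_j, j in enumerate(order)
            if rank_j + 1 >= rank_i
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


def targets_frame(conditions):
    return pd.DataFrame(
        {
            "FileName": [f"f{i}.gpr" for i in range(len(conditions))],
            "SampleID": [f"S{i + 1}" for i in range(len(conditions))],
            "Condition": conditions,
        }
    )


class TestDesignAndContrasts:
    def test_group_means_design(self):
        tg = targets_frame(["PDAC", "PDAC", "control", "control"])
        X = make_design(tg)
        assert list(X.columns) == ["PDAC", "control"]
        np.testing.assert_array_equal(
            X.to_numpy(), [[1, 0], [1, 0], [0, 1], [0, 1]]
        )

    def test_two_group_contrast(self):
        tg = targets_frame(["PDAC", "PDAC", "control", "control"])
        C = make_contrasts(tg, ["PDAC-control"])
        assert C["PDAC-control"].tolist() == [1.0, -1.0]

    def test_degenerate_contrast_rejected(self):
        tg = targets_frame(["PDAC", "control"])
        with pytest.raises(ValidationError, match="degenerate"):
            make_contrasts(tg, ["PDAC-PDAC"])

    def test_unknown_level_named_in_error(self):
        tg = targets_frame(["PDAC", "control"])
        with pytest.raises(ValidationError, match="CP"):
            make_contrasts(tg, ["PDAC-CP"])

    def test_three_conditions_two_comparisons(self):
        tg = targets_frame(["a", "a", "b", "b", "c", "c"])
        C = make_contrasts(tg, ["a-b", "b-c"])
        assert C.shape == (3, 2)


class TestFitProbewise:
    def test_hand_least_squares(self):
        """Groups (1,3) vs (5,7): difference -4, pooled s^2 = 2, df = 2."""
        tg = targets_frame(["g1", "g1", "g2", "g2"])
        E = pd.DataFrame([[1.0, 3.0, 5.0, 7.0]], columns=tg["SampleID"])
        fit = contrasts_fit(
            fit_probewise(E, make_design(tg)), make_contrasts(tg, ["g2-g1"])
        )
        assert fit.coefficients.iloc[0, 0] == pytest.approx(4.0)
        assert fit.sigma.iloc[0] ** 2 == pytest.approx(2.0)
        assert fit.df_residual.iloc[0] == 2

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(1)
        E = pd.DataFrame(rng.normal(8, 1, (50, 8)))
        X = two_group_design()
        b1 = fit_probewise(E, X, weights=np.full(8, 1.0)).coefficients
        b2 = fit_probewise(E, X, weights=np.full(8, 3.7)).coefficients
        pd.testing.assert_frame_equal(b1, b2)

    def test_missing_group_makes_contrast_inestimable(self):
        tg = targets_frame(["g1", "g1", "g2", "g2"])
        E = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan]], columns=tg["SampleID"]
        )
        fit = fit_probewise(E, make_design(tg))
        assert np.isfinite(fit.coefficients.iloc[0, 0])
        assert np.isnan(fit.coefficients.iloc[0, 1]) or fit.df_residual.iloc[0] == 0

    def test_missing_values_reduce_df(self):
        tg = targets_frame(["g1"] * 4 + ["g2"] * 4)
        rng = np.random.default_rng(2)
        V = rng.normal(0, 1, (10, 8))
        V[0, 0] = np.nan
        fit = fit_probewise(pd.DataFrame(V, columns=tg["SampleID"]),
                            make_design(tg))
        assert fit.df_residual.iloc[0] == 5
        assert fit.df_residual.iloc[1] == 6


class TestEbayes:
    def test_identical_variances_give_infinite_prior_df(self):
        tg = targets_frame(["g1", "g1", "g2", "g2"])
        base = np.array([1.0, -1.0, 2.0, 4.0])
        E = pd.DataFrame(
            np.vstack([base + k for k in range(20)]), columns=tg["SampleID"]
        )
        fit = contrasts_fit(
            fit_probewise(E, make_design(tg)), make_contrasts(tg, ["g2-g1"])
        )
        st_ = ebayes(fit)
        assert np.isinf(st_.d0)
        np.testing.assert_allclose(
            st_.s_tilde_2, fit.sigma**2, rtol=1e-10
        )

    def test_d0_zero_limit_recovers_classical_t(self):
        rng = np.random.default_rng(3)
        tg = targets_frame(["g1"] * 4 + ["g2"] * 4)
        E = pd.DataFrame(rng.normal(8, 1, (200, 8)), columns=tg["SampleID"])
        fit = contrasts_fit(
            fit_probewise(E, make_design(tg)), make_contrasts(tg, ["g2-g1"])
        )
        st_ = ebayes(fit, d0=0.0, s0_2=1.0)
        V = E.to_numpy()
        t_classic, _ = sps.ttest_ind(V[:, 4:], V[:, :4], axis=1)
        np.testing.assert_allclose(
            st_.t.iloc[:, 0].to_numpy(), t_classic, atol=1e-10
        )

    def test_prior_parameter_recovery_under_scaled_f(self):
        """Simulate s_g^2 ~ s0^2 d0 / chi^2_d0-style prior (d0=4,
        s0^2=0.05, d_g=6) and recover both hyperparameters."""
        rng = np.random.default_rng(5)
        G, d0, s0_2, dg = 5000, 4.0, 0.05, 6
        true_var = s0_2 * d0 / rng.chisquare(d0, G)
        s2 = true_var * rng.chisquare(dg, G) / dg
        fit_like = _fit_from_variances(s2, dg)
        st_ = ebayes(fit_like)
        assert st_.d0 == pytest.approx(4.0, rel=0.25)
        assert st_.s0_2 == pytest.approx(0.05, rel=0.15)

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(6)
        s2 = rng.chisquare(6, 500) / 6 * 0.1
        st_ = ebayes(_fit_from_variances(s2, 6))
        lo = np.minimum(s2, st_.s0_2)
        hi = np.maximum(s2, st_.s0_2)
        sq = st_.s_tilde_2.to_numpy()
        assert ((sq >= lo - 1e-12) & (sq <= hi + 1e-12)).all()

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.1, 0.7, 2.0, 10.0, 200.0):
            x = float(polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


def _fit_from_variances(s2: np.ndarray, dg: int):
    """Minimal ProbeFit carrying given residual variances."""
    from spma.diffexp import ProbeFit

    G = len(s2)
    idx = [f"P{i}" for i in range(G)]
    ones = pd.DataFrame(np.ones((G, 1)), index=idx, columns=["c"])
    return ProbeFit(
        coefficients=ones,
        stdev_unscaled=ones,
        sigma=pd.Series(np.sqrt(s2), index=idx),
        df_residual=pd.Series(float(dg), index=idx),
        cov_unscaled=np.ones((G, 1, 1)),
        design_columns=["c"],
    )


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_capped_at_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 40)))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestTopTable:
    def test_type_one_error_near_nominal(self):
        """Null two-group data: raw-p flagging at 0.05 stays within 2 SE of
        5% across seeds."""
        rates = []
        tg = targets_frame(["g1"] * 4 + ["g2"] * 4)
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            E = pd.DataFrame(rng.normal(8, 0.6, (400, 8)),
                             columns=tg["SampleID"])
            fit = contrasts_fit(
                fit_probewise(E, make_design(tg)),
                make_contrasts(tg, ["g2-g1"]),
            )
            tt = toptable(ebayes(fit), alpha=0.05)
            rates.append(tt["significant"].mean())
        mean_rate = float(np.mean(rates))
        se = float(np.std(rates, ddof=1) / np.sqrt(len(rates)))
        assert abs(mean_rate - 0.05) <= max(2 * se, 0.01)

    def test_spiked_probes_rank_above_nulls(self):
        rng = np.random.default_rng(9)
        tg = targets_frame(["g1"] * 4 + ["g2"] * 4)
        V = rng.normal(8, 0.4, (300, 8))
        V[:20, 4:] += 1.5  # spiked probes
        fit = contrasts_fit(
            fit_probewise(pd.DataFrame(V, columns=tg["SampleID"]),
                          make_design(tg)),
            make_contrasts(tg, ["g2-g1"]),
        )
        tt = toptable(ebayes(fit))
        top20 = {int(p[1:]) for p in
                 (f"P{i}" for i in tt.index[:20])}  # placeholder ids
        spiked_hits = sum(int(pid) < 20 for pid in tt["probe_id"].head(25))
        assert spiked_hits >= 18

    def test_empty_stats_give_empty_table(self):
        st_ = ebayes(_fit_from_variances(np.full(5, 0.1), 4))
        empty = toptable(st_, alpha=0.05)
        assert len(empty) == 5  # non-empty fit gives full table
        import spma.diffexp as dx

        class Dummy:
            t = pd.DataFrame()
            p = pd.DataFrame()
            adj_p = pd.DataFrame()
            coefficients = pd.DataFrame()

        out = dx.toptable(Dummy(), alpha=0.05)
        assert out.empty
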