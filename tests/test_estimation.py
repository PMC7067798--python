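"""Tests of the parameter-estimation chain."""

import warnings

import numpy as np
import pandas as pd
import pytest

from filokin.estimation import (
    DevelopmentalModel,
    FilopodiumTrack,
    bootstrap_estimate,
    estimate_c6,
    estimate_generation_rate,
    estimate_lambda,
    estimate_retraction_rates,
    steepest_slope,
)
from filokin.synthetic import gen_bulb_observations, gen_track_table


def _track(i, life, cls="filopodium", birth=0.0):
    return FilopodiumTrack(str(i), cls, birth, None if life is None else birth + life)


class TestRetractionRates:
    def test_reciprocal_of_constant_lifetimes(self):
        tracks = [_track(i, 2.0) for i in range(5)] + [_track("L", 10.0)]
        c2_sF, c2_lF = estimate_retraction_rates(tracks)
        assert c2_sF == pytest.approx(0.5)
        assert c2_lF == pytest.approx(0.1)

    def test_exponential_sample_recovery(self):
        rng = np.random.default_rng(0)
        lifes = rng.exponential(1.0 / 0.25, size=10_000)
        # keep every draw below the cutoff by using a cutoff beyond the max
        cutoff = lifes.max() + 1.0
        tracks = [_track(i, lf) for i, lf in enumerate(lifes)] + [
            _track("L", cutoff + 1.0)
        ]
        c2_sF, _ = estimate_retraction_rates(tracks, cutoff=cutoff)
        assert c2_sF == pytest.approx(0.25, rel=0.05)

    def test_missing_class_raises(self):
        tracks = [_track(i, 2.0) for i in range(3)]
        with pytest.raises(ValueError, match=">= 8"):
            estimate_retraction_rates(tracks)

    def test_censored_tracks_excluded(self):
        tracks = [_track(i, 2.0) for i in range(3)] + [
            _track("c", None),  # censored: must not contribute
            _track("L", 20.0),
        ]
        c2_sF, c2_lF = estimate_retraction_rates(tracks)
        assert c2_sF == pytest.approx(0.5)
        assert c2_lF == pytest.approx(0.05)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            estimate_retraction_rates([_track(0, 1.0)], cutoff=0.0)


class TestLambda:
    def test_exact_mean_and_zero_dispersion(self):
        snaps = pd.DataFrame({"t_min": [0, 1, 2], "sF": [2, 2, 2]})
        lam, disp = estimate_lambda(snaps, "sF")
        assert lam == 2.0
        assert disp == 0.0

    def test_poisson_sample(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.4, size=10_000)
        snaps = pd.DataFrame({"t_min": np.arange(10_000), "lF": counts})
        lam, disp = estimate_lambda(snaps, "lF")
        assert lam == pytest.approx(3.4, rel=0.02)
        assert disp == pytest.approx(1.0, abs=0.1)

    def test_single_snapshot(self):
        snaps = pd.DataFrame({"t_min": [0.0], "sF": [5]})
        lam, disp = estimate_lambda(snaps, "sF")
        assert lam == 5.0
        assert np.isnan(disp)

    def test_unknown_category(self):
        with pytest.raises(ValueError, match="unknown category"):
            estimate_lambda(pd.DataFrame({"t_min": [0], "sF": [1]}), "xF")


class TestGenerationRate:
    @pytest.mark.parametrize(
        "lam,c2,fF,expected", [(2.0, 0.5, 1.0, 1.0), (0.0, 0.5, 1.0, 0.0)]
    )
    def test_direct(self, lam, c2, fF, expected):
        assert estimate_generation_rate(lam, c2, fF) == pytest.approx(expected)

    def test_zero_drive_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="drive"):
            estimate_generation_rate(2.0, 0.5, 0.0)


class TestC6:
    def test_printed_slope_arithmetic_exact(self):
        # 5 synapses over 600 min at mean synB 1.1: exactly 1/132 per min
        got = estimate_c6(5.0, 600.0, 1.1)
        assert got == pytest.approx(1.0 / 132.0, rel=1e-12)

    @pytest.mark.parametrize(
        "dS,dt,synB,expected", [(0.0, 100.0, 1.0, 0.0), (6.0, 100.0, 2.0, 0.03)]
    )
    def test_direct(self, dS, dt, synB, expected):
        assert estimate_c6(dS, dt, synB) == pytest.approx(expected)

    def test_nonpositive_denominator(self):
        with pytest.raises(ValueError):
            estimate_c6(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            estimate_c6(1.0, 10.0, 0.0)

    def test_steepest_slope_helper(self):
        table = pd.DataFrame(
            {"t_min": [0, 600, 1200, 1800], "mean_S": [0.0, 1.0, 6.0, 8.0]}
        )
        dS, dt = steepest_slope(table)
        assert (dS, dt) == (5.0, 600.0)


def test_bootstrap_interval_covers_mean():
    rng = np.random.default_rng(2)
    data = rng.exponential(4.0, size=500)
    lo, hi = bootstrap_estimate(data, lambda d: float(np.mean(d)), n_boot=200, seed=3)
    assert lo < np.mean(data) < hi
    assert hi - lo < 2.0


class TestEndToEnd:
    def test_recovery_at_large_n(self):
        """Full chain on large synthetic data recovers the ground truth.

        Track/snapshot recovery: c2 within 10%, lambda within 5%.  Bulb
        trio from a long stationary sample: within 25%.
        """
        truth = dict(lambda_sF=7.0, lambda_lF=5.0, c2_sF=0.5, c2_lF=1 / 30,
                     c5=0.05, B50=2.0, r3=0.019)
        tracks, snaps, _ = gen_track_table(
            lambda_sF=truth["lambda_sF"], lambda_lF=truth["lambda_lF"],
            c2_sF=truth["c2_sF"], c2_lF=truth["c2_lF"],
            duration=5000.0, n_terminals=4, seed=10,
        )
        sB, synB, _ = gen_bulb_observations(
            r3=truth["r3"], c4=1 / 120, c5=truth["c5"], c6=1 / 132,
            B50=truth["B50"], total_time=1_000_000.0, sample_dt=5.0, seed=11,
        )
        model = DevelopmentalModel.from_dataframes(
            tracks, snaps,
            obs_sB=sB["frequency"], obs_synB=synB["frequency"],
            fixed={"c6": 1 / 132}, genotype_label="synthetic",
        )
        res = model.fit()
        p = res.params
        assert p.c2_sF == pytest.approx(truth["c2_sF"], rel=0.10)
        assert p.c2_lF == pytest.approx(truth["c2_lF"], rel=0.10)
        assert res.diagnostics["lambda_sF"] == pytest.approx(truth["lambda_sF"], rel=0.05)
        assert res.diagnostics["lambda_lF"] == pytest.approx(truth["lambda_lF"], rel=0.05)
        assert p.c5 == pytest.approx(truth["c5"], rel=0.25)
        assert p.B50 == pytest.approx(truth["B50"], rel=0.25)
        assert res.diagnostics["r3_P60"] == pytest.approx(truth["r3"], rel=0.25)
        # provenance bookkeeping
        assert res.provenance["c4"] == "fixed"
        assert res.provenance["c5"] == "estimated"
        assert "genotype" in res.summary().lower() or "synthetic" in res.summary()

    def test_study_scale_stays_in_the_ballpark(self):
        """8 terminals x 60 min: noisier, but lambdas still land within 15%."""
        tracks, snaps, _ = gen_track_table(duration=60.0, n_terminals=8, seed=4)
        model = DevelopmentalModel.from_dataframes(
            tracks, snaps, fixed={"c6": 1 / 132}, genotype_label="study-scale"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        assert res.diagnostics["lambda_sF"] == pytest.approx(7.0, rel=0.15)
        assert res.diagnostics["lambda_lF"] == pytest.approx(5.0, rel=0.15)

    def test_missing_bulb_observations_flagged(self):
        tracks, snaps, _ = gen_track_table(duration=200.0, n_terminals=2, seed=5)
        model = DevelopmentalModel.from_dataframes(
            tracks, snaps, fixed={"c6": 1 / 132}
        )
        with pytest.warns(UserWarning, match="unestimated"):
            res = model.fit()
        assert res.provenance["c5"] == "unestimated"
        assert res.bulb_fit is None

    def test_fit_is_deterministic(self):
        tracks, snaps, _ = gen_track_table(duration=120.0, n_terminals=2, seed=6)
        model = DevelopmentalModel.from_dataframes(
            tracks, snaps, fixed={"c6": 1 / 132}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = model.fit()
            b = model.fit()
        assert a.params == b.params
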