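import dataclasses

import numpy as np
import pandas as pd
import pytest

from bdqsim import CovariateSet, typical_parameters
from bdqsim.params import ModelParameters, OmegaSet, ResidualError
from bdqsim.population import (
    generate_observed,
    generate_population,
    nc005_observation_design,
    nc005_population_spec,
    nc005_regimens,
)
from bdqsim.vpc import (
    DEFAULT_LEVELS,
    ObservedDataset,
    percentile_bands,
    simulate_replicates,
    vpc_report,
)


def small_spec(n_per_arm=12):
    spec = nc005_population_spec()
    return dataclasses.replace(
        spec, arms=tuple(dataclasses.replace(a, n=n_per_arm) for a in spec.arms))


def arm_map(spec):
    return {a.name: a.regimen_name for a in spec.arms}


def make_obs(params, spec, seed=0, residual=None):
    residual = params.residual if residual is None else residual
    rng = np.random.default_rng(seed)
    pop = generate_population(spec, params, rng)
    df = generate_observed(pop, nc005_observation_design(), nc005_regimens(),
                           arm_map(spec), residual, rng)
    return ObservedDataset(df)


class TestObservedDataset:
    def test_missing_column_is_named(self, params):
        obs = make_obs(params, small_spec(4), seed=1)
        with pytest.raises(ValueError, match="conc"):
            ObservedDataset(obs.df.drop(columns=["conc"]))

    def test_empty_and_negative_rejected(self, params):
        obs = make_obs(params, small_spec(4), seed=1)
        with pytest.raises(ValueError):
            ObservedDataset(obs.df.iloc[:0])
        bad = obs.df.copy()
        bad.loc[0, "conc"] = -1.0
        with pytest.raises(ValueError):
            ObservedDataset(bad)

    def test_subject_in_two_arms_rejected(self, params):
        obs = make_obs(params, small_spec(4), seed=1)
        bad = obs.df.copy()
        bad.loc[bad.index[-1], "subject_id"] = bad.loc[0, "subject_id"]
        with pytest.raises(ValueError, match="multiple arms"):
            ObservedDataset(bad)


class TestSimulateReplicates:
    def test_zero_omega_single_replicate_equals_typical_prediction(self, params):
        spec = small_spec(5)
        zero = ModelParameters(theta=params.theta, omega=OmegaSet.zero(),
                               residual=ResidualError(0.0, 0.0))
        obs = make_obs(zero, spec, seed=2, residual=ResidualError(0.0, 0.0))
        sims = simulate_replicates(obs, zero, nc005_regimens(), arm_map(spec),
                                   n_rep=1, seed=3, include_residual=False)
        # noise-free data from a BSV-free model: replicate == observed == typical
        np.testing.assert_allclose(sims[0], obs.df["conc"].to_numpy(), rtol=1e-9)

    def test_requested_number_of_replicates(self, params):
        spec = small_spec(3)
        obs = make_obs(params, spec, seed=4)
        sims = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec),
                                   n_rep=7, seed=5)
        assert sims.shape == (7, len(obs))

    def test_seed_contract(self, params):
        spec = small_spec(3)
        obs = make_obs(params, spec, seed=6)
        a = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec), n_rep=4, seed=7)
        b = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec), n_rep=4, seed=7)
        c = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec), n_rep=4, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_missing_covariate_rejected(self, params):
        spec = small_spec(3)
        obs = make_obs(params, spec, seed=9)
        df = obs.df.copy()
        df.loc[:, "sex"] = None
        broken = ObservedDataset.__new__(ObservedDataset)
        broken.df = df
        with pytest.raises(ValueError, match="sex"):
            simulate_replicates(broken, params, nc005_regimens(), arm_map(spec), n_rep=1)


class TestPercentileBands:
    def test_identical_replicates_give_zero_width(self, params):
        spec = small_spec(4)
        obs = make_obs(params, spec, seed=10)
        one = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec),
                                  n_rep=1, seed=11, include_residual=False)
        sims = np.repeat(one, 30, axis=0)
        bands = percentile_bands(obs, sims)
        np.testing.assert_allclose(bands["ci_lo"], bands["ci_hi"], rtol=1e-12)

    def test_levels_per_record_type(self, params):
        spec = small_spec(16)
        obs = make_obs(params, spec, seed=12)
        sims = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec),
                                   n_rep=10, seed=13)
        bands = percentile_bands(obs, sims)
        assert set(bands[bands.record_type == "trough"]["level"]) == {5.0, 50.0, 95.0}
        assert set(bands[bands.record_type == "profile"]["level"]) == {10.0, 50.0, 90.0}

    def test_unsupported_levels_rejected(self, params):
        spec = small_spec(4)
        obs = make_obs(params, spec, seed=14)
        sims = np.ones((3, len(obs)))
        with pytest.raises(ValueError):
            percentile_bands(obs, sims, levels={"trough": (1.0, 50.0, 99.0),
                                                "profile": (10.0, 50.0, 90.0)})

    def test_ci_width_converges_with_more_replicates(self, params):
        """The percentile CI estimate converges to the finite-population
        sampling spread as replicates grow; more replicates estimate that
        limiting width more accurately (it does not shrink to zero)."""
        spec = small_spec(10)
        obs = make_obs(params, spec, seed=15)
        kw = dict(params=params, regimens=nc005_regimens(), arm_regimen=arm_map(spec))

        def width(n_rep, seed):
            sims = simulate_replicates(obs, n_rep=n_rep, seed=seed, **kw)
            b = percentile_bands(obs, sims)
            return (b.ci_hi - b.ci_lo).mean()

        w_ref = width(1200, 16)
        assert abs(width(300, 17) - w_ref) < abs(width(20, 17) - w_ref)


class TestVpcReport:
    def test_self_generated_data_is_overwhelmingly_inside(self, params):
        spec = small_spec(25)
        obs = make_obs(params, spec, seed=17)
        sims = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec),
                                   n_rep=120, seed=18)
        result = vpc_report(obs, sims)
        assert result.fraction_inside >= 0.75
        med = result.bands[result.bands.level == 50.0]
        assert med["inside"].mean() >= 0.75

    def test_inflated_clearance_data_falls_below_the_bands(self, params):
        spec = small_spec(25)
        fast = ModelParameters(
            theta=dataclasses.replace(
                params.theta,
                apparent_clearance_typical=3.0 * params.theta.apparent_clearance_typical),
            omega=params.omega, residual=params.residual)
        obs = make_obs(fast, spec, seed=19)  # data from a 3x-clearance world
        sims = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec),
                                   n_rep=80, seed=20)
        bands = vpc_report(obs, sims).bands
        troughs = bands[(bands.record_type == "trough") & (bands.level == 50.0)]
        assert (troughs["position"] == "below").mean() > 0.5

    def test_outputs_written(self, params, tmp_path):
        spec = small_spec(6)
        obs = make_obs(params, spec, seed=21)
        sims = simulate_replicates(obs, params, nc005_regimens(), arm_map(spec),
                                   n_rep=10, seed=22)
        csv = tmp_path / "bands.csv"
        png = tmp_path / "bands.png"
        result = vpc_report(obs, sims, csv_path=csv, plot_path=png)
        assert csv.exists() and png.stat().st_size > 0
        back = pd.read_csv(csv)
        assert len(back) == len(result.bands)
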