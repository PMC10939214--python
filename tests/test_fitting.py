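import math

import numpy as np
import pandas as pd
import pytest

from arenasim.ecopath import solve_mass_balance
from arenasim.ecosim import ForcingSet, VulnerabilityMatrix, run_simulation
from arenasim.fitting import (
    ClimateIndex,
    ReferenceSeries,
    TimeSeriesSet,
    compare_to_climate_index,
    fit_pp_anomaly,
    fit_pipeline,
    fit_vulnerabilities,
    load_timeseries,
    save_timeseries,
    sum_of_squares,
)
from arenasim.model import FunctionalGroup
from arenasim.synth import SyntheticScenario, generate_foodweb, generate_reference_data
from tests.conftest import make_model

YEARS = pd.Index(range(1979, 2021))


@pytest.fixture(scope="module")
def chain_run():
    model = make_model(
        [FunctionalGroup("phyto", role="producer", B=30, PB=100),
         FunctionalGroup("zoop", B=5, PB=20, QB=60),
         FunctionalGroup("fish", B=0.5, PB=1.5, QB=8)],
        {("phyto", "zoop"): 1.0, ("zoop", "fish"): 1.0}, base_year=1979)
    sol = solve_mass_balance(model)
    run = run_simulation(model, sol)
    return model, sol, run


class TestSumOfSquares:
    def test_perfect_prediction_is_zero(self, chain_run):
        _, _, run = chain_run
        ts = TimeSeriesSet([ReferenceSeries("fish", "absolute_biomass",
                                            run.annual_B["fish"])])
        ss, detail = sum_of_squares(run, ts)
        assert ss == pytest.approx(0.0, abs=1e-20)

    def test_catchability_absorbs_constant_scaling(self, chain_run):
        _, _, run = chain_run
        ts = TimeSeriesSet([ReferenceSeries("fish", "relative_biomass",
                                            3.0 * run.rel_B["fish"])])
        ss, detail = sum_of_squares(run, ts)
        assert ss == pytest.approx(0.0, abs=1e-20)
        assert detail["q"].iloc[0] == pytest.approx(3.0)

    def test_absolute_series_keeps_offsets(self, chain_run):
        """Three years of (1, e, 1) against flat unit predictions give SS = 1
        for an absolute series; no q rescaling applies."""
        _, _, run = chain_run
        pred = run.annual_B["fish"].iloc[:3]
        obs = pred * np.array([1.0, math.e, 1.0])
        ts = TimeSeriesSet([ReferenceSeries("fish", "absolute_biomass", obs)])
        ss, _ = sum_of_squares(run, ts)
        assert ss == pytest.approx(1.0, rel=1e-12)

    def test_weights_scale_contributions(self, chain_run):
        _, _, run = chain_run
        obs = run.annual_B["fish"] * math.e
        ts1 = TimeSeriesSet([ReferenceSeries("fish", "absolute_biomass", obs, 1.0)])
        ts3 = TimeSeriesSet([ReferenceSeries("fish", "absolute_biomass", obs, 3.0)])
        assert sum_of_squares(run, ts3)[0] == pytest.approx(
            3 * sum_of_squares(run, ts1)[0])

    def test_nonpositive_observation_rejected(self, chain_run):
        with pytest.raises(ValueError):
            ReferenceSeries("fish", "relative_biomass",
                            pd.Series([1.0, -1.0], index=[1979, 1980]))

    def test_series_round_trip(self, tmp_path, chain_run):
        _, _, run = chain_run
        ts = TimeSeriesSet([
            ReferenceSeries("fish", "relative_biomass", run.rel_B["fish"], 2.0),
            ReferenceSeries("zoop", "total_mortality", run.annual_Z["zoop"]),
        ])
        save_timeseries(ts, tmp_path / "ts.csv")
        loaded = load_timeseries(tmp_path / "ts.csv")
        assert sum_of_squares(run, loaded)[0] == pytest.approx(
            sum_of_squares(run, ts)[0])


class TestVulnerabilitySearch:
    def test_flat_series_keep_defaults(self, chain_run):
        model, sol, run = chain_run
        ts = TimeSeriesSet([ReferenceSeries("fish", "relative_biomass",
                                            pd.Series(1.0, index=YEARS))])
        fr = fit_vulnerabilities(model, sol, ts, budget=120)
        x = fr.x.x
        for j in x.columns:
            col = x[j].dropna()
            assert (col == 2.0).all()

    def test_trace_is_monotone(self, small_web, small_refdata):
        model, sol = small_web
        ts, forc, _ = small_refdata
        fr = fit_vulnerabilities(model, sol, ts, forc, budget=80)
        assert all(a >= b - 1e-12 for a, b in zip(fr.trace, fr.trace[1:]))

    def test_budget_exhaustion_flagged_not_raised(self, small_web, small_refdata):
        model, sol = small_web
        ts, forc, _ = small_refdata
        fr = fit_vulnerabilities(model, sol, ts, forc, budget=15)
        assert fr.budget_exhausted

    def test_truth_never_beaten_on_noise_free_data(self):
        """Self-consistency: series generated by the model at known x give
        SS = 0 at the truth, so no default-x fit can do better."""
        sc = SyntheticScenario(seed=4, sigma_obs=0.0, n_stanza_species=0,
                               n_predators=1)
        model = generate_foodweb(sc)
        sol = solve_mass_balance(model)
        ts, forc, truth = generate_reference_data(sc, model)
        f_truth = ForcingSet(F=forc.F, producer_anomaly=truth["ppa"],
                             biomass=forc.biomass)
        run_truth = run_simulation(model, sol, x=truth["x"], forcings=f_truth)
        assert sum_of_squares(run_truth, ts)[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_perturbed_link_recovered(self):
        """One strongly vulnerable link (true x = 10) behind a growing
        predator is recovered within +/-20% from noise-free series."""
        model = make_model(
            [FunctionalGroup("prey", role="producer", B=50.0, PB=10.0),
             FunctionalGroup("herb", B=4.0, PB=1.0, QB=5.0),
             FunctionalGroup("seal", B=0.2, PB=0.2, QB=15.0, UN=0.15)],
            {("prey", "herb"): 1.0, ("prey", "seal"): 0.3, ("herb", "seal"): 0.7},
            base_year=1979)
        sol = solve_mass_balance(model)
        x_true = VulnerabilityMatrix.default(model)
        x_true = x_true.with_predator_column("seal", 10.0)
        traj = pd.Series(np.minimum(1 + np.arange(42) * 0.15, 4.0), index=YEARS)
        forc = ForcingSet(biomass={"seal": traj})
        run = run_simulation(model, sol, x=x_true, forcings=forc)
        ts = TimeSeriesSet([
            ReferenceSeries("herb", "relative_biomass", run.rel_B["herb"]),
            ReferenceSeries("herb", "total_mortality", run.annual_Z["herb"]),
            ReferenceSeries("prey", "relative_biomass", run.rel_B["prey"]),
        ])
        fr = fit_vulnerabilities(model, sol, ts, forc, budget=200)
        fitted = fr.x.x.at["herb", "seal"]
        assert 8.0 <= fitted <= 12.0


class TestAnomalySearch:
    def test_flat_data_gives_unit_anomaly(self, chain_run):
        model, sol, run = chain_run
        ts = TimeSeriesSet([ReferenceSeries("phyto", "relative_biomass",
                                            pd.Series(1.0, index=YEARS))])
        fp = fit_pp_anomaly(model, sol, VulnerabilityMatrix.default(model),
                            ts, budget=600, max_sweeps=1)
        assert np.abs(np.log(fp.ppa.to_numpy())).max() < 0.01

    def test_anomaly_has_one_node_per_year(self, chain_run):
        model, sol, run = chain_run
        ts = TimeSeriesSet([ReferenceSeries("phyto", "relative_biomass",
                                            pd.Series(1.0, index=YEARS))])
        fp = fit_pp_anomaly(model, sol, VulnerabilityMatrix.default(model),
                            ts, budget=40, max_sweeps=1)
        assert len(fp.ppa) == 42
        assert np.log(fp.ppa.to_numpy()).mean() == pytest.approx(0.0, abs=1e-12)

    def test_square_wave_recovered_noise_free(self):
        """A +/-0.2 log-unit, 6-year-period producer anomaly is recovered
        (>= 90% of yearly signs) from noise-free observations."""
        sc = SyntheticScenario(seed=9, sigma_obs=0.0, n_stanza_species=0,
                               n_predators=1)
        model = generate_foodweb(sc)
        sol = solve_mass_balance(model)
        ts, forc, truth = generate_reference_data(sc, model)
        fp = fit_pp_anomaly(model, sol, VulnerabilityMatrix.default(model),
                            ts, forc, budget=900, max_sweeps=2)
        agree = np.mean(np.sign(np.log(fp.ppa.to_numpy()))
                        == np.sign(np.log(truth["ppa"].to_numpy())))
        assert agree >= 0.90

    def test_requires_a_producer(self):
        model = make_model([FunctionalGroup("det", role="detritus", B=1.0)], {})
        with pytest.raises(ValueError, match="producer"):
            fit_pp_anomaly(model, None, None, TimeSeriesSet([]))


class TestPipeline:
    def test_stage_ss_monotone_and_truth_recovered(self, small_web, small_refdata):
        model, sol = small_web
        ts, forc, truth = small_refdata
        res = fit_pipeline(model, sol, ts, forc, cycles=2, budget_vul=200,
                           budget_ppa=500)
        assert all(a >= b - 1e-9 for a, b in
                   zip(res.ss_stages, res.ss_stages[1:]))
        agree = np.mean(np.sign(np.log(res.ppa.to_numpy()))
                        == np.sign(np.log(truth["ppa"].to_numpy())))
        errs = [abs(math.log(res.x.x[j].dropna().iloc[0]
                             / truth["x"].x[j].dropna().iloc[0]))
                for j in res.x.x.columns if len(res.x.x[j].dropna())]
        assert agree >= 0.8
        assert np.median(errs) < 0.5


class TestClimateComparison:
    @pytest.fixture
    def ppa(self):
        rng = np.random.default_rng(3)
        logv = rng.normal(0, 0.2, 42)
        logv -= logv.mean()
        return pd.Series(np.exp(logv), index=YEARS)

    def test_identity_agrees_everywhere(self, ppa):
        logv = np.log(ppa.to_numpy())
        idx = ClimateIndex("self", pd.Series(
            (logv - logv.mean()) / logv.std(), index=YEARS))
        pair, agree, r = compare_to_climate_index(ppa, idx)
        assert agree == 42
        assert r == pytest.approx(1.0)

    def test_antisymmetry(self, ppa):
        logv = np.log(ppa.to_numpy())
        idx = ClimateIndex("anti", pd.Series(-logv, index=YEARS))
        _, agree, r = compare_to_climate_index(ppa, idx)
        assert agree == 0
        assert r == pytest.approx(-1.0)

    def test_four_year_enumeration(self):
        ppa = pd.Series(np.exp([0.2, 0.2, -0.2, -0.2]), index=range(2000, 2004))
        idx = ClimateIndex("toy", pd.Series([0.5, -0.5, -0.5, 0.5],
                                            index=range(2000, 2004)))
        _, agree, _ = compare_to_climate_index(ppa, idx)
        assert agree == 2

    def test_zero_variance_rejected(self, ppa):
        idx = ClimateIndex("flat", pd.Series(1.0, index=YEARS))
        with pytest.raises(ValueError, match="variance"):
            compare_to_climate_index(ppa, idx)
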