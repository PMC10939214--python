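"""Synthetic food webs, forcing scenarios and noisy reference series with
known ground truth.

The generator builds a producer → zooplankton → forage-fish → salmon-like
split species → marine-mammal-like predator web, sized top-down so every
prey's ecotrophic efficiency stays below a cap (default 0.95) and the web
balances.  Reference data emulate the structure of an agency-derived
calibration set: relative-biomass indices with lognormal observation
noise, total-mortality (Z) series for salmon stanzas, fishing-mortality
forcings with a strong mid-series decline (the 1990s restrictions
pattern), census-forced growing predator populations (severalfold
increases plateauing ~2 decades in), and an oscillating annual
producer-productivity anomaly with known sign pattern.

Everything is driven by one integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from arenasim.ecopath import solve_mass_balance
from arenasim.ecosim import ForcingSet, VulnerabilityMatrix, run_simulation
from arenasim.fitting import ClimateIndex, ReferenceSeries, TimeSeriesSet
from arenasim.model import (
    DietMatrix,
    EcopathModel,
    Fleet,
    FunctionalGroup,
    Stanza,
    StanzaSet,
)
from arenasim.stanzas import distribute_stanza_parameters

__all__ = [
    "SyntheticScenario",
    "GenerationError",
    "salish_like",
    "generate_foodweb",
    "generate_reference_data",
    "generate_climate_index",
]


class GenerationError(ValueError):
    """The requested scenario cannot be realized."""


@dataclass
class SyntheticScenario:
    """Knobs for one synthetic study; defaults give a small, fast web."""

    seed: int = 0
    n_stanza_species: int = 1      # salmon-like split species
    n_predators: int = 2           # growing marine-mammal-like predators
    include_forage_fish: bool = True
    include_detritus: bool = True
    horizon_years: int = 42
    base_year: int = 1979
    sigma_obs: float = 0.1         # lognormal observation noise, log units
    ee_cap: float = 0.95
    # fishing-mortality decline (mid-series restrictions)
    f_decline_start: int = 11      # years after base (≈1990)
    f_decline_end: int = 21        # (≈2000)
    f_decline_range: tuple[float, float] = (0.37, 0.84)
    # predator growth (census-forced), plateau two decades in
    predator_growth_range: tuple[float, float] = (2.0, 6.0)
    predator_growth_plateau: int = 21
    # truth for the searches
    x_default: float = 2.0
    predator_x_log_mean: float = math.log(3.0)
    predator_x_log_sd: float = 0.5
    ppa_log_amplitude: float = 0.2
    ppa_period_years: int = 6

    def n_groups(self) -> int:
        return (1 + 1 + int(self.include_forage_fish) + int(self.include_detritus)
                + 4 * self.n_stanza_species + self.n_predators)


def salish_like(seed: int = 0) -> SyntheticScenario:
    """Preset mirroring the northeast Pacific study structure at reduced
    size: 4 salmon-like split species (16 stanza groups), 6 growing
    predator groups, fishing declines of 37–84%% and predator growth of
    2–6× over a 42-year horizon."""
    return SyntheticScenario(seed=seed, n_stanza_species=4, n_predators=6)


# ---------------------------------------------------------------------------
# food web

def _stanza_def(rng: np.random.Generator, name: str) -> dict:
    return {
        "z_smolt": rng.uniform(2.0, 3.0),
        "z_juv": rng.uniform(0.4, 0.7),
        "z_adult": rng.uniform(0.8, 1.2),
        "z_escapee": rng.uniform(0.3, 0.6),
        "adult_B": rng.uniform(0.05, 0.12),
        "adult_QB": rng.uniform(2.0, 3.0),
        "F0": rng.uniform(0.2, 0.4),
        # semelparous fish approach asymptotic size within the modelled span
        "vbK": rng.uniform(0.6, 0.9),
    }


def generate_foodweb(scenario: SyntheticScenario) -> EcopathModel:
    """Build a balanced web; every prey EE <= scenario.ee_cap by sizing.

    Predator biomasses are drawn first; forage-fish, zooplankton and
    producer pools are then sized so the demand on each equals the drawn
    EE target times its production (a web assembled this way passes
    :func:`solve_mass_balance` with ``balanced = True`` by construction).
    """
    if scenario.n_groups() < 3:
        raise GenerationError("need at least 3 groups (producer, grazer, consumer)")
    rng = np.random.default_rng(scenario.seed)
    cap = scenario.ee_cap

    names: list[str] = []
    groups: list[FunctionalGroup] = []
    diet_cols: dict[str, dict[str, float]] = {}
    landings: dict[str, float] = {}
    stanza_sets: list[StanzaSet] = []

    producer = "producer"
    zoop = "zooplankton"
    forage = "forage fish" if scenario.include_forage_fish else zoop
    detritus = "detritus" if scenario.include_detritus else None

    pb_prod = rng.uniform(40.0, 80.0)
    pb_zoop = rng.uniform(10.0, 20.0)
    qb_zoop = pb_zoop / rng.uniform(0.28, 0.35)
    pb_forage = rng.uniform(0.7, 1.1)
    qb_forage = pb_forage / rng.uniform(0.18, 0.25)

    # salmon-like split species -------------------------------------------
    species_names = [f"salmon {chr(ord('A') + k)}" for k in range(scenario.n_stanza_species)]
    sdefs = {sp: _stanza_def(rng, sp) for sp in species_names}
    salmon_groups: dict[str, dict[str, str]] = {}
    for sp in species_names:
        d = sdefs[sp]
        st_names = {s: f"{sp} {s}" for s in ("smolts", "juveniles", "adults", "escapees")}
        salmon_groups[sp] = st_names
        ss = StanzaSet(
            species=sp,
            stanzas=[
                Stanza(st_names["smolts"], 0, 12, d["z_smolt"]),
                Stanza(st_names["juveniles"], 12, 24, d["z_juv"]),
                Stanza(st_names["adults"], 24, 36, d["z_adult"], leading=True),
                Stanza(st_names["escapees"], 36, 48, d["z_escapee"]),
            ],
            vbK=d["vbK"], wmat_over_winf=0.5, terminal=True)
        stanza_sets.append(ss)
        dist = distribute_stanza_parameters(ss, d["adult_B"], d["adult_QB"])
        zmap = {st.name: st.Z for st in ss.stanzas}
        for st_name, (b_s, qb_s) in dist.items():
            groups.append(FunctionalGroup(st_name, B=b_s, PB=zmap[st_name], QB=qb_s))
            names.append(st_name)
        landings[st_names["adults"]] = d["F0"] * dist[st_names["adults"]][0]
        diet_cols[st_names["smolts"]] = {zoop: 1.0}
        diet_cols[st_names["juveniles"]] = {zoop: 0.3, forage: 0.7}
        diet_cols[st_names["adults"]] = {forage: 0.9, zoop: 0.1}
        diet_cols[st_names["escapees"]] = {}  # spawning run: import only

    # predators ------------------------------------------------------------
    predator_names = [f"predator {chr(ord('A') + k)}" for k in range(scenario.n_predators)]
    adult_names = [salmon_groups[sp]["adults"] for sp in species_names]
    smolt_names = [salmon_groups[sp]["smolts"] for sp in species_names]
    for k, pn in enumerate(predator_names):
        b = rng.uniform(0.002, 0.02)
        pb = rng.uniform(0.08, 0.2)
        qb = rng.uniform(12.0, 25.0)
        groups.append(FunctionalGroup(pn, B=b, PB=pb, QB=qb, UN=0.15))
        names.append(pn)
        smolt_specialist = scenario.n_stanza_species > 0 and k % 3 == 0
        col: dict[str, float] = {forage: 0.5}
        if scenario.n_stanza_species:
            targets = smolt_names if smolt_specialist else adult_names
            w = rng.dirichlet(np.ones(len(targets))) * 0.5
            for t_name, wt in zip(targets, w):
                col[t_name] = float(wt)
        else:
            col[forage] = 1.0
        diet_cols[pn] = col

    # cap EE on salmon stanzas by scaling predator biomass down ------------
    def predation_on(prey: str) -> float:
        tot = 0.0
        for j, col in diet_cols.items():
            if prey in col:
                gj = next(g for g in groups if g.name == j)
                tot += col[prey] * gj.QB * gj.B
        return tot

    scale = 1.0
    for g in groups:
        if g.name in diet_cols and g.name.startswith("salmon"):
            f0 = landings.get(g.name, 0.0) / g.B
            demand = predation_on(g.name)
            if demand > 0:
                room = (cap * g.PB - f0) * g.B
                if room <= 0:
                    raise GenerationError(
                        f"fishing alone exceeds the EE cap for {g.name!r}")
                scale = min(scale, room / demand)
    for g in groups:
        if g.name in predator_names:
            g.B *= scale

    # size the lower pools so each prey's EE equals its target -------------
    def add_pool(name: str, pb: float, qb: float | None, ee_target: float,
                 role: str = "consumer"):
        demand = predation_on(name)
        b = demand / (pb * ee_target) if demand > 0 else rng.uniform(1.0, 5.0)
        groups.append(FunctionalGroup(name, role=role, B=b, PB=pb, QB=qb or 0.0))
        names.append(name)

    if scenario.include_forage_fish:
        add_pool(forage, pb_forage, qb_forage, rng.uniform(0.6, cap))
        diet_cols[forage] = {zoop: 1.0}
    add_pool(zoop, pb_zoop, qb_zoop, rng.uniform(0.5, cap))
    diet_cols[zoop] = ({producer: 0.9, detritus: 0.1} if detritus
                       else {producer: 1.0})
    add_pool(producer, pb_prod, None, rng.uniform(0.1, 0.5), role="producer")
    if detritus:
        groups.append(FunctionalGroup(detritus, role="detritus", B=10.0,
                                      PB=None, QB=None, UN=0.0))
        names.append(detritus)

    dc = pd.DataFrame(0.0, index=names, columns=names)
    imp = pd.Series(0.0, index=names)
    for j, col in diet_cols.items():
        tot = sum(col.values())
        if tot > 1.0 + 1e-9:
            raise GenerationError(f"diet of {j!r} exceeds 1")
        for i, wgt in col.items():
            dc.at[i, j] = wgt
        imp[j] = 1.0 - tot
    # escapees feed outside the modelled web entirely
    diet = DietMatrix(dc, imp)

    fleets = [Fleet("fishery", dict(landings))] if landings else []
    model = EcopathModel(
        groups=groups, diet=diet, fleets=fleets, stanza_sets=stanza_sets,
        area=1.0, base_year=scenario.base_year,
        flags={"synthetic": True,
               "predator_groups": predator_names,
               "salmon_species": species_names,
               "producer_group": producer})

    sol = solve_mass_balance(model)
    living = [g.name for g in model.living()]
    if not sol.balanced or (sol.EE[living] > cap + 1e-6).any():
        raise GenerationError(
            "generated web failed to balance under the EE cap "
            f"(max EE {sol.EE[living].max():.3f})")
    return model


# ---------------------------------------------------------------------------
# forcings, truth and observations

def _true_vulnerabilities(scenario: SyntheticScenario, model: EcopathModel,
                          rng: np.random.Generator) -> VulnerabilityMatrix:
    x = VulnerabilityMatrix.default(model, scenario.x_default)
    for pn in model.flags.get("predator_groups", []):
        val = float(np.exp(rng.normal(scenario.predator_x_log_mean,
                                      scenario.predator_x_log_sd)))
        x = x.with_predator_column(pn, max(1.05, val))
    return x


def _true_ppa(scenario: SyntheticScenario) -> pd.Series:
    years = pd.Index(range(scenario.base_year,
                           scenario.base_year + scenario.horizon_years))
    t = np.arange(scenario.horizon_years)
    half = scenario.ppa_period_years // 2
    sign = np.where((t // max(half, 1)) % 2 == 0, 1.0, -1.0)
    logv = scenario.ppa_log_amplitude * sign
    logv = logv - logv.mean()
    return pd.Series(np.exp(logv), index=years)


def generate_reference_data(scenario: SyntheticScenario, model: EcopathModel):
    """Run the truth simulation and derive noisy observations.

    Returns ``(ts, forcings, truth)``: the reference series, the forcings
    handed to a fitting pipeline (fishing decline + predator biomass
    trajectories, but NOT the productivity anomaly — that is what the
    fit must recover), and the ground-truth dictionary with the true
    vulnerabilities, true anomaly and the noise-free truth run.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    years = pd.Index(range(scenario.base_year,
                           scenario.base_year + scenario.horizon_years))
    t = np.arange(scenario.horizon_years)
    solution = solve_mass_balance(model)
    x_true = _true_vulnerabilities(scenario, model, rng)
    ppa_true = _true_ppa(scenario)

    # fishing declines
    f_cols = {}
    decline_mag = {}
    for fl in model.fleets:
        for g, y in fl.landings.items():
            f0 = y / solution.B[g]
            mag = float(rng.uniform(*scenario.f_decline_range))
            decline_mag[g] = mag
            frac = np.clip((t - scenario.f_decline_start)
                           / max(scenario.f_decline_end - scenario.f_decline_start, 1),
                           0.0, 1.0)
            f_cols[g] = f0 * (1.0 - mag * frac)
    F = pd.DataFrame(f_cols, index=years) if f_cols else None

    # census-forced predator growth
    growth = {}
    biomass_forcings = {}
    for pn in model.flags.get("predator_groups", []):
        factor = float(rng.uniform(*scenario.predator_growth_range))
        growth[pn] = factor
        frac = np.minimum(t / scenario.predator_growth_plateau, 1.0)
        biomass_forcings[pn] = pd.Series(factor ** frac, index=years)

    forcings_fit = ForcingSet(F=F, biomass=biomass_forcings)
    forcings_truth = ForcingSet(F=F, producer_anomaly=ppa_true,
                                biomass=biomass_forcings)
    run = run_simulation(model, solution, x=x_true, forcings=forcings_truth,
                         years=scenario.horizon_years)

    def noisy(values: pd.Series) -> pd.Series:
        eps = rng.normal(0.0, scenario.sigma_obs, size=len(values))
        return values * np.exp(eps)

    series: list[ReferenceSeries] = []
    obs_groups = [model.flags.get("producer_group", "producer")]
    if "forage fish" in run.names:
        obs_groups.append("forage fish")
    for ss in model.stanza_sets:
        obs_groups.append(ss.leading.name)
    for g in obs_groups:
        series.append(ReferenceSeries(g, "relative_biomass", noisy(run.rel_B[g])))
    for ss in model.stanza_sets:
        for st in ss.stanzas:
            if st.name.endswith("smolts") or st.leading:
                series.append(ReferenceSeries(st.name, "total_mortality",
                                              noisy(run.annual_Z[st.name])))

    truth = {"x": x_true, "ppa": ppa_true, "run": run,
             "f_decline": decline_mag, "predator_growth": growth,
             "solution": solution}
    return TimeSeriesSet(series), forcings_fit, truth


# ---------------------------------------------------------------------------
# climate-like index

def generate_climate_index(seed: int, horizon: int, period: float = 6.0,
                           phase_match: pd.Series | None = None,
                           agree_fraction: float = 1.0,
                           base_year: int = 1979,
                           name: str = "synthetic index") -> ClimateIndex:
    """AR(1)-plus-sinusoid standardized annual anomalies.

    With ``phase_match`` (an anomaly-multiplier series, e.g. a fitted or
    true PPA) the signs are adjusted so exactly
    ``round(agree_fraction · n)`` overlapping years share the sign of the
    matched series.
    """
    if horizon < 2:
        raise GenerationError("need a horizon of at least 2 years")
    rng = np.random.default_rng(seed)
    tt = np.arange(horizon)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    ar = np.empty(horizon)
    ar[0] = rng.normal()
    rho = 0.5
    for k in range(1, horizon):
        ar[k] = rho * ar[k - 1] + math.sqrt(1 - rho ** 2) * rng.normal()
    vals = 1.5 * np.sin(2.0 * math.pi * tt / period + phase) + ar
    years = pd.Index(range(base_year, base_year + horizon))

    if phase_match is not None:
        if not 0.0 <= agree_fraction <= 1.0:
            raise GenerationError(
                f"agreement fraction {agree_fraction} outside [0, 1]")
        ref = np.sign(np.log(phase_match.reindex(years).to_numpy()))
        ref[ref == 0] = 1.0
        n_agree = round(agree_fraction * horizon)
        order = rng.permutation(horizon)
        mag = np.abs(vals)
        mag[mag < 0.1] = 0.1
        vals = np.where(np.isin(np.arange(horizon), order[:n_agree]),
                        mag * ref, -mag * ref)
        # rescale the positive and negative sides so the mean is exactly
        # zero: standardization elsewhere then never flips a sign, keeping
        # the constructed agreement count exact
        pos, neg = vals > 0, vals < 0
        if pos.any() and neg.any():
            target = (vals[pos].sum() - vals[neg].sum()) / 2.0
            vals[pos] *= target / vals[pos].sum()
            vals[neg] *= target / (-vals[neg].sum())
        vals = vals / vals.std()
    else:
        vals = (vals - vals.mean()) / vals.std()
    return ClimateIndex(name, pd.Series(vals, index=years))
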