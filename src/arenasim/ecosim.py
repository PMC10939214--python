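"""Monthly time-dynamic food-web simulation with foraging-arena predation.

Biomass dynamics follow

    dB_i/dt = g_i·Σ_j Q_ji − Σ_j Q_ij + I_i − (M0_i + F_i(t) + e_i)·B_i

with g_i = P/B ÷ Q/B the food conversion efficiency and consumption flows
given by the foraging-arena form

    Q_ij = a_ij·v_ij·B_i·B_j / (2·v_ij + a_ij·B_j),

where v_ij is the rate at which prey i exchanges into the arena where
predator j can reach it and a_ij the predator's effective search rate.
Setting v_ij = x_ij·M2_ij(base) with the vulnerability multiplier x_ij
caps the realized predation mortality at x_ij times its base-year value:
x close to 1 means the predator is already near the carrying capacity its
prey can support, large x approaches mass-action (Lotka-Volterra)
dynamics.  a_ij is then solved so every link reproduces its base-year
flow exactly, which makes the balanced base an equilibrium of the
dynamics.

Producers use a self-limiting production rate r·B/(1 + h·B) (the maximum
relative P/B is configurable, default 2) scaled by the annual
primary-production anomaly forcing.  Split species are advanced by the
discrete monthly age-structured update of :mod:`arenasim.stanzas`, driven
by mortality and feeding rates read off the same flow terms.  Detritus
biomass is held constant (a donor pool).  Fishing enters as forced
instantaneous rates F(t), annual values held constant within a year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from arenasim._kernels import advance_month
from arenasim.ecopath import EcopathSolution
from arenasim.model import CONSUMER, DETRITUS, PRODUCER, EcopathModel
from arenasim.stanzas import StanzaState, init_stanza_state, monthly_stanza_update

__all__ = [
    "VulnerabilityMatrix",
    "ForcingSet",
    "ArenaParams",
    "EcosimRun",
    "ArenaParameterizationError",
    "IntegrationError",
    "derive_arena_parameters",
    "run_simulation",
    "mortality_decomposition",
]

DEFAULT_VULNERABILITY = 2.0
BIOMASS_FLOOR_FRACTION = 1e-10


class ArenaParameterizationError(ValueError):
    """A vulnerability multiplier makes the arena search rate undefined."""


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""


class VulnerabilityMatrix:
    """Vulnerability multipliers x_ij >= 1, defined on links with DC > 0."""

    def __init__(self, x: pd.DataFrame):
        self.x = x.astype(float)
        vals = self.x.values
        if (vals[np.isfinite(vals)] < 1.0).any():
            raise ValueError("vulnerability multipliers must be >= 1")

    @classmethod
    def default(cls, model: EcopathModel,
                value: float = DEFAULT_VULNERABILITY) -> "VulnerabilityMatrix":
        dc = model.diet.dc
        x = pd.DataFrame(np.nan, index=dc.index, columns=dc.columns)
        x[dc > 0] = value
        return cls(x)

    def get(self, prey: str, predator: str) -> float:
        return float(self.x.at[prey, predator])

    def with_value(self, prey: str, predator: str, value: float) -> "VulnerabilityMatrix":
        out = VulnerabilityMatrix(self.x.copy())
        out.x.at[prey, predator] = value
        return out

    def with_predator_column(self, predator: str, value: float) -> "VulnerabilityMatrix":
        out = VulnerabilityMatrix(self.x.copy())
        col = out.x[predator]
        out.x.loc[col.notna(), predator] = value
        return out

    def copy(self) -> "VulnerabilityMatrix":
        return VulnerabilityMatrix(self.x.copy())


@dataclass
class ForcingSet:
    """Time-varying drivers, all on an annual grid.

    ``F``: fishing mortality (yr⁻¹) per group; held constant within each
    year; groups absent keep their base-year F.
    ``producer_anomaly``: multiplier on producer P/B, linearly interpolated
    between annual nodes (mean ≈ 1 for a pure anomaly).
    ``biomass``: imposed relative-biomass trajectories (B/B_base) for
    groups driven from outside the model (e.g. census-forced predators).
    """

    F: pd.DataFrame | None = None
    producer_anomaly: pd.Series | None = None
    biomass: dict[str, pd.Series] = field(default_factory=dict)

    def validate(self, years: pd.Index) -> None:
        if self.producer_anomaly is not None:
            if (self.producer_anomaly <= 0).any():
                raise ValueError("producer anomaly multipliers must be > 0")
            missing = years.difference(self.producer_anomaly.index)
            if len(missing):
                raise ValueError(f"producer anomaly missing years {list(missing)}")
        if self.F is not None:
            missing = years.difference(self.F.index)
            if len(missing):
                raise ValueError(f"fishing forcing missing years {list(missing)}")
            if (self.F.values < 0).any():
                raise ValueError("fishing mortality forcings must be >= 0")
        for g, s in self.biomass.items():
            if (s <= 0).any():
                raise ValueError(f"biomass forcing for {g!r} must be > 0")
            missing = years.difference(s.index)
            if len(missing):
                raise ValueError(f"biomass forcing for {g!r} missing years {list(missing)}")


def save_forcings(forcings: ForcingSet, path) -> None:
    """Write a forcings directory: ``f_mortality.csv`` (year × group),
    ``producer_anomaly.csv`` (year, multiplier), ``biomass_forcing.csv``
    (year × group, relative to base)."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if forcings.F is not None:
        forcings.F.to_csv(path / "f_mortality.csv", index_label="year")
    if forcings.producer_anomaly is not None:
        forcings.producer_anomaly.rename("multiplier").to_csv(
            path / "producer_anomaly.csv", index_label="year")
    if forcings.biomass:
        pd.DataFrame(forcings.biomass).to_csv(path / "biomass_forcing.csv",
                                              index_label="year")


def load_forcings(path) -> ForcingSet:
    from pathlib import Path

    path = Path(path)
    F = anom = None
    biomass = {}
    f_file = path / "f_mortality.csv"
    if f_file.exists():
        F = pd.read_csv(f_file, index_col="year")
    a_file = path / "producer_anomaly.csv"
    if a_file.exists():
        anom = pd.read_csv(a_file, index_col="year")["multiplier"]
    b_file = path / "biomass_forcing.csv"
    if b_file.exists():
        bdf = pd.read_csv(b_file, index_col="year")
        biomass = {c: bdf[c] for c in bdf.columns}
    return ForcingSet(F=F, producer_anomaly=anom, biomass=biomass)


@dataclass
class ArenaParams:
    """Per-link arena constants, aligned arrays over trophic links."""

    prey: np.ndarray     # int indices
    pred: np.ndarray
    a: np.ndarray        # effective search rates
    v: np.ndarray        # vulnerability exchange rates = x * M2(base)
    m2_base: np.ndarray
    x: np.ndarray


def derive_arena_parameters(solution: EcopathSolution,
                            x: VulnerabilityMatrix) -> ArenaParams:
    """Calibrate (a_ij, v_ij) so every link reproduces its base flow.

    v_ij = x_ij·M2_ij(base); a_ij solves
    Q_ij(base) = a·v·B_i·B_j/(2v + a·B_j), which requires x_ij > 1 on
    links with nonzero base flow (at x = 1 the predator cannot increase
    its predation mortality at all, leaving no finite search rate).
    """
    model = solution.model
    names = model.names
    dc = model.diet.dc
    prey_l, pred_l, a_l, v_l, m2_l, x_l = [], [], [], [], [], []
    for j in dc.columns:
        col = dc[j]
        for i in col.index[col > 0]:
            m2 = solution.M2.at[i, j]
            if m2 <= 0:
                continue
            xij = x.get(i, j)
            if not np.isfinite(xij):
                raise ArenaParameterizationError(f"no vulnerability set for link {i!r}->{j!r}")
            if xij <= 1.0:
                raise ArenaParameterizationError(
                    f"link {i!r}->{j!r}: x={xij} <= 1 with nonzero base flow "
                    "leaves the arena search rate undefined")
            bi, bj = solution.B[i], solution.B[j]
            a = 2.0 * xij * m2 / (bj * (xij - 1.0))
            prey_l.append(names.index(i))
            pred_l.append(names.index(j))
            a_l.append(a)
            v_l.append(xij * m2)
            m2_l.append(m2)
            x_l.append(xij)
    return ArenaParams(prey=np.array(prey_l, dtype=int),
                       pred=np.array(pred_l, dtype=int),
                       a=np.array(a_l), v=np.array(v_l),
                       m2_base=np.array(m2_l), x=np.array(x_l))


def arena_flows(params: ArenaParams, B: np.ndarray) -> np.ndarray:
    """Link flows Q_ij (t/km²/yr) at biomass state B."""
    bi = B[params.prey]
    bj = B[params.pred]
    return params.a * params.v * bi * bj / (2.0 * params.v + params.a * bj)


@dataclass
class EcosimRun:
    """Monthly biomass trajectories plus the annual mortality ledger."""

    model: EcopathModel
    years: pd.Index
    monthly_B: pd.DataFrame           # (months × groups)
    annual_B: pd.DataFrame            # annual mean biomass
    annual_F: pd.DataFrame
    annual_M0: pd.DataFrame
    annual_M2: np.ndarray             # (years × prey × predator)
    floor_warnings: int = 0

    @property
    def names(self) -> list[str]:
        return list(self.annual_B.columns)

    @property
    def rel_B(self) -> pd.DataFrame:
        """Annual biomass relative to the first simulated year."""
        return self.annual_B / self.annual_B.iloc[0]

    @property
    def annual_M2_total(self) -> pd.DataFrame:
        return pd.DataFrame(self.annual_M2.sum(axis=2), index=self.years,
                            columns=self.names)

    @property
    def annual_Z(self) -> pd.DataFrame:
        return self.annual_F + self.annual_M2_total + self.annual_M0

    def m2_by_predator(self, group: str) -> pd.DataFrame:
        gi = self.names.index(group)
        df = pd.DataFrame(self.annual_M2[:, gi, :], index=self.years,
                          columns=self.names)
        return df.loc[:, (df != 0).any(axis=0)]

    def export(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for g in self.names:
            for y in self.years:
                rows.append({"year": y, "group": g,
                             "B": self.annual_B.at[y, g],
                             "B_rel": self.rel_B.at[y, g],
                             "F": self.annual_F.at[y, g],
                             "M2_total": self.annual_M2_total.at[y, g],
                             "M0": self.annual_M0.at[y, g],
                             "Z": self.annual_Z.at[y, g]})
        pd.DataFrame(rows).to_csv(path / "trajectories.csv", index=False)
        m2rows = []
        for g in self.names:
            df = self.m2_by_predator(g)
            for pred in df.columns:
                for y in self.years:
                    m2rows.append({"prey": g, "predator": pred, "year": y,
                                   "M2": df.at[y, pred]})
        pd.DataFrame(m2rows, columns=["prey", "predator", "year", "M2"]).to_csv(
            path / "m2_by_predator.csv", index=False)


def run_simulation(model: EcopathModel, solution: EcopathSolution,
                   x: VulnerabilityMatrix | None = None,
                   forcings: ForcingSet | None = None,
                   years: int = 42, steps_per_month: int = 2,
                   max_relative_pb: float = 2.0,
                   integrator: str = "exponential") -> EcosimRun:
    """Integrate the web monthly for ``years`` years from the balanced base.

    Non-stanza living groups follow the foraging-arena ODE on a fixed
    monthly step (``steps_per_month`` sub-steps).  The default
    ``integrator="exponential"`` writes each group's dynamics as
    gains − (per-capita loss rate)·B and advances the linear-loss part
    exactly, B ← G/λ + (B − G/λ)·e^{−λ·dt}; this is unconditionally
    stable and positivity-preserving, which matters because planktonic
    producers turn over 1–2 orders of magnitude faster than the monthly
    clock.  ``integrator="ab2"`` is a two-step Adams–Bashforth explicit
    scheme (Euler start) for webs slow enough to afford it.  Split
    species use the discrete monthly stanza update; detritus is constant;
    biomass-forced groups follow their imposed trajectory.  Without
    forcing the balanced base is an equilibrium (groups with positive
    biomass accumulation grow toward their foraging-arena carrying
    capacity, which is the intended behaviour for recovering predators).
    """
    if integrator not in ("exponential", "ab2"):
        raise ValueError(f"unknown integrator {integrator!r}")
    if x is None:
        x = VulnerabilityMatrix.default(model)
    if forcings is None:
        forcings = ForcingSet()
    year_index = pd.Index(range(model.base_year, model.base_year + years))
    forcings.validate(year_index)

    names = model.names
    n = len(names)
    idx = {g: k for k, g in enumerate(names)}
    B0 = solution.B.reindex(names).to_numpy()
    params = derive_arena_parameters(solution, x)

    roles = np.array([g.role for g in model.groups])
    stanza_groups = {g for ss in model.stanza_sets for g in ss.group_names()}
    is_det = roles == DETRITUS
    is_stanza = np.array([g in stanza_groups for g in names])
    forced = np.array([g in forcings.biomass for g in names])
    is_ode = ~is_det & ~is_stanza & ~forced

    PB = solution.PB.reindex(names).to_numpy()
    QB = solution.QB.reindex(names).to_numpy()
    M0 = solution.M0.reindex(names).to_numpy()
    F_base = solution.F.reindex(names).to_numpy()
    imp = model.diet.import_fraction.reindex(names).fillna(0.0).to_numpy()
    g_eff = np.zeros(n)
    cons = roles == CONSUMER
    g_eff[cons & (QB > 0)] = PB[cons & (QB > 0)] / QB[cons & (QB > 0)]

    is_prod = roles == PRODUCER
    m = max_relative_pb
    h = np.where((B0 > 0) & is_prod, (m - 1.0) / np.where(B0 > 0, B0, 1.0), 0.0)
    r = PB * m  # producer max P/B as B -> 0

    # annual forcing tables expanded to per-month lookups
    F_tab = np.tile(F_base, (years, 1))
    if forcings.F is not None:
        for g in forcings.F.columns:
            F_tab[:, idx[g]] = forcings.F[g].reindex(year_index).to_numpy()
    anom_nodes = np.ones(years)
    if forcings.producer_anomaly is not None:
        anom_nodes = forcings.producer_anomaly.reindex(year_index).to_numpy()
    months = years * 12
    tm = (np.arange(months) + 0.5) / 12.0  # years since start, month midpoints
    anom_m = np.interp(tm, np.arange(years) + 0.5, anom_nodes)
    forced_m = {}
    for g, s in forcings.biomass.items():
        forced_m[idx[g]] = np.interp(tm, np.arange(years) + 0.5,
                                     s.reindex(year_index).to_numpy()) * B0[idx[g]]

    # stanza machinery
    states: list[StanzaState] = []
    stanza_meta = []  # (group indices per stanza, M0_s, F col, QB0_s)
    for ss in model.stanza_sets:
        lead = ss.leading
        st = init_stanza_state(ss, solution.B[lead.name], solution.QB[lead.name])
        states.append(st)
        gidx = np.array([idx[g] for g in ss.group_names()])
        stanza_meta.append(gidx)

    B = B0.copy()
    for st, gidx in zip(states, stanza_meta):
        B[gidx] = st.stanza_biomass()
    for k, traj in forced_m.items():
        B[k] = traj[0]

    # groups relaxing much faster than the monthly clock (plankton-like) are
    # kept at their moving equilibrium instead of being integrated explicitly
    lam_base = np.where(B0 > 0, solution.M2.sum(axis=1).reindex(names).to_numpy()
                        + M0 + F_base, 0.0)
    # classified on the monthly clock, independent of sub-stepping
    is_fast = is_ode & (lam_base / 12.0 >= 1.0) if integrator == "exponential" \
        else np.zeros(n, dtype=bool)
    is_slow = is_ode & ~is_fast

    monthly_B = np.empty((months, n))
    annual_M2 = np.zeros((years, n, n))
    floor_count = 0
    floor_B = BIOMASS_FLOOR_FRACTION * np.where(B0 > 0, B0, 1.0)
    dt = 1.0 / (12.0 * steps_per_month)
    fast_idx = np.nonzero(is_fast)[0]
    imp_qb = imp * QB
    Ql = np.empty(len(params.prey))
    Qin = np.zeros(n)
    Qout = np.zeros(n)
    prev_deriv = np.zeros(n)
    have_prev = False
    exponential = integrator == "exponential"

    for t in range(months):
        yr = t // 12
        F_t = F_tab[yr]
        alpha = anom_m[t]
        for k, traj in forced_m.items():
            B[k] = traj[t]

        nfloor, finite, have_prev = advance_month(
            B, params.prey, params.pred, params.a, params.v, g_eff, imp_qb,
            M0, F_t, alpha, r, h, is_prod, is_ode, is_slow, fast_idx,
            steps_per_month, dt, floor_B, exponential, prev_deriv, have_prev,
            Ql, Qin, Qout)
        floor_count += nfloor
        if not finite:
            bad = [names[k] for k in np.nonzero(~np.isfinite(B))[0]]
            raise IntegrationError(
                f"non-finite biomass for {bad} at month {t} "
                f"(year {model.base_year + yr})")

        # stanza species: discrete monthly update driven by the flow rates
        for st_i, (st, gidx) in enumerate(zip(states, stanza_meta)):
            bs = np.maximum(B[gidx], 1e-30)
            z_s = Qout[gidx] / bs + F_t[gidx] + M0[gidx]
            z_s = np.maximum(z_s, 0.0)
            qb0 = QB[gidx]
            feed = np.ones(len(gidx))
            has_q = qb0 > 0
            feed[has_q] = (Qin[gidx][has_q] / bs[has_q]
                           + imp[gidx][has_q] * qb0[has_q]) / qb0[has_q]
            new = monthly_stanza_update(st, z_s, feed)
            states[st_i] = new
            B[gidx] = np.maximum(new.stanza_biomass(), 0.0)

        monthly_B[t] = B
        with np.errstate(divide="ignore", invalid="ignore"):
            m2_inst = np.where(B[params.prey] > 0, Ql / B[params.prey], 0.0)
        annual_M2[yr, params.prey, params.pred] += m2_inst / 12.0

    month_index = pd.RangeIndex(months, name="month")
    monthly = pd.DataFrame(monthly_B, index=month_index, columns=names)
    annual_B = monthly.groupby(np.arange(months) // 12).mean()
    annual_B.index = year_index
    annual_F = pd.DataFrame(F_tab, index=year_index, columns=names)
    annual_M0 = pd.DataFrame(np.tile(M0, (years, 1)), index=year_index,
                             columns=names)
    return EcosimRun(model=model, years=year_index, monthly_B=monthly,
                     annual_B=annual_B, annual_F=annual_F, annual_M0=annual_M0,
                     annual_M2=annual_M2, floor_warnings=floor_count)


def mortality_decomposition(run: EcosimRun, group: str):
    """Annual mortality components for one group plus end/start trend factors.

    Returns ``(table, trends)``: the table has one row per year with F, M0,
    per-predator M2, total M2 and Z; ``trends`` maps each component to
    value(last year)/value(first year) (NaN where the base value is 0).
    Predator shares of total predation sum to 1 in every year with
    nonzero predation.
    """
    if group not in run.names:
        raise KeyError(f"no group named {group!r} in this run")
    m2 = run.m2_by_predator(group)
    table = pd.DataFrame({
        "F": run.annual_F[group],
        "M0": run.annual_M0[group],
        "M2_total": run.annual_M2_total[group],
        "Z": run.annual_Z[group],
    })
    for pred in m2.columns:
        table[f"M2:{pred}"] = m2[pred]

    def trend(s: pd.Series) -> float:
        first, last = s.iloc[0], s.iloc[-1]
        return float(last / first) if first != 0 else float("nan")

    trends = {c: trend(table[c]) for c in table.columns}
    trends["B_rel"] = trend(run.annual_B[group])
    return table, trends
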