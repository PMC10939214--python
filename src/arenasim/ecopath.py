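"""Static trophic mass-balance solver.

For every living group *i* the production balance

    PB_i·B_i·EE_i = Y_i + Σ_j DC_ij·QB_j·B_j + E_i + BA_i·B_i

must hold, where the sum runs over predators *j*, Y is fisheries catch, E
net emigration, BA biomass accumulation, and EE the ecotrophic efficiency
(the share of production accounted for by modelled fates; 1 − EE is
"other" mortality).  Each group supplies three of {B, P/B, Q/B, EE} and
the solver fills the fourth.  Because every term is a product of at most
one unknown per group, the whole web reduces to a single linear system,
solved simultaneously (no per-group sweeps, no order dependence).

The energy balance per consumer, Q = P + R + UN·Q, defines respiration
R = (1 − UN)·Q − P, which must be non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from arenasim.model import CONSUMER, DETRITUS, PRODUCER, EcopathModel, ModelError

__all__ = [
    "EcopathSolution",
    "SolverError",
    "InfeasibleError",
    "ThermodynamicError",
    "solve_mass_balance",
    "pb_from_demographics",
    "fishing_mortality",
    "respiration",
    "rebalance_scale_biomass",
    "ee_diagnostics",
]

EE_TOL = 1e-9


class SolverError(RuntimeError):
    """The mass-balance linear system is singular or ill-posed."""


class InfeasibleError(RuntimeError):
    """The balance has a solution, but it is not ecologically feasible."""


class ThermodynamicError(ValueError):
    """Respiration would be negative (growth efficiency too high given UN)."""


# ---------------------------------------------------------------------------
# scalar helpers

def pb_from_demographics(Z: float, lam: float) -> float:
    """P/B for a population with total mortality Z and finite annual rate of
    increase λ:  P/B = Z + ln λ.  At equilibrium (λ = 1) P/B is simply Z."""
    if lam <= 0:
        raise ValueError(f"finite rate of increase must be > 0, got {lam}")
    if Z < 0:
        raise ValueError(f"total mortality must be >= 0, got {Z}")
    return Z + math.log(lam)


def fishing_mortality(Y: float, B: float) -> float:
    """Instantaneous fishing mortality F = catch / biomass."""
    if B <= 0:
        raise ValueError(f"biomass must be > 0, got {B}")
    if Y < 0:
        raise ValueError(f"catch must be >= 0, got {Y}")
    return Y / B


def respiration(B: float, PB: float, QB: float, UN: float) -> float:
    """Respiration R = Q − P − UN·Q = ((1 − UN)·QB − PB)·B (t/km²/yr).

    A negative R means the implied growth efficiency exceeds what
    assimilation allows; that is an error, never silently clamped.
    """
    R = ((1.0 - UN) * QB - PB) * B
    if R <= 0:  # a feeding consumer must respire; R = 0 is the violated bound
        raise ThermodynamicError(
            f"negative respiration {R:.6g}: P/B={PB} exceeds assimilated "
            f"consumption (1-UN)*Q/B={(1 - UN) * QB:.6g}")
    return R


# ---------------------------------------------------------------------------
# solution container

@dataclass
class EcopathSolution:
    """Filled parameter set plus the base-year mortality ledger.

    All per-group quantities are pandas Series indexed by group name; M2 is
    a DataFrame with prey as rows and predators as columns, so that
    ``M2.loc[i, j]`` is the predation mortality (yr⁻¹) predator *j* exerts
    on prey *i* and total mortality closes as
    PB = F + M2.sum(axis=1) + M0 + BA + E/B for living groups.
    """

    model: EcopathModel
    B: pd.Series
    PB: pd.Series
    QB: pd.Series
    EE: pd.Series
    F: pd.Series
    M0: pd.Series
    BA: pd.Series
    M2: pd.DataFrame
    R: pd.Series
    balanced: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def P(self) -> pd.Series:
        return self.PB * self.B

    @property
    def Q(self) -> pd.Series:
        return self.QB * self.B

    @property
    def flows(self) -> pd.DataFrame:
        """Base consumption flows Q_ij (t/km²/yr), prey rows × predator cols."""
        return self.M2.mul(self.B, axis=0)

    def export(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "B": self.B, "PB": self.PB, "QB": self.QB, "EE": self.EE,
            "F": self.F, "M0": self.M0, "BA": self.BA,
            "M2_total": self.M2.sum(axis=1), "R": self.R,
        }).to_csv(path / "solution.csv", index_label="group")
        self.M2.to_csv(path / "m2_matrix.csv", index_label="prey")


# ---------------------------------------------------------------------------
# solver

def solve_mass_balance(model: EcopathModel) -> EcopathSolution:
    """Fill the missing parameter of every group and build the ledger.

    Raises :class:`SolverError` when the linear system is singular (e.g.
    mutually unknown biomasses in a predation loop) and
    :class:`InfeasibleError` when a solved biomass or Q/B is negative.
    """
    names = model.names
    model = model.copy()  # GE pre-fill below must not mutate the caller's model
    living = [g for g in model.groups if g.role != DETRITUS]
    det = [g for g in model.groups if g.role == DETRITUS]
    Y = model.total_catch()

    # a missing Q/B (or P/B) backed by a growth efficiency is filled directly:
    # the production balance itself carries no information on the group's own
    # consumption, so GE is the only route (standard practice)
    for g in living:
        if g.QB is None and g.role == CONSUMER:
            if g.GE is None:
                raise SolverError(
                    f"group {g.name!r}: unknown Q/B requires a growth "
                    "efficiency GE to be supplied")
            if g.PB is not None:
                g.QB = g.PB / g.GE
        elif g.PB is None and g.GE is not None and g.QB:
            g.PB = g.GE * g.QB

    unknowns: list[tuple[str, str]] = []  # (group, param)
    fully_specified: list[str] = []
    for g in living:
        unk = g.unknowns()
        if g.role == PRODUCER:
            unk = [u for u in unk if u != "QB"]
        if len(unk) > 1:
            raise SolverError(
                f"group {g.name!r} must have at most one unknown among "
                f"B, PB, QB, EE; has {unk}")
        if not unk:
            # fully specified: EE is treated as the output and recomputed
            fully_specified.append(g.name)
            unk = ["EE"]
        unknowns.append((g.name, unk[0]))
    uindex = {gname: k for k, (gname, _) in enumerate(unknowns)}
    upar = {gname: p for gname, p in unknowns}

    n = len(living)
    A = np.zeros((n, n))
    c = np.zeros(n)
    dc = model.diet.dc

    def val(g, p):
        v = getattr(g, p)
        return v if v is not None else np.nan

    for row, gi in enumerate(living):
        i = gi.name
        # production used: PB*B*EE
        parts = {"PB": val(gi, "PB"), "B": val(gi, "B"), "EE": val(gi, "EE")}
        p = upar[i]
        if p in parts:
            coef = float(np.prod([v for q, v in parts.items() if q != p]))
            A[row, uindex[i]] += coef
        else:
            c[row] += parts["PB"] * parts["B"] * parts["EE"]
        # -BA*B
        if upar.get(i) == "B":
            A[row, uindex[i]] -= gi.BA
        else:
            c[row] -= gi.BA * val(gi, "B")
        # -sum_j DC_ij * QB_j * B_j
        if i in dc.index:
            for j in dc.columns:
                frac = dc.at[i, j]
                if frac <= 0:
                    continue
                gj = model.group(j)
                pj = upar.get(j)
                if pj == "B":
                    A[row, uindex[j]] -= frac * val(gj, "QB")
                elif pj == "QB":
                    A[row, uindex[j]] -= frac * val(gj, "B")
                else:
                    c[row] -= frac * val(gj, "QB") * val(gj, "B")
        # constants
        c[row] -= Y[i] + gi.E

    try:
        sol = np.linalg.solve(A, -c)
    except np.linalg.LinAlgError as exc:
        offenders = [f"{g}.{p}" for g, p in unknowns
                     if p in ("B", "QB")] or [f"{g}.{p}" for g, p in unknowns]
        raise SolverError(
            "singular mass-balance system; check mutually unknown parameters "
            f"in a predation loop among: {', '.join(offenders)}") from exc

    filled = {g.name: {p: getattr(g, p) for p in ("B", "PB", "QB", "EE")}
              for g in model.groups}
    for (gname, p), v in zip(unknowns, sol):
        if p in ("B", "QB") and v <= 0:
            raise InfeasibleError(f"solved {p} for group {gname!r} is {v:.6g} <= 0")
        if p == "PB" and v < 0:
            raise InfeasibleError(f"solved PB for group {gname!r} is {v:.6g} < 0")
        filled[gname][p] = float(v)

    warnings: list[str] = []
    for gname in fully_specified:
        given = model.group(gname).EE
        if given is not None and abs(given - filled[gname]["EE"]) > 1e-6:
            warnings.append(
                f"group {gname!r}: provided EE={given} replaced by computed "
                f"EE={filled[gname]['EE']:.6g}")

    B = pd.Series({g: filled[g]["B"] for g in names}, dtype=float)
    PB = pd.Series({g: filled[g]["PB"] for g in names}, dtype=float)
    QB = pd.Series({g: filled[g]["QB"] for g in names}, dtype=float)
    EE = pd.Series({g: filled[g]["EE"] for g in names}, dtype=float)
    BA = pd.Series({g.name: g.BA for g in model.groups}, dtype=float)

    # mortality ledger
    M2 = pd.DataFrame(0.0, index=names, columns=names)
    for j in dc.columns:
        col = dc[j]
        pred_q = QB[j] * B[j]
        if pred_q > 0:
            M2[j] = col.reindex(names).fillna(0.0) * pred_q / B
    F = (Y / B).fillna(0.0)

    # detritus: EE = consumption of detritus / inflow (egestion + deaths)
    living_names = [g.name for g in living]
    if det:
        un = pd.Series({g.name: g.UN for g in model.groups}, dtype=float)
        inflow = float((un[living_names] * QB[living_names] * B[living_names]).sum())
    for g in living:
        i = g.name
        m2t = M2.loc[i].sum()
        ee = (F[i] + m2t + BA[i] + g.E / B[i]) / PB[i] if PB[i] > 0 else 0.0
        if np.isnan(EE[i]):
            EE[i] = ee
        M0_i = PB[i] * (1.0 - ee)
        if M0_i < -1e-9 * max(PB[i], 1.0):
            warnings.append(f"group {i!r}: EE={ee:.4f} > 1 (negative other mortality)")
    M0 = PB * (1.0 - EE)
    if det:
        inflow += float((M0[living_names] * B[living_names]).clip(lower=0.0).sum())
        for g in det:
            i = g.name
            outflow = float((model.diet.dc.loc[i] * QB * B).sum()) if i in dc.index else 0.0
            share = inflow / len(det)
            EE[i] = outflow / share if share > 0 else 0.0
            PB[i] = 0.0 if np.isnan(PB[i]) else PB[i]
            M0[i] = 0.0

    R = pd.Series(np.nan, index=names)
    for g in model.groups:
        if g.role == CONSUMER:
            r = ((1.0 - g.UN) * QB[g.name] - PB[g.name]) * B[g.name]
            R[g.name] = r
            if r < 0:
                warnings.append(
                    f"group {g.name!r}: negative respiration {r:.4g} "
                    "(growth efficiency too high for UN)")

    ee_liv = EE[living_names]
    balanced = bool(((ee_liv >= -EE_TOL) & (ee_liv <= 1.0 + EE_TOL)).all())
    return EcopathSolution(model=model, B=B, PB=PB, QB=QB, EE=EE, F=F, M0=M0,
                           BA=BA, M2=M2, R=R, balanced=balanced,
                           warnings=warnings)


# ---------------------------------------------------------------------------
# rebalancing helpers

def rebalance_scale_biomass(model: EcopathModel, group: str, factor: float,
                            preserve_F: bool = True) -> EcopathModel:
    """Return a copy with one group's biomass scaled by ``factor``.

    With ``preserve_F`` the landings of that group are scaled by the same
    factor in every fleet, so F = Y/B is unchanged — the standard move when
    an index covered only part of the stock (e.g. a spawner-only survey
    scaled up by an immature/mature ratio).
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    out = model.copy()
    g = out.group(group)
    if g.B is None:
        raise ModelError(f"group {group!r} has no biomass to scale")
    g.B = g.B * factor
    if preserve_F:
        for fl in out.fleets:
            if group in fl.landings:
                fl.landings[group] *= factor
    return out


def ee_diagnostics(solution: EcopathSolution) -> list[dict]:
    """Groups with EE > 1, ordered by exceedance, with per-predator shares.

    Each entry carries the predator M2 components expressed as shares of EE
    (they sum, together with F/PB, BA/PB and E/(PB·B), to the group's EE),
    pointing at which remedy applies: raise B, raise P/B, or trim the
    offending predator's diet fraction.
    """
    out = []
    for g in solution.model.living():
        i = g.name
        ee = solution.EE[i]
        if ee <= 1.0 + EE_TOL:
            continue
        denom = solution.PB[i]
        shares = (solution.M2.loc[i] / denom) if denom > 0 else solution.M2.loc[i] * 0.0
        shares = shares[shares > 0].sort_values(ascending=False)
        out.append({"group": i, "EE": float(ee), "exceedance": float(ee - 1.0),
                    "predator_shares_of_EE": shares.to_dict(),
                    "F_share_of_EE": float(solution.F[i] / denom) if denom > 0 else 0.0})
    out.sort(key=lambda d: d["exceedance"], reverse=True)
    return out
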