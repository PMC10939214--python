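"""Multi-stanza age structure: survivorship parameterization and the
monthly discrete-time update used by the dynamic model for split species.

A split species is tracked as numbers-at-age N(a) on a monthly age grid.
Body weight follows a von Bertalanffy cube, w(a) = (1 − e^{−K·a/12})³ in
units of the asymptotic weight, and per-capita consumption scales
metabolically as w^{2/3}.  Equilibrium survivorship
l(a) = Π_m exp(−Z_s(m)/12) distributes biomass and consumption across
stanzas, so only the leading stanza's B and Q/B need to be supplied; the
rest are model-derived.

Aging is a one-month shift with survival exp(−Z_s/12); growth increments
are the baseline von Bertalanffy steps scaled by the stanza's relative
feeding rate; recruitment into age 0 is proportional (optionally with a
power) to mature-mass-weighted abundance, eggs = Σ N(a)·max(0, w(a) − w_mat).
Semelparous species are flagged ``terminal``: ages beyond the final stanza
die (spawning once); otherwise the oldest ages pool in a plus group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from arenasim.model import StanzaSet

__all__ = [
    "PLUS_GROUP_MONTHS",
    "DegenerateStanzaError",
    "stanza_age_grid",
    "distribute_stanza_parameters",
    "StanzaState",
    "init_stanza_state",
    "monthly_stanza_update",
]

#: oldest modelled age (months) for iteroparous species; longevities of the
#: species this grid is used for are far below 400 months
PLUS_GROUP_MONTHS = 400


class DegenerateStanzaError(ValueError):
    """Survivorship vanished over a stanza's age span (Z too large)."""


def stanza_age_grid(ss: StanzaSet, plus_months: int = PLUS_GROUP_MONTHS):
    """Monthly ages with survivorship l, weight w, consumption weight q and
    the stanza index each age belongs to."""
    last = ss.stanzas[-1]
    if ss.terminal and last.end_month is not None:
        n_ages = last.end_month
    else:
        n_ages = max(plus_months, last.start_month + 1)
    ages = np.arange(n_ages)

    stanza_of = np.zeros(n_ages, dtype=int)
    for k, st in enumerate(ss.stanzas):
        hi = n_ages if st.end_month is None else min(st.end_month, n_ages)
        stanza_of[st.start_month:hi] = k
    stanza_of[ss.stanzas[-1].start_month:] = len(ss.stanzas) - 1

    z_monthly = np.array([st.Z for st in ss.stanzas])[stanza_of] / 12.0
    l = np.empty(n_ages)
    l[0] = 1.0
    np.cumprod(np.exp(-z_monthly[:-1]), out=l[1:])
    if not ss.terminal:
        # plus group pools all survivors past the oldest age: geometric sum
        s_last = math.exp(-z_monthly[-1])
        l[-1] = l[-1] / (1.0 - s_last)

    w = (1.0 - np.exp(-ss.vbK * ages / 12.0)) ** 3
    q = w ** (2.0 / 3.0)
    return ages, l, w, q, stanza_of


def distribute_stanza_parameters(ss: StanzaSet, leading_B: float,
                                 leading_QB: float,
                                 plus_months: int = PLUS_GROUP_MONTHS) -> dict[str, tuple[float, float]]:
    """Per-stanza (B, QB) implied by equilibrium survivorship.

    B_s ∝ Σ_{a∈s} l(a)·w(a) and Q_s ∝ Σ_{a∈s} l(a)·w(a)^{2/3}, with both
    scales fixed so the leading stanza reproduces ``leading_B`` and
    ``leading_QB``.  Non-leading values are outputs, mirroring the
    convention that only leading-stanza parameters are observed.
    """
    if leading_B <= 0 or leading_QB < 0:
        raise ValueError("leading_B must be > 0 and leading_QB >= 0")
    _, l, w, q, stanza_of = stanza_age_grid(ss, plus_months)
    nst = len(ss.stanzas)
    sb = np.array([np.sum(l[stanza_of == k] * w[stanza_of == k]) for k in range(nst)])
    sq = np.array([np.sum(l[stanza_of == k] * q[stanza_of == k]) for k in range(nst)])
    lead = next(k for k, st in enumerate(ss.stanzas) if st.leading)
    if sb[lead] <= 0 or not np.isfinite(sb).all():
        raise DegenerateStanzaError(
            f"stanza set {ss.species!r}: survivorship-weighted biomass of the "
            "leading stanza is zero; Z too large for the age span")
    bscale = leading_B / sb[lead]
    qc = leading_QB * leading_B / (bscale * sq[lead])  # flow per unit Σ l·q
    out = {}
    for k, st in enumerate(ss.stanzas):
        b_k = bscale * sb[k]
        qb_k = (qc * bscale * sq[k] / b_k) if b_k > 0 else 0.0
        out[st.name] = (b_k, qb_k)
    return out


@dataclass
class StanzaState:
    """Numbers- and weight-at-age for one split species.

    ``n_scale`` converts Σ N·w to t/km²; consumption flows are
    ``q_coef · Σ N·w^{2/3}`` at baseline feeding.
    """

    ss: StanzaSet
    N: np.ndarray
    w: np.ndarray
    wbase: np.ndarray
    dwbase: np.ndarray
    stanza_of: np.ndarray
    wmat: float
    eggs_base: float
    recruits_base: float
    q_coef: float
    warnings: list[str] = field(default_factory=list)

    def eggs(self) -> float:
        return float(np.sum(self.N * np.maximum(0.0, self.w - self.wmat)))

    def stanza_biomass(self) -> np.ndarray:
        """Biomass per stanza (t/km²)."""
        return np.bincount(self.stanza_of, weights=self.N * self.w,
                           minlength=len(self.ss.stanzas))

    def stanza_consumption(self) -> np.ndarray:
        """Baseline-feeding consumption per stanza (t/km²/yr)."""
        qw = self.q_coef * self.N * np.maximum(self.w, 0.0) ** (2.0 / 3.0)
        return np.bincount(self.stanza_of, weights=qw,
                           minlength=len(self.ss.stanzas))

    def copy(self) -> "StanzaState":
        return StanzaState(self.ss, self.N.copy(), self.w.copy(), self.wbase,
                           self.dwbase, self.stanza_of, self.wmat,
                           self.eggs_base, self.recruits_base, self.q_coef,
                           list(self.warnings))


def init_stanza_state(ss: StanzaSet, leading_B: float, leading_QB: float,
                      plus_months: int = PLUS_GROUP_MONTHS) -> StanzaState:
    """Equilibrium state whose stanza biomasses and consumptions equal the
    :func:`distribute_stanza_parameters` values exactly."""
    _, l, w, q, stanza_of = stanza_age_grid(ss, plus_months)
    lead = next(k for k, st in enumerate(ss.stanzas) if st.leading)
    sb_lead = np.sum(l[stanza_of == lead] * w[stanza_of == lead])
    sq_lead = np.sum(l[stanza_of == lead] * q[stanza_of == lead])
    if sb_lead <= 0:
        raise DegenerateStanzaError(
            f"stanza set {ss.species!r}: zero survivorship-weighted biomass")
    n0 = leading_B / sb_lead
    N = n0 * l
    q_coef = leading_QB * leading_B / (n0 * sq_lead)
    wmat = ss.wmat_over_winf
    eggs_base = float(np.sum(N * np.maximum(0.0, w - wmat)))
    if eggs_base <= 0:
        raise DegenerateStanzaError(
            f"stanza set {ss.species!r}: no mature biomass at equilibrium "
            f"(wmat_over_winf={wmat} unreachable within the modelled ages)")
    dw = np.diff(w, append=w[-1])  # baseline monthly growth increment
    return StanzaState(ss=ss, N=N, w=w.copy(), wbase=w, dwbase=dw,
                       stanza_of=stanza_of, wmat=wmat, eggs_base=eggs_base,
                       recruits_base=N[0], q_coef=q_coef)


def monthly_stanza_update(state: StanzaState, Z_per_stanza: np.ndarray,
                          feeding: np.ndarray | float = 1.0,
                          recruit: bool = True) -> StanzaState:
    """Advance one month: survive, age, grow, recruit.

    ``Z_per_stanza`` are realized total mortality rates (yr⁻¹) from the
    dynamic model (predation + fishing + other); ``feeding`` is the
    relative feeding rate per stanza (1 = base consumption), scaling the
    von Bertalanffy growth increments.
    """
    Z = np.asarray(Z_per_stanza, dtype=float)
    f = np.broadcast_to(np.asarray(feeding, dtype=float), Z.shape)
    if not np.isfinite(Z).all() or (Z < 0).any():
        raise ValueError(f"mortality rates must be finite and >= 0, got {Z}")
    if not np.isfinite(f).all() or (f < 0).any():
        raise ValueError(f"feeding rates must be finite and >= 0, got {f}")

    N, w = state.N, state.w
    surv = N * np.exp(-Z[state.stanza_of] / 12.0)
    grown = w + f[state.stanza_of] * state.dwbase

    nN = np.empty_like(N)
    nw = state.wbase.copy()
    nN[1:] = surv[:-1]
    nw[1:] = grown[:-1]
    if not state.ss.terminal:
        # plus group: survivors of the oldest age stay, weights number-averaged
        tot = surv[-2] + surv[-1]
        nN[-1] = tot
        if tot > 0:
            nw[-1] = (surv[-2] * grown[-2] + surv[-1] * grown[-1]) / tot
    # terminal (semelparous): the oldest age class dies after spawning

    if recruit and state.eggs_base > 0:
        rel = state.eggs() / state.eggs_base
        nN[0] = state.recruits_base * rel ** state.ss.rec_power
    elif recruit:
        nN[0] = 0.0
    else:
        nN[0] = 0.0
    nw[0] = state.wbase[0]

    return StanzaState(ss=state.ss, N=nN, w=nw, wbase=state.wbase,
                       dwbase=state.dwbase, stanza_of=state.stanza_of,
                       wmat=state.wmat, eggs_base=state.eggs_base,
                       recruits_base=state.recruits_base, q_coef=state.q_coef,
                       warnings=state.warnings)
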