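"""Core kinetics of the compartmental AMPA-receptor trafficking model.

The model tracks anchored-receptor occupancy of four saturable membrane
compartments around a postsynaptic spine -- the postsynaptic density (PSD),
two small perisynaptic staging pools (PeriIN, PeriOut) and the unanchored
surface pool (UA) -- exchanging receptors with a non-saturable internal
endocytic reservoir (Endo) whose free-receptor concentration is normalized
to 1.  Two auxiliary variables, the normalized kinase and phosphatase
activities, gate the PeriIN->PSD and PSD->PeriOut fluxes; both relax to a
resting value of 1.

All rates are per minute; occupancies are dimensionless in units of the PSD
capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "AGONISTS",
    "INDUCTIONS",
    "PHASES",
    "Parameters",
    "State",
    "EffectiveRates",
    "default_parameters",
    "saturating_transfer",
    "effective_rates",
    "rhs",
]

AGONISTS = ("none", "gs", "gq", "gs+gq")
INDUCTIONS = ("none", "ltp", "ltd")
PHASES = ("modulation", "induction", "post")


@dataclass(frozen=True)
class Parameters:
    """Full parameter set of the trafficking model.

    Attributes
    ----------
    t_psd, t_ua, t_peri_in, t_peri_out:
        Compartment capacities (total anchoring slots), in units of the PSD
        capacity.  The PSD capacity is the normalization unit (default 1);
        the three small pools default to 0.2.
    k_periin_psd, k_psd_periout:
        Base rates of the kinase-gated PeriIN->PSD flux and the
        phosphatase-gated PSD->PeriOut flux (per min).  These are the only
        transitions touching the PSD.
    k_peri_endo, k_endo_peri:
        Baseline exchange rates between either perisynaptic pool and the
        endocytic reservoir, both directions (per min, default 1/50).
    k_ua_endo, k_endo_ua:
        Baseline UA<->Endo exchange rates (per min, default 1/20).
    km2_kin, km2_pp:
        Half-saturation occupancies of the donor-side Michaelis-Menten
        factor in the two PSD-bound fluxes (default 0.1, half a peri pool).
    k_kin, k_pp:
        First-order relaxation rates of the kinase and phosphatase
        variables (per min; defaults 1/4 and 1/10, i.e. time constants of
        4 and 10 minutes).
    f_ltp_kin, f_ltd_pp:
        Multiplicative step applied to the kinase (LTP) or phosphatase
        (LTD) variable at induction onset (defaults 1000 and 400).
    gs_factors:
        Multiplicative factors under a Gs-coupled agonist on the exocytic
        rates (Endo->PeriIN, Endo->PeriOut, Endo->UA) = (100, 10, 4.5).
    gq_factors:
        Multiplicative factors under a Gq-coupled agonist on the endocytic
        rates (PeriIN->Endo, PeriOut->Endo, UA->Endo) = (10, 100, 2).
    t_mod, t_ind, t_total:
        Phase durations: agonist modulation, induction pairing, and the
        full simulated horizon (minutes; defaults 9, 2, 50).
    tau_smooth:
        Time constant of the causal exponential kernel smoothing the weight
        readout (min).  Zero disables smoothing.
    w_ua:
        Fraction of unanchored surface receptors contributing to the
        synaptic weight, in [0, 1].
    """

    t_psd: float = 1.0
    t_ua: float = 0.2
    t_peri_in: float = 0.2
    t_peri_out: float = 0.2
    k_periin_psd: float = 0.001
    k_psd_periout: float = 0.004
    k_peri_endo: float = 1.0 / 50.0
    k_endo_peri: float = 1.0 / 50.0
    k_ua_endo: float = 1.0 / 20.0
    k_endo_ua: float = 1.0 / 20.0
    km2_kin: float = 0.1
    km2_pp: float = 0.1
    k_kin: float = 0.25
    k_pp: float = 0.1
    f_ltp_kin: float = 1000.0
    f_ltd_pp: float = 400.0
    gs_factors: tuple = (100.0, 10.0, 4.5)
    gq_factors: tuple = (10.0, 100.0, 2.0)
    t_mod: float = 9.0
    t_ind: float = 2.0
    t_total: float = 50.0
    tau_smooth: float = 1.0
    w_ua: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gs_factors", tuple(float(x) for x in self.gs_factors))
        object.__setattr__(self, "gq_factors", tuple(float(x) for x in self.gq_factors))
        for name in ("t_psd", "t_ua", "t_peri_in", "t_peri_out"):
            if not getattr(self, name) > 0:
                raise ValueError(f"capacity {name} must be > 0, got {getattr(self, name)}")
        for name in (
            "k_periin_psd", "k_psd_periout", "k_peri_endo", "k_endo_peri",
            "k_ua_endo", "k_endo_ua", "k_kin", "k_pp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0, got {getattr(self, name)}")
        for name in ("km2_kin", "km2_pp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"half-saturation {name} must be > 0")
        if self.f_ltp_kin < 1 or self.f_ltd_pp < 1:
            raise ValueError("induction step factors must be >= 1")
        for fac in (*self.gs_factors, *self.gq_factors):
            if fac < 0:
                raise ValueError("agonist factors must be >= 0")
        if len(self.gs_factors) != 3 or len(self.gq_factors) != 3:
            raise ValueError("agonist factor sets must have exactly 3 entries")
        if not (self.t_mod > 0 and self.t_ind > 0 and self.t_total > 0):
            raise ValueError("phase durations must be > 0")
        if self.t_mod + self.t_ind > self.t_total:
            raise ValueError("t_mod + t_ind must not exceed t_total")
        if self.tau_smooth < 0:
            raise ValueError("tau_smooth must be >= 0")
        if not 0.0 <= self.w_ua <= 1.0:
            raise ValueError("w_ua must lie in [0, 1]")

    # The kinase/phosphatase source terms are pinned to the relaxation rates
    # so that the resting solution of each first-order equation is exactly 1
    # (the "normalized resting value" convention).
    @property
    def s_kin(self) -> float:
        return self.k_kin

    @property
    def s_pp(self) -> float:
        return self.k_pp

    def capacity(self, compartment: str) -> float:
        """Capacity of ``compartment`` in {'psd', 'peri_in', 'peri_out', 'ua'}."""
        return {
            "psd": self.t_psd,
            "peri_in": self.t_peri_in,
            "peri_out": self.t_peri_out,
            "ua": self.t_ua,
        }[compartment]


def default_parameters() -> Parameters:
    """Return the published parameter set of the model."""
    return Parameters()


@dataclass(frozen=True)
class State:
    """Instantaneous model state.

    ``a_*`` are anchored-receptor occupancies (0 <= a_c <= T_c; free slots
    F_c = T_c - a_c are implicit).  ``kin`` and ``pp`` are the normalized
    kinase and phosphatase activities (resting value 1).
    """

    a_psd: float
    a_peri_in: float
    a_peri_out: float
    a_ua: float
    kin: float = 1.0
    pp: float = 1.0

    _FIELDS = ("a_psd", "a_peri_in", "a_peri_out", "a_ua", "kin", "pp")

    def as_array(self):
        import numpy as np

        return np.array([self.a_psd, self.a_peri_in, self.a_peri_out,
                         self.a_ua, self.kin, self.pp], dtype=float)

    @classmethod
    def from_array(cls, y) -> "State":
        return cls(*(float(v) for v in y))

    def validate(self, p: Parameters, tol: float = 1e-8) -> None:
        """Raise if occupancies escape [0, T_c] or activities go negative."""
        for name, cap in (
            ("a_psd", p.t_psd), ("a_peri_in", p.t_peri_in),
            ("a_peri_out", p.t_peri_out), ("a_ua", p.t_ua),
        ):
            v = getattr(self, name)
            if v < -tol or v > cap + tol:
                raise ValueError(f"{name}={v} outside [0, {cap}]")
        if self.kin < -tol or self.pp < -tol:
            raise ValueError("kinase/phosphatase activity must be >= 0")


@dataclass(frozen=True)
class EffectiveRates:
    """Phase-effective first-order rates of every transition present.

    Transitions not listed (PSD<->Endo, PSD<->UA, Peri<->Peri, ...) are
    structurally absent from the model.
    """

    periin_psd: float
    psd_periout: float
    periin_endo: float
    endo_periin: float
    periout_endo: float
    endo_periout: float
    ua_endo: float
    endo_ua: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"effective rate {f.name} must be >= 0")


def saturating_transfer(a_donor: float, km2: float) -> float:
    """Michaelis-Menten flux-capacity factor ``a * km2 / (km2 + a)``.

    Monotone increasing in the donor occupancy ``a_donor`` and bounded
    above by ``km2``: a crowded donor pool cannot push receptors out faster
    than the saturation ceiling allows.
    """
    if a_donor < 0:
        raise ValueError("donor occupancy must be >= 0")
    if not km2 > 0:
        raise ValueError("half-saturation constant must be > 0")
    return a_donor * km2 / (km2 + a_donor)


def effective_rates(p: Parameters, agonist: str, phase: str) -> EffectiveRates:
    """Transition rates in force for ``agonist`` during ``phase``.

    Agonist factors apply during the modulation and induction phases only
    ("gs+gq" applies both sets); the post phase always runs at baseline.
    The two PSD-bound rates are never modulated by agonists.
    """
    if agonist not in AGONISTS:
        raise ValueError(f"unknown agonist {agonist!r}; expected one of {AGONISTS}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")

    endo_pi = p.k_endo_peri
    endo_po = p.k_endo_peri
    endo_ua = p.k_endo_ua
    pi_endo = p.k_peri_endo
    po_endo = p.k_peri_endo
    ua_endo = p.k_ua_endo

    if phase in ("modulation", "induction"):
        if agonist in ("gs", "gs+gq"):
            f_pi, f_po, f_ua = p.gs_factors
            endo_pi *= f_pi
            endo_po *= f_po
            endo_ua *= f_ua
        if agonist in ("gq", "gs+gq"):
            f_pi, f_po, f_ua = p.gq_factors
            pi_endo *= f_pi
            po_endo *= f_po
            ua_endo *= f_ua

    return EffectiveRates(
        periin_psd=p.k_periin_psd,
        psd_periout=p.k_psd_periout,
        periin_endo=pi_endo,
        endo_periin=endo_pi,
        periout_endo=po_endo,
        endo_periout=endo_po,
        ua_endo=ua_endo,
        endo_ua=endo_ua,
    )


def fluxes(s: State, p: Parameters, r: EffectiveRates) -> tuple:
    """The two PSD-bound fluxes (J_in, J_out) at state ``s`` (per min).

    J_in moves receptors PeriIN->PSD, gated by the kinase activity and
    saturated in the donor (PeriIN) occupancy; J_out moves PSD->PeriOut,
    gated by the phosphatase and saturated in the PSD occupancy.  Each
    flux also requires free slots on the acceptor side.
    """
    f_psd = p.t_psd - s.a_psd
    f_peri_out = p.t_peri_out - s.a_peri_out
    j_in = r.periin_psd * s.kin * saturating_transfer(max(s.a_peri_in, 0.0), p.km2_kin) * f_psd
    j_out = r.psd_periout * s.pp * saturating_transfer(max(s.a_psd, 0.0), p.km2_pp) * f_peri_out
    return j_in, j_out


def rhs(s: State, p: Parameters, r: EffectiveRates) -> State:
    """Time derivative of the model state (pure function, per minute).

    Occupancy balance: each membrane pool exchanges with the endocytic
    reservoir (free concentration identically 1) at first-order rates, and
    the PSD exchanges with the peri pools through the gated saturable
    fluxes.  The kinase/phosphatase equations are autonomous first-order
    relaxations to 1.
    """
    j_in, j_out = fluxes(s, p, r)
    f_peri_in = p.t_peri_in - s.a_peri_in
    f_peri_out = p.t_peri_out - s.a_peri_out
    f_ua = p.t_ua - s.a_ua
    return State(
        a_psd=j_in - j_out,
        a_peri_in=-r.periin_endo * s.a_peri_in + r.endo_periin * f_peri_in - j_in,
        a_peri_out=-r.periout_endo * s.a_peri_out + r.endo_periout * f_peri_out + j_out,
        a_ua=-r.ua_endo * s.a_ua + r.endo_ua * f_ua,
        kin=p.s_kin - p.k_kin * s.kin,
        pp=p.s_pp - p.k_pp * s.pp,
    )


def make_rhs(p: Parameters, r: EffectiveRates):
    """Build a fast ``f(t, y)`` right-hand side for the ODE integrator.

    ``y = [a_psd, a_peri_in, a_peri_out, a_ua, kin, pp]``.  Scalar float
    arithmetic on unpacked components; returns a tuple.  Mirrors
    :func:`rhs` exactly (shared algebra, no clipping).
    """
    t_psd, t_pi, t_po, t_ua = p.t_psd, p.t_peri_in, p.t_peri_out, p.t_ua
    k_ip, k_po = p.k_periin_psd, p.k_psd_periout
    km_k, km_p = p.km2_kin, p.km2_pp
    k_kin, k_pp, s_kin, s_pp = p.k_kin, p.k_pp, p.s_kin, p.s_pp
    r_pi_e, r_e_pi = r.periin_endo, r.endo_periin
    r_po_e, r_e_po = r.periout_endo, r.endo_periout
    r_u_e, r_e_u = r.ua_endo, r.endo_ua

    def f(t, y):
        a_psd, a_pi, a_po, a_ua, kin, pp = y
        f_psd = t_psd - a_psd
        f_pi = t_pi - a_pi
        f_po = t_po - a_po
        f_ua = t_ua - a_ua
        j_in = k_ip * kin * (a_pi * km_k / (km_k + a_pi)) * f_psd
        j_out = k_po * pp * (a_psd * km_p / (km_p + a_psd)) * f_po
        return (
            j_in - j_out,
            -r_pi_e * a_pi + r_e_pi * f_pi - j_in,
            -r_po_e * a_po + r_e_po * f_po + j_out,
            -r_u_e * a_ua + r_e_u * f_ua,
            s_kin - k_kin * kin,
            s_pp - k_pp * pp,
        )

    return f
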