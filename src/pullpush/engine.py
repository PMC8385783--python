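"""Phase-structured integration of the trafficking ODE system.

A protocol is a three-phase schedule on the experiment's clock: agonist
modulation on [0, t_mod], the 2-minute induction pairing on
[t_mod, t_mod + t_ind] (entered through a multiplicative step on the
kinase or phosphatase variable), and an unmodulated post phase out to
t_total.  Each phase is integrated with its own effective rates and the
final state of one phase seeds the next; the system is stiff at induction
onset (the kinase variable jumps by three orders of magnitude), so an
adaptive stiff-capable solver is used and integration restarts at every
phase boundary rather than interpolating across the jump.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    AGONISTS,
    INDUCTIONS,
    EffectiveRates,
    Parameters,
    State,
    effective_rates,
    make_rhs,
)

__all__ = [
    "Protocol",
    "Phase",
    "Trajectory",
    "EquilibriumError",
    "IntegrationError",
    "resting_equilibrium",
    "build_schedule",
    "apply_induction_step",
    "integrate_phase",
    "simulate_protocol",
]

#: State-vector component order used throughout.
STATE_COLUMNS = ("a_psd", "a_peri_in", "a_peri_out", "a_ua", "kin", "pp")

# Tight enough that the kinase variable (magnitude up to 1e3 after an LTP
# step) is still resolved to ~1e-7 absolute; the system is tiny, so the
# extra steps are free.
DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12
DEFAULT_GRID = 0.1  # minutes, internal dense output spacing


class EquilibriumError(RuntimeError):
    """Resting-state solve failed to reach the required residual."""


class IntegrationError(RuntimeError):
    """The ODE solver failed inside a phase."""


@dataclass(frozen=True)
class Protocol:
    """One experimental scenario: agonist condition x induction type.

    Durations default to the values carried by :class:`Parameters` when
    left as ``None``.
    """

    agonist: str = "none"
    induction: str = "none"
    t_mod: Optional[float] = None
    t_ind: Optional[float] = None
    t_total: Optional[float] = None

    def __post_init__(self) -> None:
        if self.agonist not in AGONISTS:
            raise ValueError(f"unknown agonist {self.agonist!r}; expected one of {AGONISTS}")
        if self.induction not in INDUCTIONS:
            raise ValueError(
                f"unknown induction {self.induction!r}; expected one of {INDUCTIONS}"
            )
        for name in ("t_mod", "t_ind", "t_total"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0")

    def resolve_times(self, p: Parameters) -> tuple:
        """(t_mod, t_ind, t_total) with parameter defaults filled in."""
        t_mod = self.t_mod if self.t_mod is not None else p.t_mod
        t_ind = self.t_ind if self.t_ind is not None else p.t_ind
        t_total = self.t_total if self.t_total is not None else p.t_total
        if t_mod + t_ind > t_total:
            raise ValueError("t_mod + t_ind must not exceed t_total")
        return t_mod, t_ind, t_total

    @property
    def scenario_id(self) -> str:
        return f"{self.agonist}:{self.induction}"


@dataclass(frozen=True)
class Phase:
    """One integration interval with its effective rates."""

    label: str
    t_start: float
    t_end: float
    rates: EffectiveRates

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("phase must have t_start < t_end")


@dataclass
class PhaseSegment:
    """Solution of a single phase, endpoints included."""

    label: str
    times: np.ndarray
    states: np.ndarray  # shape (n, 6), columns per STATE_COLUMNS

    def final_state(self) -> State:
        return State.from_array(self.states[-1])


@dataclass
class Trajectory:
    """Concatenated multi-phase solution on a strictly increasing grid.

    At the boundary between two phases a single sample is kept, carrying
    the state of the *later* phase; the induction-onset jump in kin/pp is
    therefore visible at t = t_mod.  The per-phase ``segments`` (with both
    endpoints, i.e. left limits) remain available.
    """

    segments: list

    def __post_init__(self) -> None:
        times, states, labels = [], [], []
        for i, seg in enumerate(self.segments):
            t, y = seg.times, seg.states
            if i + 1 < len(self.segments):
                t, y = t[:-1], y[:-1]  # drop pre-jump boundary sample
            times.append(t)
            states.append(y)
            labels.extend([seg.label] * len(t))
        self.times = np.concatenate(times)
        self.states = np.vstack(states)
        self.phase_labels = np.array(labels)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory grid must be strictly increasing")
        self.boundaries = [seg.times[-1] for seg in self.segments[:-1]]

    def __len__(self) -> int:
        return len(self.times)

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_COLUMNS.index(name)]

    @property
    def a_psd(self):
        return self.column("a_psd")

    @property
    def a_peri_in(self):
        return self.column("a_peri_in")

    @property
    def a_peri_out(self):
        return self.column("a_peri_out")

    @property
    def a_ua(self):
        return self.column("a_ua")

    @property
    def kin(self):
        return self.column("kin")

    @property
    def pp(self):
        return self.column("pp")

    def state_at(self, t: float) -> State:
        """State at the grid point nearest to ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return State.from_array(self.states[i])

    def initial_state(self) -> State:
        return State.from_array(self.states[0])

    def final_state(self) -> State:
        return State.from_array(self.states[-1])


def _occupancy_residual(x: np.ndarray, p: Parameters, r: EffectiveRates) -> np.ndarray:
    f = make_rhs(p, r)
    y = (x[0], x[1], x[2], x[3], 1.0, 1.0)
    return np.array(f(0.0, y)[:4])


def resting_equilibrium(
    p: Parameters,
    residual_tol: float = 1e-9,
    max_iter: int = 60,
) -> State:
    """Resting fixed point of the unmodulated dynamics with kin = pp = 1.

    Solves the 4-dimensional occupancy balance by damped Newton iteration
    (finite-difference Jacobian, step halving) initialized at half
    capacity; falls back to a long integration of the baseline dynamics if
    Newton stalls.  Raises :class:`EquilibriumError` with the residual
    norm if neither route reaches ``residual_tol``.
    """
    r = effective_rates(p, "none", "post")
    caps = np.array([p.t_psd, p.t_peri_in, p.t_peri_out, p.t_ua])
    x = caps / 2.0

    fx = _occupancy_residual(x, p, r)
    for _ in range(max_iter):
        if np.max(np.abs(fx)) < residual_tol:
            break
        jac = np.empty((4, 4))
        for j in range(4):
            h = 1e-7 * max(abs(x[j]), 1e-3)
            xp = x.copy()
            xp[j] += h
            jac[:, j] = (_occupancy_residual(xp, p, r) - fx) / h
        try:
            step = np.linalg.solve(jac, -fx)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        norm0 = np.linalg.norm(fx)
        while lam > 1e-6:
            x_new = np.clip(x + lam * step, 0.0, caps)
            f_new = _occupancy_residual(x_new, p, r)
            if np.linalg.norm(f_new) < norm0:
                x, fx = x_new, f_new
                break
            lam /= 2.0
        else:
            break

    if np.max(np.abs(fx)) >= residual_tol:
        # Fallback: relax the full system from empty membrane pools.  The
        # slowest mode under default rates has a time constant of order
        # 1e4 min, hence the long horizon.
        sol = solve_ivp(
            make_rhs(p, r), (0.0, 1e6),
            [0.0, 0.0, 0.0, 0.0, 1.0, 1.0],
            method="LSODA", rtol=1e-12, atol=1e-12,
        )
        x = sol.y[:4, -1]
        fx = _occupancy_residual(x, p, r)
        if np.max(np.abs(fx)) >= residual_tol:
            raise EquilibriumError(
                f"equilibrium solve failed; residual max|f| = {np.max(np.abs(fx)):.3e}"
            )

    return State(a_psd=float(x[0]), a_peri_in=float(x[1]),
                 a_peri_out=float(x[2]), a_ua=float(x[3]), kin=1.0, pp=1.0)


def build_schedule(proto: Protocol, p: Parameters) -> list:
    """Three tiling phases for ``proto``: modulation, induction, post.

    The agonist's rate factors act during modulation and induction; the
    post phase runs at baseline rates regardless of agonist.
    """
    t_mod, t_ind, t_total = proto.resolve_times(p)
    return [
        Phase("modulation", 0.0, t_mod, effective_rates(p, proto.agonist, "modulation")),
        Phase("induction", t_mod, t_mod + t_ind,
              effective_rates(p, proto.agonist, "induction")),
        Phase("post", t_mod + t_ind, t_total, effective_rates(p, proto.agonist, "post")),
    ]


def apply_induction_step(s: State, induction: str, p: Parameters) -> State:
    """Instantaneous induction-onset step on the enzyme variables.

    LTP multiplies the kinase activity by ``f_ltp_kin``; LTD multiplies
    the phosphatase activity by ``f_ltd_pp``; occupancies are never
    touched.  ``none`` is the identity.
    """
    if induction == "none":
        return s
    if induction == "ltp":
        return replace(s, kin=s.kin * p.f_ltp_kin)
    if induction == "ltd":
        return replace(s, pp=s.pp * p.f_ltd_pp)
    raise ValueError(f"unknown induction {induction!r}; expected one of {INDUCTIONS}")


def _phase_grid(t_start: float, t_end: float, dt: float) -> np.ndarray:
    n = max(int(round((t_end - t_start) / dt)), 1)
    grid = t_start + dt * np.arange(n + 1)
    grid[-1] = t_end
    if grid[-1] <= grid[-2]:
        grid = np.append(grid[:-2], t_end)
    return grid


def integrate_phase(
    s0: State,
    phase: Phase,
    p: Parameters,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    dt_grid: float = DEFAULT_GRID,
    method: str = "LSODA",
) -> PhaseSegment:
    """Integrate one phase from ``s0`` on a dense output grid.

    Occupancy columns of the returned segment are clipped to
    ``[-atol, T_c + atol]`` to strip sub-tolerance solver excursions.
    """
    grid = _phase_grid(phase.t_start, phase.t_end, dt_grid)
    f = make_rhs(p, phase.rates)
    sol = solve_ivp(
        f, (phase.t_start, phase.t_end), s0.as_array(),
        method=method, rtol=rtol, atol=atol, t_eval=grid,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed in phase {phase.label!r} near t = {sol.t[-1] if len(sol.t) else phase.t_start:.3f} min: {sol.message}"
        )
    states = sol.y.T.copy()
    caps = (p.t_psd, p.t_peri_in, p.t_peri_out, p.t_ua)
    for j, cap in enumerate(caps):
        np.clip(states[:, j], -atol, cap + atol, out=states[:, j])
    return PhaseSegment(phase.label, sol.t.copy(), states)


def simulate_protocol(
    proto: Protocol,
    p: Parameters,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    dt_grid: float = DEFAULT_GRID,
    method: str = "LSODA",
) -> Trajectory:
    """Run one full scenario from the resting equilibrium.

    Phase 1 (modulation) starts at the resting fixed point; the induction
    step is applied to its final state; phases 2 and 3 continue with
    final-state handoff.
    """
    schedule = build_schedule(proto, p)
    s = resting_equilibrium(p)
    segments = []
    for phase in schedule:
        if phase.label == "induction":
            s = apply_induction_step(s, proto.induction, p)
        seg = integrate_phase(s, phase, p, rtol=rtol, atol=atol,
                              dt_grid=dt_grid, method=method)
        segments.append(seg)
        s = seg.final_state()
    return Trajectory(segments)
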