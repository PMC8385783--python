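"""Synaptic-weight readout and qualitative scenario outcomes.

The experimental observable the model is matched to is a synaptic response
normalized to its pre-treatment baseline.  Here the raw weight is the
anchored-receptor content of the PSD plus a configurable fraction of the
unanchored surface pool; it is passed through a causal exponential smoother
and expressed as percent of its value at t = 0.

The headline qualitative result is the pull-push matrix: across the eleven
scenarios {none, gs, gq, gs+gq} x {none, ltp, ltd} (minus the trivial
none:none), Gs agonists permit LTP while blocking LTD, Gq agonists permit
LTD while blocking LTP, and coactivation permits both; agonists alone
produce only transient weight changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Protocol, Trajectory, resting_equilibrium, simulate_protocol
from .kinetics import Parameters

__all__ = [
    "SCENARIOS",
    "WeightTrace",
    "OutcomeRecord",
    "SignatureRecord",
    "raw_weight",
    "smooth_exponential",
    "normalize_weight",
    "weight_trace",
    "classify_outcome",
    "run_scenario_matrix",
    "compartment_signature",
]

#: The eleven scenarios of the full pull-push matrix.
SCENARIOS = tuple(
    (agonist, induction)
    for agonist in ("none", "gs", "gq", "gs+gq")
    for induction in ("none", "ltp", "ltd")
    if not (agonist == "none" and induction == "none")
)


@dataclass
class WeightTrace:
    """Raw, smoothed and baseline-normalized weight on the trajectory grid."""

    times: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    normalized: np.ndarray  # percent of the t=0 smoothed baseline


@dataclass
class OutcomeRecord:
    """Terminal outcome of one scenario."""

    scenario: str
    agonist: str
    induction: str
    final_pct: float          # mean normalized weight over the terminal window
    peak_pct: float           # max |deviation| sample of the normalized trace
    classification: str       # potentiated | depressed | unchanged
    peri_in_rel_final: float  # terminal PeriIN occupancy / resting value
    peri_out_rel_final: float


@dataclass
class SignatureRecord:
    """Perisynaptic occupancies at key times, with resting references.

    ``*_end_mod`` is sampled at the end of the modulation phase,
    ``*_end_ind`` at the end of induction (when the agonist-modulated
    rates switch off), ``*_final`` at t_total.
    """

    peri_in_rest: float
    peri_out_rest: float
    peri_in_end_mod: float
    peri_out_end_mod: float
    peri_in_end_ind: float
    peri_out_end_ind: float
    peri_in_final: float
    peri_out_final: float


def raw_weight(traj: Trajectory, p: Parameters) -> np.ndarray:
    """w(t) = a_psd(t) + w_ua * a_ua(t), the bound-receptor readout."""
    return traj.a_psd + p.w_ua * traj.a_ua


def smooth_exponential(times: np.ndarray, x: np.ndarray, tau: float) -> np.ndarray:
    """Causal first-order exponential filter with time constant ``tau`` min.

    Exact discretization of dy/dt = (x - y)/tau for piecewise-constant
    input on a (possibly non-uniform) grid; y(t0) = x(t0).  ``tau = 0``
    returns the input unchanged.
    """
    if tau < 0:
        raise ValueError("smoothing time constant must be >= 0")
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    if times.shape != x.shape:
        raise ValueError("times and series must have the same shape")
    if tau == 0 or len(x) == 0:
        return x.copy()
    y = np.empty_like(x)
    y[0] = x[0]
    alpha = 1.0 - np.exp(-np.diff(times) / tau)
    for i in range(1, len(x)):
        y[i] = y[i - 1] + alpha[i - 1] * (x[i] - y[i - 1])
    return y


def normalize_weight(w: np.ndarray) -> np.ndarray:
    """Express a weight series as percent of its first sample."""
    w = np.asarray(w, dtype=float)
    if len(w) == 0 or not w[0] > 0:
        raise ValueError("baseline weight must be > 0 for normalization")
    return 100.0 * w / w[0]


def weight_trace(traj: Trajectory, p: Parameters) -> WeightTrace:
    """Full raw -> smoothed -> normalized weight pipeline for a trajectory."""
    raw = raw_weight(traj, p)
    smoothed = smooth_exponential(traj.times, raw, p.tau_smooth)
    return WeightTrace(times=traj.times.copy(), raw=raw,
                       smoothed=smoothed, normalized=normalize_weight(smoothed))


def classify_outcome(
    wt: WeightTrace, window: float = 5.0, threshold: float = 10.0
) -> str:
    """Classify the terminal normalized weight.

    Mean over the final ``window`` minutes; above 100 + threshold percent
    is 'potentiated', below 100 - threshold 'depressed', else 'unchanged'.
    The default 10% band is the conventional no-plasticity margin of slice
    physiology; under the published constants it cleanly separates the
    neuromodulator-blocked scenarios (which keep <8% residual plasticity,
    the enzyme tails outlasting the agonist) from expressed LTP/LTD
    (>16% weight change).
    """
    if not window > 0:
        raise ValueError("window must be > 0")
    t_end = wt.times[-1]
    mask = wt.times >= t_end - window
    if not mask.any():
        raise ValueError("terminal window contains no samples")
    final = float(np.mean(wt.normalized[mask]))
    if final > 100.0 + threshold:
        return "potentiated"
    if final < 100.0 - threshold:
        return "depressed"
    return "unchanged"


def terminal_mean(wt: WeightTrace, window: float = 5.0) -> float:
    """Mean normalized weight (percent) over the final ``window`` minutes."""
    mask = wt.times >= wt.times[-1] - window
    return float(np.mean(wt.normalized[mask]))


def run_scenario_matrix(
    p: Parameters,
    window: float = 5.0,
    threshold: float = 10.0,
    return_trajectories: bool = False,
    **sim_kwargs,
):
    """Simulate all eleven scenarios and classify their outcomes.

    Returns a list of :class:`OutcomeRecord`; with
    ``return_trajectories=True`` also returns ``{scenario_id: Trajectory}``.
    """
    rest = resting_equilibrium(p)
    records, trajs = [], {}
    for agonist, induction in SCENARIOS:
        proto = Protocol(agonist=agonist, induction=induction)
        traj = simulate_protocol(proto, p, **sim_kwargs)
        wt = weight_trace(traj, p)
        final = terminal_mean(wt, window)
        peak = float(np.max(np.abs(wt.normalized - 100.0)))
        records.append(OutcomeRecord(
            scenario=proto.scenario_id,
            agonist=agonist,
            induction=induction,
            final_pct=final,
            peak_pct=peak,
            classification=classify_outcome(wt, window, threshold),
            peri_in_rel_final=float(traj.a_peri_in[-1] / rest.a_peri_in),
            peri_out_rel_final=float(traj.a_peri_out[-1] / rest.a_peri_out),
        ))
        if return_trajectories:
            trajs[proto.scenario_id] = traj
    if return_trajectories:
        return records, trajs
    return records


def compartment_signature(traj: Trajectory, p: Parameters) -> SignatureRecord:
    """Perisynaptic occupancy signature of a simulated trajectory.

    Samples PeriIN/PeriOut at the end of modulation, the end of induction
    and at the horizon, against the resting equilibrium: a Gs agonist
    drives both pools above rest (PeriIN near capacity), a Gq agonist
    drives both below rest (PeriOut near empty), and coactivation fills
    PeriIN while emptying PeriOut.
    """
    rest = resting_equilibrium(p)
    bounds = traj.boundaries
    t_mod = bounds[0] if bounds else traj.times[-1]
    t_ind = bounds[1] if len(bounds) > 1 else traj.times[-1]
    s_mod = traj.state_at(t_mod)
    s_ind = traj.state_at(t_ind)
    return SignatureRecord(
        peri_in_rest=rest.a_peri_in,
        peri_out_rest=rest.a_peri_out,
        peri_in_end_mod=s_mod.a_peri_in,
        peri_out_end_mod=s_mod.a_peri_out,
        peri_in_end_ind=s_ind.a_peri_in,
        peri_out_end_ind=s_ind.a_peri_out,
        peri_in_final=float(traj.a_peri_in[-1]),
        peri_out_final=float(traj.a_peri_out[-1]),
    )
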