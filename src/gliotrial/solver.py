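"""Finite-difference spatial discretisation and explicit time integration.

The invasive-cell field moves by two mechanisms on the brain grid:

* concentration-driven motility — passive diffusion ``delta div(D grad I)``
  discretised with a 5-point Laplacian (harmonic-mean face diffusivity);
* hypoxia-driven motility — active transport up the healthy-brain
  gradient, ``-eta div(I grad B)``, discretised with donor-cell upwinding.

Both discretisations are written in flux form with fluxes zeroed on faces
leading out of the brain mask, so they conserve invasive-cell mass exactly
(impermeable skull).  Diffusive support collapses (D ~ 0) on voxels with
at least 80% brain death: white-matter tracks and vessels are dead in the
necrotic core, so cells cannot diffuse back into it.

Time stepping is forward Euler under a conservative stability bound.  The
production path (:func:`simulate`) runs a fused numba kernel; the plain
NumPy operators in this module are the readable reference the kernel is
tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import BrainGeometry
from .imaging import ImagingSummary, imaging_summary
from .model_core import ModelParams, TumorState, reaction_terms
from . import _kernel

NECROTIC_CORE_BRAIN_FRACTION = 0.2  # >= 80% brain death kills diffusive support
NECROTIC_CORE_D = 1e-6              # residual diffusivity there (avoids artefacts)
HOURS_PER_MONTH = 730.0             # 30.42-day months
MAX_SIM_HOURS = 5 * 8760.0          # censoring guard
CLIP_TOLERANCE = 1e-6               # max clipped |mass| relative to total

__all__ = [
    "Schedule",
    "Trajectory",
    "diffusion_term",
    "advection_term",
    "stable_dt",
    "step",
    "simulate",
    "HOURS_PER_MONTH",
]

Trigger = Callable[[ImagingSummary], bool]
Action = Callable[[ModelParams], ModelParams]


@dataclass
class Schedule:
    """Timed or imaging-triggered, one-shot modifications of the model params.

    Each event is ``(trigger, action)``: ``trigger`` is either a time in
    hours or a predicate on the current imaging summary; ``action`` maps a
    ``ModelParams`` to the modified one (idempotent).  Events fire at most
    once, at the first output-cadence point where their trigger holds.
    """

    events: list[tuple[float | Trigger, Action]] = field(default_factory=list)

    def pending(self) -> "Schedule":
        return Schedule(events=list(self.events))

    def fire(self, summary: ImagingSummary, params: ModelParams
             ) -> tuple[ModelParams, list[float]]:
        """Apply every event whose trigger holds; return fired times."""
        fired = []
        remaining = []
        for trig, action in self.events:
            hit = (summary.t >= trig) if isinstance(trig, (int, float)) else trig(summary)
            if hit:
                params = action(params)
                fired.append(summary.t)
            else:
                remaining.append((trig, action))
        self.events = remaining
        return params, fired


@dataclass
class Trajectory:
    """Simulation output: imaging summaries at a fixed cadence."""

    summaries: list[ImagingSummary]
    final_state: TumorState
    event_times: list[float] = field(default_factory=list)
    censored: bool = False
    clipped_mass: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.summaries])


def _effective_D(geom: BrainGeometry, state: TumorState) -> np.ndarray:
    Deff = np.where(geom.mask, geom.D, 0.0)
    core = geom.mask & (state.B < NECROTIC_CORE_BRAIN_FRACTION * geom.B0)
    Deff[core] = NECROTIC_CORE_D
    return Deff


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def diffusion_term(
    I: np.ndarray, geom: BrainGeometry, state: TumorState, delta: float
) -> np.ndarray:
    """Discrete ``delta div(D_eff grad I)`` with no-flux mask boundary (per hr)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    h = geom.spacing
    Deff = _effective_D(geom, state)
    out = np.zeros_like(I)
    for axis in (0, 1):
        lo = tuple(slice(0, -1) if ax == axis else slice(None) for ax in (0, 1))
        hi = tuple(slice(1, None) if ax == axis else slice(None) for ax in (0, 1))
        open_face = geom.mask[lo] & geom.mask[hi]
        Dface = _harmonic(Deff[lo], Deff[hi])
        flux = delta * Dface * (I[hi] - I[lo]) / h * open_face
        out[lo] += flux / h
        out[hi] -= flux / h
    return out


def advection_term(
    I: np.ndarray, B: np.ndarray, geom: BrainGeometry, eta: float
) -> np.ndarray:
    """Discrete ``-eta div(I grad B)``: upwind transport up the B gradient (per hr).

    The face velocity is ``eta * dB/dn``; the transported concentration is
    taken from the donor (upstream) cell, which keeps the update positive
    under the advective time-step bound.  Zero gradient moves nothing.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    h = geom.spacing
    out = np.zeros_like(I)
    for axis in (0, 1):
        lo = tuple(slice(0, -1) if ax == axis else slice(None) for ax in (0, 1))
        hi = tuple(slice(1, None) if ax == axis else slice(None) for ax in (0, 1))
        open_face = geom.mask[lo] & geom.mask[hi]
        v = eta * (B[hi] - B[lo]) / h          # >0: cells move lo -> hi
        donor = np.where(v > 0, I[lo], I[hi])
        flux = v * donor * open_face
        out[lo] -= flux / h
        out[hi] += flux / h
    return out


def stable_dt(
    params: ModelParams, geom: BrainGeometry, safety: float = 0.5
) -> float:
    """Conservative forward-Euler time step (hours).

    Takes the minimum of the diffusive bound ``h^2 / (4 delta max D)``, the
    advective bound with ``|grad B|`` bounded by ``max B0 / h``, and a
    reaction bound ``1 / (alpha + beta + 100 gamma)`` (the factor 100 is
    the worst-case necrosis multiplier as B -> 0).
    """
    h = geom.spacing
    maxD = max(float(geom.D.max()), 1.0)
    bounds = [1.0 / (params.alpha + params.beta + 100.0 * params.gamma)]
    if params.delta > 0:
        bounds.append(h * h / (4.0 * params.delta * maxD))
    if params.eta > 0:
        gradB_max = float(geom.B0.max()) / h
        bounds.append(h / (params.eta * gradB_max))
    return safety * min(bounds)


def step(
    state: TumorState,
    geom: BrainGeometry,
    params: ModelParams,
    dt: float,
    override_stability: bool = False,
) -> TumorState:
    """One forward-Euler step (NumPy reference path).

    Negative values produced by round-off at sharp fronts are clipped to
    zero; clipped magnitudes are tracked by :func:`simulate`.
    """
    if not override_stability and dt > stable_dt(params, geom) * (1 + 1e-12):
        raise ValueError(f"dt={dt} exceeds the stability bound; pass override_stability=True to force")
    dP, dI, dB, dN = reaction_terms(state, params)
    dI = dI + diffusion_term(state.I, geom, state, params.delta)
    dI = dI + advection_term(state.I, state.B, geom, params.eta)
    new = TumorState(
        P=np.clip(state.P + dt * dP, 0.0, None),
        I=np.clip(state.I + dt * dI, 0.0, None),
        B=np.clip(state.B + dt * dB, 0.0, None),
        N=np.clip(state.N + dt * dN, 0.0, None),
        t=state.t + dt,
    )
    for f in (new.P, new.I, new.B, new.N):
        f[~geom.mask] = 0.0
    return new


def _tau_field(params: ModelParams, shape: tuple[int, int]) -> np.ndarray:
    tau = np.asarray(params.tau, dtype=float)
    if tau.ndim == 0:
        return np.full(shape, float(tau))
    if tau.shape != shape:
        raise ValueError("per-voxel tau field does not match the grid shape")
    return np.ascontiguousarray(tau)


def advance(
    state: TumorState,
    geom: BrainGeometry,
    params: ModelParams,
    dt: float,
    n_steps: int,
) -> tuple[TumorState, float]:
    """Advance ``n_steps`` forward-Euler steps with the fused numba kernel.

    Returns the new state and the total clipped (negative) mass.
    """
    P, I, B, N = (np.ascontiguousarray(f, dtype=float) for f in
                  (state.P.copy(), state.I.copy(), state.B.copy(), state.N.copy()))
    clipped = _kernel.advance(
        P, I, B, N,
        geom.mask, np.ascontiguousarray(geom.D), np.ascontiguousarray(geom.B0),
        geom.spacing, dt, n_steps,
        params.alpha, params.beta, _tau_field(params, geom.shape),
        params.gamma, params.delta, params.eta,
        params.sigma, params.omega, params.phi, params.steepness,
        params.log_base == "decimal", params.angiogenic_drive == "total",
        params.switch_concentration == "living", params.growth_floor,
        params.necrosis_multiplier == "burden_scaled",
    )
    return TumorState(P, I, B, N, t=state.t + dt * n_steps), float(clipped)


def simulate(
    geom: BrainGeometry,
    init: TumorState,
    params: ModelParams,
    schedule: Schedule | None = None,
    stop: Trigger | None = None,
    cadence: float = 12.0,
    max_time: float = MAX_SIM_HOURS,
    safety: float = 0.5,
) -> Trajectory:
    """Integrate the model, recording imaging summaries every ``cadence`` hours.

    Schedule triggers and the stop predicate are evaluated at cadence
    points (12 simulated hours by default — fine relative to month-scale
    outcomes).  The run is censored at ``max_time`` if the stop predicate
    never fires.  Raises if clipped negative mass ever exceeds
    ``CLIP_TOLERANCE`` of the total mass.
    """
    state = init.copy()
    sched = schedule.pending() if schedule is not None else Schedule()
    summaries = [imaging_summary(state, geom)]
    event_times: list[float] = []
    clipped_total = 0.0

    params_now = params
    # land exactly on cadence points
    while state.t < max_time - 1e-9:
        dt0 = stable_dt(params_now, geom, safety=safety)
        n = max(1, int(np.ceil(cadence / dt0)))
        dt = cadence / n
        state, clipped = advance(state, geom, params_now, dt, n)
        clipped_total += clipped
        if clipped_total > CLIP_TOLERANCE * max(state.total_mass, 1.0):
            raise RuntimeError("clipped negative mass exceeds tolerance; unstable run")
        summary = imaging_summary(state, geom)
        summaries.append(summary)
        params_now, fired = sched.fire(summary, params_now)
        event_times.extend(fired)
        if stop is not None and stop(summary):
            return Trajectory(summaries, state, event_times, censored=False,
                              clipped_mass=clipped_total)
    return Trajectory(summaries, state, event_times, censored=True,
                      clipped_mass=clipped_total)
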