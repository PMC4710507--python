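"""Pointwise closures and reaction terms of the go-or-grow glioblastoma model.

The model tracks four interacting cell populations on a 2-D brain grid:
proliferative tumour cells ``P`` (stationary, dividing), invasive tumour
cells ``I`` (motile, non-dividing), healthy brain cells ``B`` and necrotic
debris ``N``.  All concentrations are dimensionless, normalised so that
healthy brain has ``B = 1``.  Hypoxia drives the phenotype switch P -> I
(go-or-grow); angiogenesis raises the local cell-density threshold the
tissue can sustain; past a second, slightly higher threshold cells necrose.

Everything in this module is pointwise (no spatial coupling); the motility
terms live in :mod:`gliotrial.solver`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Union

import numpy as np
import yaml

Field = np.ndarray
TauLike = Union[float, np.ndarray]

__all__ = [
    "ModelParams",
    "TumorState",
    "total_concentration",
    "hypoxic_threshold",
    "necrotic_threshold",
    "hypoxia_measure",
    "mitotic_rate",
    "necrosis_rate",
    "reaction_terms",
]


@dataclass
class ModelParams:
    """Rate and threshold constants of the growth/invasion model.

    Parameters
    ----------
    alpha : float
        Transition rate P -> I under hypoxia (/hr).
    beta : float
        Transition rate I -> P under normoxia (/hr).
    tau : float or ndarray
        Maximal mitotic rate of P cells (/hr).  May be a per-voxel field
        (e.g. under a spatially varying rate-reducing agent such as
        tumour-treating fields).
    delta : float
        Concentration-driven (diffusive) motility coefficient of I cells
        (mm^2/hr).
    gamma : float
        Base necrotic rate of living cells (/hr).
    eta : float
        Hypoxia-driven (haptotactic) motility coefficient of I cells
        (mm/hr): active transport up the healthy-brain gradient.
    omega : float
        Initial hypoxic threshold (dimensionless total concentration).
    sigma : float
        Angiogenic rate; 1.5 models functional angiogenesis, 0 models
        anti-angiogenic treatment.
    phi : float
        Fixed gap between the necrotic and hypoxic thresholds.
    steepness : float
        Slope constant of the tanh switches.
    log_base : {"natural", "decimal"}
        Base of the logarithm in the angiogenic threshold term.
    angiogenic_drive : {"P", "total"}
        Which tumour population recruits vasculature in the hypoxic
        threshold: proliferative cells only, or total tumour burden P + I.
        Default "total": both compartments are viable tumour secreting
        angiogenic factors.
    necrosis_multiplier : {"burden_scaled", "additive"}
        Density dependence of the necrosis rate.  "burden_scaled"
        (default): gamma_F scales with local tumour burden,
        multiplier = (P + I) (1/100 + 1/(B + 0.01)), so dense cores
        necrose on the week scale while sparse infiltration erodes the
        brain orders of magnitude more slowly, and tumour-free tissue
        never necroses.  "additive": multiplier = (P + I)/100 +
        1/(B + 0.01), which is density-independent near healthy tissue
        and gives every hypoxia-stalled voxel the same slow necrosis
        clock regardless of burden.
    growth_floor : float
        Minimum local tumour density (P + I) for mitosis.  Below it cells
        are below clonogenic density at voxel scale and do not divide
        (motility and phenotype switching are unaffected).  Without a
        floor, exponential amplification of arbitrarily small diffusive
        leakage propagates growth fronts at a near-delta-independent
        lattice speed, which suppresses the motility phenotypes.
    switch_concentration : {"living", "total"}
        Which concentration the hypoxia and necrosis switches compare
        against the thresholds: living cells P + I + B (default; necrotic
        debris consumes no oxygen) or total including the inert necrotic
        compartment.  With "total" the conservation identity
        dC/dt = M P makes every dense focus run away into necrosis on the
        reaction timescale, which suppresses all motility-phenotype
        structure; see the methods notes.
    """

    alpha: float = 2.02
    beta: float = 2.00
    tau: TauLike = 0.35
    delta: float = 8e-5
    gamma: float = 0.17
    eta: float = 1.4e-3
    omega: float = 1.1
    sigma: float = 1.5
    phi: float = 0.10
    steepness: float = 40.0
    log_base: str = "natural"
    angiogenic_drive: str = "total"
    switch_concentration: str = "living"
    growth_floor: float = 0.045
    necrosis_multiplier: str = "burden_scaled"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "delta", "gamma", "eta", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if np.any(np.asarray(self.tau) < 0):
            raise ValueError("tau must be non-negative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.log_base not in ("natural", "decimal"):
            raise ValueError("log_base must be 'natural' or 'decimal'")
        if self.angiogenic_drive not in ("P", "total"):
            raise ValueError("angiogenic_drive must be 'P' or 'total'")
        if self.switch_concentration not in ("living", "total"):
            raise ValueError("switch_concentration must be 'living' or 'total'")
        if self.growth_floor < 0:
            raise ValueError("growth_floor must be non-negative")
        if self.necrosis_multiplier not in ("burden_scaled", "additive"):
            raise ValueError("necrosis_multiplier must be 'burden_scaled' or 'additive'")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    # -- flat key/value (YAML) serialisation ---------------------------------
    def to_file(self, path) -> None:
        d = asdict(self)
        if isinstance(d["tau"], np.ndarray):
            raise ValueError("cannot serialise a per-voxel tau field to config")
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


@dataclass
class TumorState:
    """Cell-concentration fields at one time point."""

    P: Field
    I: Field
    B: Field
    N: Field
    t: float = 0.0

    def __post_init__(self) -> None:
        shapes = {f.shape for f in (self.P, self.I, self.B, self.N)}
        if len(shapes) != 1:
            raise ValueError("P, I, B, N must share one shape")

    def copy(self) -> "TumorState":
        return TumorState(
            self.P.copy(), self.I.copy(), self.B.copy(), self.N.copy(), self.t
        )

    @property
    def total_mass(self) -> float:
        return float(self.P.sum() + self.I.sum() + self.B.sum() + self.N.sum())


def _check_finite(*fields: Field) -> None:
    for f in fields:
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite values in input field")


def total_concentration(state: TumorState) -> Field:
    """Total cell concentration C = P + I + B + N."""
    return state.P + state.I + state.B + state.N


def hypoxic_threshold(P: Field, params: ModelParams) -> Field:
    """Angiogenesis-raised hypoxic threshold.

    C_hyp = sigma * log(1 + P) + omega.  A denser tumour mass recruits
    vasculature and so tolerates a higher total concentration before
    hypoxia sets in; with sigma = 0 (anti-angiogenesis) the threshold is
    pinned at omega everywhere.  ``P`` here is the driving population:
    callers pass P alone or total tumour P + I according to
    ``params.angiogenic_drive``.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("P must be non-negative")
    log = np.log1p(P) if params.log_base == "natural" else np.log10(1.0 + P)
    return params.sigma * log + params.omega


def necrotic_threshold(Chyp: Field, params: ModelParams) -> Field:
    """Necrotic threshold C_ltm = C_hyp + phi."""
    return np.asarray(Chyp, dtype=float) + params.phi


def hypoxia_measure(C: Field, Chyp: Field, params: ModelParams) -> Field:
    """Smooth hypoxia indicator H = (1 - tanh(k (C_hyp - C))) / 2, in (0, 1)."""
    return 0.5 * (1.0 - np.tanh(params.steepness * (np.asarray(Chyp) - np.asarray(C))))


def mitotic_rate(H: Field, tau: TauLike) -> Field:
    """Mitotic rate M = tau (1 - H): proliferation shuts down under hypoxia."""
    return np.asarray(tau) * (1.0 - np.asarray(H))


def necrosis_rate(
    state: TumorState, C: Field, Cltm: Field, params: ModelParams
) -> Field:
    """Necrosis rate gamma_F.

    gamma_F = gamma * mult * (1 - tanh(k (C_ltm - C))) / 2

    where ``mult`` couples the rate to the local state (see
    ``ModelParams.necrosis_multiplier``).  In either form the multiplier
    diverges as the brain dies (B -> 0 brings a factor 1/0.01 = 100), so
    no cell population survives inside the necrotic core, and it grows
    with tumour burden, capping the total mass.  The tanh switch confines
    necrosis to regions whose concentration exceeds C_ltm.
    """
    switch = 0.5 * (1.0 - np.tanh(params.steepness * (np.asarray(Cltm) - np.asarray(C))))
    burden = state.P + state.I
    if params.necrosis_multiplier == "burden_scaled":
        mult = burden * (0.01 + 1.0 / (state.B + 0.01))
    else:
        mult = burden / 100.0 + 1.0 / (state.B + 0.01)
    return params.gamma * mult * switch


def reaction_terms(
    state: TumorState, params: ModelParams
) -> tuple[Field, Field, Field, Field]:
    """Local (non-motility) right-hand sides for P, I, B, N.

    dP = M P - alpha H P + beta (1 - H) I - gamma_F P
    dI = alpha H P - beta (1 - H) I - gamma_F I        (motility excluded)
    dB = -gamma_F B
    dN = +gamma_F (P + I + B)

    The terms cancel pairwise except for the mitotic source, so
    dP + dI + dB + dN = M P identically.
    """
    _check_finite(state.P, state.I, state.B, state.N)
    if params.switch_concentration == "living":
        C = state.P + state.I + state.B
    else:
        C = total_concentration(state)
    drive = state.P if params.angiogenic_drive == "P" else state.P + state.I
    Chyp = hypoxic_threshold(drive, params)
    Cltm = necrotic_threshold(Chyp, params)
    H = hypoxia_measure(C, Chyp, params)
    M = mitotic_rate(H, params.tau)
    M = np.where(state.P + state.I >= params.growth_floor, M, 0.0)
    gF = necrosis_rate(state, C, Cltm, params)

    switch_PI = params.alpha * H * state.P - params.beta * (1.0 - H) * state.I
    dP = M * state.P - switch_PI - gF * state.P
    dI = switch_PI - gF * state.I
    dB = -gF * state.B
    dN = gF * (state.P + state.I + state.B)
    return dP, dI, dB, dN
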