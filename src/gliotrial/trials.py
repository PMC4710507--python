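"""In-silico clinical trials: cohorts, interventions, arms, population sweeps.

A virtual patient is one simulation of the growth model on a brain
geometry.  Clinical heterogeneity is emulated by titrating the imaging
criteria that trigger treatment (or diagnosis) and that define death
across stated ranges; each patient in an arm gets one (trigger, death)
criterion pair from an evenly spaced grid over those ranges.  Overall
survival is death time minus treatment (diagnosis) time, in months.

Interventions fire at the trigger crossing:

* ``anti_angiogenesis`` — set the angiogenic rate sigma to 0;
* ``rate_reduction(e)``  — multiply the mitotic rate tau by (1 - e),
  uniformly or by a per-voxel efficacy field (tumour-treating fields);
* ``motility_reduction(e)`` — multiply the hypoxia-driven motility eta
  by (1 - e);
* ``none`` — controls; the trigger only marks the diagnosis time.

Patients within an arm share the whole pre-trigger (untreated) course, so
it is simulated once per parameter set and resumed per patient; the
forward-Euler kernel is chunking-invariant, making this exactly
equivalent to simulating each patient from seeding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import BrainGeometry, seed_tumor
from .imaging import ImagingSummary, imaging_summary, progression_pattern
from .model_core import ModelParams, TumorState
from .solver import HOURS_PER_MONTH, MAX_SIM_HOURS, advance, stable_dt
from .survival import km_estimate, logrank, median_survival

__all__ = [
    "PHENOTYPES",
    "CriterionRange",
    "Intervention",
    "TrialArm",
    "PatientRecord",
    "TrialResult",
    "phenotype_params",
    "make_cohort",
    "run_patient",
    "run_trial",
    "population_trial",
    "table5_arms",
]

# (delta mm^2/hr, eta mm/hr) per motility phenotype; eta is the high
# hypoxia-driven value for all three, per the trial design
PHENOTYPES: dict[str, tuple[float, float]] = {
    "highly_dispersive": (4e-3, 1.4e-3),
    "moderately_dispersive": (8e-5, 1.4e-3),
    "hypoxia_driven": (8e-7, 1.4e-3),
}
LOW_ETA = 1.4e-4
FIRST_FOLLOWUP_HOURS = 2 * HOURS_PER_MONTH  # imaging 2 months after treatment
LETHAL_NECROSIS_PCT = 50.0  # necrosis of half the brain is always fatal


def phenotype_params(phenotype: str, high_eta: bool = True) -> tuple[float, float]:
    """(delta, eta) for a named motility phenotype."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    delta, eta = PHENOTYPES[phenotype]
    return (delta, eta if high_eta else LOW_ETA)


@dataclass(frozen=True)
class CriterionRange:
    """A titration window for one imaging quantity (percent of brain)."""

    quantity: str  # "hiden" | "necrosis" | "flair"
    lo: float
    hi: float

    def __post_init__(self):
        if self.quantity not in ("hiden", "necrosis", "flair"):
            raise ValueError(f"unknown imaging quantity {self.quantity!r}")
        if not 0 <= self.lo <= self.hi:
            raise ValueError("need 0 <= lo <= hi")

    def grid(self, n: int) -> np.ndarray:
        return np.linspace(self.lo, self.hi, n)


@dataclass(frozen=True)
class Criterion:
    quantity: str
    threshold: float

    def crossed(self, s: ImagingSummary) -> bool:
        value = {
            "hiden": s.pct_hiden,
            "necrosis": s.pct_necrosis,
            "flair": s.pct_flair,
        }[self.quantity]
        return value >= self.threshold


@dataclass(frozen=True)
class Intervention:
    """What happens to the model parameters at the trigger crossing."""

    kind: str = "none"  # none | anti_angiogenesis | rate_reduction | motility_reduction
    efficacy: float = 0.0
    tau_field: np.ndarray | None = None  # spatial efficacy (TTFields)

    def __post_init__(self):
        if self.kind not in ("none", "anti_angiogenesis", "rate_reduction",
                             "motility_reduction"):
            raise ValueError(f"unknown intervention {self.kind!r}")
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError("efficacy must be in [0, 1]")

    def apply(self, params: ModelParams) -> ModelParams:
        if self.kind == "none":
            return params
        if self.kind == "anti_angiogenesis":
            return params.replace(sigma=0.0)
        if self.kind == "rate_reduction":
            if self.tau_field is not None:
                return params.replace(tau=np.asarray(params.tau) * self.tau_field)
            return params.replace(tau=params.tau * (1.0 - self.efficacy))
        return params.replace(eta=params.eta * (1.0 - self.efficacy))


@dataclass
class TrialArm:
    """One trial group: phenotype, size, criteria windows and intervention."""

    name: str
    n: int
    phenotype: str
    treatment_range: CriterionRange
    death_range: CriterionRange
    intervention: Intervention = field(default_factory=Intervention)
    seed: int = 0
    tau: float = 0.35
    high_eta: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("arm needs n >= 1")


@dataclass
class PatientRecord:
    arm: str
    index: int
    phenotype: str
    delta: float
    eta: float
    tau: float
    treatment_criterion: Criterion
    death_criterion: Criterion
    treatment_time: float  # hr; NaN if never triggered
    death_time: float      # hr; NaN if censored
    os_months: float
    censored: bool
    pattern: str


def make_cohort(arm: TrialArm) -> list[tuple[Criterion, Criterion]]:
    """Evenly spaced (trigger, death) criterion pairs, shuffled by the arm seed.

    Both thresholds span their windows on an n-point grid; the pairing is a
    seed-reproducible shuffle of the death grid against the ordered trigger
    grid, so the cohort covers both windows evenly without correlating the
    two criteria.
    """
    tgrid = arm.treatment_range.grid(arm.n)
    dgrid = arm.death_range.grid(arm.n)
    rng = np.random.default_rng(arm.seed)
    dgrid = rng.permutation(dgrid)
    return [
        (Criterion(arm.treatment_range.quantity, float(t)),
         Criterion(arm.death_range.quantity, float(d)))
        for t, d in zip(tgrid, dgrid)
    ]


def _advance_cadence(state: TumorState, geom: BrainGeometry, params: ModelParams,
                     cadence: float) -> TumorState:
    dt0 = stable_dt(params, geom)
    n = max(1, int(np.ceil(cadence / dt0)))
    new, _ = advance(state, geom, params, cadence / n, n)
    new.t = state.t + cadence
    return new


class UntreatedCourse:
    """Cached untreated run: summaries plus state snapshots at every cadence."""

    def __init__(self, geom: BrainGeometry, params: ModelParams,
                 cadence: float = 12.0, max_time: float = MAX_SIM_HOURS):
        self.geom = geom
        self.params = params
        self.cadence = cadence
        self.max_time = max_time
        state = seed_tumor(geom)
        self.states: list[TumorState] = [state]
        self.summaries: list[ImagingSummary] = [imaging_summary(state, geom)]

    def extend_until(self, predicate) -> int | None:
        """Index of the first cadence point where predicate holds (or None)."""
        for i, s in enumerate(self.summaries):
            if predicate(s):
                return i
        while self.states[-1].t < self.max_time:
            state = _advance_cadence(self.states[-1], self.geom, self.params,
                                     self.cadence)
            self.states.append(state)
            self.summaries.append(imaging_summary(state, self.geom))
            if predicate(self.summaries[-1]):
                return len(self.summaries) - 1
        return None


class _CourseCache:
    def __init__(self, geom: BrainGeometry, cadence: float, max_time: float):
        self.geom = geom
        self.cadence = cadence
        self.max_time = max_time
        self._courses: dict[tuple, UntreatedCourse] = {}

    def get(self, params: ModelParams) -> UntreatedCourse:
        key = (params.delta, params.eta, float(np.asarray(params.tau).mean()),
               params.sigma, params.growth_floor)
        if key not in self._courses:
            self._courses[key] = UntreatedCourse(
                self.geom, params, self.cadence, self.max_time)
        return self._courses[key]


def _lethal(s: ImagingSummary, death: Criterion) -> bool:
    # arm-specific criterion, plus an unconditional lethal-necrosis guard
    return death.crossed(s) or s.pct_necrosis >= LETHAL_NECROSIS_PCT


def _simulate_from(state: TumorState, geom: BrainGeometry, params: ModelParams,
                   death: Criterion, cadence: float, max_time: float
                   ) -> tuple[float, list[ImagingSummary]]:
    """Run until the death criterion fires; returns (death time or NaN, summaries)."""
    summaries = [imaging_summary(state, geom)]
    while state.t < max_time:
        state = _advance_cadence(state, geom, params, cadence)
        summaries.append(imaging_summary(state, geom))
        if _lethal(summaries[-1], death):
            return state.t, summaries
    return float("nan"), summaries


def _closest_summary(summaries: list[ImagingSummary], t: float) -> ImagingSummary:
    times = np.array([s.t for s in summaries])
    return summaries[int(np.argmin(np.abs(times - t)))]


def run_patient(
    geom: BrainGeometry,
    params: ModelParams,
    treatment: Criterion,
    death: Criterion,
    intervention: Intervention = Intervention(),
    cadence: float = 12.0,
    max_time: float = MAX_SIM_HOURS,
    _course: UntreatedCourse | None = None,
    arm: str = "", index: int = 0, phenotype: str = "",
) -> PatientRecord:
    """Simulate one virtual patient: seed, trigger, intervene, follow to death.

    The trigger fires at the first cadence point where the treatment (or
    diagnosis) criterion is crossed; the intervention modifies the model
    parameters from then on.  Death is the first crossing of the death
    criterion; a run reaching ``max_time`` is censored.
    """
    course = _course or UntreatedCourse(geom, params, cadence, max_time)
    i_trig = course.extend_until(treatment.crossed)

    def record(ttime, dtime, pattern):
        censored = not np.isfinite(dtime)
        os_m = ((dtime - ttime) / HOURS_PER_MONTH
                if np.isfinite(dtime) and np.isfinite(ttime)
                else (max_time - ttime) / HOURS_PER_MONTH if np.isfinite(ttime)
                else float("nan"))
        tau0 = float(np.asarray(params.tau).mean())
        return PatientRecord(arm, index, phenotype, params.delta, params.eta,
                             tau0, treatment, death, ttime, dtime, os_m,
                             censored, pattern)

    if i_trig is None:  # never diagnosed within the horizon
        return record(float("nan"), float("nan"), "NoProgression")

    t_treat = course.summaries[i_trig].t
    at_treatment = course.summaries[i_trig]
    post_params = intervention.apply(params)
    if intervention.kind == "none":
        # control: continue the shared untreated course
        i_death = course.extend_until(
            lambda s, d=death: s.t > t_treat and _lethal(s, d))
        t_death = course.summaries[i_death].t if i_death is not None else float("nan")
        post = course.summaries[i_trig:]
        if i_death is not None:
            post = course.summaries[i_trig:i_death + 1]
    else:
        state = course.states[i_trig].copy()
        t_death, post = _simulate_from(state, geom, post_params, death,
                                       cadence, max_time)

    first_fu = _closest_summary(post, t_treat + FIRST_FOLLOWUP_HOURS)
    last = post[-1]
    if last.t > first_fu.t > at_treatment.t - 1e-9:
        pattern = progression_pattern(at_treatment, first_fu, last)
    else:
        pattern = "NoProgression"
    return record(t_treat, t_death, pattern)


@dataclass
class TrialResult:
    patients: pd.DataFrame
    curves: dict
    medians: dict
    logrank_table: pd.DataFrame

    def arm_times(self, arm: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.patients[self.patients.arm == arm]
        return sub.os_months.to_numpy(), (~sub.censored).to_numpy()


def run_trial(
    arms: list[TrialArm],
    geom: BrainGeometry,
    base_params: ModelParams | None = None,
    cadence: float = 12.0,
    max_time: float = MAX_SIM_HOURS,
) -> TrialResult:
    """Run every arm, estimate per-arm KM curves and pairwise log-rank tests."""
    if not arms:
        raise ValueError("empty arm list")
    base = base_params or ModelParams()
    cache = _CourseCache(geom, cadence, max_time)
    records: list[PatientRecord] = []
    for arm in arms:
        delta, eta = phenotype_params(arm.phenotype, arm.high_eta)
        params = base.replace(delta=delta, eta=eta, tau=arm.tau)
        course = cache.get(params)
        for i, (trig, death) in enumerate(make_cohort(arm)):
            records.append(run_patient(
                geom, params, trig, death, arm.intervention, cadence,
                max_time, _course=course, arm=arm.name, index=i,
                phenotype=arm.phenotype))
    patients = pd.DataFrame([vars(r) for r in records])
    # drop never-diagnosed patients from survival analysis
    analysable = patients[np.isfinite(patients.treatment_time)]
    curves, medians = {}, {}
    for name in patients.arm.unique():
        sub = analysable[analysable.arm == name]
        if len(sub):
            curves[name] = km_estimate(sub.os_months, ~sub.censored)
            medians[name] = median_survival(curves[name])
    rows = []
    for a, b in itertools.combinations(sorted(curves), 2):
        sa = analysable[analysable.arm == a]
        sb = analysable[analysable.arm == b]
        chi2, p = logrank((sa.os_months, ~sa.censored),
                          (sb.os_months, ~sb.censored))
        rows.append({"arm_a": a, "arm_b": b, "chi2": chi2, "p": p})
    return TrialResult(patients, curves, medians,
                       pd.DataFrame(rows, columns=["arm_a", "arm_b", "chi2", "p"]))


def table5_arms(
    n_treated: tuple[int, int, int] = (30, 25, 25),
    n_control_each: int = 25,
    seed: int = 0,
) -> list[TrialArm]:
    """The four-group anti-angiogenesis trial design (reduced sizes allowed).

    Treated arms: highly-dispersive (trigger on tumour size 2.0-2.8% of
    brain, death on FLAIR 55-88%), moderately-dispersive (tumour 2.0-2.8%,
    death necrosis 3.5-4.4%), hypoxia-driven (necrosis 0.09-0.32%, death
    necrosis 3.5-4.4%).  The control group pools untreated patients of all
    three phenotypes with death on tumour 10-18% (highly dispersive) or
    necrosis 3.5-4.3% / 3.5-4.4% (the other two).
    """
    aa = Intervention("anti_angiogenesis")
    arms = [
        TrialArm("highly_dispersive+AA", n_treated[0], "highly_dispersive",
                 CriterionRange("hiden", 2.0, 2.8),
                 CriterionRange("flair", 55.0, 88.0), aa, seed=seed),
        TrialArm("moderately_dispersive+AA", n_treated[1], "moderately_dispersive",
                 CriterionRange("hiden", 2.0, 2.8),
                 CriterionRange("necrosis", 3.5, 4.4), aa, seed=seed + 1),
        TrialArm("hypoxia_driven+AA", n_treated[2], "hypoxia_driven",
                 CriterionRange("necrosis", 0.09, 0.32),
                 CriterionRange("necrosis", 3.5, 4.4), aa, seed=seed + 2),
        TrialArm("control_highly_dispersive", n_control_each, "highly_dispersive",
                 CriterionRange("hiden", 2.0, 2.8),
                 CriterionRange("hiden", 10.0, 18.0), Intervention(), seed=seed + 3),
        TrialArm("control_moderately_dispersive", n_control_each,
                 "moderately_dispersive",
                 CriterionRange("hiden", 2.0, 2.8),
                 CriterionRange("necrosis", 3.5, 4.3), Intervention(), seed=seed + 4),
        TrialArm("control_hypoxia_driven", n_control_each, "hypoxia_driven",
                 CriterionRange("necrosis", 0.09, 0.32),
                 CriterionRange("necrosis", 3.5, 4.4), Intervention(), seed=seed + 5),
    ]
    return arms


CONTROL_DEATH = {
    "highly_dispersive": CriterionRange("hiden", 10.0, 18.0),
    "moderately_dispersive": CriterionRange("necrosis", 3.5, 4.3),
    "hypoxia_driven": CriterionRange("necrosis", 3.5, 4.4),
}
CONTROL_TRIGGER = {
    "highly_dispersive": CriterionRange("hiden", 2.0, 2.8),
    "moderately_dispersive": CriterionRange("hiden", 2.0, 2.8),
    "hypoxia_driven": CriterionRange("necrosis", 0.09, 0.32),
}


def population_trial(
    geom: BrainGeometry,
    efficacies,
    n_rates: int = 13,
    rate_interval: tuple[float, float] = (0.294, 0.35),
    per_cell_n: int = 25,
    seed: int = 0,
    intervention_kind: str = "rate_reduction",
    cadence: float = 12.0,
    max_time: float = MAX_SIM_HOURS,
    base_params: ModelParams | None = None,
) -> pd.DataFrame:
    """Population sweep: pooled median OS versus agent efficacy.

    For each efficacy the cohort pools all three phenotypes (equally
    represented), ``n_rates`` baseline mitotic rates drawn uniformly from
    ``rate_interval``, and ``per_cell_n`` criterion-titrated patients per
    (phenotype, rate) cell.  Patients are diagnosed on the control
    criteria; the agent fires at diagnosis; death uses the control death
    criteria.  Returns a frame with efficacy, median OS (months) and n.
    """
    rng = np.random.default_rng(seed)
    rates = rng.uniform(min(rate_interval), max(rate_interval), size=n_rates)
    base = base_params or ModelParams()
    cache = _CourseCache(geom, cadence, max_time)
    out = []
    for e in efficacies:
        os_all, ev_all = [], []
        for pheno in PHENOTYPES:
            delta, eta = phenotype_params(pheno)
            for j, tau0 in enumerate(rates):
                params = base.replace(delta=delta, eta=eta, tau=float(tau0))
                course = cache.get(params)
                arm = TrialArm(f"pop_{pheno}_{j}", per_cell_n, pheno,
                               CONTROL_TRIGGER[pheno], CONTROL_DEATH[pheno],
                               seed=seed + j)
                iv = Intervention(intervention_kind, efficacy=float(e))
                for i, (trig, death) in enumerate(make_cohort(arm)):
                    rec = run_patient(geom, params, trig, death, iv, cadence,
                                      max_time, _course=course,
                                      arm=arm.name, index=i, phenotype=pheno)
                    if np.isfinite(rec.treatment_time):
                        os_all.append(rec.os_months)
                        ev_all.append(not rec.censored)
        curve = km_estimate(os_all, ev_all)
        out.append({"efficacy": float(e), "median_os_months":
                    median_survival(curve), "n": len(os_all)})
    return pd.DataFrame(out)
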