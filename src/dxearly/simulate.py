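"""Consultation-study simulator: synthetic evidence bases, scenarios, virtual
GPs, and clustered two-session study datasets.

The simulated study mirrors a within-participant crossover evaluation of the
decision support system (DSS): each virtual GP consults twice with six
standardised-patient scenarios per session, the DSS session always second,
and the two six-scenario sets counterbalanced across GPs (each set is seen
aided and unaided equally often) and matched in mean difficulty.

Outcome model
-------------
The probability that GP :math:`i` diagnoses scenario :math:`j` correctly is

.. math:: p_{ij} = \\mathrm{expit}(\\mu_s + a_i + b_i\\,[\\text{aided}] + d_j)

with GP ability :math:`a_i \\sim N(0, \\sigma_{gp}^2)`, optional per-GP DSS
benefit :math:`b_i`, and scenario difficulty :math:`d_j`.  Two calibrations
make the configured study conditions exact rather than approximate:

* :math:`\\sigma_{gp}` is solved numerically so the intraclass correlation of
  the *binary* outcome (ANOVA / latent-threshold definition,
  :math:`\\rho = \\mathrm{Var}(p_i)/(\\bar p(1-\\bar p))`) equals the target
  ``icc``;
* the session intercepts :math:`\\mu_{baseline}, \\mu_{dss}` are solved so the
  *marginal* accuracies — integrating over abilities and the realized
  scenario difficulties — equal the configured ``baseline_accuracy`` and
  ``aided_accuracy``.

Secondary outcomes (items coded, tests ordered, consultation length,
certainty) are drawn from per-session distributions whose means/SDs are the
study conditions; they feed the "no significant increase" linear analyses.

All randomness flows from the single study seed through one numpy Generator
consumed in a fixed, documented order (evidence base, difficulties,
scenarios, then GPs outer / scenarios inner), so a design is reproducible
from its seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import consultation as consult
from .consultation import ConsultationRecord, ManagementAction
from .errors import DomainError, ReferenceLookupError
from .evidence import (
    DiagnosisEntry,
    EvidenceBase,
    Finding,
    FindingAssociation,
    PatientContext,
    candidate_diagnoses,
)

__all__ = [
    "Scenario",
    "VirtualGP",
    "StudyDesign",
    "SimulationParams",
    "generate_evidence_base",
    "generate_scenario",
    "simulate_consultation",
    "simulate_study",
    "calibrate_gp_sigma",
    "solve_session_intercept",
    "STUDY_RESULT_COLUMNS",
]

STUDY_RESULT_COLUMNS = [
    "gp_id",
    "session",
    "scenario_order",
    "scenario_id",
    "correct_working",
    "correct_inclusive",
    "appropriate_mgmt",
    "certainty",
    "n_coded",
    "n_tests",
    "duration_min",
]

_RFE_NAMES = ("chest_pain", "abdominal_pain", "dyspnoea")


# ---------------------------------------------------------------------------
# evidence-base fixture generator


def generate_evidence_base(
    n_rfes: int,
    dx_per_rfe: int,
    findings_per_dx: int,
    seed: int,
    pool_per_rfe: Optional[int] = None,
) -> EvidenceBase:
    """Generate a valid synthetic evidence base, deterministic in ``seed``.

    The first three RfEs are named chest_pain / abdominal_pain / dyspnoea;
    further ones are ``rfe_4``, ``rfe_5``, ...  Incidences cycle through the
    three tiers so every tier is populated.  Each diagnosis draws
    ``findings_per_dx`` distinct findings from a shared per-RfE vocabulary of
    ``pool_per_rfe`` findings (default ``max(2 * findings_per_dx,
    findings_per_dx + 3)``), so findings are shared across diagnoses.
    Generated entries apply to both sexes and all ages 0-110 so a candidate
    list always has exactly ``dx_per_rfe`` entries.
    """
    if min(n_rfes, dx_per_rfe, findings_per_dx) < 1:
        raise DomainError("n_rfes, dx_per_rfe and findings_per_dx must all be >= 1")
    if pool_per_rfe is None:
        pool_per_rfe = max(2 * findings_per_dx, findings_per_dx + 3)
    if pool_per_rfe < findings_per_dx:
        raise DomainError("pool_per_rfe must be >= findings_per_dx")

    rng = np.random.default_rng(seed)
    findings: dict[str, Finding] = {}
    rfes: dict[str, tuple[DiagnosisEntry, ...]] = {}
    for r in range(n_rfes):
        rfe = _RFE_NAMES[r] if r < len(_RFE_NAMES) else f"rfe_{r + 1}"
        pool = []
        for k in range(pool_per_rfe):
            fid = f"{rfe}_f{k + 1:02d}"
            findings[fid] = Finding(
                finding_id=fid,
                label=f"{rfe.replace('_', ' ')} finding {k + 1:02d}",
                synonyms=(),
            )
            pool.append(fid)
        entries = []
        tiers = ("common", "uncommon", "rare")
        for i in range(dx_per_rfe):
            tier = tiers[i % 3]
            if tier == "common":
                incidence = float(rng.uniform(55.0, 400.0))
            elif tier == "uncommon":
                incidence = float(rng.uniform(10.0, 50.0))
            else:
                incidence = float(rng.uniform(0.5, 9.5))
            chosen = rng.choice(pool, size=findings_per_dx, replace=False)
            assocs = tuple(
                FindingAssociation(
                    finding_id=str(fid),
                    p_given_dx=float(rng.uniform(0.55, 0.95)),
                    p_given_not_dx=float(rng.uniform(0.05, 0.45)),
                )
                for fid in chosen
            )
            entries.append(
                DiagnosisEntry(
                    dx_id=f"{rfe}_dx{i + 1:02d}",
                    label=f"{rfe.replace('_', ' ')} diagnosis {i + 1:02d}",
                    incidence=incidence,
                    sex_applicability="both",
                    age_range=(0, 110),
                    associations=assocs,
                )
            )
        rfes[rfe] = tuple(entries)
    return EvidenceBase(rfes=rfes, findings=findings, version=f"synthetic-{seed}")


# ---------------------------------------------------------------------------
# scenarios and virtual GPs


@dataclass(frozen=True)
class Scenario:
    """One standardised-patient scenario with a single correct diagnosis."""

    scenario_id: str
    patient: PatientContext
    true_dx: str
    finding_profile: Mapping[str, str]  # finding_id -> "present" | "absent"
    difficulty: float = 0.0  # latent logit offset; negative = harder


@dataclass(frozen=True)
class VirtualGP:
    gp_id: str
    ability: float  # random intercept on the logit of a correct diagnosis
    dss_benefit: float = 0.0  # per-GP uplift applied in aided sessions


def _profile_probabilities(eb: EvidenceBase, rfe: str, true_dx: str) -> dict[str, float]:
    """P(finding present | true diagnosis) for every finding reachable from the RfE.

    Findings associated with the true diagnosis use its p_given_dx; other
    findings use the mean p_given_not_dx over their associations under this
    RfE (the finding's typical background rate).
    """
    entry = eb.diagnosis(rfe, true_dx)
    true_p = {a.finding_id: a.p_given_dx for a in entry.associations}
    background: dict[str, list[float]] = {}
    for e in eb.diagnoses_for(rfe):
        for a in e.associations:
            background.setdefault(a.finding_id, []).append(a.p_given_not_dx)
    probs = {}
    for fid, ps in background.items():
        probs[fid] = true_p.get(fid, float(np.mean(ps)))
    return probs


def _sample_scenario(
    eb: EvidenceBase,
    rfe: str,
    true_dx: str,
    rng: np.random.Generator,
    scenario_id: str,
    difficulty: float = 0.0,
    sex: Optional[str] = None,
) -> Scenario:
    entry = eb.diagnosis(rfe, true_dx)
    lo, hi = entry.age_range
    age_lo, age_hi = max(lo, 22), min(hi, 70)
    if age_lo > age_hi:
        age_lo, age_hi = lo, hi
    age = int(rng.integers(age_lo, age_hi + 1))
    if sex is None:
        sex = entry.sex_applicability
        if sex == "both":
            sex = "male" if rng.random() < 0.5 else "female"
    profile = {
        fid: ("present" if rng.random() < p else "absent")
        for fid, p in _profile_probabilities(eb, rfe, true_dx).items()
    }
    patient = PatientContext(age=age, sex=sex, rfe=rfe)
    return Scenario(
        scenario_id=scenario_id,
        patient=patient,
        true_dx=true_dx,
        finding_profile=profile,
        difficulty=difficulty,
    )


def generate_scenario(eb: EvidenceBase, rfe: str, true_dx: str, seed: int) -> Scenario:
    """Sample a scenario whose finding profile follows the true diagnosis.

    Findings associated with the true diagnosis are present with their
    ``p_given_dx``; other findings with their background rate.  Deterministic
    in ``seed``.
    """
    rng = np.random.default_rng(seed)
    return _sample_scenario(eb, rfe, true_dx, rng, scenario_id=f"{rfe}:{true_dx}:{seed}")


# ---------------------------------------------------------------------------
# study conditions


@dataclass(frozen=True)
class SimulationParams:
    """Per-consultation outcome distributions (the study conditions).

    Means/SDs are per session (baseline without the DSS, aided with it).
    ``mu_baseline`` / ``mu_aided`` are the logit intercepts; when ``None``
    they default to ``logit`` of the configured accuracies (the calibrated
    study-level values are filled in by :func:`simulate_study`).
    """

    baseline_accuracy: float = 0.495
    aided_accuracy: float = 0.583
    mu_baseline: Optional[float] = None
    mu_aided: Optional[float] = None
    n_coded_mean_baseline: float = 1.64
    n_coded_mean_aided: float = 12.35
    certainty_mean_baseline: float = 7.61
    certainty_sd_baseline: float = 1.77
    certainty_mean_aided: float = 8.01
    certainty_sd_aided: float = 1.37
    tests_mean_baseline: float = 2.51
    tests_sd_baseline: float = 2.96
    tests_mean_aided: float = 2.83
    tests_sd_aided: float = 2.92
    duration_mean_baseline: float = 13.73
    duration_sd_baseline: float = 4.81
    duration_mean_aided: float = 14.42
    duration_sd_aided: float = 5.28
    # probability the true diagnosis is rescued into the differential / that
    # management is appropriate despite a wrong working diagnosis
    p_differential_rescue: float = 0.2
    p_management_rescue: float = 0.2

    def intercept(self, aided: bool) -> float:
        if aided:
            return self.mu_aided if self.mu_aided is not None else float(logit(self.aided_accuracy))
        return (
            self.mu_baseline
            if self.mu_baseline is not None
            else float(logit(self.baseline_accuracy))
        )


@dataclass(frozen=True)
class StudyDesign:
    """Two-session within-participant crossover design, DSS always second."""

    n_gps: int
    icc_target: float = 0.05
    baseline_accuracy: float = 0.495
    aided_accuracy: float = 0.583
    scenarios_per_session: int = 6
    sessions: int = 2
    counterbalanced: bool = True
    difficulty_sd: float = 0.3
    gp_benefit_sd: float = 0.0
    alpha: float = 0.05
    power: float = 0.90
    seed: int = 0
    params: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self) -> None:
        if self.n_gps < 2:
            raise DomainError("a study needs at least 2 GPs")
        if not 0.0 <= self.icc_target < 1.0:
            raise DomainError("icc_target must lie in [0, 1)")
        for name in ("baseline_accuracy", "aided_accuracy"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise DomainError(f"{name} must lie strictly in (0, 1)")

    @property
    def n_scenarios(self) -> int:
        return self.sessions * self.scenarios_per_session


# ---------------------------------------------------------------------------
# ICC / marginal calibration (Gauss-Hermite quadrature + root finding)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(41)


def _cluster_mean_curve(mu: float, sigma: float, difficulties: Sequence[float]):
    """g(a_k) = mean_j expit(mu + a_k + d_j) at the quadrature abilities."""
    d = np.asarray(difficulties, dtype=float)
    a = math.sqrt(2.0) * sigma * _GH_NODES
    g = expit(mu + a[:, None] + d[None, :]).mean(axis=1)
    w = _GH_WEIGHTS / math.sqrt(math.pi)
    return g, w


def _marginal_mean(mu: float, sigma: float, difficulties: Sequence[float]) -> float:
    g, w = _cluster_mean_curve(mu, sigma, difficulties)
    return float(w @ g)


def solve_session_intercept(
    target: float, sigma: float, difficulties: Sequence[float]
) -> float:
    """Intercept mu with marginal accuracy = ``target`` after integrating out
    the GP random intercept and averaging the realized scenario difficulties."""
    if not 0.0 < target < 1.0:
        raise DomainError("target accuracy must lie strictly in (0, 1)")
    return float(brentq(lambda mu: _marginal_mean(mu, sigma, difficulties) - target, -20, 20))


def calibrate_gp_sigma(
    target_accuracy: float, icc: float, difficulties: Sequence[float] = (0.0,)
) -> float:
    """SD of the GP random intercept giving binary-outcome ICC = ``icc``.

    The binary ICC is Var(p_i) / (pbar (1 - pbar)) with p_i the GP-level mean
    probability; the intercept is re-solved for every candidate sigma so the
    marginal mean stays at ``target_accuracy``.
    """
    if not 0.0 <= icc < 1.0:
        raise DomainError("icc must lie in [0, 1)")
    if icc == 0.0:
        return 0.0

    def icc_of(sigma: float) -> float:
        mu = solve_session_intercept(target_accuracy, sigma, difficulties)
        g, w = _cluster_mean_curve(mu, sigma, difficulties)
        pbar = float(w @ g)
        var_between = float(w @ (g * g)) - pbar * pbar
        return var_between / (pbar * (1.0 - pbar))

    return float(brentq(lambda s: icc_of(s) - icc, 1e-6, 8.0))


# ---------------------------------------------------------------------------
# consultations


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo=0.0, hi=math.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def simulate_consultation(
    gp: VirtualGP,
    scenario: Scenario,
    aided: bool,
    eb: EvidenceBase,
    seed_or_rng: int | np.random.Generator,
    params: SimulationParams = SimulationParams(),
) -> tuple[ConsultationRecord, dict]:
    """Simulate one consultation; returns the coded record and its outcome row.

    The GP codes ``k ~ Poisson(mean)`` findings sampled from the scenario's
    profile (aided GPs code many during the consultation; unaided GPs code
    few, emulating records written up only at the end).  Correctness is
    Bernoulli on the logit scale: session intercept + GP ability (+ per-GP
    DSS benefit when aided) + scenario difficulty.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    candidates = candidate_diagnoses(eb, scenario.patient)
    ids = [e.dx_id for e in candidates]
    if scenario.true_dx not in ids:
        raise ReferenceLookupError(
            f"true diagnosis {scenario.true_dx!r} is not a candidate for the scenario patient"
        )

    rec = ConsultationRecord(patient=scenario.patient)
    mean_coded = params.n_coded_mean_aided if aided else params.n_coded_mean_baseline
    profile_ids = list(scenario.finding_profile)
    k = min(int(rng.poisson(mean_coded)), len(profile_ids))
    for fid in rng.choice(profile_ids, size=k, replace=False) if k else []:
        consult.code_finding(rec, str(fid), scenario.finding_profile[str(fid)], eb=eb)

    eta = (
        params.intercept(aided)
        + gp.ability
        + scenario.difficulty
        + (gp.dss_benefit if aided else 0.0)
    )
    correct = bool(rng.random() < expit(eta))
    if correct:
        working = scenario.true_dx
    else:
        others = [d for d in ids if d != scenario.true_dx]
        working = str(rng.choice(others)) if others else scenario.true_dx
        correct = working == scenario.true_dx

    differential: list[str] = []
    rescued = False
    if not correct and rng.random() < params.p_differential_rescue:
        differential.append(scenario.true_dx)
        rescued = True
    extras = [d for d in ids if d != working and d not in differential]
    n_extra = int(rng.integers(0, 3))
    differential.extend(str(d) for d in rng.choice(extras, size=min(n_extra, len(extras)), replace=False))

    appropriate = correct or (rng.random() < params.p_management_rescue)
    action = str(rng.choice(consult.MANAGEMENT_ACTIONS))
    cert_mean = params.certainty_mean_aided if aided else params.certainty_mean_baseline
    cert_sd = params.certainty_sd_aided if aided else params.certainty_sd_baseline
    certainty = int(round(_trunc_normal(rng, cert_mean, cert_sd, 0.0, 10.0)))
    tests_mean = params.tests_mean_aided if aided else params.tests_mean_baseline
    tests_sd = params.tests_sd_aided if aided else params.tests_sd_baseline
    n_tests = int(round(_trunc_normal(rng, tests_mean, tests_sd, 0.0)))
    dur_mean = params.duration_mean_aided if aided else params.duration_mean_baseline
    dur_sd = params.duration_sd_aided if aided else params.duration_sd_baseline
    duration = _trunc_normal(rng, dur_mean, dur_sd, 0.0)

    consult.finalize(
        rec,
        working_dx=working,
        differential=differential,
        certainty=certainty,
        management=(ManagementAction(action=action),),
        tests_ordered=tuple(f"test_{i + 1}" for i in range(n_tests)),
    )
    outcome = {
        "correct_working": int(correct),
        "correct_inclusive": int(correct or rescued),
        "appropriate_mgmt": int(appropriate),
        "certainty": certainty,
        "n_coded": rec.coded_count,
        "n_tests": n_tests,
        "duration_min": duration,
    }
    return rec, outcome


# ---------------------------------------------------------------------------
# full study


def _matched_difficulty_sets(difficulties: np.ndarray) -> tuple[list[int], list[int]]:
    """Split scenario indices into two sets with near-equal mean difficulty.

    Sort by difficulty and alternate assignment within consecutive pairs.
    """
    order = np.argsort(difficulties)
    set_a: list[int] = []
    set_b: list[int] = []
    for p in range(len(order) // 2):
        i, j = order[2 * p], order[2 * p + 1]
        if p % 2 == 0:
            set_a.append(int(i))
            set_b.append(int(j))
        else:
            set_a.append(int(j))
            set_b.append(int(i))
    return set_a, set_b


def simulate_study(design: StudyDesign, return_records: bool = False):
    """Simulate a full counterbalanced two-session study.

    Returns the per-consultation outcome table (a DataFrame with
    ``STUDY_RESULT_COLUMNS``, ``n_gps * 12`` rows), plus the list of
    consultation records when ``return_records`` is true.  Deterministic in
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    eb = generate_evidence_base(
        n_rfes=3,
        dx_per_rfe=18,
        findings_per_dx=5,
        seed=int(rng.integers(2**31)),
        pool_per_rfe=30,
    )

    n_sc = design.n_scenarios
    difficulties = rng.normal(0.0, design.difficulty_sd, n_sc)
    difficulties -= difficulties.mean()
    rfe_cycle = [list(eb.rfes)[i % len(eb.rfes)] for i in range(n_sc)]
    scenarios: list[Scenario] = []
    used: dict[str, list[str]] = {r: [] for r in eb.rfes}
    for j in range(n_sc):
        rfe = rfe_cycle[j]
        pool = [e.dx_id for e in eb.rfes[rfe] if e.dx_id not in used[rfe]]
        true_dx = str(rng.choice(pool))
        used[rfe].append(true_dx)
        scenarios.append(
            _sample_scenario(
                eb,
                rfe,
                true_dx,
                rng,
                scenario_id=f"sc{j + 1:02d}",
                difficulty=float(difficulties[j]),
                sex="male" if j % 2 == 0 else "female",
            )
        )

    sigma = calibrate_gp_sigma(design.baseline_accuracy, design.icc_target, difficulties)
    params = replace(
        design.params,
        baseline_accuracy=design.baseline_accuracy,
        aided_accuracy=design.aided_accuracy,
        mu_baseline=solve_session_intercept(design.baseline_accuracy, sigma, difficulties),
        mu_aided=solve_session_intercept(design.aided_accuracy, sigma, difficulties),
    )

    set_a, set_b = _matched_difficulty_sets(difficulties)
    rows: list[dict] = []
    records: list[ConsultationRecord] = []
    for i in range(design.n_gps):
        gp = VirtualGP(
            gp_id=f"gp{i + 1:03d}",
            ability=float(rng.normal(0.0, sigma)),
            dss_benefit=float(rng.normal(0.0, design.gp_benefit_sd))
            if design.gp_benefit_sd > 0
            else 0.0,
        )
        if design.counterbalanced:
            baseline_set = set_a if i % 2 == 0 else set_b
        else:
            baseline_set = set_a if rng.random() < 0.5 else set_b
        aided_set = set_b if baseline_set is set_a else set_a
        order_counter = 0
        for session, sc_set, aided in (
            ("baseline", baseline_set, False),
            ("dss", aided_set, True),
        ):
            presented = list(sc_set)
            rng.shuffle(presented)
            for j in presented:
                order_counter += 1
                rec, outcome = simulate_consultation(
                    gp, scenarios[j], aided, eb, rng, params
                )
                rows.append(
                    {
                        "gp_id": gp.gp_id,
                        "session": session,
                        "scenario_order": order_counter,
                        "scenario_id": scenarios[j].scenario_id,
                        **outcome,
                    }
                )
                if return_records:
                    records.append(rec)

    table = pd.DataFrame(rows, columns=STUDY_RESULT_COLUMNS)
    if return_records:
        return table, records
    return table
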