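"""Synthetic EHR cohort generator.

Emulates the statistical structure the trajectory models assume: per-patient
visit processes with department/procedure vocabularies drawn jointly (so the
masked-language model has co-occurrence structure to learn), five serum
markers with configurable missingness, a dynamic-NPI-driven event model with
a target prevalence (default 6.2% positive events), independent censoring,
and templated pseudo-clinical reports into which multi-word signal phrases
can be planted for relapse-bound patients.

Event generation: a logistic model on (NPI, molecular subtype, abnormal
CA 15-3) gives each patient a 3-year event probability; the intercept is
calibrated by bisection so the cohort mean matches the target prevalence.
Event times are then exponential with the rate matched to that probability at
the horizon, which yields both a binary label and Kaplan–Meier-compatible
times.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    DEFAULT_HORIZON_DAYS,
    DEFAULT_MARKERS,
    MOLECULAR_SUBTYPES,
    PatientRecord,
    VisitEvent,
    compute_npi,
)

BASE_DATE = dt.date(2015, 1, 1)

#: department → procedures offered there; drawn jointly per visit so that the
#: procedure is predictable from the department (and vice versa) in context.
DEFAULT_DEPT_PROCEDURES = {
    "oncologie medicale": ["consultation oncologie", "rcp"],
    "radiotherapie": ["seance radiotherapie", "simulation dosimetrie"],
    "chirurgie": ["intervention chirurgicale", "consultation postoperatoire"],
    "imagerie": ["mammographie", "echographie mammaire"],
    "biologie": ["prelevement sanguin", "dosage marqueurs"],
    "anatomo-cyto-pathologie": ["examen histologique", "relecture lames"],
}

DEFAULT_THERAPIES = {
    "chimiotherapie": ["anthracyclines", "taxanes"],
    "hormonotherapie": ["tamoxifene", "anti-aromatase"],
    "radiotherapie": ["photons", "electrons"],
    "chirurgie": ["tumorectomie", "mastectomie"],
}

#: filler vocabulary for templated pseudo-reports (accent-free pseudo-French)
REPORT_WORDS = (
    "patiente examen clinique sein droit gauche palpation nodule axillaire "
    "bilan controle traitement tolerance correcte surveillance evolution "
    "favorable stable dossier discute protocole cure prochaine consultation "
    "resultat biologie marqueurs normaux douleur absence signe local regional "
    "cicatrice souple adenopathie profil radiologique image dense tissu "
    "glandulaire decision poursuite suivi rapproche"
).split()

DEFAULT_TEMPLATES = (
    "compte rendu {department} du jour {procedure} realise",
    "consultation de suivi en {department} {procedure} sans particularite",
    "examen {procedure} effectue en {department} conclusion ci dessous",
)

#: multi-word (3–9 word) phrases planted into reports of relapse-bound
#: patients, mirroring discriminative sentences a phrase miner should recover.
DEFAULT_SIGNAL_PHRASES = (
    "sein en involution adipeuse partielle",
    "curage ganglionnaire axillaire realise ce jour",
)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = 500
    seed: int | None = None                    # mandatory at generation time
    prevalence: float = 0.062                  # target 3-year event rate
    visits_per_month: float = 1.5
    dept_procedures: dict = field(default_factory=lambda: dict(DEFAULT_DEPT_PROCEDURES))
    therapies: dict = field(default_factory=lambda: dict(DEFAULT_THERAPIES))
    markers: tuple = DEFAULT_MARKERS
    marker_missingness: float = 0.2            # per marker, per lab visit
    bio_visit_fraction: float = 0.5            # visits carrying lab values
    therapy_fraction: float = 0.4
    # event-model log-odds
    beta_npi: float = 0.5                      # per NPI unit above 4
    beta_subtype: dict = field(default_factory=lambda: {
        "Luminal": 0.0, "TNBC": 0.7, "HER2+/RH-": 0.4, "HER2+/RH+": 0.1})
    beta_abnormal_ca153: float = 0.5           # ever-abnormal CA 15-3
    # censoring (independent of covariates)
    censor_fraction: float = 0.10
    censor_range_days: tuple = (150, 2400)
    max_followup_days: int = 2600
    # clinical-feature missingness (exercises the imputation paths)
    missing_grade_frac: float = 0.05
    missing_nodes_frac: float = 0.05
    missing_size_frac: float = 0.05
    # reports
    templates: tuple = DEFAULT_TEMPLATES
    signal_phrases: tuple = DEFAULT_SIGNAL_PHRASES
    signal_phrase_prob_event: float = 0.0
    signal_phrase_prob_noevent: float = 0.0
    mean_report_words: float = 159.0           # mean body length of a report

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        for name in ("visits_per_month", "marker_missingness", "bio_visit_fraction",
                     "therapy_fraction", "censor_fraction", "mean_report_words"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Bisection for b0 such that mean(sigmoid(b0 + lp)) = prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + lp).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_marker_value(rng, spec, abnormal_prob=0.25):
    mid = 0.5 * (spec.normal_low + spec.normal_high)
    span = spec.normal_high - spec.normal_low
    if rng.random() < abnormal_prob:
        sign = 1.0 if rng.random() < 0.7 else -1.0
        value = mid + sign * span * (0.6 + 0.5 * rng.random())
    else:
        value = mid + span * 0.3 * rng.standard_normal()
    return float(max(value, 0.0))


def generate_cohort(config: SimConfig, return_truth: bool = False):
    """Draw a reproducible cohort of :class:`PatientRecord`.

    With ``return_truth=True`` also returns a per-patient dict of the latent
    quantities (NPI, prognostic group, event probability, raw event/censor
    times) used by calibration checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    depts = sorted(config.dept_procedures)
    therapies = sorted(config.therapies)

    drafts = []
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        age_dx = float(np.clip(rng.normal(55, 10), 25, 90))
        diagnosis = BASE_DATE + dt.timedelta(days=int(rng.integers(0, 3 * 365)))
        birth = diagnosis - dt.timedelta(days=int(age_dx * 365.25))
        surgery = diagnosis + dt.timedelta(days=int(rng.integers(20, 60)))
        grade = int(rng.choice([1, 2, 3], p=[0.25, 0.45, 0.30]))
        n_nodes = int(rng.poisson(1.2))
        size = float(np.clip(rng.lognormal(0.7, 0.45), 0.3, 9.0))
        tnm = "T1" if size < 2 else ("T2" if size < 5 else "T3")
        subtype = str(rng.choice(MOLECULAR_SUBTYPES, p=[0.65, 0.15, 0.08, 0.12]))

        window_start = diagnosis - dt.timedelta(days=170)
        window_end = surgery + dt.timedelta(days=350)
        months = (window_end - window_start).days / 30.0
        n_visits = max(3, int(rng.poisson(config.visits_per_month * months)))
        offsets = np.sort(rng.integers(0, (window_end - window_start).days + 1, n_visits))

        visits, abnormal_ca = [], False
        for k, off in enumerate(offsets):
            date = window_start + dt.timedelta(days=int(off))
            dept = depts[int(rng.integers(len(depts)))]
            proc = config.dept_procedures[dept][int(rng.integers(len(config.dept_procedures[dept])))]
            therapy = subtherapy = None
            if rng.random() < config.therapy_fraction:
                therapy = therapies[int(rng.integers(len(therapies)))]
                subs = config.therapies[therapy]
                subtherapy = subs[int(rng.integers(len(subs)))]
            bio = {}
            if rng.random() < config.bio_visit_fraction:
                for spec in config.markers:
                    if rng.random() >= config.marker_missingness:
                        bio[spec.name] = _draw_marker_value(rng, spec)
                if bio.get("CA15-3", 0.0) > config.markers[-1].normal_high:
                    abnormal_ca = True
            tumor = None
            if k == 0:
                tumor = size
            elif abs((date - surgery).days) < 7 and rng.random() < 0.8:
                tumor = float(max(0.3, size * rng.uniform(0.8, 1.2)))  # pathological size
            visits.append(VisitEvent(date=date, department=dept, procedure=proc,
                                     therapy=therapy, subtherapy=subtherapy,
                                     bio_values=bio, tumor_size_cm=tumor))

        npi = compute_npi(size, grade, n_nodes)
        lp = (config.beta_npi * (npi.npi - 4.0)
              + config.beta_subtype.get(subtype, 0.0)
              + config.beta_abnormal_ca153 * float(abnormal_ca))
        drafts.append({
            "pid": pid, "birth": birth, "diagnosis": diagnosis, "surgery": surgery,
            "grade": grade, "n_nodes": n_nodes, "size": size, "tnm": tnm,
            "subtype": subtype, "visits": visits, "npi": npi, "lp": lp,
            "abnormal_ca": abnormal_ca,
        })

    lps = np.array([d["lp"] for d in drafts])
    b0 = _calibrate_intercept(lps, config.prevalence)

    records, truth = [], []
    for d in drafts:
        p_event = float(_sigmoid(b0 + d["lp"]))
        lam = -np.log1p(-p_event) / DEFAULT_HORIZON_DAYS
        t_event = float(rng.exponential(1.0 / lam)) if lam > 0 else np.inf
        if rng.random() < config.censor_fraction:
            t_censor = float(rng.uniform(*config.censor_range_days))
        else:
            t_censor = float(config.max_followup_days)
        event = t_event <= t_censor
        followup = int(round(min(t_event, t_censor)))

        grade = None if rng.random() < config.missing_grade_frac else d["grade"]
        n_nodes = None if rng.random() < config.missing_nodes_frac else d["n_nodes"]
        visits = d["visits"]
        if rng.random() < config.missing_size_frac:
            visits = [dataclasses.replace(v, tumor_size_cm=None) for v in visits]

        records.append(PatientRecord(
            patient_id=d["pid"], birth_date=d["birth"], diagnosis_date=d["diagnosis"],
            surgery_date=d["surgery"], visits=visits, molecular_subtype=d["subtype"],
            tumor_grade=grade, n_nodes=n_nodes, tnm_stage=d["tnm"],
            dfs_event=event, followup_days=followup))
        truth.append({
            "patient_id": d["pid"], "npi": d["npi"].npi,
            "prognostic_group": d["npi"].prognostic_group, "p_event": p_event,
            "event_time": t_event, "censor_time": t_censor,
            "event_within_horizon": t_event <= DEFAULT_HORIZON_DAYS,
            "abnormal_ca": d["abnormal_ca"],
        })
    return (records, truth) if return_truth else records


def generate_reports(record: PatientRecord, config: SimConfig,
                     seed: int | None = None) -> PatientRecord:
    """Attach a templated pseudo-clinical report to every visit (in place).

    Relapse-bound records (``dfs_event`` true) receive one of the configured
    signal phrases with probability ``signal_phrase_prob_event``; others with
    ``signal_phrase_prob_noevent``.  Deterministic given the seed (default:
    derived from the config seed and the patient id)."""
    if seed is None:
        config.validate()
        seed = (config.seed * 1000003 + hash_stable(record.patient_id)) % (2 ** 31)
    rng = np.random.default_rng(seed)
    p_phrase = (config.signal_phrase_prob_event if record.dfs_event
                else config.signal_phrase_prob_noevent)
    for visit in record.visits:
        if not config.templates:
            visit.report_text = ""
            continue
        template = config.templates[int(rng.integers(len(config.templates)))]
        head = template.format(department=visit.department or "consultation",
                               procedure=visit.procedure or "examen")
        n_body = max(0, int(rng.poisson(max(config.mean_report_words - len(head.split()), 1))))
        body = [REPORT_WORDS[int(j)] for j in rng.integers(0, len(REPORT_WORDS), n_body)]
        if config.signal_phrases and rng.random() < p_phrase:
            phrase = config.signal_phrases[int(rng.integers(len(config.signal_phrases)))]
            pos = int(rng.integers(0, len(body) + 1))
            body[pos:pos] = phrase.split()
        visit.report_text = " ".join([head] + body)
    return record


def hash_stable(s: str) -> int:
    """Platform-stable string hash (FNV-1a, 32-bit)."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2 ** 32)
    return h
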