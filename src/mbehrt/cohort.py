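"""Clinical domain model and tabular trajectory tokenization.

Turns longitudinal breast-cancer EHR records into token sequences a BERT-style
encoder can consume.  Each visit contributes at most 17 feature tokens:
binarized values and discretized deltas for five biological markers (MONO,
LEUK, LYMP, PN, CA 15-3), department, procedure, therapy, subtherapy, age,
the dynamic Nottingham Prognostic Index prognostic group, and the molecular
subtype.  Missing features are simply skipped — the parallel modality layer
tells the encoder what kind of feature each token is, so no imputation token
is needed.  Four aligned layers (token, modality, delay bucket, position) form
a :class:`TokenizedTrajectory`, truncated to the first 512 entries.
"""

from __future__ import annotations

import collections
import datetime as dt
import json
import math
import re
import unicodedata
from dataclasses import dataclass, field, replace

# ---------------------------------------------------------------------------
# constants

MAX_TOKENS = 512
SPECIAL_TOKENS = {"PAD": 0, "CLS": 1, "SEP": 2, "MASK": 3, "UNK": 4}
N_SPECIALS = len(SPECIAL_TOKENS)
SPECIAL_MODALITY = "special"

#: Blamey's six prognostic groups, ordered from best to worst prognosis, with
#: the NPI upper bound of each band (boundaries belong to the lower band).
PROGNOSTIC_GROUPS = ("EPG", "GPG", "MPG I", "MPG II", "PPG", "VPPG")
_PG_UPPER = (2.4, 3.4, 4.4, 5.4, 6.4, math.inf)

#: Delay buckets: W0–W3 (weeks, [0, 28) days), M1–M12 (months of 30 days,
#: [28, 365)), LT for a year or more.  Every nonnegative day count maps to
#: exactly one bucket.
DELAY_BUCKETS = tuple(f"W{k}" for k in range(4)) + tuple(f"M{k}" for k in range(1, 13)) + ("LT",)

PRE_DIAGNOSIS_DAYS = 182      # "6 months" of history before diagnosis
POST_SURGERY_DAYS = 365       # index date = first surgery + 1 year
DEFAULT_HORIZON_DAYS = 1095   # 3-year disease-free survival horizon
MIN_VISITS = 3

MOLECULAR_SUBTYPES = ("Luminal", "TNBC", "HER2+/RH-", "HER2+/RH+")


def round_half_away(x: float) -> int:
    """Round half away from zero (used for ages and marker deltas)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class BioMarkerSpec:
    """Normal range and delta-discretization divisor for one serum marker."""

    name: str
    normal_low: float
    normal_high: float
    delta_unit_divisor: float = 10.0

    def __post_init__(self):
        if not self.normal_low < self.normal_high:
            raise ValueError(f"{self.name}: normal_low must be < normal_high")
        if self.delta_unit_divisor <= 0:
            raise ValueError(f"{self.name}: delta_unit_divisor must be positive")


#: Reference marker panel (ranges in conventional lab units).
DEFAULT_MARKERS = (
    BioMarkerSpec("MONO", 0.2, 0.8),
    BioMarkerSpec("LEUK", 4.0, 10.0),
    BioMarkerSpec("LYMP", 1.0, 4.0),
    BioMarkerSpec("PN", 1.5, 7.5),
    BioMarkerSpec("CA15-3", 0.0, 30.0),
)


@dataclass
class VisitEvent:
    date: dt.date
    department: str | None = None
    procedure: str | None = None
    therapy: str | None = None
    subtherapy: str | None = None
    bio_values: dict = field(default_factory=dict)
    tumor_size_cm: float | None = None
    report_text: str | None = None

    def __post_init__(self):
        if self.date is None:
            raise ValueError("visit date is required")
        if not any((self.department, self.procedure, self.therapy, self.subtherapy,
                    self.bio_values, self.tumor_size_cm is not None,
                    self.report_text is not None)):
            raise ValueError("visit must carry at least one field besides the date")


@dataclass
class PatientRecord:
    patient_id: str
    birth_date: dt.date | None
    diagnosis_date: dt.date
    surgery_date: dt.date
    visits: list
    molecular_subtype: str | None = None
    tumor_grade: int | None = None
    n_nodes: int | None = None
    tnm_stage: str | None = None
    dfs_event: bool | None = None
    followup_days: int | None = None

    def __post_init__(self):
        if self.surgery_date < self.diagnosis_date:
            raise ValueError(f"{self.patient_id}: surgery_date precedes diagnosis_date")
        dates = [v.date for v in self.visits]
        if dates != sorted(dates):
            raise ValueError(f"{self.patient_id}: visits must be chronologically ordered")
        if self.tumor_grade is not None and self.tumor_grade not in (1, 2, 3):
            raise ValueError(f"{self.patient_id}: tumor_grade must be 1, 2 or 3")
        if self.followup_days is not None and self.followup_days < 0:
            raise ValueError(f"{self.patient_id}: followup_days must be nonnegative")

    @property
    def index_date(self) -> dt.date:
        return self.surgery_date + dt.timedelta(days=POST_SURGERY_DAYS)


@dataclass(frozen=True)
class NPIResult:
    npi: float
    node_stage: int
    prognostic_group: str


# ---------------------------------------------------------------------------
# NPI / prognostic groups

def compute_node_stage(n_nodes: int) -> int:
    """Lymph-node stage: 1 for 0 nodes, 2 for 1–3, 3 for more than 3."""
    if not isinstance(n_nodes, (int,)) or isinstance(n_nodes, bool) or n_nodes < 0:
        raise ValueError(f"n_nodes must be a nonnegative integer, got {n_nodes!r}")
    if n_nodes == 0:
        return 1
    return 2 if n_nodes <= 3 else 3


def assign_prognostic_group(npi: float) -> str:
    """Map an NPI score to Blamey's six bands (EPG ≤ 2.4 … VPPG > 6.4)."""
    if npi < 0:
        raise ValueError("NPI must be nonnegative")
    for group, upper in zip(PROGNOSTIC_GROUPS, _PG_UPPER):
        if npi <= upper:
            return group
    raise AssertionError("unreachable")


def compute_npi(tumor_size_cm: float, grade: int, n_nodes: int) -> NPIResult:
    """NPI = 0.2 × tumor size (cm) + tumor grade + lymph-node stage."""
    if tumor_size_cm is None or grade is None or n_nodes is None:
        raise ValueError("all NPI inputs must be non-missing; impute first (impute_for_dnpi)")
    if tumor_size_cm < 0:
        raise ValueError("tumor size must be nonnegative")
    if grade not in (1, 2, 3):
        raise ValueError("grade must be 1, 2 or 3")
    stage = compute_node_stage(n_nodes)
    npi = 0.2 * tumor_size_cm + grade + stage
    return NPIResult(npi=npi, node_stage=stage, prognostic_group=assign_prognostic_group(npi))


def _first_tumor_size(record: PatientRecord) -> float | None:
    for v in record.visits:
        if v.tumor_size_cm is not None:
            return v.tumor_size_cm
    return None


def impute_for_dnpi(record: PatientRecord, cohort) -> tuple | None:
    """Complete (size, grade, nodes) for the dNPI: missing nodes → 0, missing
    grade → G2, missing size → modal size among cohort members with the same
    TNM stage.  Returns None when the dNPI is unavailable (all three inputs
    missing, or size missing with no TNM peer)."""
    size = _first_tumor_size(record)
    grade, nodes = record.tumor_grade, record.n_nodes
    if size is None and grade is None and nodes is None:
        return None
    if nodes is None:
        nodes = 0
    if grade is None:
        grade = 2
    if size is None:
        peers = [
            s for r in cohort
            if r.patient_id != record.patient_id and r.tnm_stage == record.tnm_stage
            and record.tnm_stage is not None and (s := _first_tumor_size(r)) is not None
        ]
        if not peers:
            return None
        counts = collections.Counter(peers)
        top = max(counts.values())
        size = min(s for s, c in counts.items() if c == top)  # smallest mode: deterministic
    return size, grade, nodes


# ---------------------------------------------------------------------------
# discretization

def binarize_bio(value: float, spec: BioMarkerSpec) -> int:
    """1 if the measurement lies outside the marker's normal range, else 2.
    The range is closed: boundary values count as normal."""
    if value is None:
        raise ValueError("missing value: caller should skip the token instead")
    return 1 if (value < spec.normal_low or value > spec.normal_high) else 2


def delta_token(v_t: float, v_prev: float, spec: BioMarkerSpec) -> int | None:
    """Discretized change between consecutive observations of one marker:
    round((v_t − v_prev) / divisor).  A zero token is not emitted."""
    if v_prev is None:
        return None
    tok = round_half_away((v_t - v_prev) / spec.delta_unit_divisor)
    return None if tok == 0 else tok


def discretize_age(birth_date: dt.date | None, visit_date: dt.date) -> int | None:
    """Age at visit in years, rounded to the nearest integer."""
    if birth_date is None:
        return None
    if visit_date < birth_date:
        raise ValueError("visit predates birth")
    return round_half_away((visit_date - birth_date).days / 365.25)


def discretize_delay(days: int) -> str:
    """Inter-visit gap → delay bucket (W0–W3, M1–M12, LT)."""
    if days < 0:
        raise ValueError("delay must be nonnegative")
    if days < 28:
        return f"W{days // 7}"
    if days < 365:
        return f"M{min(12, math.ceil(days / 30))}"
    return "LT"


# ---------------------------------------------------------------------------
# cohort-level preprocessing

def filter_bio_features(records, marker_names=None, max_missing: float = 0.30):
    """Keep markers missing in fewer than `max_missing` of the lab visits
    (visits carrying at least one biological measurement)."""
    if not records:
        raise ValueError("empty cohort")
    if marker_names is None:
        marker_names = sorted({m for r in records for v in r.visits for m in v.bio_values})
    lab_visits = [v for r in records for v in r.visits if v.bio_values]
    if not lab_visits:
        return []
    kept = []
    for name in marker_names:
        observed = sum(1 for v in lab_visits if v.bio_values.get(name) is not None)
        missing_frac = 1.0 - observed / len(lab_visits)
        if missing_frac < max_missing:
            kept.append(name)
    return kept


_PUNCT_RE = re.compile(r"[^0-9a-z ]+")


def strip_accents(text: str) -> str:
    return "".join(c for c in unicodedata.normalize("NFKD", text)
                   if not unicodedata.combining(c))


def normalize_label(raw: str, synonym_map: dict | None = None,
                    min_count: int = 100, corpus_counts: dict | None = None) -> str | None:
    """Canonicalize a department/procedure label: lowercase, strip accents,
    punctuation and special characters, merge synonyms, and drop labels seen
    fewer than `min_count` times in the whole corpus."""
    label = _PUNCT_RE.sub(" ", strip_accents(raw.lower()))
    label = " ".join(label.split())
    if synonym_map:
        label = synonym_map.get(label, label)
    if not label:
        return None
    if corpus_counts is not None and corpus_counts.get(label, 0) < min_count:
        return None
    return label


def select_history_window(record: PatientRecord):
    """Visits from 6 months (182 days) before diagnosis to one year (365 days)
    after the first surgery, order preserved."""
    lo = record.diagnosis_date - dt.timedelta(days=PRE_DIAGNOSIS_DAYS)
    hi = record.surgery_date + dt.timedelta(days=POST_SURGERY_DAYS)
    return [v for v in record.visits if lo <= v.date <= hi]


#: Exclusion reason codes used by :func:`apply_cohort_filters`.
EXCL_PRE_INDEX_RELAPSE = "pre_index_relapse"
EXCL_INSUFFICIENT_FOLLOWUP = "insufficient_followup"
EXCL_TOO_FEW_VISITS = "too_few_visits"


def apply_cohort_filters(records, horizon_days: int = DEFAULT_HORIZON_DAYS):
    """Label records for the 3-year DFS task and exclude those that cannot be
    labelled: relapse before the index date (surgery + 1 year), censoring
    before the horizon, or fewer than 3 visits.  Returns (labelled records,
    exclusion log); each excluded record carries exactly one reason code, the
    first that applies in the order above.  Kept records get
    ``dfs_event = event occurred within the horizon``."""
    kept, exclusions = [], []
    for r in records:
        if r.followup_days is None or r.dfs_event is None:
            raise ValueError(f"{r.patient_id}: outcome fields required")
        if r.dfs_event and r.followup_days < POST_SURGERY_DAYS:
            exclusions.append((r.patient_id, EXCL_PRE_INDEX_RELAPSE))
        elif not r.dfs_event and r.followup_days < horizon_days:
            exclusions.append((r.patient_id, EXCL_INSUFFICIENT_FOLLOWUP))
        elif len(r.visits) < MIN_VISITS:
            exclusions.append((r.patient_id, EXCL_TOO_FEW_VISITS))
        else:
            kept.append(replace(r, visits=list(r.visits),
                                dfs_event=bool(r.dfs_event and r.followup_days <= horizon_days)))
    return kept, exclusions


# ---------------------------------------------------------------------------
# vocabulary

def modality_names(markers=DEFAULT_MARKERS):
    """The 17 feature modalities, in canonical within-visit order."""
    names = [f"bio_{m.name}" for m in markers]
    names += [f"delta_{m.name}" for m in markers]
    names += ["department", "procedure", "therapy", "subtherapy", "age", "dnpi", "subtype"]
    return names


class Vocabulary:
    """Token / modality / delay-bucket id maps with reserved special ids."""

    def __init__(self, token_to_id: dict, modality_to_id: dict):
        self.token_to_id = dict(token_to_id)
        self.modality_to_id = dict(modality_to_id)
        self.delay_to_id = {b: i for i, b in enumerate(DELAY_BUCKETS)}
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("token ids must be dense and unique")
        for name, sid in SPECIAL_TOKENS.items():
            if self.token_to_id.get(name) != sid:
                raise ValueError(f"special token {name} must have id {sid}")

    def __len__(self):
        return len(self.token_to_id)

    @property
    def n_modalities(self):
        return len(self.modality_to_id)

    @property
    def n_delays(self):
        return len(self.delay_to_id)

    @property
    def content_ids(self):
        return [i for t, i in self.token_to_id.items() if t not in SPECIAL_TOKENS]

    def encode(self, token: str) -> int:
        return self.token_to_id.get(token, SPECIAL_TOKENS["UNK"])

    @classmethod
    def build(cls, token_modality_streams, markers=DEFAULT_MARKERS) -> "Vocabulary":
        """Build from the training cohort's (token, modality) streams; unseen
        tokens at inference map to UNK."""
        tokens = sorted({tok for stream in token_modality_streams for tok, _ in stream})
        token_to_id = dict(SPECIAL_TOKENS)
        for i, t in enumerate(tokens):
            token_to_id[t] = N_SPECIALS + i
        modality_to_id = {SPECIAL_MODALITY: 0}
        for i, m in enumerate(modality_names(markers)):
            modality_to_id[m] = i + 1
        return cls(token_to_id, modality_to_id)

    def to_json(self) -> str:
        return json.dumps({"tokens": self.token_to_id, "modalities": self.modality_to_id},
                          ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        obj = json.loads(payload)
        return cls(obj["tokens"], obj["modalities"])


# ---------------------------------------------------------------------------
# tokenization

@dataclass
class TokenizerContext:
    """Mutable per-patient state threaded through visit tokenization."""

    markers: tuple = DEFAULT_MARKERS
    prev_bio: dict = field(default_factory=dict)
    tumor_size_cm: float | None = None
    tumor_grade: int | None = None
    n_nodes: int | None = None
    birth_date: dt.date | None = None
    molecular_subtype: str | None = None

    @classmethod
    def for_record(cls, record: PatientRecord, cohort=None, markers=DEFAULT_MARKERS):
        """Initial context with imputed dNPI inputs (missing nodes → 0, grade
        → G2, size → TNM-peer mode).  When no baseline size is available the
        prognostic-group token stays pending until a visit measures one; a
        record with none of the three inputs never emits it."""
        size = grade = nodes = None
        if (_first_tumor_size(record) is not None or record.tumor_grade is not None
                or record.n_nodes is not None):
            grade = record.tumor_grade if record.tumor_grade is not None else 2
            nodes = record.n_nodes if record.n_nodes is not None else 0
            completed = impute_for_dnpi(record, cohort or [])
            if completed is not None:
                size = completed[0]
        return cls(markers=markers, tumor_size_cm=size, tumor_grade=grade,
                   n_nodes=nodes, birth_date=record.birth_date,
                   molecular_subtype=record.molecular_subtype)


def tokenize_visit(visit: VisitEvent, context: TokenizerContext):
    """Emit the visit's (token, modality) pairs in canonical order: bio binary
    tokens, bio delta tokens, department, procedure, therapy, subtherapy, age,
    dNPI prognostic group, molecular subtype.  Missing features are skipped;
    at most 17 pairs are produced.  Updates `context` (previous marker values,
    carried-forward tumor size) in place."""
    pairs = []
    for spec in context.markers:
        value = visit.bio_values.get(spec.name)
        if value is not None:
            pairs.append((f"{spec.name}:{binarize_bio(value, spec)}", f"bio_{spec.name}"))
    for spec in context.markers:
        value = visit.bio_values.get(spec.name)
        if value is not None:
            tok = delta_token(value, context.prev_bio.get(spec.name), spec)
            if tok is not None:
                pairs.append((f"d{spec.name}:{tok:+d}", f"delta_{spec.name}"))
            context.prev_bio[spec.name] = value
    if visit.department is not None:
        pairs.append((f"DEPT:{visit.department}", "department"))
    if visit.procedure is not None:
        pairs.append((f"PROC:{visit.procedure}", "procedure"))
    if visit.therapy is not None:
        pairs.append((f"THER:{visit.therapy}", "therapy"))
    if visit.subtherapy is not None:
        pairs.append((f"SUBTHER:{visit.subtherapy}", "subtherapy"))
    age = discretize_age(context.birth_date, visit.date)
    if age is not None:
        pairs.append((f"AGE:{age}", "age"))
    if visit.tumor_size_cm is not None:
        context.tumor_size_cm = visit.tumor_size_cm  # dNPI is dynamic in size
    if (context.tumor_size_cm is not None and context.tumor_grade is not None
            and context.n_nodes is not None):
        pg = compute_npi(context.tumor_size_cm, context.tumor_grade,
                         context.n_nodes).prognostic_group
        pairs.append((f"PG:{pg}", "dnpi"))
    if context.molecular_subtype is not None:
        pairs.append((f"SUBTYPE:{context.molecular_subtype}", "subtype"))
    return pairs


@dataclass
class TokenizedTrajectory:
    """Four aligned id layers for one patient, at most 512 entries long."""

    patient_id: str
    token_ids: list
    modality_ids: list
    delay_ids: list
    positions: list
    label: bool | None = None

    def __post_init__(self):
        n = len(self.token_ids)
        if not (len(self.modality_ids) == len(self.delay_ids) == len(self.positions) == n):
            raise ValueError("layers must have equal length")
        if n > MAX_TOKENS:
            raise ValueError(f"trajectory exceeds {MAX_TOKENS} tokens")
        if n and self.token_ids[0] != SPECIAL_TOKENS["CLS"]:
            raise ValueError("first token must be CLS")

    def __len__(self):
        return len(self.token_ids)

    def to_json(self) -> str:
        return json.dumps({
            "patient_id": self.patient_id, "token_ids": list(map(int, self.token_ids)),
            "modality_ids": list(map(int, self.modality_ids)),
            "delay_ids": list(map(int, self.delay_ids)),
            "positions": list(map(int, self.positions)),
            "label": self.label,
        })

    @classmethod
    def from_json(cls, payload: str) -> "TokenizedTrajectory":
        obj = json.loads(payload)
        return cls(obj["patient_id"], obj["token_ids"], obj["modality_ids"],
                   obj["delay_ids"], obj["positions"], obj["label"])


def token_modality_stream(record: PatientRecord, cohort=None, markers=DEFAULT_MARKERS):
    """All (token, modality) pairs of a record's in-window visits; used to
    build the vocabulary from the training cohort."""
    ctx = TokenizerContext.for_record(record, cohort, markers)
    pairs = []
    for visit in select_history_window(record):
        pairs.extend(tokenize_visit(visit, ctx))
    return pairs


def build_trajectory(record: PatientRecord, vocab: Vocabulary, cohort=None,
                     markers=DEFAULT_MARKERS, max_len: int = MAX_TOKENS) -> TokenizedTrajectory:
    """CLS + per-visit token blocks, each closed by SEP; the delay layer
    carries each visit's bucket (gap to the previous visit) on every token of
    that visit including its SEP; CLS gets W0.  Truncated to the first
    `max_len` entries (mid-visit truncation allowed)."""
    visits = select_history_window(record)
    if not visits:
        raise ValueError(f"{record.patient_id}: no visits in the history window")
    ctx = TokenizerContext.for_record(record, cohort, markers)
    cls_id, sep_id = SPECIAL_TOKENS["CLS"], SPECIAL_TOKENS["SEP"]
    sp_mod, w0 = 0, 0
    tokens, mods, delays = [cls_id], [sp_mod], [w0]
    prev_date = None
    for visit in visits:
        gap = 0 if prev_date is None else (visit.date - prev_date).days
        bucket = vocab.delay_to_id[discretize_delay(gap)]
        prev_date = visit.date
        for token, modality in tokenize_visit(visit, ctx):
            tokens.append(vocab.encode(token))
            mods.append(vocab.modality_to_id[modality])
            delays.append(bucket)
        tokens.append(sep_id)
        mods.append(sp_mod)
        delays.append(bucket)
    tokens, mods, delays = tokens[:max_len], mods[:max_len], delays[:max_len]
    return TokenizedTrajectory(record.patient_id, tokens, mods, delays,
                               list(range(len(tokens))), label=record.dfs_event)


def save_trajectories(trajectories, path) -> None:
    with open(path, "w") as fh:
        for t in trajectories:
            fh.write(t.to_json() + "\n")


def load_trajectories(path):
    with open(path) as fh:
        return [TokenizedTrajectory.from_json(line) for line in fh if line.strip()]
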