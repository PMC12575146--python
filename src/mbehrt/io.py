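"""Disk formats for cohorts: a per-patient CSV (static features, outcome), a
wide per-visit CSV, and a reports JSONL — all dates ISO-8601."""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import pandas as pd

from .cohort import PatientRecord, VisitEvent, DEFAULT_MARKERS

PATIENTS_CSV = "patients.csv"
VISITS_CSV = "visits.csv"
REPORTS_JSONL = "reports.jsonl"


def _opt(value):
    return None if pd.isna(value) else value


def save_cohort(records, out_dir, markers=DEFAULT_MARKERS) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, visits, reports = [], [], []
    for r in records:
        patients.append({
            "patient_id": r.patient_id,
            "birth_date": r.birth_date.isoformat() if r.birth_date else None,
            "diagnosis_date": r.diagnosis_date.isoformat(),
            "surgery_date": r.surgery_date.isoformat(),
            "molecular_subtype": r.molecular_subtype,
            "tumor_grade": r.tumor_grade, "n_nodes": r.n_nodes,
            "tnm_stage": r.tnm_stage, "dfs_event": r.dfs_event,
            "followup_days": r.followup_days,
        })
        for v in r.visits:
            row = {"patient_id": r.patient_id, "date": v.date.isoformat(),
                   "department": v.department, "procedure": v.procedure,
                   "therapy": v.therapy, "subtherapy": v.subtherapy,
                   "tumor_size_cm": v.tumor_size_cm}
            for m in markers:
                row[f"bio_{m.name}"] = v.bio_values.get(m.name)
            visits.append(row)
            if v.report_text is not None:
                reports.append({"patient_id": r.patient_id, "date": v.date.isoformat(),
                                "department": v.department, "procedure": v.procedure,
                                "text": v.report_text})
    pd.DataFrame(patients).to_csv(out / PATIENTS_CSV, index=False)
    pd.DataFrame(visits).to_csv(out / VISITS_CSV, index=False)
    with open(out / REPORTS_JSONL, "w") as fh:
        for rec in reports:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def load_cohort(data_dir, markers=DEFAULT_MARKERS):
    data = Path(data_dir)
    patients = pd.read_csv(data / PATIENTS_CSV)
    visits = pd.read_csv(data / VISITS_CSV)
    report_map = {}
    path = data / REPORTS_JSONL
    if path.exists():
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    report_map[(rec["patient_id"], rec["date"])] = rec["text"]
    records = []
    for _, p in patients.iterrows():
        rows = visits[visits.patient_id == p.patient_id].sort_values("date")
        visit_list = []
        for _, v in rows.iterrows():
            bio = {m.name: float(val) for m in markers
                   if (val := _opt(v.get(f"bio_{m.name}"))) is not None}
            visit_list.append(VisitEvent(
                date=dt.date.fromisoformat(v.date),
                department=_opt(v.department), procedure=_opt(v.procedure),
                therapy=_opt(v.therapy), subtherapy=_opt(v.subtherapy),
                bio_values=bio,
                tumor_size_cm=_opt(v.tumor_size_cm),
                report_text=report_map.get((p.patient_id, v.date))))
        records.append(PatientRecord(
            patient_id=p.patient_id,
            birth_date=dt.date.fromisoformat(p.birth_date) if _opt(p.birth_date) else None,
            diagnosis_date=dt.date.fromisoformat(p.diagnosis_date),
            surgery_date=dt.date.fromisoformat(p.surgery_date),
            visits=visit_list,
            molecular_subtype=_opt(p.molecular_subtype),
            tumor_grade=int(g) if (g := _opt(p.tumor_grade)) is not None else None,
            n_nodes=int(n) if (n := _opt(p.n_nodes)) is not None else None,
            tnm_stage=_opt(p.tnm_stage),
            dfs_event=bool(e) if (e := _opt(p.dfs_event)) is not None else None,
            followup_days=int(f) if (f := _opt(p.followup_days)) is not None else None))
    return records
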