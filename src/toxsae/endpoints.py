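"""Late-toxicity endpoint derivation from longitudinal CTCAE-style grades.

Each endpoint is a binary case/control label derived from ordinal symptom
grades recorded at baseline (pre-radiotherapy), 12 and 24 months.  A patient
is a case when a follow-up grade reaches the endpoint threshold at 12 or 24
months.  Patients already at or above the threshold at baseline are handled
by a configurable policy (excluded from the analysis by default, or recoded
as controls when follow-up does not worsen).  Patients with collagen
vascular disease are always excluded (known intrinsic radiosensitivity);
urinary endpoints additionally exclude transurethral bladder resection and
anti-muscarinic medication (confounders of urinary scoring), and rectal
bleeding excludes pre-treatment hemorrhoids.

The five shipped endpoint definitions:

====================  =========  =====================================
endpoint              threshold  extra exclusions
====================  =========  =====================================
rectal_bleeding       grade >=1  hemorrhoids at baseline
urinary_frequency     grade >=2  TURB / anti-muscarinics
haematuria            grade >=1  TURB / anti-muscarinics
nocturia              grade >=2  TURB / anti-muscarinics
decreased_stream      grade >=1  TURB / anti-muscarinics
====================  =========  =====================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

Grade = int | None

CASE = "case"
CONTROL = "control"
EXCLUDED = "excluded"

SYMPTOMS = (
    "rectal_bleeding",
    "urinary_frequency",
    "haematuria",
    "nocturia",
    "decreased_stream",
)

_FLAGS = ("hemorrhoids", "turb", "antimuscarinic", "cvd")


@dataclass
class ToxicityRecord:
    """Per-patient grade trajectories (baseline, 12 m, 24 m) plus flags."""

    patient_id: str
    grades: dict[str, tuple[Grade, Grade, Grade]] = field(default_factory=dict)
    hemorrhoids_baseline: bool = False
    turb: bool = False
    antimuscarinic: bool = False
    collagen_vascular_disease: bool = False

    def __post_init__(self) -> None:
        for sym, traj in self.grades.items():
            for g in traj:
                if g is not None and g not in range(5):
                    raise ValueError(
                        f"{self.patient_id}/{sym}: grade {g!r} outside 0-4"
                    )


@dataclass(frozen=True)
class EndpointSpec:
    """Definition of one binary endpoint over a symptom trajectory."""

    name: str
    grade_threshold: int
    urinary: bool
    exclude_hemorrhoids: bool = False
    baseline_policy: str = "exclude"  # or "recode_control"

    def __post_init__(self) -> None:
        if self.grade_threshold < 1:
            raise ValueError("grade_threshold must be >= 1")
        if self.baseline_policy not in ("exclude", "recode_control"):
            raise ValueError(f"unknown baseline_policy {self.baseline_policy!r}")

    def with_policy(self, policy: str) -> "EndpointSpec":
        return EndpointSpec(
            self.name, self.grade_threshold, self.urinary,
            self.exclude_hemorrhoids, policy,
        )


ENDPOINT_SPECS: dict[str, EndpointSpec] = {
    "rectal_bleeding": EndpointSpec("rectal_bleeding", 1, False, True),
    "urinary_frequency": EndpointSpec("urinary_frequency", 2, True),
    "haematuria": EndpointSpec("haematuria", 1, True),
    "nocturia": EndpointSpec("nocturia", 2, True),
    "decreased_stream": EndpointSpec("decreased_stream", 1, True),
}


@dataclass
class EndpointLabels:
    """Case/control/excluded status per patient for one endpoint."""

    endpoint: str
    status: pd.Series  # index patient_id, values case/control/excluded
    exclusion_reason: pd.Series  # index patient_id, NaN unless excluded

    @property
    def n_cases(self) -> int:
        return int((self.status == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == CONTROL).sum())

    @property
    def n_excluded(self) -> int:
        return int((self.status == EXCLUDED).sum())

    def binary(self) -> pd.Series:
        """0/1 outcome over non-excluded patients (1 = case)."""
        kept = self.status[self.status != EXCLUDED]
        return (kept == CASE).astype(int)


def _classify(rec: ToxicityRecord, spec: EndpointSpec) -> tuple[str, str | None]:
    if rec.collagen_vascular_disease:
        return EXCLUDED, "collagen_vascular_disease"
    if spec.urinary and rec.turb:
        return EXCLUDED, "turb"
    if spec.urinary and rec.antimuscarinic:
        return EXCLUDED, "antimuscarinic"
    if spec.exclude_hemorrhoids and rec.hemorrhoids_baseline:
        return EXCLUDED, "hemorrhoids_baseline"

    base, m12, m24 = rec.grades.get(spec.name, (None, None, None))
    followup = [g for g in (m12, m24) if g is not None]
    T = spec.grade_threshold

    if base is not None and base >= T:
        if spec.baseline_policy == "exclude":
            return EXCLUDED, "baseline_prevalent"
        if not followup:
            return EXCLUDED, "no_followup"
        # recode_control: non-worsening trajectories are controls; a
        # follow-up grade strictly above the threshold still counts as a case
        if max(followup) > T:
            return CASE, None
        return CONTROL, None

    if not followup:
        return EXCLUDED, "no_followup"
    return (CASE, None) if max(followup) >= T else (CONTROL, None)


def derive_labels(records: Iterable[ToxicityRecord], spec: EndpointSpec) -> EndpointLabels:
    """Apply one endpoint definition to a cohort of grade trajectories."""
    ids, statuses, reasons = [], [], []
    for rec in records:
        status, reason = _classify(rec, spec)
        ids.append(rec.patient_id)
        statuses.append(status)
        reasons.append(reason)
    idx = pd.Index(ids, name="patient_id")
    return EndpointLabels(
        endpoint=spec.name,
        status=pd.Series(statuses, index=idx, name="status"),
        exclusion_reason=pd.Series(reasons, index=idx, name="exclusion_reason", dtype=object),
    )


def prevalence(labels: EndpointLabels) -> float:
    """Case fraction among non-excluded patients."""
    denom = labels.n_cases + labels.n_controls
    if denom == 0:
        raise ValueError("no non-excluded patients; prevalence undefined")
    return labels.n_cases / denom


def format_prevalence(labels: EndpointLabels) -> str:
    """Percentage to one decimal, as conventionally reported (e.g. '11.7%')."""
    return f"{100 * prevalence(labels):.1f}%"


# --- phenotype table I/O -------------------------------------------------

def records_to_frame(records: Iterable[ToxicityRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {"patient_id": rec.patient_id}
        for sym, (b, m12, m24) in rec.grades.items():
            row[f"{sym}_base"], row[f"{sym}_m12"], row[f"{sym}_m24"] = b, m12, m24
        row["hemorrhoids"] = int(rec.hemorrhoids_baseline)
        row["turb"] = int(rec.turb)
        row["antimuscarinic"] = int(rec.antimuscarinic)
        row["cvd"] = int(rec.collagen_vascular_disease)
        rows.append(row)
    return pd.DataFrame(rows)


def write_phenotypes(records: Iterable[ToxicityRecord], path: str | Path) -> None:
    """Write one row per patient; missing grades become empty fields."""
    df = records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%g")


def read_phenotypes(path: str | Path) -> list[ToxicityRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    symptoms = sorted(
        {c[: -len("_base")] for c in df.columns if c.endswith("_base")}
    )

    def _grade(v: object) -> Grade:
        return None if pd.isna(v) else int(v)

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        grades: dict[str, tuple[Grade, Grade, Grade]] = {}
        for sym in symptoms:
            grades[sym] = (
                _grade(d.get(f"{sym}_base")),
                _grade(d.get(f"{sym}_m12")),
                _grade(d.get(f"{sym}_m24")),
            )
        records.append(
            ToxicityRecord(
                patient_id=str(d["patient_id"]),
                grades=grades,
                hemorrhoids_baseline=bool(d.get("hemorrhoids", 0)),
                turb=bool(d.get("turb", 0)),
                antimuscarinic=bool(d.get("antimuscarinic", 0)),
                collagen_vascular_disease=bool(d.get("cvd", 0)),
            )
        )
    return records
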