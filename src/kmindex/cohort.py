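"""Cohort tables: reading, validation, writing and inclusion filtering.

The canonical on-disk form is a UTF-8 comma-separated file with a versioned
schema line (``#schema=kmindex-cohort-v1``) followed by a header row. Blank
cells mean *missing*, never zero. Exclusion reasons are carried as explicit
flags so the study's inclusion rules become an auditable filtering step
rather than silent row drops.
"""

from __future__ import annotations

import csv
import io
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .core import (
    MTICI,
    UNKNOWN,
    PerfusionVolumes,
    TreatmentRecord,
    ValidationError,
)

__all__ = [
    "EXCLUSION_REASONS",
    "VESSELS",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "SCHEMA_VERSION",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_filters",
]

SCHEMA_VERSION = "kmindex-cohort-v1"

#: Exclusion reasons in the fixed order of the study's criteria table; a
#: patient with several reasons is tallied once under the first one.
EXCLUSION_REASONS = (
    "large_hemorrhage",
    "iatrogenic_bleed_gt20ml",
    "ctp_technical_failure",
    "no_followup_imaging",
)

VESSELS = ("CCA", "ICA", "carotid-T", "M1", "M2", "M3", "combined")

_COLUMNS = [
    "id", "age", "sex", "occluded_vessel", "nihss",
    "v_core", "v_penumbra", "v_mip", "v_mtt",
    "thrombectomy", "mtici", "rtpa", "onset_to_groin_hours",
    "mls_max_mm", "dhc", "death_7d", "exclusion_flags",
]


class CohortValidationError(ValidationError):
    """Aggregates row-numbered parse/validation diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("cohort validation failed:\n" + "\n".join(self.problems))


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: float
    sex: str  # "f" / "m"
    occluded_vessel: str
    volumes: PerfusionVolumes
    treatment: TreatmentRecord
    nihss: int | None = None
    mls_max_mm: float | None = None
    dhc: bool = False
    death_7d: bool = False
    exclusion_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.occluded_vessel not in VESSELS:
            raise ValidationError(f"unknown occluded vessel {self.occluded_vessel!r}")
        if self.sex not in ("f", "m"):
            raise ValidationError(f"sex must be 'f' or 'm', got {self.sex!r}")
        if self.mls_max_mm is not None and self.mls_max_mm < 0:
            raise ValidationError(f"mls_max_mm must be >= 0, got {self.mls_max_mm!r}")
        unknown = set(self.exclusion_flags) - set(EXCLUSION_REASONS)
        if unknown:
            raise ValidationError(f"unknown exclusion flags {sorted(unknown)}")

    @property
    def included(self) -> bool:
        return not self.exclusion_flags


@dataclass(frozen=True)
class Cohort:
    patients: tuple[PatientRecord, ...]
    source: str | None = None
    filter_log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def _parse_bool(text: str, row: int, col: str, problems: list[str]) -> bool:
    t = text.strip().lower()
    if t in ("1", "true", "yes", "y"):
        return True
    if t in ("0", "false", "no", "n", ""):
        return False
    problems.append(f"row {row}: column {col!r}: cannot parse boolean {text!r}")
    return False


def _parse_float(text: str, row: int, col: str, problems: list[str]) -> float | None:
    t = text.strip()
    if not t:
        return None
    try:
        return float(t)
    except ValueError:
        problems.append(f"row {row}: column {col!r}: cannot parse number {text!r}")
        return None


def _row_to_record(rowno: int, row: dict[str, str], problems: list[str]) -> PatientRecord | None:
    before = len(problems)
    age = _parse_float(row["age"], rowno, "age", problems)
    nihss_f = _parse_float(row["nihss"], rowno, "nihss", problems)
    vols_raw = {c: _parse_float(row[c], rowno, c, problems) for c in
                ("v_core", "v_penumbra", "v_mip", "v_mtt")}
    thrombectomy = _parse_bool(row["thrombectomy"], rowno, "thrombectomy", problems)
    rtpa = _parse_bool(row["rtpa"], rowno, "rtpa", problems)
    dhc = _parse_bool(row["dhc"], rowno, "dhc", problems)
    death = _parse_bool(row["death_7d"], rowno, "death_7d", problems)
    mls = _parse_float(row["mls_max_mm"], rowno, "mls_max_mm", problems)
    onset = _parse_float(row["onset_to_groin_hours"], rowno, "onset_to_groin_hours", problems)

    mtici = None
    mtici_text = row["mtici"].strip()
    if mtici_text:
        try:
            mtici = MTICI.parse(mtici_text)
        except ValidationError as exc:
            problems.append(f"row {rowno}: {exc}")
    flags_text = row["exclusion_flags"].strip()
    flags = frozenset(f for f in flags_text.split(";") if f) if flags_text else frozenset()

    if len(problems) > before:
        return None
    if any(v is None for v in vols_raw.values()) or age is None:
        problems.append(f"row {rowno}: age and all four volumes are required")
        return None
    try:
        volumes = PerfusionVolumes(
            v_core=vols_raw["v_core"], v_penumbra=vols_raw["v_penumbra"],
            v_mip=vols_raw["v_mip"], v_mtt=vols_raw["v_mtt"],
        )
        treatment = TreatmentRecord(
            thrombectomy_performed=thrombectomy,
            mtici=mtici,
            rtpa=rtpa,
            onset_to_groin_hours=UNKNOWN if onset is None else onset,
        )
        return PatientRecord(
            id=row["id"].strip(),
            age=age,
            sex=row["sex"].strip().lower(),
            occluded_vessel=row["occluded_vessel"].strip(),
            nihss=None if nihss_f is None else int(round(nihss_f)),
            volumes=volumes,
            treatment=treatment,
            mls_max_mm=mls,
            dhc=dhc,
            death_7d=death,
            exclusion_flags=flags,
        )
    except ValidationError as exc:
        problems.append(f"row {rowno}: {exc}")
        return None


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV; raises with row-numbered diagnostics."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return _read_cohort_text(text, source=str(path))


def _read_cohort_text(text: str, source: str | None = None) -> Cohort:
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#schema="):
        raise CohortValidationError(["missing '#schema=' version line"])
    version = lines[0].removeprefix("#schema=").strip()
    if version != SCHEMA_VERSION:
        raise CohortValidationError([f"unsupported schema version {version!r}"])
    reader = csv.DictReader(io.StringIO("\n".join(lines[1:])))
    if reader.fieldnames is None or list(reader.fieldnames) != _COLUMNS:
        raise CohortValidationError(
            [f"header mismatch: expected {_COLUMNS}, got {reader.fieldnames}"]
        )
    problems: list[str] = []
    records: list[PatientRecord] = []
    for rowno, row in enumerate(reader, start=3):  # line 1 schema, line 2 header
        rec = _row_to_record(rowno, row, problems)
        if rec is not None:
            records.append(rec)
    ids = [r.id for r in records]
    for dup in sorted({i for i in ids if ids.count(i) > 1}):
        problems.append(f"duplicate patient id {dup!r}")
    if problems:
        raise CohortValidationError(problems)
    return Cohort(patients=tuple(records), source=source)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest exact representation: lossless round trip
    return str(value)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to the canonical CSV form (round-trips losslessly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"#schema={SCHEMA_VERSION}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for p in cohort:
            t = p.treatment
            onset = t.onset_to_groin_hours
            writer.writerow([
                p.id, _fmt(float(p.age)), p.sex, p.occluded_vessel,
                _fmt(p.nihss),
                _fmt(float(p.volumes.v_core)), _fmt(float(p.volumes.v_penumbra)),
                _fmt(float(p.volumes.v_mip)), _fmt(float(p.volumes.v_mtt)),
                _fmt(t.thrombectomy_performed),
                t.mtici.value if t.mtici is not None else "",
                _fmt(t.rtpa),
                "" if onset is UNKNOWN else _fmt(float(onset)),
                _fmt(None if p.mls_max_mm is None else float(p.mls_max_mm)),
                _fmt(p.dhc), _fmt(p.death_7d),
                ";".join(sorted(p.exclusion_flags)),
            ])


def apply_inclusion_filters(cohort: Cohort) -> tuple[Cohort, dict[str, int]]:
    """Split a cohort into included patients and an exclusion tally.

    A patient with any exclusion flag is removed and counted once, under the
    first matching reason in the fixed criteria order. Counts are conserved:
    ``len(included) + sum(tally.values()) == len(cohort)``.
    """
    tally: Counter[str] = Counter()
    included: list[PatientRecord] = []
    log: list[str] = []
    for p in cohort:
        if p.exclusion_flags:
            reason = next(r for r in EXCLUSION_REASONS if r in p.exclusion_flags)
            tally[reason] += 1
            log.append(f"excluded {p.id}: {reason}")
        else:
            included.append(p)
    out = Cohort(
        patients=tuple(included),
        source=cohort.source,
        filter_log=cohort.filter_log + tuple(log),
    )
    return out, {r: tally.get(r, 0) for r in EXCLUSION_REASONS}


def filter_log_json(cohort: Cohort) -> str:
    """Machine-readable provenance of applied filters."""
    return json.dumps({"source": cohort.source, "filter_log": list(cohort.filter_log)}, indent=2)
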