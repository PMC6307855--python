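"""Study-level records: loading, validation, and normalization.

Each record summarizes one published tracer experiment comparing an AQP4
(or perivascular-AQP4) deficient arm ("ko") against wild-type controls
("ctrl"): per-arm mean, dispersion, and sample size, plus the experimental
covariates used later as meta-regression moderators.

Normalization applies the extraction conventions used when building such
tables from the literature:

* dispersions reported as SEM are converted to SD via ``SD = SEM * sqrt(n)``,
  using the resolved sample size of that arm;
* sample sizes reported as a range (``"6-8"`` or ``"6–8"``) resolve to the
  range minimum, the conservative choice;
* original values are retained in provenance fields so nothing is lost.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

from .exceptions import ValidationError

SPECIES = frozenset({"mouse", "rat"})
DETECTION = frozenset({"fluorescence", "radioactivity", "mri"})
INJECTION_ROUTES = frozenset(
    {"cisterna_magna", "striatum", "cortex", "thalamus", "lateral_ventricle"}
)
DISP_TYPES = frozenset({"sd", "sem"})

UNREPORTED = "unreported"

#: tolerate plain hyphen, en dash, or em dash between the two bounds
_RANGE_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")


def parse_n_token(token: str | int | float) -> tuple[int, int]:
    """Parse a sample-size cell into ``(n_min, n_max)``.

    Accepts a bare integer (``"6"`` -> ``(6, 6)``) or a dash-separated range
    in either dash dialect (``"6-8"`` / ``"6–8"`` -> ``(6, 8)``).
    """
    if isinstance(token, (int, float)) and not isinstance(token, bool):
        if float(token) != int(token):
            raise ValidationError(f"sample size must be an integer, got {token!r}")
        return int(token), int(token)
    text = str(token).strip()
    if m := _RANGE_RE.match(text):
        lo, hi = int(m.group(1)), int(m.group(2))
        return lo, hi
    if re.fullmatch(r"\d+", text):
        n = int(text)
        return n, n
    raise ValidationError(f"cannot parse sample-size token {token!r}")


@dataclass(frozen=True)
class StudyRecord:
    """One extracted dataset: two-arm summary statistics plus covariates."""

    dataset_id: str
    source_study: str = ""
    lab: str = ""
    species: str = "mouse"
    ko_line: str = UNREPORTED
    age_weeks_min: float | None = None
    age_weeks_max: float | None = None
    anesthesia: str = UNREPORTED
    tracer_name: str = ""
    tracer_kda: float | None = None
    detection: str = "fluorescence"
    injection_route: str = "cisterna_magna"
    injection_volume_ul: float | None = None
    injection_rate: str = UNREPORTED
    duration_min: float | None = None
    outcome_measure: str = ""
    ctrl_mean: float = 0.0
    ctrl_disp: float = 1.0
    ctrl_disp_type: str = "sd"
    ctrl_n_min: int = 2
    ctrl_n_max: int = 2
    ko_mean: float = 0.0
    ko_disp: float = 1.0
    ko_disp_type: str = "sd"
    ko_n_min: int = 2
    ko_n_max: int = 2
    # provenance, filled by normalize_record when a value is rewritten
    ctrl_disp_orig: float | None = None
    ctrl_disp_type_orig: str | None = None
    ctrl_n_orig: str | None = None
    ko_disp_orig: float | None = None
    ko_disp_type_orig: str | None = None
    ko_n_orig: str | None = None

    def __post_init__(self) -> None:
        validate_record(self)

    @property
    def ctrl_n(self) -> int:
        """Resolved control-arm size (range minimum)."""
        return self.ctrl_n_min

    @property
    def ko_n(self) -> int:
        """Resolved KO-arm size (range minimum)."""
        return self.ko_n_min

    @property
    def is_normalized(self) -> bool:
        return (
            self.ctrl_disp_type == "sd"
            and self.ko_disp_type == "sd"
            and self.ctrl_n_min == self.ctrl_n_max
            and self.ko_n_min == self.ko_n_max
        )


def validate_record(rec: StudyRecord) -> None:
    rid = rec.dataset_id
    if not rid:
        raise ValidationError("dataset_id must be non-empty")
    if rec.species not in SPECIES:
        raise ValidationError(
            f"{rid}: unknown species {rec.species!r} (expected one of {sorted(SPECIES)})"
        )
    if rec.detection not in DETECTION:
        raise ValidationError(
            f"{rid}: unknown detection {rec.detection!r} (expected one of {sorted(DETECTION)})"
        )
    if rec.injection_route not in INJECTION_ROUTES:
        raise ValidationError(
            f"{rid}: unknown injection_route {rec.injection_route!r} "
            f"(expected one of {sorted(INJECTION_ROUTES)})"
        )
    for arm in ("ctrl", "ko"):
        disp = getattr(rec, f"{arm}_disp")
        dtype = getattr(rec, f"{arm}_disp_type")
        n_min = getattr(rec, f"{arm}_n_min")
        n_max = getattr(rec, f"{arm}_n_max")
        mean = getattr(rec, f"{arm}_mean")
        if not (isinstance(mean, (int, float)) and math.isfinite(mean)):
            raise ValidationError(f"{rid}: {arm}_mean must be a finite number")
        if not (isinstance(disp, (int, float)) and math.isfinite(disp) and disp > 0):
            raise ValidationError(f"{rid}: {arm}_disp must be strictly positive")
        if dtype not in DISP_TYPES:
            raise ValidationError(f"{rid}: {arm}_disp_type must be 'sd' or 'sem'")
        if n_min < 2:
            raise ValidationError(f"{rid}: {arm} sample size must be >= 2")
        if n_min > n_max:
            raise ValidationError(f"{rid}: {arm}_n_min > {arm}_n_max")
    if rec.age_weeks_min is not None and rec.age_weeks_min < 0:
        raise ValidationError(f"{rid}: age_weeks_min must be nonnegative")
    if (
        rec.age_weeks_min is not None
        and rec.age_weeks_max is not None
        and rec.age_weeks_min > rec.age_weeks_max
    ):
        raise ValidationError(f"{rid}: age_weeks_min > age_weeks_max")
    if rec.tracer_kda is not None and rec.tracer_kda <= 0:
        raise ValidationError(f"{rid}: tracer_kda must be positive")
    if rec.injection_volume_ul is not None and rec.injection_volume_ul <= 0:
        raise ValidationError(f"{rid}: injection_volume_ul must be positive")
    if rec.duration_min is not None and rec.duration_min <= 0:
        raise ValidationError(f"{rid}: duration_min must be positive")


def normalize_record(rec: StudyRecord) -> StudyRecord:
    """Return an SD-based, single-n copy of ``rec``.

    * SEM dispersions become ``SEM * sqrt(n)`` with ``n`` the resolved
      (minimum) size of that arm; the dispersion type becomes ``sd``.
    * ``n_min``/``n_max`` collapse to ``n_min``.
    * Originals are stored in the ``*_orig`` provenance fields; already
      normalized records pass through unchanged, so the operation is
      idempotent.
    """
    changes: dict[str, object] = {}
    for arm in ("ctrl", "ko"):
        n_min = getattr(rec, f"{arm}_n_min")
        n_max = getattr(rec, f"{arm}_n_max")
        disp = getattr(rec, f"{arm}_disp")
        dtype = getattr(rec, f"{arm}_disp_type")
        if dtype == "sem":
            changes[f"{arm}_disp"] = disp * math.sqrt(n_min)
            changes[f"{arm}_disp_type"] = "sd"
            changes[f"{arm}_disp_orig"] = disp
            changes[f"{arm}_disp_type_orig"] = "sem"
        if n_min != n_max:
            changes[f"{arm}_n_orig"] = f"{n_min}-{n_max}"
            changes[f"{arm}_n_max"] = n_min
    if not changes:
        return rec
    return replace(rec, **changes)


def resolve_covariates(
    rec: StudyRecord, age_rule: str = "midpoint"
) -> dict[str, object]:
    """Derive the moderator mapping used by meta-regression.

    Numeric age is computed from the reported (min, max) range according to
    ``age_rule`` (``midpoint`` | ``min`` | ``max``); missing categorical
    values become the explicit level ``"unreported"`` so no record drops out
    of a categorical model silently; missing numeric covariates are ``None``
    and excluded per-moderator downstream. Duration is exposed both as a
    number (``duration_min``) and as a categorical token (``duration``),
    because an unreported circulation time is itself an analyzable level.
    """
    if age_rule not in ("midpoint", "min", "max"):
        raise ValueError(f"unknown age_rule {age_rule!r}")
    lo, hi = rec.age_weeks_min, rec.age_weeks_max
    if lo is not None and hi is not None and lo > hi:
        raise ValidationError(f"{rec.dataset_id}: age_weeks_min > age_weeks_max")
    if lo is None and hi is None:
        age: float | None = None
    else:
        lo = hi if lo is None else lo
        hi = lo if hi is None else hi
        age = {"midpoint": (lo + hi) / 2.0, "min": lo, "max": hi}[age_rule]

    def cat(value: str | None) -> str:
        text = (value or "").strip()
        return text if text else UNREPORTED

    return {
        "species": cat(rec.species),
        "ko_line": cat(rec.ko_line),
        "anesthesia": cat(rec.anesthesia),
        "detection": cat(rec.detection),
        "injection_route": cat(rec.injection_route),
        "injection_rate": cat(rec.injection_rate),
        "age_weeks": age,
        "tracer_kda": rec.tracer_kda,
        "injection_volume_ul": rec.injection_volume_ul,
        "duration_min": rec.duration_min,
        "duration": (
            UNREPORTED if rec.duration_min is None else format(rec.duration_min, "g")
        ),
    }


# ---------------------------------------------------------------------------
# CSV I/O

_NUMERIC_OPTIONAL = {
    "age_weeks_min",
    "age_weeks_max",
    "tracer_kda",
    "injection_volume_ul",
    "ctrl_disp_orig",
    "ko_disp_orig",
}
_STRING_OPTIONAL = {
    "ctrl_disp_type_orig",
    "ko_disp_type_orig",
    "ctrl_n_orig",
    "ko_n_orig",
}
_MANDATORY = (
    "dataset_id",
    "species",
    "detection",
    "injection_route",
    "ctrl_mean",
    "ctrl_disp",
    "ctrl_disp_type",
    "ko_mean",
    "ko_disp",
    "ko_disp_type",
)

CSV_COLUMNS = [f.name for f in fields(StudyRecord)]


def _parse_float(text: str, row: int, col: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"non-numeric value {text!r}", row=row, column=col) from None


def _record_from_row(row: Mapping[str, str], rownum: int) -> StudyRecord:
    kwargs: dict[str, object] = {}
    get = lambda col: (row.get(col) or "").strip()

    for col in _MANDATORY:
        if col not in row:
            raise ValidationError(f"missing mandatory column {col!r}", row=rownum)

    for col in ("dataset_id", "source_study", "lab", "species", "ko_line",
                "anesthesia", "tracer_name", "detection", "injection_route",
                "outcome_measure", "ctrl_disp_type", "ko_disp_type"):
        if col in row:
            kwargs[col] = get(col)
    kwargs["injection_rate"] = get("injection_rate") or UNREPORTED
    kwargs["anesthesia"] = kwargs.get("anesthesia") or UNREPORTED

    for col in ("ctrl_mean", "ctrl_disp", "ko_mean", "ko_disp"):
        kwargs[col] = _parse_float(get(col), rownum, col)
    for col in _NUMERIC_OPTIONAL:
        if col in row and get(col):
            kwargs[col] = _parse_float(get(col), rownum, col)
    for col in _STRING_OPTIONAL:
        if col in row and get(col):
            kwargs[col] = get(col)

    dur = get("duration_min")
    if dur and dur.lower() != UNREPORTED:
        kwargs["duration_min"] = _parse_float(dur, rownum, "duration_min")

    # sample sizes: either a single token column per arm ("ctrl_n", possibly a
    # range) or an explicit min/max pair
    for arm in ("ctrl", "ko"):
        tok_col, min_col, max_col = f"{arm}_n", f"{arm}_n_min", f"{arm}_n_max"
        try:
            if min_col in row and get(min_col):
                lo = int(_parse_float(get(min_col), rownum, min_col))
                hi = int(_parse_float(get(max_col), rownum, max_col)) if get(max_col) else lo
            elif tok_col in row and get(tok_col):
                lo, hi = parse_n_token(get(tok_col))
            else:
                raise ValidationError(
                    f"missing sample size for arm {arm!r}", row=rownum
                )
        except ValidationError as err:
            if err.row is None:
                raise ValidationError(str(err), row=rownum, column=tok_col) from None
            raise
        kwargs[min_col], kwargs[max_col] = lo, hi

    try:
        return StudyRecord(**kwargs)  # type: ignore[arg-type]
    except ValidationError as err:
        raise ValidationError(str(err), row=rownum) from None


def load_dataset(path: str | Path) -> list[StudyRecord]:
    """Read an input CSV into validated :class:`StudyRecord` objects.

    Rows are returned in file order. Parse or validation failures raise
    :class:`~glymeta.exceptions.ValidationError` naming the 1-based data row
    (and column where known). Duplicate ``dataset_id`` values are rejected.
    """
    path = Path(path)
    records: list[StudyRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header row required")
        for i, row in enumerate(reader, start=1):
            rec = _record_from_row(row, i)
            if rec.dataset_id in seen:
                raise ValidationError(
                    f"duplicate dataset_id {rec.dataset_id!r}", row=i
                )
            seen.add(rec.dataset_id)
            records.append(rec)
    return records


def write_dataset(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write records to CSV with the full schema including provenance columns."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for rec in records:
            row = {}
            for f in fields(StudyRecord):
                value = getattr(rec, f.name)
                if value is None:
                    row[f.name] = ""
                elif isinstance(value, float):
                    row[f.name] = repr(value)
                else:
                    row[f.name] = value
            writer.writerow(row)
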