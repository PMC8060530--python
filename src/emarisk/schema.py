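"""Questionnaire schema, score standardisation and observation matrices.

The instrument is a 32-item EMA questionnaire covering four symptom domains:
wish to die / wish to live (2 items), sleep (10), negative feelings (13) and
appetite (7). Raw answers live on per-item scales; every downstream step works
on scores standardised to [0, 1] with the convention that *higher always means
a worse mental state*. Items phrased positively (wish to live, slept well,
good appetite, ...) carry ``worse_low`` polarity and are reversed.

Because only 2-4 randomly chosen items are prompted per day, per-day
observation vectors are mostly missing; they are represented as an
:class:`ObservationMatrix` carrying an explicit observed-entry mask instead of
being dropped or imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DOMAINS = ("wish_to_die_live", "sleep", "negative_feelings", "appetite")
#: number of items per domain in the default instrument
DOMAIN_SIZES = {
    "wish_to_die_live": 2,
    "sleep": 10,
    "negative_feelings": 13,
    "appetite": 7,
}
N_ITEMS = 32

#: default binarization threshold on the standardized scale (inclusive)
POSITIVE_THRESHOLD = 0.5

#: decimal places used when writing raw values
RAW_DECIMALS = 4


class SchemaError(ValueError):
    """Raised for malformed schemas or records that violate one."""


class RangeError(ValueError):
    """Raised when a raw value falls outside its item's range."""


@dataclass(frozen=True)
class QuestionSpec:
    """A single questionnaire item.

    ``polarity`` states which end of the raw scale is clinically worse:
    ``worse_high`` items standardise linearly, ``worse_low`` items are
    reversed so that 1 is always the worst state.
    """

    question_id: str
    domain: str
    min_raw: float = 0.0
    max_raw: float = 10.0
    polarity: str = "worse_high"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise SchemaError(f"unknown domain {self.domain!r} for {self.question_id}")
        if not self.max_raw > self.min_raw:
            raise SchemaError(f"max_raw must exceed min_raw for {self.question_id}")
        if self.polarity not in ("worse_high", "worse_low"):
            raise SchemaError(f"bad polarity {self.polarity!r} for {self.question_id}")


@dataclass(frozen=True)
class QuestionnaireSchema:
    """An ordered 32-item instrument; item order fixes column order downstream."""

    questions: tuple[QuestionSpec, ...]

    def __post_init__(self) -> None:
        if len(self.questions) != N_ITEMS:
            raise SchemaError(f"schema must contain exactly {N_ITEMS} items, got {len(self.questions)}")
        ids = [q.question_id for q in self.questions]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate question_id in schema")

    def __len__(self) -> int:
        return len(self.questions)

    def __getitem__(self, question_id: str) -> QuestionSpec:
        try:
            return self._by_id[question_id]
        except KeyError:
            raise SchemaError(f"unknown question_id {question_id!r}") from None

    @property
    def _by_id(self) -> dict[str, QuestionSpec]:
        return {q.question_id: q for q in self.questions}

    @property
    def question_ids(self) -> list[str]:
        return [q.question_id for q in self.questions]

    def column_index(self, question_id: str) -> int:
        return self.question_ids.index(question_id)

    def domain_columns(self, domain: str) -> np.ndarray:
        """Column indices of all items in ``domain``."""
        return np.array([i for i, q in enumerate(self.questions) if q.domain == domain])


def default_schema() -> QuestionnaireSchema:
    """The shipped default instrument: 32 items, domain sizes 2/10/13/7.

    Item wording is not part of the schema; ids are synthetic but the
    structure (domains, 0-10 ranges, reversed positively-phrased items)
    matches the instrument layout. ``wish_to_live``, the positively phrased
    sleep items and the positive appetite items are ``worse_low``.
    """
    q: list[QuestionSpec] = [
        QuestionSpec("wish_to_die", "wish_to_die_live"),
        QuestionSpec("wish_to_live", "wish_to_die_live", polarity="worse_low"),
    ]
    sleep_worse_low = {"sleep_quality", "sleep_restedness"}
    for name in (
        "sleep_quality", "sleep_latency", "sleep_awakenings", "sleep_early_waking",
        "sleep_restedness", "sleep_nightmares", "sleep_daytime_drowsiness",
        "sleep_medication_use", "sleep_restlessness", "sleep_worry_at_night",
    ):
        q.append(QuestionSpec(name, "sleep",
                              polarity="worse_low" if name in sleep_worse_low else "worse_high"))
    for name in (
        "neg_sadness", "neg_anxiety", "neg_hopelessness", "neg_loneliness",
        "neg_guilt", "neg_irritability", "neg_emptiness", "neg_worthlessness",
        "neg_burden_to_others", "neg_rumination", "neg_anhedonia",
        "neg_stress", "neg_despair",
    ):
        q.append(QuestionSpec(name, "negative_feelings"))
    app_worse_low = {"appetite_level", "food_enjoyment", "meal_regularity"}
    for name in (
        "appetite_level", "food_enjoyment", "food_tastelessness", "appetite_loss",
        "meal_regularity", "eating_effort", "weight_concern",
    ):
        q.append(QuestionSpec(name, "appetite",
                              polarity="worse_low" if name in app_worse_low else "worse_high"))
    return QuestionnaireSchema(tuple(q))


@dataclass(frozen=True)
class EMARecord:
    """One answered prompt: who, when, which item, raw answer."""

    patient_id: str
    timestamp: datetime
    question_id: str
    raw_value: float


@dataclass(frozen=True)
class PeriodSchedule:
    """Study period windows; boundaries inclusive on both ends."""

    pre_start: date = date(2019, 10, 1)
    pre_end: date = date(2020, 3, 13)
    lockdown_start: date = date(2020, 3, 14)
    lockdown_end: date = date(2020, 4, 14)

    def label(self, day: date) -> str | None:
        """Period label for a calendar day, or None when outside both windows."""
        if self.pre_start <= day <= self.pre_end:
            return "pre_lockdown"
        if self.lockdown_start <= day <= self.lockdown_end:
            return "lockdown"
        return None

    def days(self, period: str) -> list[date]:
        start, end = {
            "pre_lockdown": (self.pre_start, self.pre_end),
            "lockdown": (self.lockdown_start, self.lockdown_end),
        }[period]
        return [date.fromordinal(o) for o in range(start.toordinal(), end.toordinal() + 1)]


#: daily prompting window (local study time)
PROMPT_WINDOW = (time(10, 0), time(22, 0))


def standardize_response(raw: float, spec: QuestionSpec) -> float:
    """Map a raw answer to [0, 1] with 1 = worst state.

    Affine on the item's range; ``worse_low`` items are reversed so their
    best raw value maps to 1.
    """
    if not (spec.min_raw <= raw <= spec.max_raw):
        raise RangeError(
            f"raw value {raw!r} outside [{spec.min_raw}, {spec.max_raw}] "
            f"for question {spec.question_id!r}"
        )
    score = (raw - spec.min_raw) / (spec.max_raw - spec.min_raw)
    if spec.polarity == "worse_low":
        score = 1.0 - score
    return float(score)


def destandardize_score(score: float, spec: QuestionSpec) -> float:
    """Inverse of :func:`standardize_response` (used by the generator)."""
    if spec.polarity == "worse_low":
        score = 1.0 - score
    return float(spec.min_raw + score * (spec.max_raw - spec.min_raw))


def binarize(score, threshold: float = POSITIVE_THRESHOLD):
    """Positive flag: standardized score at or above ``threshold``.

    Accepts scalars or arrays; the boundary is inclusive.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return np.asarray(score) >= threshold if np.ndim(score) else bool(score >= threshold)


# ---------------------------------------------------------------------------
# long-table I/O

TABLE_COLUMNS = ["patient_id", "timestamp", "question_id", "raw_value"]


def read_ema_table(path: str | Path, schema: QuestionnaireSchema, sep: str = ",") -> list[EMARecord]:
    """Read a long-format EMA table, validating every row against the schema.

    Malformed rows raise with their (1-based, header included) line number.
    """
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "question_id": str})
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records: list[EMARecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header on line 1
        qid = row.question_id
        try:
            spec = schema[qid]
        except SchemaError:
            raise SchemaError(f"{path}:{line_no}: unknown question_id {qid!r}") from None
        try:
            ts = datetime.fromisoformat(str(row.timestamp))
        except ValueError:
            raise ValueError(f"{path}:{line_no}: unparseable timestamp {row.timestamp!r}") from None
        raw = float(row.raw_value)
        if not (spec.min_raw <= raw <= spec.max_raw):
            raise RangeError(
                f"{path}:{line_no}: raw value {raw} out of range for {qid!r}"
            )
        records.append(EMARecord(str(row.patient_id), ts, qid, raw))
    return records


def write_ema_table(records: Iterable[EMARecord], path: str | Path, sep: str = ",") -> None:
    """Write records as CSV with ISO timestamps and fixed raw-value precision."""
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "timestamp": [r.timestamp.isoformat(timespec="minutes") for r in records],
            "question_id": [r.question_id for r in records],
            "raw_value": [round(r.raw_value, RAW_DECIMALS) for r in records],
        },
        columns=TABLE_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False, float_format=f"%.{RAW_DECIMALS}f")


# ---------------------------------------------------------------------------
# observation matrices

@dataclass
class ObservationMatrix:
    """N session vectors x 32 items, with an observed-entry mask.

    ``values`` holds standardized scores (only meaningful where ``mask`` is
    true); ``row_meta`` has one row per session with patient_id, session date
    and period label.
    """

    values: np.ndarray
    mask: np.ndarray
    row_meta: pd.DataFrame
    question_ids: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def period_labels(self) -> np.ndarray:
        return self.row_meta["period"].to_numpy()

    def binarized(self, threshold: float = POSITIVE_THRESHOLD) -> np.ndarray:
        """Boolean positives; entries under a false mask are set False."""
        pos = self.values >= threshold
        return pos & self.mask


def build_observation_matrix(
    records: Sequence[EMARecord],
    schema: QuestionnaireSchema,
    schedule: PeriodSchedule | None = None,
    sessionization: str = "calendar_day",
) -> ObservationMatrix:
    """Assemble per-session observation vectors from validated records.

    One row per patient per calendar day (the default sessionization, as the
    turn-over design prompts a handful of items per day). Unanswered items are
    masked; repeated answers to the same item within a session are resolved
    last-answer-wins (logged). Sessions outside both period windows are
    excluded and counted in the log.
    """
    if sessionization != "calendar_day":
        raise ValueError(f"unsupported sessionization {sessionization!r}")
    schedule = schedule or PeriodSchedule()
    D = len(schema)
    col = {qid: j for j, qid in enumerate(schema.question_ids)}

    sessions: dict[tuple[str, date], dict[int, tuple[datetime, float]]] = {}
    n_dups = 0
    for r in records:
        key = (r.patient_id, r.timestamp.date())
        slot = sessions.setdefault(key, {})
        j = col[r.question_id]
        if j in slot:
            n_dups += 1
            if r.timestamp < slot[j][0]:
                continue  # keep the later answer
        slot[j] = (r.timestamp, standardize_response(r.raw_value, schema[r.question_id]))
    if n_dups:
        logger.info("resolved %d repeated within-session answers (last answer wins)", n_dups)

    keys = sorted(sessions)
    rows, meta, n_outside = [], [], 0
    for pid, day in keys:
        period = schedule.label(day)
        if period is None:
            n_outside += 1
            continue
        slot = sessions[(pid, day)]
        if not slot:
            continue
        v = np.zeros(D)
        m = np.zeros(D, dtype=bool)
        for j, (_, score) in slot.items():
            v[j], m[j] = score, True
        rows.append((v, m))
        meta.append((pid, day, period))
    if n_outside:
        logger.info("excluded %d sessions outside both period windows", n_outside)
    if not rows:
        raise ValueError("no sessions fall inside the period schedule: empty matrix")

    values = np.stack([v for v, _ in rows])
    mask = np.stack([m for _, m in rows])
    row_meta = pd.DataFrame(meta, columns=["patient_id", "date", "period"])
    return ObservationMatrix(values, mask, row_meta, list(schema.question_ids))


# ---------------------------------------------------------------------------
# schema config (YAML)

def save_schema(schema: QuestionnaireSchema, path: str | Path) -> None:
    payload = {
        "questions": [
            {
                "question_id": q.question_id,
                "domain": q.domain,
                "min_raw": q.min_raw,
                "max_raw": q.max_raw,
                "polarity": q.polarity,
            }
            for q in schema.questions
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_schema(path: str | Path) -> QuestionnaireSchema:
    payload = yaml.safe_load(Path(path).read_text())
    return QuestionnaireSchema(tuple(QuestionSpec(**q) for q in payload["questions"]))
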