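"""Domain types and on-disk formats for complaint and physician-interaction data.

Complaints are stored as a UTF-8 CSV with header; physician records, being
ragged (variable numbers of consulted texts, replies and voice messages), are
stored as JSON Lines with one object per physician.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

COMPLAINT_COLUMNS = ["patient_id", "text", "disease", "department", "consulted_physician_id"]


class CorpusError(Exception):
    """Base error for corpus I/O and validation."""


class SchemaError(CorpusError):
    """A required column or field is missing."""


class EmptyCorpusError(CorpusError):
    """An input file contains no records."""


class ValidationError(CorpusError):
    """Referential-integrity or invariant violation."""


@dataclass(frozen=True)
class ComplaintRecord:
    """One patient's chief complaint with its disease and department labels."""

    patient_id: str
    text: str
    disease: str
    department: str
    consulted_physician_id: str | None = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValidationError(f"complaint {self.patient_id!r}: text is empty")


@dataclass(frozen=True)
class PhysicianRecord:
    """A physician's consulted texts plus reply-length and voice-duration logs.

    ``reply_text_lengths`` counts unicode characters of each reply message;
    ``voice_durations`` are seconds. Both must be non-negative.
    """

    physician_id: str
    name: str
    department: str
    consulted_texts: tuple[str, ...] = ()
    reply_text_lengths: tuple[int, ...] = ()
    voice_durations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.reply_text_lengths):
            raise ValidationError(f"physician {self.physician_id!r}: negative reply length")
        if any(d < 0 for d in self.voice_durations):
            raise ValidationError(f"physician {self.physician_id!r}: negative voice duration")

    @property
    def mean_reply_length(self) -> float:
        """Mean characters per reply; 0.0 for a physician with no replies."""
        if not self.reply_text_lengths:
            return 0.0
        return float(sum(self.reply_text_lengths)) / len(self.reply_text_lengths)

    @property
    def mean_voice_duration(self) -> float:
        """Mean seconds per voice message; 0.0 when there are none."""
        if not self.voice_durations:
            return 0.0
        return float(sum(self.voice_durations)) / len(self.voice_durations)


@dataclass
class Corpus:
    """Complaints plus the physician pool, with referential integrity enforced."""

    complaints: list[ComplaintRecord]
    physicians: list[PhysicianRecord]
    patient_to_physician: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.complaints:
            if c.patient_id in seen:
                raise ValidationError(f"duplicate patient id {c.patient_id!r}")
            seen.add(c.patient_id)
        known = {p.physician_id for p in self.physicians}
        for c in self.complaints:
            if c.consulted_physician_id is not None and c.consulted_physician_id not in known:
                raise ValidationError(
                    f"complaint {c.patient_id!r} references unknown physician "
                    f"{c.consulted_physician_id!r}"
                )
        if not self.patient_to_physician:
            self.patient_to_physician = {
                c.patient_id: c.consulted_physician_id
                for c in self.complaints
                if c.consulted_physician_id is not None
            }
        else:
            for pid, phys in self.patient_to_physician.items():
                if phys not in known:
                    raise ValidationError(
                        f"patient {pid!r} mapped to unknown physician {phys!r}"
                    )

    @property
    def departments(self) -> list[str]:
        return sorted({c.department for c in self.complaints})

    def physician(self, physician_id: str) -> PhysicianRecord:
        for p in self.physicians:
            if p.physician_id == physician_id:
                return p
        raise KeyError(physician_id)

    def complaint(self, patient_id: str) -> ComplaintRecord:
        for c in self.complaints:
            if c.patient_id == patient_id:
                return c
        raise KeyError(patient_id)


def parse_duration(value: float | int | str) -> float:
    """Parse a voice duration; accepts plain numbers or strings like ``"10s"``."""
    if isinstance(value, (int, float)):
        return float(value)
    text = value.strip().lower()
    if text.endswith("s"):
        text = text[:-1]
    return float(text)


def read_corpus(complaints_path: str | Path, physicians_path: str | Path) -> Corpus:
    """Load and validate a corpus from ``complaints.csv`` + ``physicians.jsonl``.

    Rows with empty complaint text are dropped with a warning naming the line;
    a complaint referencing a physician absent from the pool raises
    :class:`ValidationError` naming the offending id.
    """
    complaints_path, physicians_path = Path(complaints_path), Path(physicians_path)
    for p in (complaints_path, physicians_path):
        if not p.exists():
            raise FileNotFoundError(p)

    df = pd.read_csv(complaints_path, dtype=str, keep_default_na=False)
    if df.empty:
        raise EmptyCorpusError(f"{complaints_path} contains no complaint rows")
    missing = [c for c in COMPLAINT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{complaints_path} missing columns: {missing}")

    complaints: list[ComplaintRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        text = str(row.text)
        if not text.strip():
            logger.warning("%s line %d: empty complaint text, row dropped", complaints_path, i)
            continue
        phys = str(row.consulted_physician_id) or None
        complaints.append(
            ComplaintRecord(
                patient_id=str(row.patient_id),
                text=text,
                disease=str(row.disease),
                department=str(row.department),
                consulted_physician_id=phys,
            )
        )
    if not complaints:
        raise EmptyCorpusError(f"{complaints_path}: no valid complaint rows")

    physicians: list[PhysicianRecord] = []
    with open(physicians_path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{physicians_path} line {i}: invalid JSON ({exc})") from exc
            try:
                physicians.append(
                    PhysicianRecord(
                        physician_id=str(obj["physician_id"]),
                        name=str(obj.get("name", obj["physician_id"])),
                        department=str(obj["department"]),
                        consulted_texts=tuple(obj.get("consulted_texts", [])),
                        reply_text_lengths=tuple(int(n) for n in obj.get("reply_text_lengths", [])),
                        voice_durations=tuple(
                            parse_duration(d) for d in obj.get("voice_durations", [])
                        ),
                    )
                )
            except KeyError as exc:
                raise SchemaError(f"{physicians_path} line {i}: missing field {exc}") from exc
    if not physicians:
        raise EmptyCorpusError(f"{physicians_path} contains no physician records")

    return Corpus(complaints=complaints, physicians=physicians)


def write_corpus(corpus: Corpus, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``complaints.csv`` and ``physicians.jsonl`` under ``out_dir``.

    Round-trips field-for-field through :func:`read_corpus`; CJK text is
    preserved verbatim (UTF-8 throughout), and empty lists stay empty lists.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    complaints_path = out_dir / "complaints.csv"
    physicians_path = out_dir / "physicians.jsonl"

    rows = [
        {
            "patient_id": c.patient_id,
            "text": c.text,
            "disease": c.disease,
            "department": c.department,
            "consulted_physician_id": c.consulted_physician_id or "",
        }
        for c in corpus.complaints
    ]
    pd.DataFrame(rows, columns=COMPLAINT_COLUMNS).to_csv(
        complaints_path, index=False, encoding="utf-8"
    )

    with open(physicians_path, "w", encoding="utf-8") as fh:
        for p in corpus.physicians:
            fh.write(
                json.dumps(
                    {
                        "physician_id": p.physician_id,
                        "name": p.name,
                        "department": p.department,
                        "consulted_texts": list(p.consulted_texts),
                        "reply_text_lengths": list(p.reply_text_lengths),
                        "voice_durations": list(p.voice_durations),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    return complaints_path, physicians_path
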