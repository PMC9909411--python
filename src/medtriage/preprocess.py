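"""Complaint-text preprocessing: punctuation removal, segmentation, stop words.

The pipeline is language-agnostic: segmentation is injectable so that a CJK
segmenter can replace the default regex splitter without touching the rest of
the pipeline.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .corpus import ComplaintRecord

Segmenter = Callable[[str], list[str]]

# CJK punctuation / fullwidth-form blocks on top of unicode category P*.
_CJK_PUNCT_RANGES = ((0x3000, 0x303F), (0xFF00, 0xFF0F), (0xFF1A, 0xFF20), (0xFF3B, 0xFF40), (0xFF5B, 0xFF65))


def _is_punct(ch: str) -> bool:
    if unicodedata.category(ch).startswith("P"):
        return True
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in _CJK_PUNCT_RANGES)


def strip_punctuation(text: str) -> str:
    """Replace ASCII and CJK punctuation with spaces, collapsing runs.

    Ideographs and alphanumerics survive; a punctuation-only string becomes "".
    """
    out = "".join(" " if _is_punct(ch) else ch for ch in text)
    return re.sub(r"\s+", " ", out).strip()


def whitespace_segmenter(text: str) -> list[str]:
    return text.split()


_WORD_RE = re.compile(r"\w+", re.UNICODE)


def regex_segmenter(text: str) -> list[str]:
    """Split on non-word characters; keeps alphanumeric and CJK runs."""
    return _WORD_RE.findall(text)


SEGMENTERS: dict[str, Segmenter] = {
    "whitespace": whitespace_segmenter,
    "regex": regex_segmenter,
}


def tokenize(text: str, segmenter: Segmenter = regex_segmenter) -> list[str]:
    """Segment text into tokens, delegating entirely to ``segmenter``."""
    if not text:
        return []
    return list(segmenter(text))


def remove_stopwords(tokens: Iterable[str], stoplist: set[str]) -> list[str]:
    """Drop stop-list members, preserving order of the rest."""
    return [t for t in tokens if t not in stoplist]


def load_stopwords(path: str | Path) -> set[str]:
    """Read a stop-word file: UTF-8, one token per line, blanks ignored."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line:
            words.add(line)
    return words


#: A minimal default English stop list; real deployments supply their own file.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """a an and are as at be but by for have i if in is it my of on or that the
    this to was we with you""".split()
)


@dataclass(frozen=True)
class TokenizedDocument:
    """A preprocessed complaint: ordered tokens plus bookkeeping.

    ``source_length`` is the token count before stop-word removal; a document
    whose tokens were all removed is flagged ``degenerate``.
    """

    doc_id: str
    tokens: tuple[str, ...]
    source_length: int
    label: str | None = None

    @property
    def degenerate(self) -> bool:
        return len(self.tokens) == 0


@dataclass
class PreprocessConfig:
    segmenter: Segmenter = regex_segmenter
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    lowercase: bool = True  # no-op for CJK; folds case for alphabetic scripts


def preprocess_document(
    record: ComplaintRecord, config: PreprocessConfig | None = None
) -> TokenizedDocument:
    """strip_punctuation -> tokenize -> remove_stopwords, in that order."""
    config = config or PreprocessConfig()
    text = record.text.lower() if config.lowercase else record.text
    tokens = tokenize(strip_punctuation(text), config.segmenter)
    kept = remove_stopwords(tokens, set(config.stopwords))
    return TokenizedDocument(
        doc_id=record.patient_id,
        tokens=tuple(kept),
        source_length=len(tokens),
        label=record.department,
    )


def preprocess_corpus(
    records: Iterable[ComplaintRecord], config: PreprocessConfig | None = None
) -> list[TokenizedDocument]:
    return [preprocess_document(r, config) for r in records]
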