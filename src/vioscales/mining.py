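"""Lexicon-driven symptom extraction from certificate free text.

Medical certificates are standardized digital text; patient-reported
psychological-trauma symptoms (sleep disorders, loss of appetite, stress
symptoms, pain, fear) appear as short French phrases that may carry typing
or spelling variation.  Extraction is a term search: text is normalized,
tokenized, and each lexicon term (uni- or multi-word) is matched against
token n-grams under a length-banded Levenshtein tolerance.  No negation or
section handling is attempted.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import edlib

__all__ = [
    "Lexicon",
    "ExtractionResult",
    "Match",
    "normalize_text",
    "match_concept",
    "extract_features",
    "default_lexicon",
]

_WS = re.compile(r"\s+")
_NON_ALNUM = re.compile(r"[^a-z0-9 ]+")


def normalize_text(text: str) -> str:
    """Lower-case, strip accents, collapse punctuation to single spaces.

    Idempotent: ``normalize_text(normalize_text(x)) == normalize_text(x)``.
    """
    text = unicodedata.normalize("NFKD", text.lower())
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = _NON_ALNUM.sub(" ", text)
    return _WS.sub(" ", text).strip()


def default_edit_tolerance(term_length: int) -> int:
    """Allowed Levenshtein distance by term length: 0 below 5 characters,
    1 for 5-8, 2 above 8.  Short tokens get no tolerance to avoid false
    positives between common short words."""
    if term_length < 5:
        return 0
    if term_length <= 8:
        return 1
    return 2


@dataclass
class Lexicon:
    """Concept -> term list mapping with an edit-distance policy.

    Terms are normalized at construction; every concept must keep at least
    one non-empty term.
    """

    concepts: dict[str, list[str]]
    tolerance: "callable" = field(default=default_edit_tolerance)

    def __post_init__(self) -> None:
        normalized: dict[str, list[str]] = {}
        for concept, terms in self.concepts.items():
            cleaned = [normalize_text(t) for t in terms]
            cleaned = [t for t in cleaned if t]
            if not cleaned:
                raise ValueError(f"lexicon concept {concept!r} has no usable terms")
            normalized[concept] = cleaned
        self.concepts = normalized

    def terms(self, concept: str) -> list[str]:
        return self.concepts.get(concept, [])

    def add_term(self, concept: str, term: str) -> None:
        term = normalize_text(term)
        if not term:
            raise ValueError("cannot add an empty term")
        self.concepts.setdefault(concept, []).append(term)

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        concepts = {
            name: list(entry["terms"]) + list(entry.get("variants", []))
            for name, entry in raw["concepts"].items()
        }
        return cls(concepts)


def default_lexicon() -> Lexicon:
    """The packaged French symptom lexicon."""
    import importlib.resources

    ref = importlib.resources.files("vioscales.data") / "lexicon_fr.json"
    raw = json.loads(ref.read_text(encoding="utf-8"))
    return Lexicon({name: list(e["terms"]) for name, e in raw["concepts"].items()})


@dataclass
class Match:
    concept: str
    token: str
    term: str
    distance: int
    offset: int


@dataclass
class ExtractionResult:
    """Flags per concept plus the audit trail of individual matches."""

    flags: dict[str, bool]
    matches: list[Match]


def _distance(a: str, b: str, limit: int) -> int:
    """Levenshtein distance, or -1 if above ``limit``."""
    if a == b:
        return 0
    if limit == 0:
        return -1
    res = edlib.align(a, b, mode="NW", task="distance", k=limit)
    return int(res["editDistance"])


def match_concept(token: str, term: str,
                  tolerance: "callable" = default_edit_tolerance) -> tuple[bool, int]:
    """Match a normalized token against one lexicon term.

    The allowed distance depends on the *term's* length, so a short term
    like ``peur`` never fuzzy-matches (``pour`` stays unmatched) while
    ``douleur`` tolerates one edit.
    """
    limit = tolerance(len(term))
    d = _distance(token, term, limit)
    return (d >= 0, d if d >= 0 else -1)


def extract_features(text: str, lexicon: Lexicon) -> ExtractionResult:
    """Extract concept flags from one certificate.

    Tokenizes the normalized text and matches every term of every concept
    against the token n-gram of matching word count.  A concept's flag is
    set iff at least one of its terms matches somewhere.
    """
    norm = normalize_text(text or "")
    tokens = norm.split(" ") if norm else []
    offsets: list[int] = []
    pos = 0
    for tok in tokens:
        offsets.append(pos)
        pos += len(tok) + 1

    matches: list[Match] = []
    for concept, terms in lexicon.concepts.items():
        for term in terms:
            width = term.count(" ") + 1
            limit = lexicon.tolerance(len(term))
            for i in range(len(tokens) - width + 1):
                gram = " ".join(tokens[i:i + width])
                if abs(len(gram) - len(term)) > limit:
                    continue
                d = _distance(gram, term, limit)
                if d >= 0:
                    matches.append(Match(concept, gram, term, d, offsets[i]))
    flags = {concept: False for concept in lexicon.concepts}
    for m in matches:
        flags[m.concept] = True
    return ExtractionResult(flags=flags, matches=matches)


def mine_cohort(texts: Iterable[str], lexicon: Lexicon) -> list[ExtractionResult]:
    """Apply :func:`extract_features` to an iterable of certificates."""
    return [extract_features(t if isinstance(t, str) else "", lexicon) for t in texts]
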