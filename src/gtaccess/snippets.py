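"""Keyword snippet extraction and per-patient document consolidation.

Notes are tokenized into whitespace words (punctuation stays attached).
Each keyword hit yields a context window of 100 words on either side of the
matched phrase; overlapping windows within a note merge into one snippet.
All of a patient's snippets, ordered along the care timeline, are joined and
cleaned into a single :class:`PatientDocument` — the unit that triage and
classification operate on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, ContractError

DEFAULT_WINDOW = 100

#: characters preserved by :func:`clean_text` (besides letters/digits/space)
_KEPT_PUNCT = ".,;:?!()'/-"
_DISALLOWED_RE = re.compile(rf"[^A-Za-z0-9 {re.escape(_KEPT_PUNCT)}]")
_WS_RE = re.compile(r"\s+")

# strip leading/trailing non-alphanumerics when comparing tokens to phrases,
# so "BRCA2," still matches the phrase "BRCA2"
_EDGE_PUNCT_RE = re.compile(r"^\W+|\W+$")


@dataclass(frozen=True)
class Note:
    """One clinical document for one patient."""

    patient_id: str
    note_id: str
    note_date: str  # ISO-8601 date
    specialty: str
    text: str


@dataclass(frozen=True)
class KeywordLexicon:
    """Case-insensitive keyword phrase list (1-5 words per phrase)."""

    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phrases:
            raise ConfigurationError("lexicon must contain at least one phrase")
        seen: set[str] = set()
        for phrase in self.phrases:
            if not phrase.strip():
                raise ConfigurationError("lexicon phrases must be non-empty")
            n_words = len(phrase.split())
            if not 1 <= n_words <= 5:
                raise ConfigurationError(
                    f"lexicon phrase must have 1-5 words: {phrase!r}"
                )
            folded = phrase.casefold()
            if folded in seen:
                raise ConfigurationError(f"duplicate lexicon phrase: {phrase!r}")
            seen.add(folded)

    @classmethod
    def from_phrases(cls, phrases: Iterable[str]) -> "KeywordLexicon":
        return cls(tuple(p.strip() for p in phrases if p.strip()))

    @classmethod
    def from_file(cls, path) -> "KeywordLexicon":
        """Load a lexicon from a plain-text file (one phrase per line,
        blank lines and ``#`` comments ignored) or a YAML list."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = fh.read()
        if raw.lstrip().startswith("-"):
            phrases = yaml.safe_load(raw)
        else:
            phrases = [
                line.strip()
                for line in raw.splitlines()
                if line.strip() and not line.lstrip().startswith("#")
            ]
        return cls.from_phrases(phrases)


def default_lexicon() -> KeywordLexicon:
    """The packaged default keyword lexicon (``assets/lexicon.txt``)."""
    from importlib import resources

    path = resources.files("gtaccess.assets").joinpath("lexicon.txt")
    phrases = [
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return KeywordLexicon.from_phrases(phrases)


@dataclass(frozen=True)
class Snippet:
    """A (possibly merged) keyword context window within one note.

    ``start_word``/``end_word`` are a 0-based half-open word-index range into
    the source note's word sequence; ``text`` is exactly those words joined
    with single spaces.
    """

    patient_id: str
    note_id: str
    keyword: str
    start_word: int
    end_word: int
    text: str

    @property
    def word_count(self) -> int:
        return self.end_word - self.start_word


@dataclass(frozen=True)
class PatientDocument:
    """Consolidated, cleaned per-patient snippet text."""

    patient_id: str
    text: str
    snippet_count: int
    word_count: int

    def __post_init__(self) -> None:
        if self.snippet_count < 0 or self.word_count < 0:
            raise ContractError("snippet_count and word_count must be >= 0")
        if self.snippet_count == 0 and (self.text or self.word_count):
            raise ContractError("zero-snippet document must be empty")


def tokenize_words(text: str) -> list[str]:
    """Split text into words: maximal runs of non-whitespace characters."""
    return text.split()


def clean_text(text: str) -> str:
    """Normalise whitespace and drop special characters.

    Keeps letters, digits, spaces and ``. , ; : ? ! ( ) ' / -``; collapses
    whitespace runs to single spaces and strips the ends. Idempotent.
    """
    collapsed = _WS_RE.sub(" ", text)
    kept = _DISALLOWED_RE.sub("", collapsed)
    return _WS_RE.sub(" ", kept).strip()


def _normalize_token(token: str) -> str:
    return _EDGE_PUNCT_RE.sub("", token).casefold()


def find_keyword_hits(
    note: Note | str, lexicon: KeywordLexicon
) -> list[tuple[str, int]]:
    """Locate whole-word, case-insensitive phrase matches in a note.

    Tokens are compared after stripping surrounding punctuation and
    case-folding, so "(BRCA1)" matches the phrase "BRCA1" but "BRCA1/2"
    does not. Returns ``(phrase, word_index)`` pairs sorted by position;
    overlapping hits of different phrases are all reported.
    """
    if not isinstance(lexicon, KeywordLexicon):
        lexicon = KeywordLexicon.from_phrases(lexicon)
    text = note.text if isinstance(note, Note) else note
    words = [_normalize_token(w) for w in tokenize_words(text)]
    # index phrases by first token so the scan is one dict lookup per word
    by_first: dict[str, list[tuple[str, list[str]]]] = {}
    for phrase in lexicon.phrases:
        toks = [_normalize_token(w) for w in phrase.split()]
        by_first.setdefault(toks[0], []).append((phrase, toks))
    hits: list[tuple[str, int]] = []
    for i, word in enumerate(words):
        for phrase, toks in by_first.get(word, ()):
            if words[i : i + len(toks)] == toks:
                hits.append((phrase, i))
    hits.sort(key=lambda h: (h[1], h[0].casefold()))
    return hits


def extract_snippets(
    note: Note, lexicon: KeywordLexicon, window: int = DEFAULT_WINDOW
) -> list[Snippet]:
    """Extract merged context-window snippets for every keyword hit.

    Each hit spans ``[hit_start - window, hit_end + window)`` clipped to the
    note bounds; overlapping windows merge into a single snippet whose
    keyword is the first contributing phrase. Result is sorted by
    ``start_word``.
    """
    if window < 1:
        raise ContractError("window must be >= 1")
    words = tokenize_words(note.text)
    hits = find_keyword_hits(note, lexicon)
    if not hits:
        return []
    intervals: list[tuple[int, int, str]] = []
    for phrase, idx in hits:
        length = len(phrase.split())
        start = max(0, idx - window)
        end = min(len(words), idx + length + window)
        intervals.append((start, end, phrase))
    intervals.sort(key=lambda iv: (iv[0], iv[1]))
    merged: list[list] = []
    for start, end, phrase in intervals:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end, phrase])
    return [
        Snippet(
            patient_id=note.patient_id,
            note_id=note.note_id,
            keyword=phrase,
            start_word=start,
            end_word=end,
            text=" ".join(words[start:end]),
        )
        for start, end, phrase in merged
    ]


def consolidate_patient_document(
    snippets: Sequence[Snippet],
    note_order: Mapping[str, tuple] | Sequence[Note] | None = None,
    patient_id: str | None = None,
) -> PatientDocument:
    """Merge one patient's snippets into a single cleaned document.

    Snippets are ordered by ``(note_date, note_id, start_word)`` — care
    timeline order — joined with blank lines, then cleaned with
    :func:`clean_text`. ``note_order`` supplies note dates, either as a
    mapping ``note_id -> sort key`` or a sequence of :class:`Note`; without
    it, ordering falls back to ``(note_id, start_word)``.
    """
    ids = {s.patient_id for s in snippets}
    if len(ids) > 1:
        raise ContractError(f"snippets span multiple patients: {sorted(ids)}")
    if patient_id is None:
        patient_id = next(iter(ids)) if ids else ""
    elif ids and ids != {patient_id}:
        raise ContractError("snippets do not belong to the given patient")

    if not snippets:
        return PatientDocument(patient_id, "", 0, 0)

    if note_order is None:
        key_of = lambda nid: ()  # noqa: E731
    elif isinstance(note_order, Mapping):
        key_of = lambda nid: note_order.get(nid, ())  # noqa: E731
    else:
        dates = {n.note_id: (n.note_date,) for n in note_order}
        key_of = lambda nid: dates.get(nid, ())  # noqa: E731

    ordered = sorted(snippets, key=lambda s: (key_of(s.note_id), s.note_id, s.start_word))
    text = clean_text("\n\n".join(s.text for s in ordered))
    return PatientDocument(
        patient_id=patient_id,
        text=text,
        snippet_count=len(ordered),
        word_count=len(tokenize_words(text)),
    )


def extract_corpus(
    notes: Iterable[Note],
    lexicon: KeywordLexicon,
    window: int = DEFAULT_WINDOW,
) -> tuple[list[Snippet], dict[str, PatientDocument]]:
    """Run extraction + consolidation over a whole corpus.

    Returns all snippets and one :class:`PatientDocument` per patient seen
    in the corpus (including zero-snippet patients, whose document is
    empty). Patients are keyed and returned in first-appearance order.
    """
    notes = list(notes)
    snippets: list[Snippet] = []
    per_patient: dict[str, list[Snippet]] = {}
    note_dates: dict[str, dict[str, tuple]] = {}
    for note in notes:
        per_patient.setdefault(note.patient_id, [])
        note_dates.setdefault(note.patient_id, {})[note.note_id] = (note.note_date,)
        found = extract_snippets(note, lexicon, window=window)
        snippets.extend(found)
        per_patient[note.patient_id].extend(found)
    documents = {
        pid: consolidate_patient_document(
            snips, note_order=note_dates[pid], patient_id=pid
        )
        for pid, snips in per_patient.items()
    }
    return snippets, documents
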