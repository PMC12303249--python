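"""Synthetic labeled note corpora with the study's statistical structure.

Generates per-patient clinical notes with ground-truth access labels,
embedded evidence phrases, triage strata (zero-snippet patients that carry
no lexicon keyword anywhere; high-burden patients with >= 20 keyword-bearing
notes), and simulated dual-reviewer labels with adjudicated consensus.

Count and length distributions are log-normal, parameterised by median and
a log-scale sigma (derivable from a printed IQR). The snippet-count and
snippet-length defaults are calibrated jointly so that the *cohort-wide*
medians land on the published targets (notes/patient 42, snippets/patient 4,
snippet words ~199, merged document words ~800) once the zero-snippet and
high-burden strata are mixed in; the per-stratum parameters therefore do not
read off the printed marginal IQRs directly.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, ContractError
from .labels import AccessLabel, BinaryLabel, consolidate_to_binary
from .snippets import Note

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


class Stratum(str, enum.Enum):
    ZERO_SNIPPET = "zero_snippet"
    HIGH_BURDEN = "high_burden"
    NORMAL = "normal"


class DistSpec(BaseModel):
    """Log-normal distribution given as (median, log-scale sigma)."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    sigma: float = Field(ge=0)

    @classmethod
    def from_median_iqr(cls, median: float, q1: float, q3: float) -> "DistSpec":
        if not 0 < q1 <= median <= q3:
            raise ConfigurationError("need 0 < q1 <= median <= q3")
        return cls(median=median, sigma=math.log(q3 / q1) / (2 * _Z75))

    def sample(self, rng: np.random.Generator, size=None):
        return np.exp(math.log(self.median) + self.sigma * rng.standard_normal(size))


#: notes per patient: median 42, IQR 21-82
DEFAULT_NOTES_DIST = DistSpec.from_median_iqr(42, 21, 82)
#: keyword-bearing notes (= merged snippets) per normal-stratum patient;
#: calibrated so the cohort-wide median is 4 after mixing in the strata
DEFAULT_SNIPPETS_DIST = DistSpec(median=3.9, sigma=0.5)
#: words per snippet; calibrated so snippet and merged-document medians are
#: jointly near 199 and 800
DEFAULT_SNIPPET_WORDS_DIST = DistSpec(median=185.0, sigma=0.25)

DEFAULT_LABEL_PROBS = {
    AccessLabel.YES: 0.59,
    AccessLabel.NO: 0.305,
    AccessLabel.NOT_APPLICABLE: 0.055,
    AccessLabel.NOT_SURE: 0.05,
}

#: normal-stratum documents stay under the long-document triage threshold
_NORMAL_DOC_WORD_CAP = 3600
#: exponent of the per-patient snippet length shrink (4/k)^gamma for k > 4
_LENGTH_COUNT_COUPLING = 0.3
_MIN_SNIPPET_WORDS = 30

SPECIALTIES = (
    "medical oncology",
    "radiation oncology",
    "surgery",
    "primary care",
    "gynecology",
    "palliative care",
)

# ---------------------------------------------------------------------------
# Phrase banks. Evidence phrases are fixed, versioned templates; the Yes and
# NotSure phrases contain lexicon keywords so they survive snippet
# extraction. Strings use only characters preserved by clean_text.
# ---------------------------------------------------------------------------

YES_PHRASES = (
    "germline genetic testing was ordered and consent obtained",
    "referred to the genomic medicine service for genetic counseling",
    "genetic testing completed and results reviewed with the patient",
    "recommended germline testing with a multigene panel",
    "consult placed to clinical cancer genetics for genetic counseling",
)

NOT_SURE_PHRASES = (
    "considered for germline genetic testing but did not meet criteria",
    "genetic testing was discussed but the patient did not meet criteria",
)

#: keyword-free "considered but not tested" phrasing for zero-snippet patients
NOT_SURE_PHRASES_KEYWORD_FREE = (
    "testing was considered but the patient did not meet criteria",
)

NOT_APPLICABLE_PHRASES = (
    "all breast cancer care was received in the community",
    "breast cancer care is managed entirely by community providers",
)

#: rule order for the heuristic mock backend: first marker found wins
HEURISTIC_RULES = tuple(
    [(p, AccessLabel.YES) for p in YES_PHRASES]
    + [(p, AccessLabel.NOT_SURE) for p in NOT_SURE_PHRASES]
    + [(p, AccessLabel.NOT_APPLICABLE) for p in NOT_APPLICABLE_PHRASES]
)

#: single keywords planted as incidental mentions in keyword-bearing notes
PLANT_KEYWORDS = (
    "BRCA1",
    "BRCA2",
    "PALB2",
    "CHEK2",
    "TP53",
    "CDH1",
    "PTEN",
    "germline",
)

# Filler vocabulary: shares no word with any default lexicon phrase (so a
# zero-snippet patient can never produce a hit) and cannot compose a marker
# phrase. clean_text-safe.
_FILLER_VOCAB = (
    "patient followup mammogram imaging oncology visit tolerated therapy "
    "chemotherapy radiation lumpectomy margins nodes biopsy pathology stable "
    "reviewed plan continue tamoxifen anastrozole dose cycle labs vitals "
    "unremarkable exam denies pain fatigue nausea improved scheduled clinic "
    "telephone pharmacy refill surveillance ultrasound benign lesion left "
    "right axillary resection adjuvant tolerating well returns months weeks "
    "daily morning noted without symptoms history family mother sister "
    "assessment stage grade receptor status today appointment discussed"
).split()


class CohortConfig(BaseModel):
    """Parameters of the synthetic cohort generator."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=200, ge=0)
    label_probs: dict[AccessLabel, float] = Field(
        default_factory=lambda: dict(DEFAULT_LABEL_PROBS)
    )
    zero_snippet_frac: float = Field(default=0.215, ge=0, le=1)
    high_burden_frac: float = Field(default=0.135, ge=0, le=1)
    notes_per_patient_dist: DistSpec = DEFAULT_NOTES_DIST
    snippets_per_patient_dist: DistSpec = DEFAULT_SNIPPETS_DIST
    snippet_words_dist: DistSpec = DEFAULT_SNIPPET_WORDS_DIST
    disagreement_rate: float = Field(default=0.145, ge=0, le=1)
    exact_allocation: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        probs = {AccessLabel.parse(k): v for k, v in self.label_probs.items()}
        if set(probs) != set(AccessLabel):
            raise ConfigurationError("label_probs must cover all four categories")
        if any(p < 0 for p in probs.values()):
            raise ConfigurationError("label probabilities must be non-negative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("label_probs must sum to 1")
        if self.zero_snippet_frac + self.high_burden_frac > 1:
            raise ConfigurationError("zero_snippet_frac + high_burden_frac must be <= 1")
        p_yes = probs[AccessLabel.YES]
        if self.high_burden_frac > p_yes + 1e-9:
            raise ConfigurationError(
                "high_burden_frac cannot exceed P(Yes): every high-burden "
                "patient is binary-positive"
            )
        if self.zero_snippet_frac > 1 - p_yes + 1e-9:
            raise ConfigurationError(
                "zero_snippet_frac cannot exceed P(not Yes): every zero-snippet "
                "patient is binary-negative"
            )
        object.__setattr__(self, "label_probs", probs)
        return self


@dataclass(frozen=True)
class ReviewRecord:
    """Simulated dual review with adjudicated consensus."""

    patient_id: str
    reviewer_labels: tuple[AccessLabel, AccessLabel]
    consensus: AccessLabel
    had_disagreement: bool

    def __post_init__(self) -> None:
        differ = self.reviewer_labels[0] is not self.reviewer_labels[1]
        if differ != self.had_disagreement:
            raise ContractError("had_disagreement must reflect the reviewer labels")
        if not self.had_disagreement and self.reviewer_labels[0] is not self.consensus:
            raise ContractError("agreeing reviewers must both equal the consensus")


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    truth: AccessLabel
    stratum: Stratum
    notes: tuple[Note, ...]
    review: ReviewRecord


@dataclass(frozen=True)
class SyntheticCohort:
    config: CohortConfig
    patients: tuple[SyntheticPatient, ...]

    @property
    def notes(self) -> list[Note]:
        return [n for p in self.patients for n in p.notes]

    @property
    def truth(self) -> dict[str, AccessLabel]:
        return {p.patient_id: p.truth for p in self.patients}

    @property
    def reviews(self) -> list[ReviewRecord]:
        return [p.review for p in self.patients]


# adjacency used to perturb one reviewer on disagreement
_ADJACENT = {
    AccessLabel.YES: (AccessLabel.NOT_SURE,),
    AccessLabel.NOT_SURE: (AccessLabel.YES, AccessLabel.NO),
    AccessLabel.NO: (AccessLabel.NOT_APPLICABLE, AccessLabel.NOT_SURE),
    AccessLabel.NOT_APPLICABLE: (AccessLabel.NO,),
}


def simulate_reviews(
    truth: AccessLabel,
    disagreement_rate: float,
    rng: np.random.Generator,
    patient_id: str = "",
) -> ReviewRecord:
    """Simulate two independent reviewers plus adjudication.

    The consensus always equals the truth. With probability
    ``disagreement_rate`` exactly one reviewer (chosen at random) is
    perturbed to an adjacent plausible category.
    """
    if not 0 <= disagreement_rate <= 1:
        raise ConfigurationError("disagreement_rate must be in [0, 1]")
    truth = AccessLabel.parse(truth)
    labels = [truth, truth]
    disagreed = bool(rng.random() < disagreement_rate)
    if disagreed:
        which = int(rng.integers(2))
        options = _ADJACENT[truth]
        labels[which] = options[int(rng.integers(len(options)))]
    return ReviewRecord(
        patient_id=patient_id,
        reviewer_labels=(labels[0], labels[1]),
        consensus=truth,
        had_disagreement=disagreed,
    )


def _filler(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(len(_FILLER_VOCAB), size=n)
    return [_FILLER_VOCAB[i] for i in idx]


def _plant_positions(length: int, unit_len: int) -> list[int]:
    """Word positions for keyword plants so the +/-100 windows chain-cover
    the whole note: first plant <= word 100, gaps <= 180, last plant within
    100 words of the end."""
    if length <= 180:
        return [max(0, (length - unit_len) // 2)]
    positions = [80]
    while positions[-1] + unit_len + 100 < length:
        positions.append(min(positions[-1] + 180, length - unit_len))
        if positions[-1] == length - unit_len:
            break
    return positions


def _keyword_note_text(
    rng: np.random.Generator,
    target_words: int,
    evidence_phrase: str | None,
) -> str:
    """A note of exactly ``target_words`` words that snippet extraction will
    return as a single merged snippet covering the whole note."""
    length = max(target_words, _MIN_SNIPPET_WORDS)
    words = _filler(rng, length)
    units: list[list[str]] = []
    if evidence_phrase is not None:
        units.append(evidence_phrase.split())
    first_len = len(units[0]) if units else 1
    positions = _plant_positions(length, first_len)
    for i, pos in enumerate(positions):
        if i < len(units):
            unit = units[i]
        else:
            unit = PLANT_KEYWORDS[int(rng.integers(len(PLANT_KEYWORDS)))].split()
        pos = min(pos, length - len(unit))
        words[pos : pos + len(unit)] = unit
    return " ".join(words[:length])


def _distractor_note_text(
    rng: np.random.Generator, extra_phrase: str | None = None
) -> str:
    """A short keyword-free note; optionally embeds a keyword-free evidence
    phrase (community-care or considered-but-not-tested phrasing)."""
    n = int(rng.integers(20, 80))
    words = _filler(rng, n)
    if extra_phrase is not None:
        unit = extra_phrase.split()
        pos = int(rng.integers(max(1, n - len(unit))))
        words[pos : pos + len(unit)] = unit
    return " ".join(words)


def _check_consistency(label: AccessLabel, stratum: Stratum) -> None:
    if stratum is Stratum.ZERO_SNIPPET and consolidate_to_binary(label) is BinaryLabel.POSITIVE:
        raise ContractError("zero-snippet patients must be binary-negative")
    if stratum is Stratum.HIGH_BURDEN and label is not AccessLabel.YES:
        raise ContractError("high-burden patients must have label Yes")


def generate_note(
    label: AccessLabel,
    stratum: Stratum,
    rng: np.random.Generator,
    target_words: int | None = None,
    evidence: bool = True,
) -> str:
    """Generate one note's text consistent with a label and stratum.

    Zero-snippet strata produce keyword-free distractor text (with
    keyword-free evidence phrasing for NotApplicable/NotSure). Other strata
    produce a keyword-bearing note sized to ``target_words`` (drawn from the
    default snippet-length distribution when omitted) that yields exactly
    one merged snippet; ``evidence`` embeds the label's evidence phrase,
    otherwise only incidental keywords are planted.
    """
    label = AccessLabel.parse(label)
    _check_consistency(label, stratum)
    if stratum is Stratum.ZERO_SNIPPET:
        extra = None
        if label is AccessLabel.NOT_APPLICABLE:
            extra = NOT_APPLICABLE_PHRASES[int(rng.integers(len(NOT_APPLICABLE_PHRASES)))]
        elif label is AccessLabel.NOT_SURE:
            extra = NOT_SURE_PHRASES_KEYWORD_FREE[
                int(rng.integers(len(NOT_SURE_PHRASES_KEYWORD_FREE)))
            ]
        return _distractor_note_text(rng, extra_phrase=extra)
    if target_words is None:
        target_words = int(round(float(DEFAULT_SNIPPET_WORDS_DIST.sample(rng))))
    phrase: str | None = None
    if evidence:
        if label is AccessLabel.YES:
            phrase = YES_PHRASES[int(rng.integers(len(YES_PHRASES)))]
        elif label is AccessLabel.NOT_SURE:
            phrase = NOT_SURE_PHRASES[int(rng.integers(len(NOT_SURE_PHRASES)))]
        elif label is AccessLabel.NOT_APPLICABLE:
            keyword = PLANT_KEYWORDS[int(rng.integers(len(PLANT_KEYWORDS)))]
            marker = NOT_APPLICABLE_PHRASES[int(rng.integers(len(NOT_APPLICABLE_PHRASES)))]
            phrase = f"{keyword} noted; {marker}"
    return _keyword_note_text(rng, target_words, phrase)


def _largest_remainder(probs: Sequence[float], n: int) -> list[int]:
    raw = [p * n for p in probs]
    counts = [math.floor(x) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _draw_labels(config: CohortConfig, rng: np.random.Generator) -> list[AccessLabel]:
    cats = list(AccessLabel)
    probs = [config.label_probs[c] for c in cats]
    if config.exact_allocation:
        counts = _largest_remainder(probs, config.n_patients)
        labels = [c for c, k in zip(cats, counts) for _ in range(k)]
        rng.shuffle(labels)  # in-place permutation of object array is fine
        return list(labels)
    idx = rng.choice(len(cats), size=config.n_patients, p=probs)
    return [cats[i] for i in idx]


def _assign_stratum(
    label: AccessLabel, config: CohortConfig, rng: np.random.Generator
) -> Stratum:
    p_yes = config.label_probs[AccessLabel.YES]
    if label is AccessLabel.YES:
        p_high = config.high_burden_frac / p_yes if p_yes > 0 else 0.0
        return Stratum.HIGH_BURDEN if rng.random() < p_high else Stratum.NORMAL
    p_neg = 1 - p_yes
    p_zero = config.zero_snippet_frac / p_neg if p_neg > 0 else 0.0
    return Stratum.ZERO_SNIPPET if rng.random() < p_zero else Stratum.NORMAL


_EPOCH = datetime.date(2021, 1, 1)


def _random_date(rng: np.random.Generator) -> str:
    return (_EPOCH + datetime.timedelta(days=int(rng.integers(730)))).isoformat()


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a fully labeled synthetic cohort (deterministic per config).

    Each patient gets a truth label, a triage stratum consistent with it,
    notes (keyword-bearing notes sized so snippet extraction recovers the
    intended snippet counts and lengths), and a simulated review record.
    """
    rng = np.random.default_rng(config.seed)
    labels = _draw_labels(config, rng)
    patients: list[SyntheticPatient] = []
    for i, label in enumerate(labels):
        pid = f"p{i:05d}"
        stratum = _assign_stratum(label, config, rng)
        n_notes = max(1, int(round(float(config.notes_per_patient_dist.sample(rng)))))

        if stratum is Stratum.ZERO_SNIPPET:
            n_keyword = 0
            lengths: list[int] = []
        elif stratum is Stratum.HIGH_BURDEN:
            n_keyword = 20 + int(rng.poisson(6))
            lengths = [
                max(_MIN_SNIPPET_WORDS, int(round(x)))
                for x in np.atleast_1d(config.snippet_words_dist.sample(rng, n_keyword))
            ]
        else:
            draw = float(config.snippets_per_patient_dist.sample(rng))
            n_keyword = int(np.clip(round(draw), 1, 19))
            lengths = [
                max(_MIN_SNIPPET_WORDS, int(round(x)))
                for x in np.atleast_1d(config.snippet_words_dist.sample(rng, n_keyword))
            ]
            if n_keyword > 4:
                # snippet length and snippet count are mildly anti-correlated,
                # keeping the merged-document median near its target without
                # shifting the per-note length distribution
                shrink = (4 / n_keyword) ** _LENGTH_COUNT_COUPLING
                lengths = [max(_MIN_SNIPPET_WORDS, int(x * shrink)) for x in lengths]
            total = sum(lengths)
            if total > _NORMAL_DOC_WORD_CAP:  # keep normal docs below the triage cap
                scale = _NORMAL_DOC_WORD_CAP / total
                lengths = [max(_MIN_SNIPPET_WORDS, int(x * scale)) for x in lengths]
        n_notes = max(n_notes, n_keyword)

        keyword_slots = set(
            int(j) for j in rng.choice(n_notes, size=n_keyword, replace=False)
        )
        evidence_slot = min(keyword_slots) if keyword_slots else None

        notes = []
        k = 0
        for j in range(n_notes):
            if j in keyword_slots:
                text = generate_note(
                    label,
                    stratum,
                    rng,
                    target_words=lengths[k],
                    evidence=(j == evidence_slot),
                )
                k += 1
            else:
                # non-keyword notes reuse the zero-snippet recipe, minus any
                # keyword-free evidence phrasing (carried by keyword notes)
                if stratum is Stratum.ZERO_SNIPPET:
                    text = generate_note(label, Stratum.ZERO_SNIPPET, rng)
                else:
                    text = _distractor_note_text(rng)
            notes.append(
                Note(
                    patient_id=pid,
                    note_id=f"{pid}-n{j:04d}",
                    note_date=_random_date(rng),
                    specialty=SPECIALTIES[int(rng.integers(len(SPECIALTIES)))],
                    text=text,
                )
            )
        review = simulate_reviews(label, config.disagreement_rate, rng, patient_id=pid)
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                truth=label,
                stratum=stratum,
                notes=tuple(notes),
                review=review,
            )
        )
    return SyntheticCohort(config=config, patients=tuple(patients))
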