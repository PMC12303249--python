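"""Deterministic pre-classifier routing rules.

Patients with no keyword snippets are labelled negative without model
involvement; patients with an excessive evidence burden (many snippets or a
very long consolidated document) are labelled positive. Everyone else is
routed to the classifier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ContractError
from .snippets import PatientDocument

DEFAULT_SNIPPET_THRESHOLD = 20
DEFAULT_WORD_THRESHOLD = 4000


class Route(str, enum.Enum):
    AUTO_NEGATIVE = "AUTO_NEGATIVE"
    AUTO_POSITIVE = "AUTO_POSITIVE"
    TO_CLASSIFIER = "TO_CLASSIFIER"


class Reason(str, enum.Enum):
    NO_SNIPPETS = "no_snippets"
    HIGH_SNIPPET_COUNT = "high_snippet_count"
    LONG_DOCUMENT = "long_document"
    DEFAULT = "default"


_VALID = {
    Route.AUTO_NEGATIVE: {Reason.NO_SNIPPETS},
    Route.AUTO_POSITIVE: {Reason.HIGH_SNIPPET_COUNT, Reason.LONG_DOCUMENT},
    Route.TO_CLASSIFIER: {Reason.DEFAULT},
}


@dataclass(frozen=True)
class TriageDecision:
    route: Route
    reason: Reason

    def __post_init__(self) -> None:
        if self.reason not in _VALID[self.route]:
            raise ContractError(
                f"inconsistent triage decision: {self.route.value}/{self.reason.value}"
            )


def triage_patient(
    doc: PatientDocument,
    snippet_threshold: int = DEFAULT_SNIPPET_THRESHOLD,
    word_threshold: int = DEFAULT_WORD_THRESHOLD,
) -> TriageDecision:
    """Route one consolidated document.

    Rules, in order: zero snippets -> AUTO_NEGATIVE; snippet count at or
    above ``snippet_threshold`` (inclusive) -> AUTO_POSITIVE; word count
    strictly above ``word_threshold`` -> AUTO_POSITIVE; otherwise
    TO_CLASSIFIER. Word count is measured on the cleaned consolidated text,
    i.e. the same text the classifier would see.
    """
    if snippet_threshold <= 0 or word_threshold <= 0:
        raise ContractError("triage thresholds must be positive")
    if doc.snippet_count < 0 or doc.word_count < 0:
        raise ContractError("negative counts in PatientDocument")
    if doc.snippet_count == 0:
        return TriageDecision(Route.AUTO_NEGATIVE, Reason.NO_SNIPPETS)
    if doc.snippet_count >= snippet_threshold:
        return TriageDecision(Route.AUTO_POSITIVE, Reason.HIGH_SNIPPET_COUNT)
    if doc.word_count > word_threshold:
        return TriageDecision(Route.AUTO_POSITIVE, Reason.LONG_DOCUMENT)
    return TriageDecision(Route.TO_CLASSIFIER, Reason.DEFAULT)
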