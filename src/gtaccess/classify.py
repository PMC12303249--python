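"""Answer-template prompt construction, pluggable backends, response parsing.

The classifier contract is deliberately thin: a backend receives a fully
rendered prompt plus :class:`GenerationSettings` and returns free text. The
pipeline extracts the category from the mandated ``ANSWER: <category>``
scaffold line by regular expression and consolidates it to the binary
outcome. Mock backends (scripted replay and a phrase-rule heuristic) make
the whole pipeline testable without any model weights; a minimal
OpenAI-compatible HTTP adapter is provided for real deployments but is
never exercised by the test suite.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np

from .errors import BackendError, ConfigurationError, ContractError
from .labels import AccessLabel, BinaryLabel, consolidate_to_binary
from .snippets import PatientDocument
from .triage import Route, TriageDecision

DOCUMENT_PLACEHOLDER = "{{document}}"
ANSWER_SCAFFOLD = "ANSWER: {category}"

_CATEGORY_DISPLAY = {
    AccessLabel.YES: "Yes",
    AccessLabel.NO: "No",
    AccessLabel.NOT_APPLICABLE: "Not applicable",
    AccessLabel.NOT_SURE: "Not sure",
}

# Scaffold-line pattern. Longer alternatives first so "Not applicable" is not
# swallowed by "No"; \b keeps "no" from matching the start of "not".
_ANSWER_RE = re.compile(
    r"answer\s*[:\-]*\s*[\"'(]*\s*"
    r"(not\s+applicable|n/?a\b|not\s+sure|unsure|yes|no)\b",
    re.IGNORECASE,
)

_VARIANT_TO_LABEL = {
    "yes": AccessLabel.YES,
    "no": AccessLabel.NO,
    "not applicable": AccessLabel.NOT_APPLICABLE,
    "na": AccessLabel.NOT_APPLICABLE,
    "n/a": AccessLabel.NOT_APPLICABLE,
    "not sure": AccessLabel.NOT_SURE,
    "unsure": AccessLabel.NOT_SURE,
}


@dataclass(frozen=True)
class GenerationSettings:
    """Decoding parameters passed to the backend."""

    temperature: float = 0.75
    top_p: float = 0.9
    max_new_tokens: int = 512
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ConfigurationError("temperature must be non-negative")
        if not 0 < self.top_p <= 1:
            raise ConfigurationError("top_p must be in (0, 1]")
        if self.max_new_tokens <= 0:
            raise ConfigurationError("max_new_tokens must be positive")


@dataclass(frozen=True)
class PromptTemplate:
    """Instruction text with a document placeholder and an answer scaffold."""

    instruction_text: str
    answer_template: str = ANSWER_SCAFFOLD
    document_placeholder: str = DOCUMENT_PLACEHOLDER

    def __post_init__(self) -> None:
        if self.instruction_text.count(self.document_placeholder) != 1:
            raise ConfigurationError(
                f"template must contain the placeholder {self.document_placeholder!r} "
                "exactly once"
            )
        missing = [
            name
            for name in _CATEGORY_DISPLAY.values()
            if name.casefold() not in self.instruction_text.casefold()
        ]
        if missing:
            raise ConfigurationError(f"template is missing category names: {missing}")

    def render(self, document_text: str) -> str:
        return self.instruction_text.replace(self.document_placeholder, document_text)

    @classmethod
    def from_file(cls, path) -> "PromptTemplate":
        with open(path, encoding="utf-8") as fh:
            return cls(fh.read())


def default_template(style: str = "zero_shot") -> PromptTemplate:
    """Load a packaged prompt template asset (zero_shot, prefix or cloze)."""
    from importlib import resources

    path = resources.files("gtaccess.assets").joinpath(f"prompt_{style}.txt")
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ConfigurationError(f"no packaged prompt style {style!r}") from None
    return PromptTemplate(text)


def render_answer(category: AccessLabel, rationale: str = "") -> str:
    """Produce a response in the scaffold format the parser expects."""
    line = ANSWER_SCAFFOLD.format(category=_CATEGORY_DISPLAY[AccessLabel.parse(category)])
    return f"{line}\nRATIONALE: {rationale}" if rationale else line


def build_prompt(doc: PatientDocument, template: PromptTemplate | None = None) -> str:
    """Render the prompt for one consolidated document (deterministic)."""
    if template is None:
        template = default_template()
    if not doc.text.strip():
        raise ContractError(
            f"patient {doc.patient_id!r} has an empty document; "
            "it should have been triaged AUTO_NEGATIVE"
        )
    return template.render(doc.text)


def parse_response(response: str) -> tuple[AccessLabel, bool]:
    """Extract the category from a backend response.

    Case-insensitive scan for the ``ANSWER:`` scaffold line; the first match
    wins. Close variants of the category names ("n/a", "unsure", ...) are
    accepted. When nothing matches, returns ``(NOT_SURE, False)`` so the
    failure is visible downstream rather than fatal.
    """
    match = _ANSWER_RE.search(response or "")
    if not match:
        return AccessLabel.NOT_SURE, False
    token = re.sub(r"\s+", " ", match.group(1).casefold()).strip()
    return _VARIANT_TO_LABEL[token], True


class ClassifierBackend(Protocol):
    """Contract every backend implements."""

    name: str

    def complete(self, prompt: str, settings: GenerationSettings) -> str:
        ...


def prompt_digest(prompt: str) -> str:
    """Stable key for scripting responses to a specific prompt."""
    return hashlib.sha256(prompt.encode("utf-8")).hexdigest()


@dataclass
class ScriptedBackend:
    """Deterministic replay backend for tests and worked examples.

    ``responses`` may be keyed by the exact prompt text or by its
    :func:`prompt_digest`. Unknown prompts get ``default_response``; if that
    is ``None``, the call raises :class:`BackendError`.
    """

    responses: Mapping[str, str]
    default_response: str | None = None
    name: str = "scripted"

    def complete(self, prompt: str, settings: GenerationSettings) -> str:
        if prompt in self.responses:
            return self.responses[prompt]
        digest = prompt_digest(prompt)
        if digest in self.responses:
            return self.responses[digest]
        if self.default_response is None:
            raise BackendError("scripted backend has no response for this prompt")
        return self.default_response

    @classmethod
    def from_plan(
        cls,
        docs: Iterable[PatientDocument],
        plan: Mapping[str, AccessLabel | str],
        template: PromptTemplate | None = None,
        default_response: str | None = None,
    ) -> "ScriptedBackend":
        """Script per-patient answers: ``plan`` maps patient_id -> category
        (rendered through the answer scaffold) or a raw response string."""
        responses: dict[str, str] = {}
        for doc in docs:
            if doc.patient_id not in plan or not doc.text.strip():
                continue
            wanted = plan[doc.patient_id]
            if isinstance(wanted, AccessLabel):
                wanted = render_answer(wanted, rationale="scripted")
            responses[prompt_digest(build_prompt(doc, template))] = wanted
        return cls(responses=responses, default_response=default_response)


@dataclass
class HeuristicBackend:
    """Phrase-rule stand-in for an LLM, usable at desk scale.

    Scans the prompt (hence the embedded document) for marker phrases and
    answers with the first category whose marker appears, in rule order;
    defaults to ``No``. With probability ``error_rate`` the answer is
    flipped to a uniformly random *other* category. Seeded and
    deterministic: the flip draw is keyed to the prompt digest so results do
    not depend on call order.
    """

    rules: Sequence[tuple[str, AccessLabel]]
    error_rate: float = 0.0
    seed: int = 0
    name: str = "heuristic"

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 1:
            raise ConfigurationError("error_rate must be in [0, 1]")

    def _decide(self, prompt: str) -> AccessLabel:
        folded = prompt.casefold()
        for marker, label in self.rules:
            if marker.casefold() in folded:
                return label
        return AccessLabel.NO

    def complete(self, prompt: str, settings: GenerationSettings) -> str:
        label = self._decide(prompt)
        rationale = "marker phrase rule"
        if self.error_rate > 0:
            digest = int(prompt_digest(prompt)[:16], 16)
            rng = np.random.default_rng((self.seed, digest))
            if rng.random() < self.error_rate:
                others = [l for l in AccessLabel if l is not label]
                label = others[rng.integers(len(others))]
                rationale = "randomly perturbed"
        return render_answer(label, rationale=rationale)


def default_heuristic_backend(error_rate: float = 0.0, seed: int = 0) -> HeuristicBackend:
    """Heuristic backend wired to the synthetic generator's phrase banks."""
    from .corpus import HEURISTIC_RULES

    return HeuristicBackend(rules=HEURISTIC_RULES, error_rate=error_rate, seed=seed)


@dataclass
class EndpointBackend:
    """Minimal OpenAI-compatible chat-completions adapter (stdlib only).

    Excluded from the test suite: the core pipeline must build and test with
    no model server. Expects ``base_url`` like ``http://host:8000/v1``.
    """

    base_url: str
    model: str
    api_key: str | None = None
    timeout: float = 120.0
    name: str = "endpoint"

    def complete(self, prompt: str, settings: GenerationSettings) -> str:
        import json
        import urllib.request

        payload = {
            "model": self.model,
            "messages": [{"role": "user", "content": prompt}],
            "temperature": settings.temperature,
            "top_p": settings.top_p,
            "max_tokens": settings.max_new_tokens,
        }
        if settings.seed is not None:
            payload["seed"] = settings.seed
        request = urllib.request.Request(
            self.base_url.rstrip("/") + "/chat/completions",
            data=json.dumps(payload).encode("utf-8"),
            headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
        )
        try:
            with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode("utf-8"))
            return body["choices"][0]["message"]["content"]
        except Exception as exc:  # noqa: BLE001 - adapter boundary
            raise BackendError(f"endpoint request failed: {exc}") from exc


@dataclass(frozen=True)
class PredictionRecord:
    """One patient's routed decision."""

    patient_id: str
    route: Route
    raw_response: str
    category: AccessLabel
    binary: BinaryLabel
    parse_ok: bool

    def __post_init__(self) -> None:
        if self.route is not Route.TO_CLASSIFIER and self.raw_response:
            raise ContractError("auto-routed records must have empty raw_response")
        if self.binary is not consolidate_to_binary(self.category):
            raise ContractError("binary label inconsistent with category")


def _record(pid: str, route: Route, response: str, category: AccessLabel, ok: bool) -> PredictionRecord:
    return PredictionRecord(
        patient_id=pid,
        route=route,
        raw_response=response,
        category=category,
        binary=consolidate_to_binary(category),
        parse_ok=ok,
    )


def classify_cohort(
    docs: Sequence[PatientDocument],
    decisions: Mapping[str, TriageDecision] | Sequence[TriageDecision],
    backend: ClassifierBackend,
    template: PromptTemplate | None = None,
    settings: GenerationSettings | None = None,
    on_progress: Callable[[str], None] | None = None,
) -> list[PredictionRecord]:
    """Run triage-aware classification over a cohort, in input order.

    AUTO_NEGATIVE documents become ``No`` and AUTO_POSITIVE become ``Yes``
    without touching the backend. Backend failures yield a per-patient
    record with ``parse_ok=False`` (category ``NotSure``); if *every*
    backend call fails, a run-level :class:`BackendError` is raised.
    """
    if settings is None:
        settings = GenerationSettings()
    if template is None:
        template = default_template()
    if not isinstance(decisions, Mapping):
        if len(decisions) != len(docs):
            raise ContractError("triage decisions do not align with documents")
        decisions = {d.patient_id: dec for d, dec in zip(docs, decisions)}
    seen = set()
    records: list[PredictionRecord] = []
    attempted = failed = 0
    for doc in docs:
        if doc.patient_id in seen:
            raise ContractError(f"duplicate patient in cohort: {doc.patient_id!r}")
        seen.add(doc.patient_id)
        try:
            decision = decisions[doc.patient_id]
        except KeyError:
            raise ContractError(f"no triage decision for patient {doc.patient_id!r}") from None
        if decision.route is Route.AUTO_NEGATIVE:
            records.append(_record(doc.patient_id, decision.route, "", AccessLabel.NO, True))
        elif decision.route is Route.AUTO_POSITIVE:
            records.append(_record(doc.patient_id, decision.route, "", AccessLabel.YES, True))
        else:
            attempted += 1
            try:
                response = backend.complete(build_prompt(doc, template), settings)
            except BackendError:
                failed += 1
                records.append(
                    _record(doc.patient_id, decision.route, "", AccessLabel.NOT_SURE, False)
                )
                continue
            category, ok = parse_response(response)
            records.append(_record(doc.patient_id, decision.route, response, category, ok))
        if on_progress is not None:
            on_progress(doc.patient_id)
    if attempted and failed == attempted:
        raise BackendError(f"all {attempted} backend calls failed")
    return records
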