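"""The retrieval chatbot: query matching and the question/answer session.

The bot opens with an acceptable EQR explanation, then answers free-text
follow-ups.  Each user query is a (context, request) pair; both halves are
reduced to token bags by the NLP filter, and a double-layer bag-of-words
matcher scores every stored explanation except the initial one.  The
highest-scoring entry (strict improvement, so earlier entries win ties) is
returned; a query sharing no token with any entry draws a canned fallback
that points the user to a healthcare professional.

The knowledge base is frozen for the duration of a session: new patient
data requires a restart, after which the reasoning engine re-evaluates and
rebuilds the repository.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import EmptyRepositoryError
from .explanation import Explanation, ExplanationRepository, _choose_initial
from .textproc import TokenBag, nlp_filter

__all__ = [
    "Query",
    "MatchResult",
    "SessionTurn",
    "SessionLog",
    "nlp_filter",
    "double_layer_matcher",
    "find_specific_explanation",
    "chat_session",
    "RepositoryIndex",
    "FALLBACK_RESPONSES",
]

SATISFACTION_PROMPT = "Are you satisfied with this explanation?"
CONTEXT_PROMPT = "Would you please specify the context of your explanation request?"
REQUEST_PROMPT = "What would you like to know?"

#: Canned replies for queries that match nothing in the repository.
FALLBACK_RESPONSES = (
    "I am sorry, I could not find a stored explanation matching your request. "
    "Please contact a healthcare professional for further queries.",
    "I do not hold information on that. For anything beyond the stored "
    "recommendation, please contact a healthcare professional.",
    "That request is outside the data available to me; a healthcare "
    "professional will be able to help you further.",
)

#: Matcher weights for the context and request layers.
LAMBDA_CONTEXT = 1
LAMBDA_REQUEST = 1


@dataclass(frozen=True)
class Query:
    """A free-text follow-up: a context ``c`` and a specific request ``r``."""

    context: str
    request: str


@dataclass(frozen=True)
class FilteredEntry:
    """An explanation pushed through the NLP filter once."""

    explanation: Explanation
    text_bag: TokenBag
    context_bag: TokenBag  # text tokens plus the entry's context tags


def filter_entry(ex: Explanation) -> FilteredEntry:
    text_bag = nlp_filter(ex.rendered)
    context_bag = text_bag.copy()
    for tag in ex.tags:
        context_bag[tag] += 1
    return FilteredEntry(ex, text_bag, context_bag)


class RepositoryIndex:
    """Pre-filtered repository entries, in repository order."""

    def __init__(self, repo: ExplanationRepository):
        self.repo = repo
        self.entries = tuple(filter_entry(e) for e in repo.entries)


def _overlap(query_bag: TokenBag, entry_bag: TokenBag) -> int:
    return sum(min(n, entry_bag[t]) for t, n in query_bag.items())


def double_layer_matcher(c: TokenBag, r: TokenBag, ex: FilteredEntry) -> int:
    """Clipped term-frequency overlap on two layers.

    The context bag is matched against the entry's text *and* its context
    tags; the request bag against the text alone.  The score is zero iff
    the query shares no token with the entry; the function is pure.
    """
    return LAMBDA_CONTEXT * _overlap(c, ex.context_bag) + LAMBDA_REQUEST * _overlap(
        r, ex.text_bag
    )


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one retrieval: the winning entry (or a fallback), its
    score, and how many entries were scored."""

    explanation: Optional[Explanation]
    text: str
    score: int
    n_scored: int

    @property
    def fallback(self) -> bool:
        return self.explanation is None


def find_specific_explanation(
    q: Query,
    repo: ExplanationRepository,
    initial: Explanation,
    rng: Optional[random.Random] = None,
    index: Optional[RepositoryIndex] = None,
) -> MatchResult:
    """Scan every stored entry except the initial EQR explanation, keep
    the first strictly best scorer, and return it.

    If every score is zero the result is a canned fallback response (drawn
    with ``rng`` when given), never an arbitrary entry.
    """
    c_bag = nlp_filter(q.context)
    r_bag = nlp_filter(q.request)
    entries = (index.entries if index is not None else RepositoryIndex(repo).entries)
    best: Optional[Explanation] = None
    best_score = 0
    n_scored = 0
    for fe in entries:
        if fe.explanation.id == initial.id:
            continue
        n_scored += 1
        score = double_layer_matcher(c_bag, r_bag, fe)
        if score > best_score:
            best_score = score
            best = fe.explanation
    if best is None:
        pick = rng.randrange(len(FALLBACK_RESPONSES)) if rng is not None else 0
        return MatchResult(None, FALLBACK_RESPONSES[pick], 0, n_scored)
    return MatchResult(best, best.rendered, best_score, n_scored)


# --------------------------------------------------------------------------
# Session
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionTurn:
    speaker: str  # "bot" | "user"
    text: str
    explanation_id: Optional[str] = None
    score: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "speaker": self.speaker,
            "text": self.text,
            "explanation_id": self.explanation_id,
            "score": self.score,
        }


@dataclass
class SessionLog:
    """Append-only transcript; the first turn is always the initial EQR
    explanation."""

    turns: list[SessionTurn] = field(default_factory=list)

    def append(self, turn: SessionTurn) -> None:
        self.turns.append(turn)

    def bot_turns(self) -> list[SessionTurn]:
        return [t for t in self.turns if t.speaker == "bot"]

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps(t.to_dict(), sort_keys=True) for t in self.turns
        ) + ("\n" if self.turns else "")


def is_satisfied(reply: str) -> bool:
    text = reply.strip().lower()
    return text in {"y", "ok", "okay", "satisfied"} or text.startswith("yes")


def chat_session(
    repo: ExplanationRepository,
    seed: int,
    turns: Iterable[str],
) -> SessionLog:
    """Run one scripted question/answer session.

    The bot first delivers a seeded-uniform choice among the acceptable
    EQR explanations, then loops: ask whether the user is satisfied; if
    not, request a context and then the specific request, and answer via
    :func:`find_specific_explanation`.  The session ends when the user is
    satisfied or the turn source is exhausted; the bot never emits an
    unprompted message.  The whole transcript is reproducible from
    ``(repo, seed, turns)``.
    """
    if not repo.eqr_entries:
        raise EmptyRepositoryError("cannot start a session without an EQR explanation")
    rng = random.Random(seed)
    initial = _choose_initial(repo, rng)
    index = RepositoryIndex(repo)
    source: Iterator[str] = iter(turns)
    log = SessionLog()
    log.append(SessionTurn("bot", initial.rendered, explanation_id=initial.id))
    while True:
        log.append(SessionTurn("bot", SATISFACTION_PROMPT))
        reply = next(source, None)
        if reply is None:
            break
        log.append(SessionTurn("user", reply))
        if is_satisfied(reply):
            break
        log.append(SessionTurn("bot", CONTEXT_PROMPT))
        context = next(source, None)
        if context is None:
            break
        log.append(SessionTurn("user", context))
        log.append(SessionTurn("bot", REQUEST_PROMPT))
        request = next(source, None)
        if request is None:
            break
        log.append(SessionTurn("user", request))
        result = find_specific_explanation(
            Query(context, request), repo, initial, rng=rng, index=index
        )
        log.append(
            SessionTurn(
                "bot",
                result.text,
                explanation_id=None if result.fallback else result.explanation.id,
                score=result.score,
            )
        )
    return log
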