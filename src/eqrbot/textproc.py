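"""Deterministic text normalization for the retrieval matcher.

Three steps, in order: tokenization (lowercase, split on non-alphanumeric
runs, single-character tokens dropped), stop-word removal against the
shipped list, and lemmatization (shipped exception table, then simple
plural-stripping rules).  Everything is data-file driven so the pipeline is
bit-reproducible with no model download.
"""

from __future__ import annotations

import re
from collections import Counter
from functools import lru_cache
from importlib import resources

#: A token multiset: lowercase lemmata with occurrence counts.
TokenBag = Counter

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _data_text(name: str) -> str:
    return resources.files("eqrbot").joinpath("data", name).read_text()


@lru_cache(maxsize=1)
def stopwords() -> frozenset[str]:
    words = set()
    for line in _data_text("stopwords.txt").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


@lru_cache(maxsize=1)
def lemma_table() -> dict[str, str]:
    table = {}
    for line in _data_text("lemmas.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        surface, lemma = line.split("\t")
        table[surface] = lemma
    return table


def tokenize(text: str) -> list[str]:
    """Lowercase tokens split on non-alphanumeric runs; 1-char tokens
    (stray possessive ``s`` and the like) are dropped."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if len(t) > 1]


def lemmatize(token: str) -> str:
    """Table lookup first, then conservative plural stripping."""
    table = lemma_table()
    if token in table:
        return table[token]
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("sses"):
        return token[:-2]
    if (
        token.endswith("s")
        and len(token) > 3
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    return token


def nlp_filter(text: str) -> TokenBag:
    """Tokenize, drop stop-words, lemmatize; returns the token multiset.

    Pure function of its input and the shipped data files.
    """
    stop = stopwords()
    return Counter(lemmatize(t) for t in tokenize(text) if t not in stop)
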