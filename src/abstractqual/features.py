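"""Per-document linguistic metrics and corpus n-gram tables.

Covers four metric families: baseline surface metrics (characters per word,
words per sentence, ...), syntactic class proportions, the Flesch Reading
Ease score, and Herdan's C lexical-diversity index, plus ranked
unigram/bigram frequency tables per quality group.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

from .corpus import Document
from ._text import STOP_WORDS, porter_stem

__all__ = [
    "FeaturePanel",
    "NGramTable",
    "baseline_metrics",
    "syntactic_proportions",
    "count_syllables",
    "flesch_score",
    "herdan_c",
    "ngram_table",
    "feature_panel",
    "feature_table",
    "FEATURE_ORDER",
]

# Report row order (baseline metrics first, then syntactic/readability,
# then lexical diversity).
FEATURE_ORDER = [
    "chars_per_word",
    "words_per_sentence",
    "sentences_per_100_words",
    "chars_per_100_words",
    "word_count",
    "noun_pct",
    "verb_pct",
    "conj_pct",
    "flesch",
    "herdan_c",
]


@dataclass
class FeaturePanel:
    chars_per_word: float
    words_per_sentence: float
    sentences_per_100_words: float
    chars_per_100_words: float
    word_count: int
    noun_pct: float = float("nan")
    verb_pct: float = float("nan")
    conj_pct: float = float("nan")
    flesch: float = float("nan")
    herdan_c: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


_ALNUM_RE = re.compile(r"[A-Za-z0-9]")


def _char_count(token: str) -> int:
    # letters and digits only; hyphens/apostrophes inside tokens don't count
    return len(_ALNUM_RE.findall(token))


def baseline_metrics(doc: Document) -> FeaturePanel:
    """Surface metrics from the token and sentence streams."""
    n_words = len(doc.tokens)
    if n_words == 0:
        raise ValueError(f"document {doc.id}: metrics undefined for zero tokens")
    n_sents = max(doc.n_sentences, 1)
    n_chars = sum(_char_count(t) for t in doc.tokens)
    cpw = n_chars / n_words
    return FeaturePanel(
        chars_per_word=cpw,
        words_per_sentence=n_words / n_sents,
        sentences_per_100_words=100.0 * n_sents / n_words,
        chars_per_100_words=100.0 * cpw,
        word_count=n_words,
    )


def syntactic_proportions(doc: Document) -> tuple[float, float, float]:
    """Percent of tokens classed NOUN, VERB, CONJ."""
    if not doc.pos:
        raise ValueError(f"document {doc.id}: POS classes required")
    n = len(doc.pos)
    noun = 100.0 * doc.pos.count("NOUN") / n
    verb = 100.0 * doc.pos.count("VERB") / n
    conj = 100.0 * doc.pos.count("CONJ") / n
    return noun, verb, conj


_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")


def count_syllables(word: str) -> int:
    """Heuristic syllable count: vowel groups, silent-e rule, floor 1."""
    w = re.sub(r"[^a-z]", "", word.lower())
    if not w:
        raise ValueError(f"no letters in word {word!r}")
    n = len(_VOWEL_GROUP_RE.findall(w))
    silent_e = w.endswith("e") and not (
        len(w) >= 3 and w.endswith("le") and w[-3] not in "aeiouy"
    )
    if silent_e:
        n -= 1  # "same" -> 1; consonant+"le" keeps its syllable ("table")
    return max(n, 1)


def flesch_score(doc: Document) -> float:
    """Flesch Reading Ease: 206.835 - 1.015*(words/sent) - 84.6*(syll/word)."""
    n_words = len(doc.tokens)
    n_sents = doc.n_sentences
    if n_words == 0 or n_sents == 0:
        raise ValueError(f"document {doc.id}: Flesch undefined")
    syllables = 0
    for t in doc.tokens:
        if re.search(r"[A-Za-z]", t):
            syllables += count_syllables(t)
        else:
            syllables += 1  # numeric token: read as one unit
    return 206.835 - 1.015 * (n_words / n_sents) - 84.6 * (syllables / n_words)


def herdan_c(tokens: Sequence[str]) -> float:
    """Herdan's C (LogTTR): log(distinct)/log(total), lowercased tokens."""
    low = [t.lower() for t in tokens]
    n = len(low)
    if n <= 1:
        raise ValueError("Herdan's C undefined for N <= 1")
    v = len(set(low))
    return math.log(v) / math.log(n)


def feature_panel(doc: Document) -> FeaturePanel:
    """All metrics for one document (herdan_c NaN when N <= 1)."""
    panel = baseline_metrics(doc)
    if doc.pos:
        panel.noun_pct, panel.verb_pct, panel.conj_pct = syntactic_proportions(doc)
    panel.flesch = flesch_score(doc)
    if len(doc.tokens) > 1:
        panel.herdan_c = herdan_c(doc.tokens)
    return panel


def feature_table(docs: Sequence[Document]) -> pd.DataFrame:
    """Per-document feature data frame indexed by document id."""
    rows = {d.id: feature_panel(d).to_dict() for d in docs}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df[FEATURE_ORDER]


# --- n-grams ---------------------------------------------------------------


@dataclass
class NGramTable:
    n: int
    group: str
    entries: list[tuple[str, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gram", "count"])


def _prep_tokens(doc: Document, stem: bool, drop_stop_words: bool) -> list[list[str]]:
    """Lowercased, filtered token runs, one per sentence (bigrams stay inside)."""
    spans = doc.sentences or [(0, len(doc.tokens))]
    runs = []
    for start, end in spans:
        run = []
        for tok in doc.tokens[start:end]:
            low = tok.lower()
            if drop_stop_words and low in STOP_WORDS:
                continue
            run.append(porter_stem(low) if stem else low)
        runs.append(run)
    return runs


def ngram_table(
    docs: Iterable[Document],
    n: int,
    top_k: int = 20,
    group: str = "all",
    stem: bool = True,
    drop_stop_words: bool = True,
) -> NGramTable:
    """Ranked n-gram counts (count desc, ties lexicographic), truncated to top_k."""
    if n not in (1, 2):
        raise ValueError("only unigrams and bigrams are supported")
    counts: dict[str, int] = {}
    for doc in docs:
        for run in _prep_tokens(doc, stem, drop_stop_words):
            if n == 1:
                grams = run
            else:
                grams = [f"{a} {b}" for a, b in zip(run, run[1:])]
            for g in grams:
                counts[g] = counts.get(g, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return NGramTable(n=n, group=group, entries=ranked)
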