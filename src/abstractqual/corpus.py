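"""Corpus data model, I/O, text preprocessing, and quality-label binarization.

A corpus is a list of :class:`Document` objects.  Each document carries the
raw abstract text, a derived token stream, sentence spans over that stream,
coarse part-of-speech classes, an optional 12-item risk-of-bias record, and
an optional trial covariate vector.  The 12-item record is binarized into a
quality label: an article scoring "yes" on at least ``threshold`` (default 6)
of the 12 criteria is labelled high quality (1), otherwise low quality (0).
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Score",
    "RiskOfBiasRecord",
    "CovariateVector",
    "QualityLabel",
    "Document",
    "SchemaError",
    "RowParseError",
    "tokenize",
    "split_sentences",
    "pos_class",
    "register_tagger",
    "binarize_quality",
    "read_corpus",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "encode_covariates",
    "INTERVENTION_LEVELS",
    "CONDITION_LEVELS",
    "DESIGN_LEVELS",
    "CONTROL_LEVELS",
    "N_ROB_ITEMS",
    "DEFAULT_QUALITY_THRESHOLD",
]

N_ROB_ITEMS = 12
DEFAULT_QUALITY_THRESHOLD = 6


class Score(str, enum.Enum):
    """One risk-of-bias criterion score."""

    YES = "yes"
    NO = "no"
    UNSURE = "unsure"

    @classmethod
    def parse(cls, value: str) -> "Score":
        v = str(value).strip().lower()
        aliases = {"y": "yes", "n": "no", "u": "unsure", "unclear": "unsure"}
        v = aliases.get(v, v)
        try:
            return cls(v)
        except ValueError:
            raise ValueError(f"not a risk-of-bias score: {value!r}") from None


@dataclass(frozen=True)
class RiskOfBiasRecord:
    """Exactly 12 criterion scores, each yes/no/unsure."""

    items: tuple[Score, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ROB_ITEMS:
            raise ValueError(
                f"risk-of-bias record needs {N_ROB_ITEMS} items, got {len(self.items)}"
            )
        if not all(isinstance(s, Score) for s in self.items):
            raise TypeError("all items must be Score values")

    @property
    def yes_count(self) -> int:
        return sum(1 for s in self.items if s is Score.YES)

    @classmethod
    def from_strings(cls, values: Sequence[str]) -> "RiskOfBiasRecord":
        return cls(tuple(Score.parse(v) for v in values))


# Closed category sets for the trial covariates.
INTERVENTION_LEVELS = (
    "device",
    "biological/vaccine",
    "procedure/surgery",
    "physical therapy",
    "drug and others",
)
CONDITION_LEVELS = (
    "neoplasms",
    "endocrine, nutritional and metabolic diseases",
    "mental and behavioural disorders",
    "diseases of the nervous system",
    "diseases of the circulatory system",
    "diseases of the respiratory system",
    "diseases of the digestive system",
    "diseases of the musculoskeletal system and connective tissue",
    "others",
)
DESIGN_LEVELS = ("parallel", "cross-over", "factorial")
CONTROL_LEVELS = ("head to head", "placebo", "dose response")


@dataclass(frozen=True)
class CovariateVector:
    """Trial covariates entering the logistic stage."""

    intervention: str
    condition: str
    design: str
    control: str
    arms_flag: int
    sample_size: int

    def __post_init__(self) -> None:
        for name, value, levels in (
            ("intervention", self.intervention, INTERVENTION_LEVELS),
            ("condition", self.condition, CONDITION_LEVELS),
            ("design", self.design, DESIGN_LEVELS),
            ("control", self.control, CONTROL_LEVELS),
        ):
            if value not in levels:
                raise ValueError(f"{name}={value!r} not in {levels}")
        if self.arms_flag not in (0, 1):
            raise ValueError("arms_flag must be 0 or 1")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "condition": self.condition,
            "design": self.design,
            "control": self.control,
            "arms_flag": self.arms_flag,
            "sample_size": self.sample_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateVector":
        return cls(
            intervention=d["intervention"],
            condition=d["condition"],
            design=d["design"],
            control=d["control"],
            arms_flag=int(d["arms_flag"]),
            sample_size=int(d["sample_size"]),
        )


@dataclass(frozen=True)
class QualityLabel:
    """Binary quality label derived from the yes-item count."""

    value: int
    yes_count: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("label value must be 0 or 1")
        if not 0 <= self.yes_count <= N_ROB_ITEMS:
            raise ValueError("yes_count out of range")


def binarize_quality(
    rob: RiskOfBiasRecord, threshold: int = DEFAULT_QUALITY_THRESHOLD
) -> QualityLabel:
    """Label an article high quality (1) iff it scores yes on >= threshold items.

    "unsure" and "no" both count as not-yes.
    """
    yes = rob.yes_count
    return QualityLabel(value=int(yes >= threshold), yes_count=yes)


# --- tokenization & sentence splitting -------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['’-][A-Za-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Split text into word tokens.

    A token is a maximal run of letters/digits; internal hyphens and
    apostrophes are kept ("double-blind" is one token).  Punctuation is
    dropped and a decimal point splits its digits ("0.05" -> "0", "05").
    Casing is preserved.
    """
    return _TOKEN_RE.findall(text)


# trailing words after which a period never ends a sentence
_PROTECTED_ABBREV = frozenset(
    "vs al fig figs eg ie etc dr mr mrs ms no ca cf st jr sr e.g i.e et".split()
)

_SENT_BOUNDARY_RE = re.compile(r"([.!?])\s+(?=[A-Z])")


def split_sentences(text: str) -> list[str]:
    """Split text into sentences.

    A boundary is ``. ! ?`` followed by whitespace and an uppercase letter,
    unless the preceding word is a protected abbreviation.  Decimals never
    split because no whitespace follows their period.  Trailing text without
    terminal punctuation is one sentence.
    """
    if not text.strip():
        return []
    pieces: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        before = text[start : m.end(1)]
        last = re.search(r"([A-Za-z][A-Za-z.]*)\.$", before.rstrip())
        if last and last.group(1).lower().rstrip(".") in _PROTECTED_ABBREV:
            continue
        pieces.append(before.strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return pieces


# --- POS classing ----------------------------------------------------------

POS_CLASSES = ("NOUN", "VERB", "CONJ", "OTHER")

_CONJUNCTIONS = frozenset(
    """and but or nor for so yet because although though while whereas if
    since unless until whether once however moreover furthermore therefore
    thus nevertheless""".split()
)

# small frozen lexicon: common verbs in trial abstracts
_VERB_LEXICON = frozenset(
    """be is are was were been being am have has had do does did receive
    received receives show showed shown shows compare compared compares
    randomize randomized randomise randomised assign assigned allocate
    allocated treat treated measure measured observe observed conduct
    conducted perform performed evaluate evaluated assess assessed include
    included exclude excluded report reported find found increase increased
    decrease decreased reduce reduced improve improved administer
    administered undergo underwent occur occurred use used suggest suggested
    indicate indicated demonstrate demonstrated enrol enrolled enroll
    analyze analyzed analyse analysed determine determined remain remained
    require required differ differed may might can could will would should
    examine examined investigate investigated""".split()
)

_NOUN_LEXICON = frozenset(
    """patient patients group groups study studies trial trials week weeks
    day days month months year years treatment treatments dose doses drug
    drugs placebo effect effects outcome outcomes result results level
    levels rate rates score scores number aspirin therapy surgery cancer
    pressure blood serum sample samples analysis control controls baseline
    mg ml kg p n ci sd""".split()
)

TaggerFn = Callable[[Sequence[str]], list[str]]
_TAGGERS: dict[str, TaggerFn] = {}


def register_tagger(name: str, fn: TaggerFn) -> None:
    """Register a POS tagging backend under ``name``."""
    _TAGGERS[name] = fn


def _lexicon_tagger(tokens: Sequence[str]) -> list[str]:
    out = []
    for tok in tokens:
        low = tok.lower()
        if tok.isdigit():
            out.append("NOUN")  # numbers count as nouns
        elif low in _CONJUNCTIONS:
            out.append("CONJ")
        elif low in _VERB_LEXICON:
            out.append("VERB")
        elif low in _NOUN_LEXICON:
            out.append("NOUN")
        elif tok[:1].isupper() and low not in _VERB_LEXICON:
            out.append("NOUN")  # capitalized names count as nouns
        elif low.endswith(("ed", "ing", "ize", "ise")):
            out.append("VERB")
        elif low.endswith(("tion", "sion", "ment", "ness", "ity", "er", "ers")):
            out.append("NOUN")
        else:
            out.append("OTHER")
    return out


register_tagger("lexicon", _lexicon_tagger)


def pos_class(tokens: Sequence[str], backend: str = "lexicon") -> list[str]:
    """Assign each token one coarse class in {NOUN, VERB, CONJ, OTHER}."""
    if len(tokens) == 0:
        raise ValueError("pos_class requires a non-empty token list")
    try:
        fn = _TAGGERS[backend]
    except KeyError:
        raise KeyError(
            f"unknown tagger backend {backend!r}; registered: {sorted(_TAGGERS)}"
        ) from None
    tags = fn(tokens)
    if len(tags) != len(tokens) or any(t not in POS_CLASSES for t in tags):
        raise ValueError(f"tagger backend {backend!r} violated its contract")
    return tags


# --- Document --------------------------------------------------------------


@dataclass
class Document:
    """One article: abstract text plus derived streams and metadata."""

    id: str
    text: str
    tokens: list[str] = field(default_factory=list)
    sentences: list[tuple[int, int]] = field(default_factory=list)
    pos: list[str] | None = None
    rob: RiskOfBiasRecord | None = None
    covariates: CovariateVector | None = None

    @classmethod
    def from_text(
        cls,
        id: str,
        text: str,
        rob: RiskOfBiasRecord | None = None,
        covariates: CovariateVector | None = None,
        tagger: str | None = "lexicon",
    ) -> "Document":
        """Build a document, deriving tokens, sentence spans and POS classes."""
        sents = split_sentences(text)
        tokens: list[str] = []
        spans: list[tuple[int, int]] = []
        for s in sents:
            toks = tokenize(s)
            if not toks:
                continue
            spans.append((len(tokens), len(tokens) + len(toks)))
            tokens.extend(toks)
        pos = pos_class(tokens, backend=tagger) if (tagger and tokens) else None
        return cls(
            id=id, text=text, tokens=tokens, sentences=spans, pos=pos,
            rob=rob, covariates=covariates,
        )

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    def label(self, threshold: int = DEFAULT_QUALITY_THRESHOLD) -> QualityLabel:
        if self.rob is None:
            raise ValueError(f"document {self.id} has no risk-of-bias record")
        return binarize_quality(self.rob, threshold)

    def to_dict(self, threshold: int = DEFAULT_QUALITY_THRESHOLD) -> dict:
        d: dict = {
            "id": self.id,
            "text": self.text,
            "tokens": self.tokens,
            "sentences": [list(s) for s in self.sentences],
            "pos": self.pos,
        }
        if self.rob is not None:
            d["rob"] = [s.value for s in self.rob.items]
            lab = self.label(threshold)
            d["label"] = lab.value
            d["yes_count"] = lab.yes_count
        if self.covariates is not None:
            d["covariates"] = self.covariates.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Document":
        rob = None
        if d.get("rob") is not None:
            rob = RiskOfBiasRecord.from_strings(d["rob"])
        cov = None
        if d.get("covariates") is not None:
            cov = CovariateVector.from_dict(d["covariates"])
        return cls(
            id=str(d["id"]),
            text=d["text"],
            tokens=list(d.get("tokens") or []),
            sentences=[tuple(s) for s in d.get("sentences") or []],
            pos=list(d["pos"]) if d.get("pos") is not None else None,
            rob=rob,
            covariates=cov,
        )


# --- corpus I/O ------------------------------------------------------------


class SchemaError(ValueError):
    """A mapped column is missing from the input file."""


class RowParseError(ValueError):
    """A row contains an unparseable value; carries row id and column."""

    def __init__(self, row_id: str, column: str, value: object):
        self.row_id, self.column, self.value = row_id, column, value
        super().__init__(
            f"row {row_id!r}: cannot parse column {column!r} value {value!r}"
        )


DEFAULT_SCHEMA = {
    "id": "id",
    "text": "abstract",
    "rob_prefix": "rob",
}

_COVARIATE_COLUMNS = (
    "intervention", "condition", "design", "control", "arms_flag", "sample_size",
)


def read_corpus(
    path: str,
    schema: dict | None = None,
    tagger: str | None = "lexicon",
) -> list[Document]:
    """Read a corpus table (CSV or JSONL by extension) into Documents.

    ``schema`` maps logical fields to column names: keys ``id``, ``text``,
    ``rob_prefix`` (12 columns ``<prefix>1..<prefix>12``), and optionally the
    covariate column names.  Rows with empty abstract text are rejected and
    reported.  Risk-of-bias values parse case-insensitively.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    if str(path).endswith((".jsonl", ".ndjson")):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path, dtype=str)
    if df.empty:
        logger.warning("corpus file %s has no rows", path)
        return []

    id_col, text_col = schema["id"], schema["text"]
    rob_cols = [f"{schema['rob_prefix']}{i}" for i in range(1, N_ROB_ITEMS + 1)]
    for col in [id_col, text_col]:
        if col not in df.columns:
            raise SchemaError(f"missing mapped column {col!r}")
    have_rob = all(c in df.columns for c in rob_cols)
    if not have_rob and any(c in df.columns for c in rob_cols):
        missing = [c for c in rob_cols if c not in df.columns]
        raise SchemaError(f"missing mapped column(s) {missing!r}")
    have_cov = all(schema.get(c, c) in df.columns for c in _COVARIATE_COLUMNS)

    docs: list[Document] = []
    rejected: list[str] = []
    for _, row in df.iterrows():
        rid = str(row[id_col])
        text = row[text_col]
        if not isinstance(text, str) or not text.strip():
            rejected.append(rid)
            continue
        rob = None
        if have_rob:
            try:
                rob = RiskOfBiasRecord.from_strings([row[c] for c in rob_cols])
            except ValueError:
                for c in rob_cols:
                    try:
                        Score.parse(row[c])
                    except ValueError:
                        raise RowParseError(rid, c, row[c]) from None
                raise
        cov = None
        if have_cov:
            cov = CovariateVector(
                intervention=row[schema.get("intervention", "intervention")],
                condition=row[schema.get("condition", "condition")],
                design=row[schema.get("design", "design")],
                control=row[schema.get("control", "control")],
                arms_flag=int(row[schema.get("arms_flag", "arms_flag")]),
                sample_size=int(row[schema.get("sample_size", "sample_size")]),
            )
        docs.append(Document.from_text(rid, text, rob=rob, covariates=cov, tagger=tagger))
    if rejected:
        logger.warning("rejected %d rows with empty text: %s", len(rejected), rejected)
    return docs


def write_corpus_jsonl(
    docs: Iterable[Document], path: str, threshold: int = DEFAULT_QUALITY_THRESHOLD
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_dict(threshold), sort_keys=True) + "\n")


def read_corpus_jsonl(path: str) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                docs.append(Document.from_dict(json.loads(line)))
    return docs


# --- covariate encoding ----------------------------------------------------


def encode_covariates(
    covs: Sequence[CovariateVector],
) -> tuple[np.ndarray, list[str]]:
    """Dummy-encode covariates (drop-first per category) + arms flag + log n.

    Returns a (n, p) float design matrix (no intercept column) and the
    column names.  Sample size enters as log10 to tame its scale.
    """
    names: list[str] = []
    cols: list[np.ndarray] = []
    for attr, levels in (
        ("intervention", INTERVENTION_LEVELS),
        ("condition", CONDITION_LEVELS),
        ("design", DESIGN_LEVELS),
        ("control", CONTROL_LEVELS),
    ):
        values = [getattr(c, attr) for c in covs]
        for level in levels[1:]:
            names.append(f"{attr}[{level}]")
            cols.append(np.array([1.0 if v == level else 0.0 for v in values]))
    names.append("arms_flag")
    cols.append(np.array([float(c.arms_flag) for c in covs]))
    names.append("log10_sample_size")
    cols.append(np.log10([float(c.sample_size) for c in covs]))
    return np.column_stack(cols), names
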