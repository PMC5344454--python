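"""Synthetic corpus generator with known topic/response ground truth.

Documents are drawn from the mixed-membership generative process the model
assumes (Dirichlet document mixtures, multinomial topic-word draws), then
rendered as surface text — pseudo-words grouped into capitalized,
period-terminated sentences — so every linguistic metric is computable.
Pseudo-words carry deterministic coarse POS classes, trial covariates are
drawn from configurable category frequencies, and binary quality labels
follow a logistic model on the dominant topic (or topic proportions) plus
covariates.  A truth bundle records everything needed for parameter-recovery
diagnostics.

The default planted topic log-odds correspond to odds ratios
(1, 3.44, 7.35, 1.19) versus the reference topic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import expit

from .corpus import (
    CONDITION_LEVELS,
    CONTROL_LEVELS,
    DESIGN_LEVELS,
    INTERVENTION_LEVELS,
    CovariateVector,
    Document,
    RiskOfBiasRecord,
    Score,
    encode_covariates,
)
from .slda import SldaModel, predict_quality

__all__ = [
    "SyntheticSpec",
    "SyntheticCorpus",
    "TruthBundle",
    "RecoveryReport",
    "generate_corpus",
    "recovery_report",
]

DEFAULT_ETA = (0.0, math.log(3.44), math.log(7.35), math.log(1.19))

DEFAULT_GAMMA = {
    "log10_sample_size": 2.5,
    "design[cross-over]": -1.5,
    "control[placebo]": 1.0,
}

DEFAULT_COVARIATE_FREQS = {
    "intervention": (0.10, 0.10, 0.20, 0.10, 0.50),
    "condition": (0.15, 0.10, 0.08, 0.10, 0.15, 0.08, 0.10, 0.12, 0.12),
    "design": (0.70, 0.25, 0.05),
    "control": (0.40, 0.50, 0.10),
}


@dataclass(frozen=True)
class SyntheticSpec:
    D: int = 600
    K: int = 4
    V: int = 300
    alpha: float = 0.3
    topic_separation: float = 0.8
    doc_length_mean: float = 60.0
    sentence_length_mean: float = 12.0
    intercept: float = -4.9
    eta_true: tuple[float, ...] = DEFAULT_ETA
    gamma_true: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    covariate_freqs: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_FREQS)
    )
    arms_p: float = 0.85
    log_sample_size_mean: float = math.log(80.0)
    log_sample_size_sd: float = 0.8
    noun_frac: float = 0.40
    verb_frac: float = 0.10
    conj_frac: float = 0.04
    label_encoding: str = "dominant"  # dominant | proportions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 1 or self.K < 2 or self.V < self.K:
            raise ValueError("need D >= 1, K >= 2, V >= K")
        if not 0.0 <= self.topic_separation <= 1.0:
            raise ValueError("topic_separation must be in [0, 1]")
        if len(self.eta_true) != self.K:
            raise ValueError("eta_true must have K entries (reference first)")
        if self.eta_true[0] != 0.0:
            raise ValueError("eta_true is reference-coded: first entry must be 0")
        if min(self.doc_length_mean, self.sentence_length_mean, self.alpha) <= 0:
            raise ValueError("means and alpha must be positive")
        if self.label_encoding not in ("dominant", "proportions"):
            raise ValueError("label_encoding must be dominant or proportions")
        block = int(self.V * self.topic_separation / self.K)
        if self.K * block > self.V:
            raise ValueError("exclusive blocks exceed vocabulary")


@dataclass
class TruthBundle:
    vocab: list[str]
    pos_classes: list[str]
    phi: np.ndarray
    theta: np.ndarray
    dominant: np.ndarray
    eta_full: np.ndarray
    gamma: np.ndarray
    gamma_names: list[str]
    intercept: float
    probs: np.ndarray
    spec: SyntheticSpec
    z: list = field(default_factory=list)  # per-document token-topic draws


@dataclass
class SyntheticCorpus:
    docs: list[Document]
    labels: np.ndarray
    covariates: list[CovariateVector]
    truth: TruthBundle


def _pos_plan(spec: SyntheticSpec) -> list[str]:
    """Deterministic interleaved class assignment tracking target fractions."""
    targets = {
        "NOUN": spec.noun_frac,
        "VERB": spec.verb_frac,
        "CONJ": spec.conj_frac,
        "OTHER": max(1.0 - spec.noun_frac - spec.verb_frac - spec.conj_frac, 0.0),
    }
    counts = dict.fromkeys(targets, 0)
    out = []
    for i in range(spec.V):
        deficits = {c: targets[c] * (i + 1) - counts[c] for c in targets}
        cls = max(sorted(deficits), key=lambda c: deficits[c])
        counts[cls] += 1
        out.append(cls)
    return out


_POS_PREFIX = {"NOUN": "nw", "VERB": "vw", "CONJ": "cw", "OTHER": "ow"}


def _make_phi(spec: SyntheticSpec) -> np.ndarray:
    """Topic-word rows: an exclusive high-mass block per topic.

    The residual mass is spread uniformly over the whole vocabulary (not a
    dedicated shared block) so that no coherent extra "background topic"
    exists in the generating process.
    """
    K, V = spec.K, spec.V
    block = int(V * spec.topic_separation / K)
    phi = np.zeros((K, V))
    ex_mass = 0.95 if block else 0.0
    for k in range(K):
        phi[k, :] = (1.0 - ex_mass) / V
        if block:
            phi[k, k * block : (k + 1) * block] += ex_mass / block
    return phi


def _sample_covariates(spec: SyntheticSpec, rng: np.random.Generator) -> list[CovariateVector]:
    freqs = {**DEFAULT_COVARIATE_FREQS, **spec.covariate_freqs}
    covs = []
    for _ in range(spec.D):
        n = max(2, int(round(rng.lognormal(spec.log_sample_size_mean,
                                           spec.log_sample_size_sd))))
        covs.append(
            CovariateVector(
                intervention=INTERVENTION_LEVELS[
                    rng.choice(len(INTERVENTION_LEVELS), p=freqs["intervention"])
                ],
                condition=CONDITION_LEVELS[
                    rng.choice(len(CONDITION_LEVELS), p=freqs["condition"])
                ],
                design=DESIGN_LEVELS[rng.choice(len(DESIGN_LEVELS), p=freqs["design"])],
                control=CONTROL_LEVELS[rng.choice(len(CONTROL_LEVELS), p=freqs["control"])],
                arms_flag=int(rng.random() < spec.arms_p),
                sample_size=n,
            )
        )
    return covs


def _rob_record(y: int, rng: np.random.Generator) -> RiskOfBiasRecord:
    # plumbing, not biology: yes-count consistent with the label by construction
    yes_count = int(rng.integers(6, 13)) if y == 1 else int(rng.integers(0, 6))
    idx = rng.permutation(12)
    items: list[Score] = [Score.NO] * 12
    for j in idx[:yes_count]:
        items[j] = Score.YES
    for j in idx[yes_count:]:
        items[j] = Score.NO if rng.random() < 0.5 else Score.UNSURE
    return RiskOfBiasRecord(tuple(items))


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Sample a full corpus with surface text, labels, covariates and truth."""
    rng = np.random.default_rng(spec.seed)
    K, V, D = spec.K, spec.V, spec.D

    pos_classes = _pos_plan(spec)
    vocab = [f"{_POS_PREFIX[c]}{i}q" for i, c in enumerate(pos_classes)]
    phi = _make_phi(spec)
    theta = rng.dirichlet(np.full(K, spec.alpha), size=D)
    dominant = theta.argmax(axis=1)

    covs = _sample_covariates(spec, rng)
    X, gamma_names = encode_covariates(covs)
    gamma = np.zeros(X.shape[1])
    for name, value in spec.gamma_true.items():
        if name not in gamma_names:
            raise ValueError(f"unknown covariate column {name!r} in gamma_true")
        gamma[gamma_names.index(name)] = value

    eta_full = np.asarray(spec.eta_true, dtype=float)
    if spec.label_encoding == "dominant":
        lin = spec.intercept + eta_full[dominant] + X @ gamma
    else:
        lin = spec.intercept + theta @ eta_full + X @ gamma
    probs = expit(lin)
    labels = (rng.random(D) < probs).astype(int)

    docs = []
    z_records = []
    for d in range(D):
        length = max(5, int(rng.poisson(spec.doc_length_mean)))
        z = rng.choice(K, size=length, p=theta[d])
        z_records.append(z)
        word_ids = np.array(
            [rng.choice(V, p=phi[k]) for k in z], dtype=int
        )
        tokens_lower = [vocab[w] for w in word_ids]
        pos = [pos_classes[w] for w in word_ids]

        # group into sentences, capitalize first word, terminal period
        sent_texts = []
        spans = []
        start = 0
        tokens_surface: list[str] = []
        while start < length:
            slen = min(max(3, int(rng.poisson(spec.sentence_length_mean))),
                       length - start)
            if length - (start + slen) < 3:
                slen = length - start
            chunk = tokens_lower[start : start + slen]
            chunk = [chunk[0].capitalize()] + chunk[1:]
            sent_texts.append(" ".join(chunk) + ".")
            spans.append((start, start + slen))
            tokens_surface.extend(chunk)
            start += slen
        text = " ".join(sent_texts)

        docs.append(
            Document(
                id=f"syn{d:05d}",
                text=text,
                tokens=tokens_surface,
                sentences=spans,
                pos=pos,
                rob=_rob_record(int(labels[d]), rng),
                covariates=covs[d],
            )
        )

    truth = TruthBundle(
        vocab=vocab, pos_classes=pos_classes, phi=phi, theta=theta,
        dominant=dominant, eta_full=eta_full, gamma=gamma,
        gamma_names=gamma_names, intercept=spec.intercept, probs=probs,
        spec=spec, z=z_records,
    )
    return SyntheticCorpus(docs=docs, labels=labels, covariates=covs, truth=truth)


@dataclass
class RecoveryReport:
    topic_match: list[int]            # fitted topic index per truth topic
    mean_matched_cosine: float
    matched_cosines: list[float]
    eta_errors: list[float]           # fitted - true, reference-normalized
    eta_sign_agreement: float         # over non-reference true coefficients
    heldout_auc: float | None


def _aligned_phi(truth: TruthBundle, model: SldaModel) -> tuple[np.ndarray, np.ndarray]:
    """Restrict truth and fitted phi to the shared vocabulary, renormalized."""
    truth_index = {w: i for i, w in enumerate(truth.vocab)}
    common = [w for w in model.vocab if w in truth_index]
    if not common:
        raise ValueError("no shared vocabulary between truth and fitted model")
    t_idx = [truth_index[w] for w in common]
    m_idx = [model.vocab.index(w) for w in common]
    pt = truth.phi[:, t_idx]
    pm = model.phi[:, m_idx]
    pt = pt / pt.sum(axis=1, keepdims=True)
    pm = pm / pm.sum(axis=1, keepdims=True)
    return pt, pm


def recovery_report(
    corpus: SyntheticCorpus,
    model: SldaModel,
    heldout: Sequence[int] | None = None,
) -> RecoveryReport:
    """Match fitted topics to truth and measure recovery quality.

    ``heldout`` gives document indices for the held-out AUC (documents the
    model was not fit on); None skips that diagnostic.
    """
    truth = corpus.truth
    if model.K != truth.phi.shape[0]:
        raise ValueError("fitted K differs from the generating K")
    pt, pm = _aligned_phi(truth, model)
    norm_t = np.linalg.norm(pt, axis=1)
    norm_m = np.linalg.norm(pm, axis=1)
    cos = (pt @ pm.T) / np.outer(norm_t, norm_m)
    row, col = linear_sum_assignment(-cos)  # optimal matching for any K
    match = [int(col[list(row).index(t)]) for t in range(model.K)]
    cosines = [float(cos[t, match[t]]) for t in range(model.K)]

    eta_fit = np.array([model.eta_full[match[t]] for t in range(model.K)])
    eta_fit = eta_fit - eta_fit[0]  # re-reference to the truth reference topic
    errors = eta_fit - truth.eta_full
    nonref = truth.eta_full[1:]
    signs = np.sign(eta_fit[1:]) == np.sign(nonref)
    agreement = float(np.mean(signs)) if len(nonref) else 1.0

    auc_val = None
    if heldout is not None:
        from .evaluation import auc as auc_fn

        probs, ys = [], []
        for i in heldout:
            try:
                probs.append(
                    predict_quality(model, corpus.docs[i], corpus.covariates[i])
                )
                ys.append(int(corpus.labels[i]))
            except ValueError:
                continue
        if len(set(ys)) == 2:
            auc_val = float(auc_fn(probs, ys))

    return RecoveryReport(
        topic_match=match,
        mean_matched_cosine=float(np.mean(cosines)),
        matched_cosines=cosines,
        eta_errors=[float(e) for e in errors],
        eta_sign_agreement=agreement,
        heldout_auc=auc_val,
    )


def corpus_to_frame(corpus: SyntheticCorpus) -> pd.DataFrame:
    """Tabular view (id, text, rob1..rob12, covariates) for CSV round-trips."""
    rows = []
    for doc, cov in zip(corpus.docs, corpus.covariates):
        row = {"id": doc.id, "abstract": doc.text}
        for j, s in enumerate(doc.rob.items, start=1):
            row[f"rob{j}"] = s.value
        row.update(cov.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
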