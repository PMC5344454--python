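"""Supervised topic model over abstracts with a logistic quality response.

The generative view: every document mixes K latent topics (Dirichlet prior
on the per-document mixture, multinomial topic-word distributions), and the
binary quality label follows a logistic model on the document's topic
make-up plus trial covariates.

Fitting is stochastic EM: collapsed Gibbs sweeps over token-topic
assignments carry a supervised reweighting term p(y_d | topic mixture), and
the logistic response stage (intercept, topic coefficients, covariate
coefficients) is refit periodically.  A ``two_stage`` mode (plain LDA, then
one logistic fit) is kept as a diagnostic baseline.

Topics are canonically ordered by descending corpus prevalence after
fitting; topic 1 (the most prevalent) is the reference category of the
response stage, so odds ratios read "versus topic 1".
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from sklearn.model_selection import StratifiedKFold

from . import _gibbs
from ._logistic import LogisticFit, fit_logistic
from ._text import STOP_WORDS, porter_stem
from .corpus import CovariateVector, Document, encode_covariates
from .evaluation import auc

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "SldaModel",
    "build_vocab",
    "fit_slda",
    "predict_quality",
    "select_num_topics",
    "stepwise_covariates",
    "topic_odds_ratios",
    "top_words",
]


@dataclass(frozen=True)
class FitConfig:
    iterations: int = 200
    burn_in: int = 100
    alpha: float | None = 1.0           # None -> 50/K
    beta_prior: float = 0.01
    seed: int = 0
    mode: str = "joint"                 # joint | two_stage
    tolerance: float = 0.05
    refit_every: int = 20
    encoding: str = "dominant_dummy"    # dominant_dummy | proportions
    min_df: int = 2
    stem: bool = True
    drop_stop_words: bool = True
    predict_iterations: int = 60
    predict_burn_in: int = 30

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.mode not in ("joint", "two_stage"):
            raise ValueError("mode must be joint or two_stage")
        if self.encoding not in ("dominant_dummy", "proportions"):
            raise ValueError("encoding must be dominant_dummy or proportions")


def _model_tokens(doc: Document, stem: bool, drop_stop_words: bool) -> list[str]:
    out = []
    for tok in doc.tokens:
        low = tok.lower()
        if drop_stop_words and low in STOP_WORDS:
            continue
        out.append(porter_stem(low) if stem else low)
    return out


def build_vocab(
    docs: Sequence[Document],
    min_df: int = 2,
    stem: bool = True,
    drop_stop_words: bool = True,
) -> tuple[list[str], list[np.ndarray]]:
    """Build the model vocabulary and per-document word-id arrays.

    Tokens are lowercased, stop-words removed, stemmed, and words occurring
    in fewer than ``min_df`` documents dropped.
    """
    doc_tokens = [_model_tokens(d, stem, drop_stop_words) for d in docs]
    df_count: dict[str, int] = {}
    for toks in doc_tokens:
        for w in set(toks):
            df_count[w] = df_count.get(w, 0) + 1
    vocab = sorted(w for w, c in df_count.items() if c >= min_df)
    index = {w: i for i, w in enumerate(vocab)}
    bows = [
        np.array([index[w] for w in toks if w in index], dtype=np.int32)
        for toks in doc_tokens
    ]
    return vocab, bows


@dataclass
class SldaModel:
    K: int
    vocab: list[str]
    phi: np.ndarray                 # (K, V)
    theta: np.ndarray               # (D, K)
    alpha: float
    beta: float
    intercept: float
    eta_topics: np.ndarray          # (K-1,) topic 1 is the reference
    gamma_cov: np.ndarray           # aligned with cov_names
    cov_names: list[str]
    encoding: str
    seed: int
    stage: LogisticFit
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    ridged: bool = False
    stem: bool = True
    drop_stop_words: bool = True

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("vocabulary contains duplicates")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("phi rows must sum to 1")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("theta rows must sum to 1")

    @property
    def eta_full(self) -> np.ndarray:
        """Topic coefficients including the reference zero."""
        return np.concatenate([[0.0], self.eta_topics])

    def to_json(self, path: str) -> None:
        payload = {
            "K": self.K,
            "vocab": self.vocab,
            "phi": self.phi.tolist(),
            "theta": self.theta.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
            "intercept": self.intercept,
            "eta_topics": self.eta_topics.tolist(),
            "gamma_cov": self.gamma_cov.tolist(),
            "cov_names": self.cov_names,
            "encoding": self.encoding,
            "seed": self.seed,
            "stage_coef": self.stage.coef.tolist(),
            "stage_cov": self.stage.cov.tolist(),
            "stage_llf": self.stage.llf,
            "stage_aic": self.stage.aic,
            "stage_names": self.stage.names,
            "loglik_trace": self.loglik_trace.tolist(),
            "ridged": self.ridged,
            "stem": self.stem,
            "drop_stop_words": self.drop_stop_words,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SldaModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        stage = LogisticFit(
            coef=np.array(d["stage_coef"]),
            cov=np.array(d["stage_cov"]),
            llf=d["stage_llf"],
            aic=d["stage_aic"],
            ridged=d["ridged"],
            names=d["stage_names"],
        )
        return cls(
            K=d["K"], vocab=d["vocab"],
            phi=np.array(d["phi"]), theta=np.array(d["theta"]),
            alpha=d["alpha"], beta=d["beta"],
            intercept=d["intercept"],
            eta_topics=np.array(d["eta_topics"]),
            gamma_cov=np.array(d["gamma_cov"]),
            cov_names=d["cov_names"], encoding=d["encoding"], seed=d["seed"],
            stage=stage, loglik_trace=np.array(d["loglik_trace"]),
            ridged=d["ridged"], stem=d["stem"],
            drop_stop_words=d["drop_stop_words"],
        )


def _as_cov_matrix(
    covariates, n: int
) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, np.ndarray):
        return covariates, [f"cov{i}" for i in range(covariates.shape[1])]
    return encode_covariates(covariates)


def _collapsed_loglik(
    ndk, nkw, nk, doc_len, alpha, beta, eta_full, base, y, supervised
) -> float:
    K, V = nkw.shape
    D = ndk.shape[0]
    ll = K * (gammaln(V * beta) - V * gammaln(beta))
    ll += gammaln(nkw + beta).sum() - gammaln(nk + V * beta).sum()
    ll += D * (gammaln(K * alpha) - K * gammaln(alpha))
    ll += gammaln(ndk + alpha).sum() - gammaln(doc_len + K * alpha).sum()
    if supervised:
        zbar = ndk / doc_len[:, None]
        lin = base + zbar @ eta_full
        ll += float(np.sum(y * lin - np.logaddexp(0.0, lin)))
    return float(ll)


def _topic_encoding(theta: np.ndarray, encoding: str) -> np.ndarray:
    """Drop-reference design columns for topics 2..K."""
    K = theta.shape[1]
    if encoding == "dominant_dummy":
        dom = np.argmax(theta, axis=1)
        return np.column_stack([(dom == k).astype(float) for k in range(1, K)])
    return theta[:, 1:]


def _fit_stage(
    theta: np.ndarray,
    X_cov: np.ndarray,
    cov_names: list[str],
    y: np.ndarray,
    encoding: str,
) -> LogisticFit:
    K = theta.shape[1]
    enc = _topic_encoding(theta, encoding)
    design = np.column_stack([enc, X_cov]) if X_cov.size else enc
    names = [f"topic{k}" for k in range(2, K + 1)] + list(cov_names)
    return fit_logistic(design, y, names=names)


def fit_slda(
    docs: Sequence[Document],
    labels: Sequence[int],
    covariates: Sequence[CovariateVector] | np.ndarray | None,
    K: int,
    cfg: FitConfig = FitConfig(),
    _vocab_bows: tuple[list[str], list[np.ndarray]] | None = None,
) -> SldaModel:
    """Fit the supervised topic model; deterministic given cfg.seed."""
    y = np.asarray(labels, dtype=np.int8)
    D = len(docs)
    if K >= D:
        raise ValueError(f"K={K} must be smaller than the corpus size {D}")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 documents per label class")

    vocab, bows = _vocab_bows or build_vocab(
        docs, min_df=cfg.min_df, stem=cfg.stem, drop_stop_words=cfg.drop_stop_words
    )
    V = len(vocab)
    if V < K:
        raise ValueError("vocabulary smaller than topic count; lower min_df")
    keep = [i for i, b in enumerate(bows) if len(b) > 0]
    if len(keep) < D:
        raise ValueError(
            f"{D - len(keep)} documents have no in-vocabulary tokens"
        )

    words = np.concatenate(bows)
    doc_ids = np.concatenate(
        [np.full(len(b), i, dtype=np.int32) for i, b in enumerate(bows)]
    )
    doc_len = np.array([len(b) for b in bows], dtype=np.float64)
    X_cov, cov_names = _as_cov_matrix(covariates, D)

    alpha = cfg.alpha if cfg.alpha is not None else 50.0 / K
    beta = cfg.beta_prior
    supervised = cfg.mode == "joint"

    ndk = np.zeros((D, K), dtype=np.int32)
    nkw = np.zeros((K, V), dtype=np.int32)
    nk = np.zeros(K, dtype=np.int32)
    _gibbs.seed_rng(cfg.seed)
    z = _gibbs.init_assignments(words, doc_ids, K, ndk, nkw, nk)

    eta_full = np.zeros(K)
    base = np.zeros(D)
    gamma = np.zeros(X_cov.shape[1])
    intercept = 0.0
    dot = ndk @ eta_full
    ridged = False

    acc_ndk = np.zeros((D, K))
    acc_nkw = np.zeros((K, V))
    trace = np.empty(cfg.iterations)

    for it in range(cfg.iterations):
        _gibbs.gibbs_sweep(
            z, words, doc_ids, ndk, nkw, nk,
            alpha, beta, eta_full, base, dot, y, doc_len,
            supervised,
        )
        assert nk.sum() == len(words)  # token conservation
        if supervised and (it + 1) % cfg.refit_every == 0:
            zbar = ndk / doc_len[:, None]
            design = (
                np.column_stack([zbar[:, 1:], X_cov]) if X_cov.size else zbar[:, 1:]
            )
            fit = fit_logistic(design, y)
            ridged = ridged or fit.ridged
            intercept = fit.coef[0]
            eta_full = np.concatenate([[0.0], fit.coef[1 : K]])
            gamma = fit.coef[K:]
            base = intercept + (X_cov @ gamma if X_cov.size else np.zeros(D))
            dot = ndk @ eta_full
        trace[it] = _collapsed_loglik(
            ndk, nkw, nk, doc_len, alpha, beta, eta_full, base, y, supervised
        )
        if it >= cfg.burn_in:
            acc_ndk += ndk
            acc_nkw += nkw

    n_kept = cfg.iterations - cfg.burn_in
    theta = (acc_ndk / n_kept + alpha)
    theta /= theta.sum(axis=1, keepdims=True)
    phi = (acc_nkw / n_kept + beta)
    phi /= phi.sum(axis=1, keepdims=True)

    # canonical topic order: descending corpus prevalence; topic 1 = reference
    order = np.argsort(-theta.sum(axis=0), kind="stable")
    theta = theta[:, order]
    phi = phi[order, :]

    stage = _fit_stage(theta, X_cov, cov_names, y, cfg.encoding)
    ridged = ridged or stage.ridged
    if stage.ridged:
        logger.warning("logistic stage hit separation; ridge fallback used")

    return SldaModel(
        K=K, vocab=vocab, phi=phi, theta=theta, alpha=alpha, beta=beta,
        intercept=float(stage.coef[0]),
        eta_topics=np.asarray(stage.coef[1:K]),
        gamma_cov=np.asarray(stage.coef[K:]),
        cov_names=cov_names, encoding=cfg.encoding, seed=cfg.seed,
        stage=stage, loglik_trace=trace, ridged=ridged,
        stem=cfg.stem, drop_stop_words=cfg.drop_stop_words,
    )


def _doc_word_ids(model: SldaModel, doc: Document) -> np.ndarray:
    index = {w: i for i, w in enumerate(model.vocab)}
    toks = _model_tokens(doc, model.stem, model.drop_stop_words)
    ids = [index[w] for w in toks if w in index]
    if not ids:
        raise ValueError(f"document {doc.id}: no in-vocabulary words")
    return np.array(ids, dtype=np.int32)


def infer_theta(
    model: SldaModel, doc: Document, n_iter: int = 60, burn_in: int = 30
) -> np.ndarray:
    """Fold-in inference of the topic mixture for a new document."""
    ids = _doc_word_ids(model, doc)
    # per-document deterministic seed, independent of call order
    sub = (model.seed * 1000003 + int(ids.sum()) * 31 + len(ids)) % (2**31 - 1)
    _gibbs.seed_rng(sub)
    return _gibbs.fold_in(ids, model.phi, model.alpha, n_iter, burn_in)


def predict_quality(
    model: SldaModel,
    doc: Document,
    cov: CovariateVector | np.ndarray | None = None,
    n_iter: int = 60,
    burn_in: int = 30,
) -> float:
    """Probability the document is high quality (label 1)."""
    theta = infer_theta(model, doc, n_iter=n_iter, burn_in=burn_in)
    enc = _topic_encoding(theta[None, :], model.encoding)[0]
    lin = model.intercept + float(enc @ model.eta_topics)
    if model.gamma_cov.size:
        if cov is None:
            raise ValueError("model was fit with covariates; cov required")
        if isinstance(cov, CovariateVector):
            x_full, names = encode_covariates([cov])
            sel = [names.index(n) for n in model.cov_names]
            x = x_full[0, sel]
        else:
            x = np.asarray(cov, dtype=float)
        lin += float(x @ model.gamma_cov)
    return float(expit(lin))


def select_num_topics(
    docs: Sequence[Document],
    labels: Sequence[int],
    covariates: Sequence[CovariateVector] | np.ndarray | None,
    K_grid: Sequence[int],
    folds: int = 10,
    cfg: FitConfig = FitConfig(),
    n_repeats: int = 2,
) -> tuple[int, pd.DataFrame]:
    """Choose the topic count by stratified K-fold CV on validation AUC.

    Ties go to the smaller K.  Folds whose validation split is single-class
    are excluded with a warning.  Each fold is averaged over ``n_repeats``
    independent Gibbs chains; fold seeds are shared across K values (paired
    comparisons) to damp chain noise in the argmax.
    """
    y = np.asarray(labels, dtype=int)
    docs = list(docs)
    covs = None if covariates is None else list(covariates) \
        if not isinstance(covariates, np.ndarray) else covariates
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    def take(seq, idx):
        if seq is None:
            return None
        if isinstance(seq, np.ndarray):
            return seq[idx]
        return [seq[i] for i in idx]

    rows = []
    for K in K_grid:
        fold_aucs = []
        for f, (tr, va) in enumerate(splits):
            if len(np.unique(y[va])) < 2:
                logger.warning("fold %d: single-class validation set, skipped", f)
                fold_aucs.append(np.nan)
                continue
            chain_aucs = []
            for r in range(n_repeats):
                model = fit_slda(
                    [docs[i] for i in tr], y[tr], take(covs, tr), K,
                    cfg=dataclasses.replace(
                        cfg, seed=cfg.seed + 104729 * f + 15485863 * r
                    ),
                )
                probs = []
                ok = np.ones(len(va), dtype=bool)
                for j, i in enumerate(va):
                    try:
                        probs.append(
                            predict_quality(
                                model, docs[i],
                                None if covs is None else covs[i],
                                n_iter=cfg.predict_iterations,
                                burn_in=cfg.predict_burn_in,
                            )
                        )
                    except ValueError:
                        ok[j] = False
                yv = y[va][ok]
                if len(np.unique(yv)) < 2:
                    continue
                chain_aucs.append(auc(probs, yv))
            fold_aucs.append(float(np.mean(chain_aucs)) if chain_aucs else np.nan)
        rows.append([K] + fold_aucs + [float(np.nanmean(fold_aucs))])

    cols = ["K"] + [f"fold{i}" for i in range(folds)] + ["mean_auc"]
    cv_table = pd.DataFrame(rows, columns=cols).set_index("K")
    best = cv_table["mean_auc"]
    K_star = int(best.index[np.argmax(best.to_numpy())])  # argmax: first max wins
    # enforce ties -> smallest K explicitly
    K_star = int(min(k for k in best.index if best[k] == best.max()))
    return K_star, cv_table


def _covariate_blocks(names: Sequence[str]) -> dict[str, list[int]]:
    blocks: dict[str, list[int]] = {}
    for i, n in enumerate(names):
        block = n.split("[")[0]
        blocks.setdefault(block, []).append(i)
    return blocks


def stepwise_covariates(
    model: SldaModel,
    labels: Sequence[int],
    covariates: Sequence[CovariateVector] | np.ndarray,
) -> tuple[list[str], SldaModel]:
    """Bidirectional AIC stepwise over covariate blocks; topics stay in.

    Categorical covariates enter/leave as whole dummy blocks.  Returns the
    selected block names and a model with the response stage refit on them.
    """
    y = np.asarray(labels, dtype=int)
    X_full, names = _as_cov_matrix(covariates, len(y))
    blocks = _covariate_blocks(names)
    enc = _topic_encoding(model.theta, model.encoding)
    topic_names = [f"topic{k}" for k in range(2, model.K + 1)]

    def fit_with(selected: tuple[str, ...]) -> LogisticFit:
        idx = [i for b in selected for i in blocks[b]]
        design = np.column_stack([enc, X_full[:, idx]]) if idx else enc
        return fit_logistic(
            design, y, names=topic_names + [names[i] for i in idx]
        )

    selected: tuple[str, ...] = ()
    current = fit_with(selected)
    cache = {selected: current}
    while True:
        moves = []
        for b in blocks:
            if b in selected:
                cand = tuple(x for x in selected if x != b)
            else:
                cand = tuple(sorted(selected + (b,)))
            if cand not in cache:
                cache[cand] = fit_with(cand)
            moves.append((cache[cand].aic, cand))
        best_aic, best_sel = min(moves, key=lambda m: (m[0], len(m[1])))
        if best_aic < current.aic - 1e-9:
            selected, current = best_sel, cache[best_sel]
        else:
            break

    idx = [i for b in selected for i in blocks[b]]
    new = dataclasses.replace(
        model,
        intercept=float(current.coef[0]),
        eta_topics=np.asarray(current.coef[1 : model.K]),
        gamma_cov=np.asarray(current.coef[model.K :]),
        cov_names=[names[i] for i in idx],
        stage=current,
        ridged=model.ridged or current.ridged,
    )
    return sorted(selected), new


def topic_odds_ratios(model: SldaModel) -> pd.DataFrame:
    """Per-topic odds ratios vs topic 1, 95% Wald CIs and p-values."""
    from scipy import stats as sps

    rows = [
        {"topic": 1, "OR": None, "ci_low": None, "ci_high": None,
         "p": None, "note": "Ref."}
    ]
    se = model.stage.se
    for k in range(2, model.K + 1):
        i = k - 1  # stage coef index (0 = intercept)
        coef, s = model.stage.coef[i], se[i]
        z = coef / s if s > 0 else np.inf
        note = "ridge" if model.stage.ridged else ""
        rows.append(
            {
                "topic": k,
                "OR": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - 1.96 * s)),
                "ci_high": float(np.exp(coef + 1.96 * s)),
                "p": float(2 * sps.norm.sf(abs(z))),
                "note": note,
            }
        )
    return pd.DataFrame(rows).set_index("topic")


def top_words(model: SldaModel, topic: int, n: int = 10) -> list[str]:
    """The n highest-probability words of a topic (1-based index)."""
    if not 1 <= topic <= model.K:
        raise IndexError(f"topic {topic} out of range 1..{model.K}")
    row = model.phi[topic - 1]
    ranked = sorted(zip(-row, model.vocab))
    return [w for _, w in ranked[:n]]
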