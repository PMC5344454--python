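"""End-to-end orchestration: features -> group tests -> model -> evaluation.

``run_full_analysis`` executes every stage in order and writes a report
bundle (CSV/JSON artifacts) to the output directory.  The bundle is a pure
function of the input corpus and the run configuration; a manifest stamps
every run with the config hash and seeds.  Any stage failure aborts with the
stage name while preserving artifacts already written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import evaluation, features, group_stats, slda
from .corpus import Document, read_corpus, read_corpus_jsonl

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    corpus_path: str = ""
    out_dir: str = "out"
    threshold: int = 6
    k_grid: tuple[int, ...] = tuple(range(2, 11))
    folds: int = 10
    seed: int = 0
    encoding: str = "dominant_dummy"
    positive_class: str = "low_quality"
    stem: bool = True
    drop_stop_words: bool = True
    top_k_ngrams: int = 20
    top_n_words: int = 10
    iterations: int = 200
    burn_in: int = 100
    cv_iterations: int = 120
    cv_burn_in: int = 60
    min_df: int = 2
    run_stepwise: bool = True

    def fit_config(self, cv: bool = False) -> slda.FitConfig:
        return slda.FitConfig(
            iterations=self.cv_iterations if cv else self.iterations,
            burn_in=self.cv_burn_in if cv else self.burn_in,
            seed=self.seed,
            encoding=self.encoding,
            min_df=self.min_df,
            stem=self.stem,
            drop_stop_words=self.drop_stop_words,
        )

    def hash(self) -> str:
        # output location excluded: the hash identifies the analysis, not
        # where its artifacts land
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load(cfg: RunConfig) -> list[Document]:
    if cfg.corpus_path.endswith(".jsonl"):
        return read_corpus_jsonl(cfg.corpus_path)
    return read_corpus(cfg.corpus_path)


def run_full_analysis(cfg: RunConfig, docs: list[Document] | None = None) -> dict:
    """Run every stage; returns a dict of artifact paths keyed by stage."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}

    def path(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - stage name context matters
                raise PipelineError(name, e) from e
        return wrap

    if docs is None:
        docs = stage("read_corpus")(lambda: _load(cfg))
    logger.info("corpus: %d documents", len(docs))

    labels = np.array([d.label(cfg.threshold).value for d in docs])
    yes_counts = np.array([d.label(cfg.threshold).yes_count for d in docs])
    logger.info(
        "groups: %d high / %d low quality", int(labels.sum()), int((1 - labels).sum())
    )

    def do_features():
        table = features.feature_table(docs)
        table.to_csv(path("features.csv"))
        artifacts["features"] = path("features.csv")
        return table

    feat = stage("features")(do_features)

    def do_compare():
        cmp_df = group_stats.comparison_table(feat, labels, yes_counts)
        cmp_df.to_csv(path("comparison.csv"))
        artifacts["comparison"] = path("comparison.csv")
        # group-level lexical diversity over concatenated token streams
        groups = {
            "all": [t for d in docs for t in d.tokens],
            "high": [t for d, l in zip(docs, labels) if l == 1 for t in d.tokens],
            "low": [t for d, l in zip(docs, labels) if l == 0 for t in d.tokens],
        }
        hc = {g: features.herdan_c(toks) for g, toks in groups.items() if len(toks) > 1}
        with open(path("herdan_groups.json"), "w") as fh:
            json.dump(hc, fh, sort_keys=True)
        artifacts["herdan_groups"] = path("herdan_groups.json")

    stage("compare_groups")(do_compare)

    def do_ngrams():
        frames = []
        subsets = {
            "all": docs,
            "high": [d for d, l in zip(docs, labels) if l == 1],
            "low": [d for d, l in zip(docs, labels) if l == 0],
        }
        for n in (1, 2):
            for grp, sub in subsets.items():
                tab = features.ngram_table(
                    sub, n=n, top_k=cfg.top_k_ngrams, group=grp,
                    stem=cfg.stem, drop_stop_words=cfg.drop_stop_words,
                )
                df = tab.to_frame()
                df.insert(0, "group", grp)
                df.insert(0, "n", n)
                frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path("ngrams.csv"), index=False)
        artifacts["ngrams"] = path("ngrams.csv")

    stage("ngrams")(do_ngrams)

    covs = [d.covariates for d in docs]
    if any(c is None for c in covs):
        covs = None

    def do_select_k():
        k_star, cv_table = slda.select_num_topics(
            docs, labels, covs, cfg.k_grid, folds=cfg.folds,
            cfg=cfg.fit_config(cv=True),
        )
        cv_table.to_csv(path("cv_table.csv"))
        artifacts["cv_table"] = path("cv_table.csv")
        return k_star, cv_table

    k_star, cv_table = stage("select_k")(do_select_k)
    logger.info("selected K = %d", k_star)

    def do_fit():
        model = slda.fit_slda(docs, labels, covs, k_star, cfg=cfg.fit_config())
        if cfg.run_stepwise and covs is not None:
            selected, model = slda.stepwise_covariates(model, labels, covs)
            logger.info("stepwise-selected covariate blocks: %s", selected)
        model.to_json(path("model.json"))
        artifacts["model"] = path("model.json")
        return model

    model = stage("fit")(do_fit)

    def do_topics():
        rows = []
        for k in range(1, model.K + 1):
            for rank, w in enumerate(slda.top_words(model, k, cfg.top_n_words), 1):
                rows.append({"topic": k, "rank": rank, "word": w})
        pd.DataFrame(rows).to_csv(path("top_words.csv"), index=False)
        artifacts["top_words"] = path("top_words.csv")
        slda.topic_odds_ratios(model).to_csv(path("odds_ratios.csv"))
        artifacts["odds_ratios"] = path("odds_ratios.csv")

    stage("topic_tables")(do_topics)

    def do_evaluate():
        probs = [
            slda.predict_quality(model, d, c)
            for d, c in zip(docs, covs if covs is not None else [None] * len(docs))
        ]
        report = evaluation.evaluate(
            probs, labels, positive_class=cfg.positive_class
        )
        payload = report.to_dict()
        payload["kind"] = "in_sample"
        payload["cv_mean_auc_pct"] = float(cv_table.loc[k_star, "mean_auc"] * 100.0)
        payload["config_hash"] = cfg.hash()
        with open(path("evaluation.json"), "w") as fh:
            json.dump(payload, fh, sort_keys=True)
        artifacts["evaluation"] = path("evaluation.json")

    stage("evaluate")(do_evaluate)

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "selected_K": k_star,
        "n_documents": len(docs),
        "n_high": int(labels.sum()),
        "n_low": int((1 - labels).sum()),
        "artifacts": artifacts,
    }
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, default=str)
    artifacts["manifest"] = path("manifest.json")
    return artifacts
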