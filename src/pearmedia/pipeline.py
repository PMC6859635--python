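"""End-to-end analysis: load -> split -> fit -> evaluate -> optimize -> report.

The pipeline mirrors the experimental study's workflow on either the
packaged per-medium datasets or synthetic replicate-level data: it fits the
three surrogate families (published/evolved symbolic models, RBF network,
linear baseline), scores each on the held-out split with the four error
statistics, ranks them, GA-optimizes the symbolic models, and writes every
table (plus the fully serialized run configuration) to the output
directory.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import load_dataset, split_train_test
from .factors import FACTOR_NAMES, NAME_TO_SYMBOL, RESPONSE_NAMES, canonical_rootstock
from .ga import GAConfig, optimize_all
from .gep import GEPConfig, chromosome_formula, evolve, express
from .metrics import MetricsReport, compute_metrics
from .mlr import fit_mlr
from .published import predict as published_predict
from .rbf import train_rbf
from .simulate import generate_replicates, spec_from_published
from .expressions import evaluate_tree

logger = logging.getLogger("pearmedia")


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    rootstock: str = "Pyrodwarf"
    responses: tuple[str, ...] = RESPONSE_NAMES
    data_source: str = "paper"          # "paper" | "synthetic"
    noise_sd: float | None = None       # synthetic only; None = default
    replicates: int = 10
    split_fraction: float = 0.7
    seed: int = 0
    fit_gep: bool = False               # False: use the published equations
    gep: dict = field(default_factory=dict)       # GEPConfig overrides
    rbf: dict = field(default_factory=dict)       # train_rbf overrides
    ga: dict = field(default_factory=dict)        # GAConfig overrides
    run_optimization: bool = True
    output_dir: str = "pearmedia_run"

    def validate(self) -> None:
        canonical_rootstock(self.rootstock)
        if self.data_source not in ("paper", "synthetic"):
            raise ValueError(f"invalid data_source {self.data_source!r}")
        bad = [r for r in self.responses if r not in RESPONSE_NAMES]
        if bad:
            raise ValueError(f"invalid responses {bad}")
        if not 0 < self.split_fraction < 1:
            raise ValueError("invalid split_fraction: must be in (0, 1)")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        cfg = cls(**d)
        if isinstance(cfg.responses, list):
            cfg.responses = tuple(cfg.responses)
        return cfg


def _load_records(config: RunConfig) -> pd.DataFrame:
    if config.data_source == "paper":
        return load_dataset(config.rootstock)
    spec = spec_from_published(config.rootstock, config.noise_sd,
                               replicates=config.replicates)
    design = load_dataset(config.rootstock)[["medium_id", *FACTOR_NAMES]]
    return generate_replicates(design, spec, seed=config.seed)


def _env(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {NAME_TO_SYMBOL[n]: df[n].to_numpy(float) for n in FACTOR_NAMES}


def fit_models(train: pd.DataFrame, response: str, config: RunConfig) -> dict:
    """Fit/resolve the three model families for one response."""
    models: dict[str, object] = {}
    if config.fit_gep:
        gep_cfg = GEPConfig(seed=config.seed, **config.gep)
        best, history = evolve(train, response, gep_cfg)
        tree = express(best, gep_cfg)
        models["GEP"] = {
            "predict": lambda df, t=tree: np.broadcast_to(
                np.asarray(evaluate_tree(t, _env(df)), float), (len(df),)),
            "formula": chromosome_formula(best, gep_cfg),
            "history": history,
        }
    else:
        rs = config.rootstock
        models["GEP"] = {
            "predict": lambda df, r=response: np.asarray(
                published_predict(rs, r, _env(df)), float),
            "formula": "published",
        }
    net = train_rbf(train, response, seed=config.seed, **config.rbf)
    models["RBFNN"] = {"predict": net.predict, "network": net}
    mlr = fit_mlr(train, response)
    models["MLR"] = {"predict": mlr.predict, "model": mlr}
    return models


def compare_models(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Rank models by RMSE ascending, ties broken by higher r^2."""
    if not reports:
        raise ValueError("no reports to rank")
    rows = [{"model": m, **rep.as_dict()} for m, rep in reports.items()]
    df = pd.DataFrame(rows)
    df["_r2"] = df["r_squared"].fillna(-1.0)
    df = df.sort_values(["rmse", "_r2"], ascending=[True, False],
                        kind="stable").drop(columns="_r2")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns and writes all result tables."""
    config.validate()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pearmedia %s | rootstock=%s source=%s seed=%d",
                __version__, config.rootstock, config.data_source, config.seed)
    records = _load_records(config)
    split = split_train_test(records, config.split_fraction, seed=config.seed)
    logger.info("records=%d train=%d test=%d",
                len(records), len(split.train), len(split.test))

    metric_rows, rank_frames = [], []
    for response in config.responses:
        models = fit_models(split.train, response, config)
        reports = {}
        for name, m in models.items():
            pred = np.asarray(m["predict"](split.test), float)
            obs = split.test[response].to_numpy(float)
            reports[name] = compute_metrics(obs, pred)
            metric_rows.append({
                "rootstock": config.rootstock, "response": response,
                "model": name, **reports[name].as_dict(),
            })
            if name == "GEP" and m.get("formula") not in (None, "published"):
                (out / f"gep_{response}.txt").write_text(m["formula"] + "\n")
            if name == "RBFNN":
                (out / f"rbfnn_{response}.json").write_text(m["network"].to_json())
            if name == "MLR":
                m["model"].coefficient_table().to_csv(
                    out / f"mlr_{response}.csv", index=False)
        ranking = compare_models(reports)
        ranking.insert(0, "response", response)
        rank_frames.append(ranking)

    metrics_df = pd.DataFrame(metric_rows)
    ranking_df = pd.concat(rank_frames, ignore_index=True)
    metrics_df.to_csv(out / "metrics.csv", index=False)
    ranking_df.to_csv(out / "ranking.csv", index=False)

    artifacts = {"metrics": metrics_df, "ranking": ranking_df, "split": split}
    if config.run_optimization:
        ga_cfg = GAConfig(seed=config.seed, **config.ga)
        opt = optimize_all(config.rootstock, ga_cfg,
                           responses=list(config.responses))
        opt.insert(0, "rootstock", config.rootstock)
        opt.to_csv(out / "optimization.csv", index=False)
        artifacts["optimization"] = opt

    (out / "config.yaml").write_text(config.to_yaml())
    (out / "run_info.json").write_text(json.dumps(
        {"version": __version__, "seed": config.seed,
         "n_records": len(records)}, indent=1))
    logger.info("artifacts written to %s", out)
    return artifacts
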