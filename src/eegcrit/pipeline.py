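"""End-to-end orchestration: simulate -> metrics -> statistics -> classifier.

A :class:`PipelineConfig` captures every tunable of a run; ``run_pipeline``
executes the stages into a run directory with a fixed layout::

    <out>/
      resolved-config.json
      cohort/                 per-subject CSV+JSON plus manifest.csv
      metrics.csv             subject x (metric x band) table
      stats/<metric>.csv      one inferential table per metric
      model/coefficients.csv, path.csv, roc.csv, pr.csv, metrics.json
      run.log

Determinism: the master seed spawns stable per-stage streams, so any stage
rerun in isolation reproduces its output bit for bit.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from . import io as eio
from .banding import make_bands
from .classify import assemble_features, evaluate, fit_lasso_classifier, split_stratified
from .metrics import metric_table
from .simulate import CohortSpec, gen_cohort
from .stats import band_contrasts, lzc_tests

__all__ = ["PipelineConfig", "run_pipeline", "stage_rng"]

logger = logging.getLogger("eegcrit")


def stage_rng(master_seed: int, stage: str):
    """Deterministic per-stage generator: stable hash of the stage name
    mixed into the master seed."""
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return default_rng(SeedSequence([master_seed, key]))


@dataclass
class PipelineConfig:
    out_dir: str = "eegcrit-run"
    input_dir: str | None = None  # existing cohort; None = simulate
    seed: int = 1
    # simulation
    n_hc: int = 20
    n_mdd: int = 20
    n_channels: int = 4
    fs: float = 250.0
    effects: dict = field(default_factory=dict)  # {"band_idx:metric": d}
    # banding / metrics
    f_min: float = 1.0
    f_max: float = 73.0
    fei_gate: float = 0.6
    # statistics
    n_perm: int = 10_000
    # classifier
    include_dfa: bool = False
    max_band_hz: float = 35.2
    folds: int = 10
    rule: str = "1se"
    train_frac: float = 0.7

    def effect_map(self) -> dict[tuple[int, str], float]:
        out = {}
        for key, val in self.effects.items():
            b, m = key.split(":")
            out[(int(b), m)] = float(val)
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} already contains a (possibly partial) run; pass force=True"
        )
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=out / "run.log", level=logging.INFO, force=True,
        format="%(asctime)s %(levelname)s %(message)s",
    )
    (out / "resolved-config.json").write_text(config.to_json())
    bands = make_bands(config.f_min, config.f_max)
    logger.info("band edges: %s", bands.labels())

    # --- cohort -----------------------------------------------------------
    if config.input_dir is None:
        spec = CohortSpec(
            n_hc=config.n_hc, n_mdd=config.n_mdd, effects=config.effect_map(),
            bands=list(bands), n_channels=config.n_channels, fs=config.fs,
            seed=int(stage_rng(config.seed, "simulate").integers(2**31 - 1)),
        )
        recordings, manifest = gen_cohort(spec)
        eio.write_cohort(recordings, manifest, out / "cohort")
        logger.info("simulated %d HC / %d MDD subjects", config.n_hc, config.n_mdd)
    else:
        in_dir = Path(config.input_dir)
        if not in_dir.exists():
            raise FileNotFoundError(f"input directory {in_dir} does not exist")
        recordings, manifest = eio.read_cohort(in_dir)
        logger.info("loaded %d subjects from %s", len(recordings), in_dir)

    # --- metrics ----------------------------------------------------------
    table = metric_table(recordings, bands=bands, fei_gate=config.fei_gate)
    table.to_csv(out / "metrics.csv", index=False)
    logger.info("metrics table: %s", table.shape)

    # --- statistics -------------------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    contrasts = band_contrasts(
        table, bands=bands, n_perm=config.n_perm,
        rng=stage_rng(config.seed, "stats"),
    )
    for metric, sub in contrasts.groupby("metric"):
        sub.to_csv(stats_dir / f"{metric}.csv", index=False)
    is_mdd = table["group"] == "MDD"
    lz = lzc_tests(
        table.loc[is_mdd, "lzc"].to_numpy(),
        table.loc[~is_mdd, "lzc"].to_numpy(),
        n_perm=config.n_perm, rng=stage_rng(config.seed, "lzc"),
    )
    (stats_dir / "lzc.json").write_text(json.dumps(lz, indent=1))
    logger.info("statistics written: %d cells", len(contrasts))

    # --- classifier -------------------------------------------------------
    model_dir = out / "model"
    model_dir.mkdir(exist_ok=True)
    fm = assemble_features(
        table, bands=bands, include_dfa=config.include_dfa,
        max_band_hz=config.max_band_hz,
    )
    rng = stage_rng(config.seed, "classify")
    train, test = split_stratified(fm.y, train_frac=config.train_frac, rng=rng)
    model = fit_lasso_classifier(fm, train, folds=config.folds, rule=config.rule, rng=rng)
    rep_tr = evaluate(model, fm.X[train], fm.y[train])
    rep_te = evaluate(model, fm.X[test], fm.y[test])
    pd.DataFrame(model.nonzero, columns=["feature", "weight"]).to_csv(
        model_dir / "coefficients.csv", index=False
    )
    path_df = pd.DataFrame(model.path, columns=["intercept"] + model.columns)
    path_df.insert(0, "lambda", model.lambdas)
    path_df.to_csv(model_dir / "path.csv", index=False)
    rep_te.roc.to_csv(model_dir / "roc.csv", index=False)
    rep_te.pr.to_csv(model_dir / "pr.csv", index=False)
    (model_dir / "metrics.json").write_text(json.dumps({
        "lambda": model.lam, "n_nonzero": len(model.nonzero),
        "train": {"auc": rep_tr.auc, "accuracy": rep_tr.accuracy,
                  "sensitivity": rep_tr.sensitivity, "specificity": rep_tr.specificity},
        "test": {"auc": rep_te.auc, "accuracy": rep_te.accuracy,
                 "sensitivity": rep_te.sensitivity, "specificity": rep_te.specificity},
    }, indent=1))
    logger.info("classifier: test AUC %.3f, %d nonzero features",
                rep_te.auc, len(model.nonzero))
    return out
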