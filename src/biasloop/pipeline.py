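"""Reproducible experiment runs: config -> output directory with manifest.

A :class:`RunConfig` names one experiment (``table1``, ``emotion-loop``,
``rdk-loop`` or ``report``), a master seed and experiment parameters.
:func:`run` executes it and writes plain CSV logs, a JSON summary and a
manifest (config, config hash, seeds, package/library versions) into the
output directory, so every number in a report can be recomputed from the
emitted logs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .judge import JudgeConfig, run_table1_experiment
from .stats import block_trend
from .experiments import (
    run_emotion_trend_experiment,
    run_rdk_trend_experiment,
)

__all__ = ["RunConfig", "ConfigError", "run"]

EXPERIMENTS = ("table1", "emotion-loop", "rdk-loop", "report")

_ALLOWED_PARAMS = {
    "table1": {"n_train", "n_test", "n_seeds", "schemes", "epochs", "desk_scale"},
    "emotion-loop": {"n_agents", "partner_sad_rate", "learning_rate", "sensitivity_sd"},
    "rdk-loop": {"advisor_kind", "n_agents", "n_blocks", "learning_rate"},
    "report": {"run_dir"},
}


class ConfigError(ValueError):
    """Invalid run configuration; the message lists the offending keys."""


@dataclass
class RunConfig:
    experiment: str
    seed: int = 0
    out_dir: str = "runs/latest"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        bad = set(self.params) - _ALLOWED_PARAMS[self.experiment]
        if bad:
            raise ConfigError(
                f"unknown parameter(s) for {self.experiment}: {sorted(bad)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "experiment" not in raw:
            raise ConfigError("config file must be a mapping with an 'experiment' key")
        bad = set(raw) - {"experiment", "seed", "out_dir", "params"}
        if bad:
            raise ConfigError(f"unknown top-level key(s): {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _write_manifest(out: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "master_seed": cfg.seed,
        "versions": {
            "biasloop": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _run_table1(cfg: RunConfig, out: Path) -> None:
    p = cfg.params
    seeds = [cfg.seed + i for i in range(int(p.get("n_seeds", 5)))]
    jc_kw = {"seed": cfg.seed}
    if "epochs" in p:
        jc_kw["epochs"] = int(p["epochs"])
    judge_cfg = JudgeConfig.desk_scale(**jc_kw) if p.get("desk_scale", True) \
        else JudgeConfig(**jc_kw)
    per_seed, mean = run_table1_experiment(
        n_train=int(p.get("n_train", 4000)),
        n_test=int(p.get("n_test", 300)),
        config=judge_cfg,
        seeds=seeds,
        schemes=tuple(p.get("schemes", ("objective", "objective_bias3",
                                        "sim_human", "random_bias3"))),
    )
    per_seed.to_csv(out / "table1_per_seed.csv", index=False)
    mean.to_csv(out / "table1.csv", index=False)
    _write_manifest(out, cfg, {"judge_config": asdict(judge_cfg), "seeds": seeds})


def _trend_summary(pivot: pd.DataFrame, seed: int) -> dict:
    res = block_trend(pivot, seed=seed)
    return {
        "mean_slope": res.mean_slope,
        "p_two_sided": res.test.p_two_sided,
        "cohen_d": res.test.cohen_d,
        "ci95": list(res.test.ci95),
        "n_agents": int(pivot.shape[0]),
        "n_blocks": int(pivot.shape[1]),
    }


def _run_rdk_loop(cfg: RunConfig, out: Path) -> None:
    p = cfg.params
    df = run_rdk_trend_experiment(
        advisor_kind=p.get("advisor_kind", "biased"),
        n_agents=int(p.get("n_agents", 50)),
        n_blocks=int(p.get("n_blocks", 5)),
        learning_rate=float(p.get("learning_rate", 0.005)),
        master_seed=cfg.seed,
    )
    df.to_csv(out / "blocks.csv", index=False)
    stats = {
        "induced_bias_trend": _trend_summary(
            df.pivot(index="agent", columns="interaction_block", values="induced_bias"),
            cfg.seed,
        ),
        "induced_accuracy_trend": _trend_summary(
            df.pivot(index="agent", columns="interaction_block",
                     values="induced_accuracy_change"),
            cfg.seed,
        ),
    }
    (out / "stats.json").write_text(json.dumps(stats, indent=2))
    _write_manifest(out, cfg)


def _run_emotion_loop(cfg: RunConfig, out: Path) -> None:
    p = cfg.params
    df = run_emotion_trend_experiment(
        partner_sad_rate=float(p.get("partner_sad_rate", 0.65)),
        n_agents=int(p.get("n_agents", 50)),
        learning_rate=float(p.get("learning_rate", 0.1)),
        sensitivity_sd=float(p.get("sensitivity_sd", 9.7)),
        master_seed=cfg.seed,
    )
    df.to_csv(out / "blocks.csv", index=False)
    inter = df[df.phase == "interaction"]
    stats = {
        "own_sad_rate_trend": _trend_summary(
            inter.pivot(index="agent", columns="block", values="own_sad_rate"),
            cfg.seed,
        ),
        "baseline_sad_rate": float(df[df.phase == "baseline"]["own_sad_rate"].mean()),
        "interaction_sad_rate": float(inter["own_sad_rate"].mean()),
    }
    (out / "stats.json").write_text(json.dumps(stats, indent=2))
    _write_manifest(out, cfg)


def _run_report(cfg: RunConfig, out: Path) -> None:
    run_dir = Path(cfg.params.get("run_dir", "."))
    blocks = run_dir / "blocks.csv"
    if not blocks.exists():
        raise ConfigError(f"no blocks.csv under {run_dir}")
    df = pd.read_csv(blocks)
    stats = {}
    if "induced_bias" in df.columns:          # RDK log
        for metric in ("induced_bias", "induced_accuracy_change"):
            piv = df.pivot(index="agent", columns="interaction_block", values=metric)
            stats[f"{metric}_trend"] = _trend_summary(piv, cfg.seed)
    else:                                      # emotion log
        inter = df[df.phase == "interaction"]
        piv = inter.pivot(index="agent", columns="block", values="own_sad_rate")
        stats["own_sad_rate_trend"] = _trend_summary(piv, cfg.seed)
    (out / "stats.json").write_text(json.dumps(stats, indent=2))
    _write_manifest(out, cfg)


def run(cfg: RunConfig) -> Path:
    """Execute a configured experiment; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dispatch = {
        "table1": _run_table1,
        "rdk-loop": _run_rdk_loop,
        "emotion-loop": _run_emotion_loop,
        "report": _run_report,
    }
    dispatch[cfg.experiment](cfg, out)
    return out
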