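"""Task statistics, permutation tests and block-trend analyses.

Definitions (class code 1 = more_sad):

* emotion bias = mean(C_i) - 0.5 over a classification vector; positive
  values lean sad.
* RDK bias = mean(response_i - evidence_i); RDK error =
  mean |response_i - evidence_i|.
* induced bias = interaction-phase bias - baseline bias; induced accuracy
  change = baseline error - interaction-phase error (positive = the
  interaction made the agent more accurate).

Hypothesis tests are two-sided permutation tests (sign flips for paired /
one-sample designs, label shuffles for two-sample), with exhaustive
enumeration whenever the orbit is small enough and seeded Monte Carlo
otherwise, Cohen's d effect sizes, and percentile-bootstrap 95% confidence
intervals for the mean (difference).

Group trends over blocks are summarised as one least-squares slope per
agent on the block index, tested against zero with a one-sample permutation
test - a deliberately simple substitute for mixed-effects trend models that
tests the same directional claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import as_rng

__all__ = [
    "BiasReport",
    "RdkMetrics",
    "PermResult",
    "InfluenceReport",
    "BlockTrendResult",
    "emotion_bias",
    "rdk_metrics",
    "permutation_test",
    "influence_compare",
    "block_trend",
    "bh_correct",
]

#: exhaustive enumeration thresholds: all 2^n sign patterns / all label splits
_MAX_SIGN_PATTERNS = 2 ** 14
_MAX_LABEL_SPLITS = 15000


@dataclass(frozen=True)
class BiasReport:
    emotion_bias: float
    n: int


def emotion_bias(classes) -> BiasReport:
    """Mean coded classification minus 0.5 (codes in {0, 1}, 1 = more_sad)."""
    c = np.asarray(classes, dtype=float)
    if c.size == 0:
        raise ValueError("empty classification vector")
    if not np.isin(c, (0.0, 1.0)).all():
        raise ValueError("classifications must be coded 0 (more_happy) / 1 (more_sad)")
    return BiasReport(float(c.mean() - 0.5), int(c.size))


@dataclass(frozen=True)
class RdkMetrics:
    """Signed and absolute deviation of estimates from the true evidence.

    With phase tags, ``bias``/``error`` are the interaction-phase values and
    the induced metrics compare them with baseline; without tags they cover
    all trials and the induced metrics are None.
    """

    bias: float
    error: float
    n: int
    bias_baseline: float | None = None
    error_baseline: float | None = None
    induced_bias: float | None = None
    induced_accuracy_change: float | None = None


def rdk_metrics(responses, evidence, phase_tags=None) -> RdkMetrics:
    """Compute RDK bias / error, per phase if ``phase_tags`` is given.

    phase_tags, when present, holds "baseline" / "interaction" per trial;
    both phases must occur for the induced metrics to be defined.
    """
    r = np.asarray(responses, dtype=float)
    e = np.asarray(evidence, dtype=float)
    if r.shape != e.shape:
        raise ValueError("responses and evidence must have equal length")
    dev = r - e
    if phase_tags is None:
        return RdkMetrics(float(dev.mean()), float(np.abs(dev).mean()), int(r.size))
    tags = np.asarray(phase_tags)
    if tags.shape != r.shape:
        raise ValueError("phase_tags must match responses in length")
    base = dev[tags == "baseline"]
    inter = dev[tags == "interaction"]
    if base.size == 0 or inter.size == 0:
        raise ValueError("induced metrics need both baseline and interaction trials")
    bias_b, err_b = float(base.mean()), float(np.abs(base).mean())
    bias_i, err_i = float(inter.mean()), float(np.abs(inter).mean())
    return RdkMetrics(
        bias=bias_i,
        error=err_i,
        n=int(inter.size),
        bias_baseline=bias_b,
        error_baseline=err_b,
        induced_bias=bias_i - bias_b,
        induced_accuracy_change=err_b - err_i,
    )


@dataclass(frozen=True)
class PermResult:
    p_two_sided: float
    cohen_d: float
    ci95: tuple[float, float]
    observed: float
    n_shuffles: int
    method: str          # "exhaustive" or "monte_carlo"
    seed: int | None


def _cohen_d_one(d):
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    if sd == 0:
        return 0.0 if d.mean() == 0 else float(np.inf) * np.sign(d.mean())
    return float(d.mean() / sd)


def _bootstrap_ci(stat_samples, rng, n_resamples=10_000):
    n = stat_samples.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    means = stat_samples[idx].mean(axis=1)
    return (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5)))


def _sign_flip_test(d, n_shuffles, rng):
    n = d.size
    obs = d.mean()
    if np.all(d == 0):
        return 1.0, 0, "exhaustive"
    tol = 1e-12 * max(1.0, float(np.abs(d).max()))
    if 2 ** n <= _MAX_SIGN_PATTERNS:
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        signs = 2 * bits - 1
        stats = (signs * d).mean(axis=1)
        p = float(np.mean(np.abs(stats) >= abs(obs) - tol))
        return p, 2 ** n, "exhaustive"
    signs = rng.choice((-1.0, 1.0), size=(n_shuffles, n))
    stats = (signs * d).mean(axis=1)
    hits = int(np.sum(np.abs(stats) >= abs(obs) - tol))
    return (1 + hits) / (n_shuffles + 1), n_shuffles, "monte_carlo"


def _two_sample_test(x, y, n_shuffles, rng):
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    obs = x.mean() - y.mean()
    if np.all(pooled == pooled[0]):
        return 1.0, 0, "exhaustive"
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    if comb(nx + ny, nx) <= _MAX_LABEL_SPLITS:
        total = pooled.sum()
        stats = []
        for idx in combinations(range(nx + ny), nx):
            sx = pooled[list(idx)].sum()
            stats.append(sx / nx - (total - sx) / ny)
        stats = np.asarray(stats)
        p = float(np.mean(np.abs(stats) >= abs(obs) - tol))
        return p, stats.size, "exhaustive"
    hits = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(pooled)
        stat = perm[:nx].mean() - perm[nx:].mean()
        if abs(stat) >= abs(obs) - tol:
            hits += 1
    return (1 + hits) / (n_shuffles + 1), n_shuffles, "monte_carlo"


def permutation_test(
    x,
    y=None,
    mode: str = "two_sample",
    n_shuffles: int = 100_000,
    seed=0,
    ci_resamples: int = 10_000,
) -> PermResult:
    """Two-sided permutation test of a mean (difference).

    mode "one_sample" tests mean(x) against 0 by sign flips; "paired" tests
    mean(x - y) the same way; "two_sample" shuffles group labels.  Exhaustive
    enumeration replaces Monte Carlo whenever all sign patterns (<= 2^14) or
    label splits (<= 15000) fit, in which case the p value is exact.
    """
    rng = as_rng(seed)
    x = np.asarray(x, dtype=float)
    if mode in ("one_sample", "paired"):
        if mode == "paired":
            if y is None:
                raise ValueError("paired mode needs y")
            y = np.asarray(y, dtype=float)
            if y.shape != x.shape:
                raise ValueError("paired samples must have equal length")
            d = x - y
        else:
            d = x
        if d.size < 2:
            raise ValueError("need at least 2 observations")
        p, n_used, method = _sign_flip_test(d, n_shuffles, rng)
        ci = _bootstrap_ci(d, rng, ci_resamples)
        return PermResult(p, _cohen_d_one(d), ci, float(d.mean()), n_used, method,
                          seed if isinstance(seed, (int, np.integer)) else None)
    if mode != "two_sample":
        raise ValueError(f"unknown mode {mode!r}")
    if y is None:
        raise ValueError("two_sample mode needs y")
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    p, n_used, method = _two_sample_test(x, y, n_shuffles, rng)
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    d_eff = 0.0 if pooled_var == 0 else float((x.mean() - y.mean()) / np.sqrt(pooled_var))
    # bootstrap CI of the mean difference: resample each group independently
    ix = rng.integers(0, nx, size=(ci_resamples, nx))
    iy = rng.integers(0, ny, size=(ci_resamples, ny))
    diffs = x[ix].mean(axis=1) - y[iy].mean(axis=1)
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    return PermResult(p, d_eff, ci, float(x.mean() - y.mean()), n_used, method,
                      seed if isinstance(seed, (int, np.integer)) else None)


@dataclass(frozen=True)
class InfluenceReport:
    """Biased-partner influence on bias vs accurate-partner influence on accuracy.

    Quantified both ways the study defines: within-agent z-scores across the
    three partner algorithms, and change relative to the agent's own
    baseline.  Each comparison is a paired permutation test.
    """

    z_bias_biased: np.ndarray
    z_accuracy_accurate: np.ndarray
    zscore_test: PermResult
    relative_bias_change: np.ndarray
    relative_accuracy_change: np.ndarray
    relative_test: PermResult


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    return df.sub(mean, axis=0).div(sd, axis=0)


def influence_compare(
    induced_bias: pd.DataFrame,
    induced_accuracy: pd.DataFrame,
    baseline_bias,
    baseline_error,
    n_shuffles: int = 100_000,
    seed=0,
) -> InfluenceReport:
    """Compare the biased partner's pull on bias with the accurate partner's
    push on accuracy.

    ``induced_bias`` and ``induced_accuracy`` are agent x advisor frames
    with columns "accurate", "biased", "noisy" (induced bias resp. induced
    accuracy change per advisor condition); ``baseline_bias`` and
    ``baseline_error`` are per-agent vectors.
    """
    for df in (induced_bias, induced_accuracy):
        missing = {"accurate", "biased", "noisy"} - set(df.columns)
        if missing:
            raise ValueError(f"missing advisor condition(s): {sorted(missing)}")
    zb = _zscore_rows(induced_bias[["accurate", "biased", "noisy"]])
    za = _zscore_rows(induced_accuracy[["accurate", "biased", "noisy"]])
    z_bias = zb["biased"].to_numpy()
    z_acc = za["accurate"].to_numpy()
    z_test = permutation_test(z_bias, z_acc, mode="paired", n_shuffles=n_shuffles, seed=seed)

    baseline_bias = np.asarray(baseline_bias, dtype=float)
    baseline_error = np.asarray(baseline_error, dtype=float)
    rel_bias = induced_bias["biased"].to_numpy() / baseline_bias
    rel_acc = induced_accuracy["accurate"].to_numpy() / baseline_error
    rel_test = permutation_test(rel_bias, rel_acc, mode="paired", n_shuffles=n_shuffles, seed=seed)
    return InfluenceReport(z_bias, z_acc, z_test, rel_bias, rel_acc, rel_test)


@dataclass(frozen=True)
class BlockTrendResult:
    slopes: np.ndarray       # one OLS slope per agent, per block index
    mean_slope: float
    test: PermResult


def block_trend(per_block_values, n_shuffles: int = 100_000, seed=0) -> BlockTrendResult:
    """Per-agent least-squares slope over blocks + group permutation test.

    ``per_block_values`` is an (agents x blocks) array (or DataFrame) of a
    per-block statistic; the slope of each agent's series on the block index
    0..B-1 is tested against zero with a one-sample sign-flip permutation
    test across agents.
    """
    v = np.asarray(per_block_values, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    n_blocks = v.shape[1]
    if n_blocks < 2:
        raise ValueError("block trends need at least 2 blocks")
    b = np.arange(n_blocks, dtype=float)
    bc = b - b.mean()
    slopes = (v - v.mean(axis=1, keepdims=True)) @ bc / (bc @ bc)
    test = permutation_test(slopes, mode="one_sample", n_shuffles=n_shuffles, seed=seed)
    return BlockTrendResult(slopes, float(slopes.mean()), test)


def bh_correct(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg FDR correction over a family of p values."""
    reject, p_adj, _, _ = multipletests(np.asarray(p_values, dtype=float),
                                        alpha=alpha, method="fdr_bh")
    return reject, p_adj
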