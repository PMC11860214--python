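"""Synthetic stimuli for the emotion-aggregation task and the RDK schedule.

The emotion-aggregation stimulus is an array of 12 faces, each carrying an
integer *emotion rank* on a sad-to-happy morph continuum from 1 (fully sad)
to 50 (fully happy).  The array's objective class is ``more_sad`` when the
mean rank falls below the scale midpoint of 25.5 and ``more_happy``
otherwise; arrays whose mean lands exactly on the midpoint are resampled.
Balanced stimulus sets are built by pairing every sampled array with its
*mirror* (each rank replaced by ``51 - rank``), which flips the class and
guarantees an exactly balanced set.

Real morphed photographs are replaced by schematic grayscale face glyphs
whose single expressive parameter - mouth curvature - is linear in the
emotion rank, preserving the one-dimensional continuum a classifier must
aggregate without requiring external imagery.

Simulated human labellers apply a noisy, criterion-shifted comparison of the
perceived mean rank against the class boundary (late noise on the aggregate
percept), and can be calibrated to a target accuracy / sad-bias such as the
63% / 3 pp aggregate of the original raters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from ._rng import as_rng

__all__ = [
    "RANK_MIN",
    "RANK_MAX",
    "CLASS_BOUNDARY",
    "MORE_SAD",
    "MORE_HAPPY",
    "ARRAY_SIZE",
    "RDK_EVIDENCE",
    "FaceArray",
    "SimHumanParams",
    "LabelledDataset",
    "CalibrationError",
    "mouth_curvature",
    "render_face",
    "compose_array",
    "sample_array",
    "mirror_array",
    "build_balanced_set",
    "p_more_sad",
    "simulate_human_classification",
    "calibrate_sim_human",
    "make_label_set",
    "make_rdk_schedule",
    "class_name",
    "dataset_to_frame",
    "save_dataset_csv",
    "load_dataset_csv",
]

RANK_MIN = 1
RANK_MAX = 50
CLASS_BOUNDARY = 25.5
ARRAY_SIZE = 12

#: class codes; ``more_sad`` is coded 1 so that a mean classification above
#: 0.5 reads as a sad-leaning bias.
MORE_SAD = 1
MORE_HAPPY = 0

_CLASS_NAMES = {MORE_SAD: "more_sad", MORE_HAPPY: "more_happy"}

#: the 30-trial evidence schedule of the random-dot-kinematogram task:
#: percentage of dots moving rightward on each trial (50 appears twice).
RDK_EVIDENCE: tuple[int, ...] = (
    6, 16, 22, 28, 30, 32, 34, 36, 38, 40, 42, 44, 46, 48, 50, 50,
    52, 54, 56, 58, 60, 62, 64, 66, 68, 70, 72, 78, 86, 96,
)

LABEL_SCHEMES = ("objective", "objective_bias3", "sim_human", "random_bias3")

#: more-sad share the minor-bias label regimes are driven to.
BIASED_SAD_SHARE = 0.53


def class_name(code: int) -> str:
    return _CLASS_NAMES[int(code)]


# ---------------------------------------------------------------------------
# face glyph rendering


def mouth_curvature(rank: int | np.ndarray) -> float | np.ndarray:
    """Closed-form rank -> mouth curvature map, linear on [-1, 1].

    Negative values curve the mouth into a frown (sad), positive into a
    smile (happy).  This is the renderer's single expressive parameter.
    """
    return (np.asarray(rank, dtype=float) - 25.5) / 24.5


def _check_rank(rank) -> int:
    r = int(rank)
    if not RANK_MIN <= r <= RANK_MAX:
        raise ValueError(f"emotion rank must be in [{RANK_MIN}, {RANK_MAX}], got {rank}")
    return r


def render_face(rank: int, size: int = 24) -> np.ndarray:
    """Render one schematic face as a ``size x size`` grayscale tile in [0, 1].

    Head outline and eyes are fixed; the mouth is a parabolic arc whose
    curvature is ``mouth_curvature(rank)``.  The arc is drawn with a smooth
    sub-pixel intensity falloff so the curvature parameter survives
    rasterisation even at small tile sizes.  Deterministic.
    """
    r = _check_rank(rank)
    if size < 16:
        raise ValueError(f"tile size must be >= 16 pixels, got {size}")
    # normalised pixel-centre coordinates in [0, 1]
    coords = (np.arange(size) + 0.5) / size
    yy, xx = np.meshgrid(coords, coords, indexing="ij")

    img = np.zeros((size, size), dtype=np.float32)

    # head: soft ring
    d_centre = np.hypot(yy - 0.5, xx - 0.5)
    ring = np.exp(-((d_centre - 0.46) / 0.02) ** 2)
    img += ring

    # eyes: two soft dots
    for ex in (0.35, 0.65):
        d_eye = np.hypot(yy - 0.36, xx - ex)
        img += np.exp(-((d_eye / 0.05) ** 2))

    # mouth: parabolic arc, curvature linear in rank.  y grows downward, so
    # a positive curvature pushes the mouth centre down -> smile.
    kappa = float(mouth_curvature(r))
    x0, x1 = 0.28, 0.72
    u = np.clip((xx - x0) / (x1 - x0), 0.0, 1.0)
    arc_y = 0.66 + 0.16 * kappa * (4.0 * u * (1.0 - u) - 0.5)
    in_span = (xx >= x0) & (xx <= x1)
    width = 2.0 / size  # soft pen; intensity varies smoothly with curvature
    mouth = np.exp(-((yy - arc_y) / (2.0 * width)) ** 2) * in_span
    img += mouth

    return np.clip(img, 0.0, 1.0)


_TILE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _tile(rank: int, size: int) -> np.ndarray:
    key = (int(rank), int(size))
    out = _TILE_CACHE.get(key)
    if out is None:
        out = render_face(rank, size)
        out.setflags(write=False)
        _TILE_CACHE[key] = out
    return out


def compose_array(ranks: Sequence[int], tile_size: int = 24) -> np.ndarray:
    """Tile 12 face glyphs into one stimulus image.

    Faces are laid out row-major on a 4-column x 3-row grid of
    ``tile_size`` tiles; the 4:3 grid is padded top and bottom to a square
    ``4*tile_size`` image (96x96 at the default tile of 24).
    """
    ranks = [int(r) for r in ranks]
    if len(ranks) != ARRAY_SIZE:
        raise ValueError(f"a face array needs exactly {ARRAY_SIZE} ranks, got {len(ranks)}")
    t = int(tile_size)
    grid = np.zeros((3 * t, 4 * t), dtype=np.float32)
    for i, r in enumerate(ranks):
        row, col = divmod(i, 4)
        grid[row * t:(row + 1) * t, col * t:(col + 1) * t] = _tile(r, t)
    pad = t // 2
    img = np.zeros((4 * t, 4 * t), dtype=np.float32)
    img[pad:pad + 3 * t, :] = grid
    return img


# ---------------------------------------------------------------------------
# face arrays


@dataclass(frozen=True)
class FaceArray:
    """One 12-face stimulus: integer emotion ranks plus derived quantities."""

    ranks: tuple[int, ...]

    def __post_init__(self):
        if len(self.ranks) != ARRAY_SIZE:
            raise ValueError(f"a face array needs exactly {ARRAY_SIZE} ranks")
        for r in self.ranks:
            _check_rank(r)
        if self.mean_rank == CLASS_BOUNDARY:
            raise ValueError("mean rank exactly on the class boundary (25.5)")

    @property
    def mean_rank(self) -> float:
        return float(np.mean(self.ranks))

    @property
    def objective_class(self) -> int:
        return MORE_SAD if self.mean_rank < CLASS_BOUNDARY else MORE_HAPPY

    def render(self, tile_size: int = 24) -> np.ndarray:
        """Stimulus image for this array (deterministic in ranks and size)."""
        return compose_array(self.ranks, tile_size)


def sample_array(rng, n_faces: int = ARRAY_SIZE) -> FaceArray:
    """Draw ranks i.i.d. uniform on {1..50}; resample a mean of exactly 25.5."""
    rng = as_rng(rng)
    while True:
        ranks = rng.integers(RANK_MIN, RANK_MAX + 1, size=n_faces)
        if float(ranks.mean()) != CLASS_BOUNDARY:
            return FaceArray(tuple(int(r) for r in ranks))


def mirror_array(a: FaceArray) -> FaceArray:
    """Mirror image on the rank scale: each rank r becomes 51 - r.

    Flips the objective class and satisfies
    ``mean_rank(a) + mean_rank(mirror(a)) == 51``.
    """
    return FaceArray(tuple(RANK_MAX + 1 - r for r in a.ranks))


def build_balanced_set(n_pairs: int, rng) -> list[FaceArray]:
    """Sample ``n_pairs`` arrays and append the mirror of each.

    Returns ``2 * n_pairs`` arrays with exactly equal class counts, original
    and mirror adjacent (even index original, odd index mirror).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = as_rng(rng)
    out: list[FaceArray] = []
    for _ in range(n_pairs):
        a = sample_array(rng)
        out.append(a)
        out.append(mirror_array(a))
    return out


# ---------------------------------------------------------------------------
# simulated human labellers


@dataclass(frozen=True)
class SimHumanParams:
    """Late-noise psychometric labeller.

    sensitivity_sd
        s.d. of Gaussian noise on the perceived mean rank (rank units).
    criterion
        shift of the 25.5 class boundary; positive moves the boundary up the
        scale, i.e. toward answering ``more_sad`` more often.
    lapse
        probability of a stimulus-independent coin-flip response.
    """

    sensitivity_sd: float
    criterion: float = 0.0
    lapse: float = 0.0

    def __post_init__(self):
        if self.sensitivity_sd < 0:
            raise ValueError("sensitivity_sd must be >= 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")


def p_more_sad(mean_ranks, params: SimHumanParams) -> np.ndarray:
    """P(respond more_sad) per array under the psychometric labeller.

    ``P = (1 - lapse) * Phi((25.5 + criterion - mean) / sd) + lapse / 2``;
    at ``sd == 0`` the Phi term degenerates to a step at the shifted
    boundary.
    """
    m = np.asarray(mean_ranks, dtype=float)
    shifted = CLASS_BOUNDARY + params.criterion - m
    if params.sensitivity_sd == 0:
        core = np.where(shifted > 0, 1.0, np.where(shifted < 0, 0.0, 0.5))
    else:
        core = ndtr(shifted / params.sensitivity_sd)
    return (1.0 - params.lapse) * core + params.lapse / 2.0


def simulate_human_classification(a: FaceArray, params: SimHumanParams, rng) -> int:
    """Draw one simulated-human class label for an array."""
    rng = as_rng(rng)
    p = float(p_more_sad(a.mean_rank, params))
    return MORE_SAD if rng.random() < p else MORE_HAPPY


class CalibrationError(RuntimeError):
    """Raised when no labeller parameters can hit the requested targets."""


def _expected_rate_and_accuracy(arrays_mean, arrays_class, sd, criterion):
    p = p_more_sad(arrays_mean, SimHumanParams(sd, criterion))
    rate = float(p.mean())
    acc = float(np.where(arrays_class == MORE_SAD, p, 1.0 - p).mean())
    return rate, acc


def calibrate_sim_human(
    target_accuracy: float,
    target_bias_pp: float,
    arrays: Sequence[FaceArray],
    sd_bounds: tuple[float, float] = (1e-3, 200.0),
) -> SimHumanParams:
    """Solve for (sensitivity_sd, criterion) hitting an accuracy / bias target.

    Works on expectations over the supplied array set (no Monte Carlo): for a
    candidate noise level the criterion is solved so the expected more-sad
    rate equals ``0.5 + target_bias_pp / 100``, then the noise level is
    solved so the expected accuracy matches ``target_accuracy``.  Both maps
    are monotone, so nested bisection is exact.  Raises
    :class:`CalibrationError` with diagnostics when the target is
    unattainable (e.g. below-chance accuracy).
    """
    if not 0.5 < target_accuracy <= 1.0:
        raise CalibrationError(
            f"target accuracy must be in (0.5, 1], got {target_accuracy}; "
            "below-chance accuracy is unattainable under this labeller"
        )
    means = np.array([a.mean_rank for a in arrays], dtype=float)
    classes = np.array([a.objective_class for a in arrays])
    target_rate = 0.5 + target_bias_pp / 100.0

    def crit_for(sd: float) -> float:
        lo, hi = -80.0, 80.0
        f = lambda c: _expected_rate_and_accuracy(means, classes, sd, c)[0] - target_rate
        return brentq(f, lo, hi, xtol=1e-10)

    def acc_err(sd: float) -> float:
        return _expected_rate_and_accuracy(means, classes, sd, crit_for(sd))[1] - target_accuracy

    lo, hi = sd_bounds
    err_lo, err_hi = acc_err(lo), acc_err(hi)
    if err_lo <= 0:
        # even the (near) noise-free labeller cannot reach the target; the
        # attainable ceiling is acc(lo).  Accept the bound when within 1 pp
        # (e.g. target accuracy 1.0 on a finite array set).
        if err_lo > -0.01:
            return SimHumanParams(lo, crit_for(lo))
        raise CalibrationError(
            f"target accuracy {target_accuracy:.3f} above attainable ceiling "
            f"{target_accuracy + err_lo:.3f} at sensitivity_sd={lo}"
        )
    if err_hi > 0:
        raise CalibrationError(
            f"target accuracy {target_accuracy:.3f} below attainable floor "
            f"{target_accuracy + err_hi:.3f} at sensitivity_sd={hi}"
        )
    sd = brentq(acc_err, lo, hi, xtol=1e-8)
    return SimHumanParams(sd, crit_for(sd))


# ---------------------------------------------------------------------------
# label regimes


@dataclass
class LabelledDataset:
    """Face arrays plus labels under one of the four label regimes."""

    arrays: list[FaceArray]
    labels: np.ndarray
    scheme: str
    seed: int | None = None
    sim_params: SimHumanParams | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.arrays):
            raise ValueError("labels and arrays must have equal length")

    @property
    def objective_classes(self) -> np.ndarray:
        return np.array([a.objective_class for a in self.arrays])

    @property
    def sad_share(self) -> float:
        return float(np.mean(self.labels == MORE_SAD))


def _drive_to_share(labels: np.ndarray, share: float, rng) -> np.ndarray:
    """Flip uniformly chosen labels until the more-sad count equals round(share*n)."""
    labels = labels.copy()
    target = int(round(share * len(labels)))
    n_sad = int((labels == MORE_SAD).sum())
    if n_sad < target:
        pool = np.flatnonzero(labels == MORE_HAPPY)
        flip = rng.choice(pool, size=target - n_sad, replace=False)
        labels[flip] = MORE_SAD
    elif n_sad > target:
        pool = np.flatnonzero(labels == MORE_SAD)
        flip = rng.choice(pool, size=n_sad - target, replace=False)
        labels[flip] = MORE_HAPPY
    return labels


def make_label_set(
    arrays: Sequence[FaceArray],
    scheme: str,
    rng,
    sim_params: SimHumanParams | None = None,
) -> LabelledDataset:
    """Label an array set under one of the four regimes.

    objective
        labels equal the objective class exactly.
    objective_bias3
        objective labels, then uniformly chosen more_happy labels flipped to
        more_sad until exactly 53% of all labels are more_sad (a 3 pp bias
        on a balanced set).
    sim_human
        labels drawn from the calibrated psychometric labeller (defaults to
        the 63%-accuracy / 3 pp-bias calibration on the supplied arrays).
    random_bias3
        i.i.d. fair-coin labels, then flips toward (or, if the draw
        overshoots, away from) more_sad until exactly 53% are more_sad.
    """
    seed = None if isinstance(rng, np.random.Generator) else int(rng)
    rng = as_rng(rng)
    arrays = list(arrays)
    objective = np.array([a.objective_class for a in arrays])
    if scheme == "objective":
        labels = objective.copy()
    elif scheme == "objective_bias3":
        labels = _drive_to_share(objective, BIASED_SAD_SHARE, rng)
    elif scheme == "random_bias3":
        labels = rng.integers(0, 2, size=len(arrays))
        labels = _drive_to_share(labels, BIASED_SAD_SHARE, rng)
    elif scheme == "sim_human":
        if sim_params is None:
            sim_params = calibrate_sim_human(0.63, 3.0, arrays)
        p = p_more_sad([a.mean_rank for a in arrays], sim_params)
        labels = np.where(rng.random(len(arrays)) < p, MORE_SAD, MORE_HAPPY)
    else:
        raise ValueError(f"unknown label scheme {scheme!r}; expected one of {LABEL_SCHEMES}")
    return LabelledDataset(arrays, labels, scheme, seed=seed, sim_params=sim_params)


# ---------------------------------------------------------------------------
# RDK schedule


def make_rdk_schedule() -> list[int]:
    """The fixed 30-trial RDK evidence schedule (% of dots moving rightward)."""
    return list(RDK_EVIDENCE)


# ---------------------------------------------------------------------------
# serialisation


def dataset_to_frame(ds: LabelledDataset) -> pd.DataFrame:
    rows = {f"rank_{i + 1}": [a.ranks[i] for a in ds.arrays] for i in range(ARRAY_SIZE)}
    df = pd.DataFrame(rows)
    df["mean_rank"] = [a.mean_rank for a in ds.arrays]
    df["objective_class"] = [class_name(a.objective_class) for a in ds.arrays]
    df["label"] = [class_name(c) for c in ds.labels]
    df["scheme"] = ds.scheme
    df["seed"] = ds.seed if ds.seed is not None else -1
    return df


def save_dataset_csv(ds: LabelledDataset, path) -> None:
    dataset_to_frame(ds).to_csv(path, index=False)


def load_dataset_csv(path) -> LabelledDataset:
    df = pd.read_csv(path)
    name_to_code = {v: k for k, v in _CLASS_NAMES.items()}
    arrays = [
        FaceArray(tuple(int(row[f"rank_{i + 1}"]) for i in range(ARRAY_SIZE)))
        for _, row in df.iterrows()
    ]
    labels = df["label"].map(name_to_code).to_numpy()
    seed = int(df["seed"].iloc[0]) if "seed" in df else None
    return LabelledDataset(arrays, labels, str(df["scheme"].iloc[0]),
                           seed=None if seed == -1 else seed)
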