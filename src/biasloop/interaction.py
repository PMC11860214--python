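"""Partner algorithms and the two interaction protocols.

The RDK partners are hard-coded algorithms acting on the true evidence
(percentage of dots moving rightward):

accurate
    returns the evidence exactly;
biased
    adds an offset drawn uniformly on [0, 49] percentage points (mean
    ~24.5), always upward;
noisy
    adds zero-mean Gaussian noise (default s.d. 28.46; the alternative
    reported value 30 is available by config), error-matched to the biased
    partner.

Responses are clipped to the [0, 100] response scale.

The two protocols:

* Emotion change-of-mind: baseline blocks alone, then interaction blocks
  where on each trial the agent classifies the array, sees the partner's
  classification, decides whether to change its answer, and applies its
  criterion learning update.
* RDK advice weighting: a baseline block alone, then interaction blocks
  where the agent estimates, commits a weight w on itself *before* the
  partner's response is revealed, forms the joint response
  ``w * own + (1 - w) * partner``, and applies its offset learning update.

Both return a tidy per-trial :class:`pandas.DataFrame` session log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import as_rng
from .agents import (
    EmotionAgentState,
    RdkAgentState,
    emotion_agent_change_decision,
    emotion_agent_classify,
    emotion_agent_update,
    rdk_agent_estimate,
    rdk_agent_update,
)
from .stimuli import MORE_SAD, FaceArray, class_name, make_rdk_schedule

__all__ = [
    "AdvisorSpec",
    "ProtocolConfig",
    "advisor_response",
    "joint_response",
    "latin_square_orders",
    "run_emotion_session",
    "run_rdk_session",
]

ADVISOR_KINDS = ("accurate", "biased", "noisy")


@dataclass(frozen=True)
class AdvisorSpec:
    """Contract of a hard-coded RDK partner algorithm."""

    kind: str
    offset_low: float = 0.0
    offset_high: float = 49.0
    noise_sd: float = 28.46
    clip_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self):
        if self.kind not in ADVISOR_KINDS:
            raise ValueError(f"unknown advisor kind {self.kind!r}; expected one of {ADVISOR_KINDS}")

    @property
    def mean_offset(self) -> float:
        if self.kind == "biased":
            return (self.offset_low + self.offset_high) / 2.0
        return 0.0


def advisor_response(spec: AdvisorSpec, evidence: float, rng) -> float:
    """One partner response to the true evidence, clipped to the scale."""
    if not 0.0 <= evidence <= 100.0:
        raise ValueError("evidence must be in [0, 100]")
    rng = as_rng(rng)
    if spec.kind == "accurate":
        value = float(evidence)
    elif spec.kind == "biased":
        value = evidence + rng.uniform(spec.offset_low, spec.offset_high)
    else:  # noisy
        value = evidence + rng.normal(0.0, spec.noise_sd)
    lo, hi = spec.clip_range
    return float(np.clip(value, lo, hi))


def joint_response(own: float, partner: float, w: float) -> float:
    """Weighted joint decision ``w * own + (1 - w) * partner``.

    w is the weight on the agent's own response (1 = ignore the partner).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    if not (0.0 <= own <= 100.0 and 0.0 <= partner <= 100.0):
        raise ValueError("responses must be on the [0, 100] scale")
    return float(w * own + (1.0 - w) * partner)


def latin_square_orders() -> list[tuple[str, str, str]]:
    """The three advisor orders used to counterbalance between agents."""
    return [
        ("accurate", "biased", "noisy"),
        ("biased", "noisy", "accurate"),
        ("noisy", "accurate", "biased"),
    ]


@dataclass(frozen=True)
class ProtocolConfig:
    """Block structure of a session.

    Defaults mirror the emotion change-of-mind protocol: three 50-trial
    baseline blocks (150 trials alone) then six 50-trial interaction blocks
    (300 trials with the partner).  The RDK protocol passes its own counts
    (30-trial blocks; one baseline block).
    """

    baseline_blocks: int = 3
    interaction_blocks: int = 6
    trials_per_block: int = 50
    partner_label: str = "AI"

    def __post_init__(self):
        if min(self.baseline_blocks, self.interaction_blocks, self.trials_per_block) < 1:
            raise ValueError("block and trial counts must be positive")

    @property
    def n_trials(self) -> int:
        return (self.baseline_blocks + self.interaction_blocks) * self.trials_per_block


def run_emotion_session(
    agent: EmotionAgentState,
    advisor: Callable[[FaceArray, np.random.Generator], int],
    protocol: ProtocolConfig,
    arrays: Sequence[FaceArray],
    rng,
) -> pd.DataFrame:
    """Simulate one agent through baseline + interaction emotion blocks.

    ``advisor`` maps (array, rng) to a class code; e.g. a trained judge's
    prediction, a fixed more-sad-rate emitter, or the objective class.  The
    agent's learning update is applied once per interaction trial, from its
    own initial answer and the partner's answer (not from the post-change
    answer).  Returns one row per trial.
    """
    rng = as_rng(rng)
    if len(arrays) < protocol.n_trials:
        raise ValueError(
            f"need at least {protocol.n_trials} arrays, got {len(arrays)}"
        )
    rows = []
    trial = 0
    for block in range(protocol.baseline_blocks + protocol.interaction_blocks):
        interacting = block >= protocol.baseline_blocks
        for _ in range(protocol.trials_per_block):
            array = arrays[trial]
            own = emotion_agent_classify(agent, array, rng)
            partner = changed = None
            final = own
            criterion_before = agent.criterion
            if interacting:
                partner = advisor(array, rng)
                changed = emotion_agent_change_decision(
                    agent, own, partner, protocol.partner_label, rng
                )
                final = partner if changed else own
                agent = emotion_agent_update(agent, own, partner)
            rows.append({
                "trial": trial,
                "block": block,
                "phase": "interaction" if interacting else "baseline",
                "mean_rank": array.mean_rank,
                "objective_class": class_name(array.objective_class),
                "own_class": class_name(own),
                "partner_class": None if partner is None else class_name(partner),
                "changed": changed,
                "final_class": class_name(final),
                "partner_label_shown": protocol.partner_label if interacting else None,
                "criterion": criterion_before,
            })
            trial += 1
    return pd.DataFrame(rows)


def run_rdk_session(
    agent: RdkAgentState,
    advisors: Sequence[AdvisorSpec],
    rng,
    schedule: Sequence[float] | None = None,
    baseline_blocks: int = 1,
    shuffle_trials: bool = True,
) -> pd.DataFrame:
    """Simulate one agent through a baseline block and interaction blocks.

    Each block presents the full 30-trial evidence schedule (shuffled
    within block by default).  ``advisors`` gives the partner for each
    interaction block in order - three different algorithms in the main
    design, or the same algorithm five times in the follow-up trend design.

    Within each interaction trial the order of events is: independent
    estimate -> commit weight w -> partner response revealed -> joint
    response -> learning update.  The committed w therefore never depends
    on the partner's response on that trial.
    """
    rng = as_rng(rng)
    schedule = list(make_rdk_schedule() if schedule is None else schedule)
    rows = []
    trial = 0
    block = 0
    for _ in range(baseline_blocks):
        evidence_seq = rng.permutation(schedule) if shuffle_trials else schedule
        for ev in evidence_seq:
            own = rdk_agent_estimate(agent, float(ev), rng)
            rows.append({
                "trial": trial, "block": block, "phase": "baseline",
                "advisor": None, "evidence": float(ev),
                "own_estimate": own, "w": None,
                "partner_estimate": None, "joint_estimate": None,
                "offset": agent.offset,
            })
            trial += 1
        block += 1
    for spec in advisors:
        evidence_seq = rng.permutation(schedule) if shuffle_trials else schedule
        for ev in evidence_seq:
            own = rdk_agent_estimate(agent, float(ev), rng)
            w = agent.weight_on_self          # committed before the reveal
            partner = advisor_response(spec, float(ev), rng)
            joint = joint_response(own, partner, w)
            rows.append({
                "trial": trial, "block": block, "phase": "interaction",
                "advisor": spec.kind, "evidence": float(ev),
                "own_estimate": own, "w": w,
                "partner_estimate": partner, "joint_estimate": joint,
                "offset": agent.offset,
            })
            agent = rdk_agent_update(agent, partner, own)
            trial += 1
        block += 1
    return pd.DataFrame(rows)
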