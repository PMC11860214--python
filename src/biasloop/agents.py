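"""Simulated human agents whose judgement drifts through interaction.

Two agent families, one per task:

* :class:`EmotionAgent` classifies 12-face arrays through the same noisy,
  criterion-shifted psychometric rule as the simulated labellers, and its
  criterion drifts by a delta rule toward a partner that systematically
  disagrees in one direction.
* :class:`RdkAgent` estimates the rightward-motion percentage with a
  systematic offset plus Gaussian noise, and its offset drifts by a delta
  rule toward the partner's revealed estimates.

Both updates are Rescorla-Wagner-style: the state moves a fraction
``learning_rate`` of the prediction discrepancy per interaction trial, so in
expectation the emotion criterion settles where the agent's more-sad rate
matches the partner's, and the RDK offset settles at the partner's mean
systematic offset (zero for an accurate partner - accuracy gain; ~24.5 pp
for the upward-biased partner - induced bias).

Change-of-mind behaviour on the emotion task is a calibrated Bernoulli
policy: the defaults take the empirically observed switch rates (32.72% on
disagreement with a partner labelled as an AI, 11.27% labelled as human,
0.3% on agreement) as constants, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import as_rng
from .stimuli import MORE_HAPPY, MORE_SAD, FaceArray, SimHumanParams, p_more_sad

__all__ = [
    "SWITCH_RATES",
    "EmotionAgentState",
    "RdkAgentState",
    "emotion_agent_classify",
    "emotion_agent_update",
    "emotion_agent_change_decision",
    "rdk_agent_estimate",
    "rdk_agent_update",
]

#: empirical disagreement switch rates by partner label, used as calibration
#: constants for the change-of-mind policy.
SWITCH_RATES = {
    "AI": 0.3272,
    "human": 0.1127,
    "human_labelled_AI": 0.3184,
    "AI_labelled_human": 0.1684,
}

#: agreement-trial switch rate (rare accidental changes).
SWITCH_RATE_AGREE = 0.003


def _z(cls: int) -> int:
    """Class code on the +/-1 scale used by the criterion update."""
    return 1 if cls == MORE_SAD else -1


@dataclass(frozen=True)
class EmotionAgentState:
    """Criterion-shift agent for the emotion-aggregation task.

    criterion
        current shift of the 25.5 class boundary (positive = answers
        more_sad more often); this is the quantity that learns.
    sensitivity_sd
        s.d. of late noise on the perceived mean rank, in rank units.
    learning_rate
        criterion change per unit of (partner - own) disagreement.
    switch_prob_disagree / switch_prob_agree
        change-of-mind probabilities; the disagreement rate is looked up by
        the partner's displayed label (``"AI"`` or ``"human"``).
    """

    criterion: float = 0.0
    sensitivity_sd: float = 9.7
    learning_rate: float = 0.1
    switch_prob_disagree: dict = field(
        default_factory=lambda: {"AI": SWITCH_RATES["AI"], "human": SWITCH_RATES["human"]}
    )
    switch_prob_agree: float = SWITCH_RATE_AGREE

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.sensitivity_sd < 0:
            raise ValueError("sensitivity_sd must be >= 0")


def emotion_agent_classify(state: EmotionAgentState, array: FaceArray, rng) -> int:
    """One independent classification draw from the agent's psychometric rule."""
    rng = as_rng(rng)
    params = SimHumanParams(state.sensitivity_sd, state.criterion)
    p = float(p_more_sad(array.mean_rank, params))
    return MORE_SAD if rng.random() < p else MORE_HAPPY


def emotion_agent_update(state: EmotionAgentState, own_class: int, partner_class: int) -> EmotionAgentState:
    """Delta-rule criterion update after seeing the partner's classification.

    ``c <- c + eta * (z_partner - z_own) / 2`` with z(more_sad) = +1 and
    z(more_happy) = -1: the criterion moves by +/- eta on disagreement and
    is unchanged on agreement.  In expectation the drift per trial is
    ``eta * (P_partner(more_sad) - P_own(more_sad))``.
    """
    delta = state.learning_rate * (_z(partner_class) - _z(own_class)) / 2.0
    if delta == 0.0:
        return state
    return replace(state, criterion=state.criterion + delta)


def emotion_agent_change_decision(
    state: EmotionAgentState,
    own_class: int,
    partner_class: int,
    partner_label: str,
    rng,
) -> bool:
    """Bernoulli change-of-mind decision given the partner's displayed label."""
    rng = as_rng(rng)
    if own_class == partner_class:
        p = state.switch_prob_agree
    else:
        p = state.switch_prob_disagree[partner_label]
    return bool(rng.random() < p)


@dataclass(frozen=True)
class RdkAgentState:
    """Offset-plus-noise estimator for the RDK task.

    offset
        systematic estimation bias in percentage points; the learned
        quantity.
    noise_sd
        trial-to-trial Gaussian estimation noise, percentage points.
    learning_rate
        offset change per percentage point of (partner - own) discrepancy.
    weight_on_self
        fixed weight w committed before the partner's response is revealed
        (the trust-updating alternative lives in the interaction protocol).
    """

    offset: float = 0.0
    noise_sd: float = 12.0
    learning_rate: float = 0.005
    weight_on_self: float = 0.4

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.weight_on_self <= 1.0:
            raise ValueError("weight_on_self must be in [0, 1]")


def rdk_agent_estimate(state: RdkAgentState, evidence: float, rng) -> float:
    """Independent estimate: evidence + offset + noise, clipped to [0, 100]."""
    if not 0.0 <= evidence <= 100.0:
        raise ValueError("evidence must be in [0, 100]")
    rng = as_rng(rng)
    noise = rng.normal(0.0, state.noise_sd) if state.noise_sd > 0 else 0.0
    return float(np.clip(evidence + state.offset + noise, 0.0, 100.0))


def rdk_agent_update(state: RdkAgentState, partner_estimate: float, own_estimate: float) -> RdkAgentState:
    """Delta-rule offset update after the partner's response is revealed.

    ``b <- b + eta * (partner - own)``.  Against an accurate partner the
    expected update is ``-eta * b`` (geometric decay of the agent's own
    bias); against a systematically offset partner the fixed point in
    expectation is the partner's mean offset.
    """
    delta = state.learning_rate * (partner_estimate - own_estimate)
    if delta == 0.0:
        return state
    return replace(state, offset=state.offset + delta)
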