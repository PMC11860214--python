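"""Population-level feedback-loop experiments.

These functions run many simulated agents through the interaction protocols
and collect the statistics the analysis layer consumes:

* :func:`run_rdk_trend_experiment` - one partner algorithm across five
  interaction blocks (plus a baseline block); per-agent per-block induced
  bias and induced accuracy change.  With the biased partner the induced
  bias should rise over blocks; with the accurate partner the induced
  accuracy change should rise; with a zero learning rate, neither.
* :func:`run_rdk_triad_experiment` - each agent meets all three algorithms,
  order counterbalanced by Latin square; feeds the influence comparison.
* :func:`run_emotion_trend_experiment` - emotion change-of-mind sessions
  against a partner with a fixed more-sad rate; per-agent per-block
  more-sad rates of the agent's own (pre-advice) classifications.
* :func:`estimate_learning_rate` - recover the delta-rule learning rate
  from a session log by least squares on the update recursion.

Agent populations draw individual baseline offsets (RDK) from a Gaussian
so that an accurate partner has room to improve accuracy, mirroring
idiosyncratic observer biases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .agents import EmotionAgentState, RdkAgentState
from .interaction import (
    AdvisorSpec,
    ProtocolConfig,
    latin_square_orders,
    run_emotion_session,
    run_rdk_session,
)
from .stimuli import MORE_SAD, build_balanced_set

__all__ = [
    "default_rdk_agent",
    "run_rdk_trend_experiment",
    "run_rdk_triad_experiment",
    "run_emotion_trend_experiment",
    "rdk_block_table",
    "estimate_learning_rate",
]

#: s.d. of per-agent baseline systematic offsets in the RDK population (pp).
RDK_OFFSET_SD = 8.0


def default_rdk_agent(rng, learning_rate: float = 0.005) -> RdkAgentState:
    """One agent with an individual baseline offset ~ N(0, 8 pp)."""
    return RdkAgentState(
        offset=float(rng.normal(0.0, RDK_OFFSET_SD)),
        noise_sd=12.0,
        learning_rate=learning_rate,
        weight_on_self=0.4,
    )


def _block_dev_stats(log: pd.DataFrame) -> pd.DataFrame:
    dev = log["own_estimate"] - log["evidence"]
    out = pd.DataFrame({"block": log["block"], "phase": log["phase"], "dev": dev})
    g = out.groupby("block", sort=True)
    return pd.DataFrame({
        "phase": g["phase"].first(),
        "bias": g["dev"].mean(),
        "error": g["dev"].apply(lambda s: s.abs().mean()),
    }).reset_index()


def rdk_block_table(log: pd.DataFrame) -> pd.DataFrame:
    """Per-block bias / error of the agent's independent estimates, with
    induced metrics relative to the session's baseline block(s)."""
    tab = _block_dev_stats(log)
    base = tab[tab.phase == "baseline"]
    bias0, err0 = base["bias"].mean(), base["error"].mean()
    tab["induced_bias"] = tab["bias"] - bias0
    tab["induced_accuracy_change"] = err0 - tab["error"]
    return tab


def run_rdk_trend_experiment(
    advisor_kind: str,
    n_agents: int = 50,
    n_blocks: int = 5,
    learning_rate: float = 0.005,
    master_seed: int = 0,
    advisor_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Population of agents, one partner algorithm, ``n_blocks`` interaction
    blocks after a baseline block.

    Returns a tidy frame: one row per agent per block with the block's
    induced bias and induced accuracy change (agent's independent
    estimates vs the session's baseline block).
    """
    spec = AdvisorSpec(advisor_kind, **(advisor_kwargs or {}))
    rows = []
    for agent_id in range(n_agents):
        rng = spawn_rng(master_seed, "rdk_trend", advisor_kind, agent_id)
        agent = default_rdk_agent(rng, learning_rate=learning_rate)
        log = run_rdk_session(agent, [spec] * n_blocks, rng)
        tab = rdk_block_table(log)
        tab = tab[tab.phase == "interaction"].copy()
        tab["interaction_block"] = np.arange(len(tab))
        tab["agent"] = agent_id
        tab["advisor"] = advisor_kind
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def run_rdk_triad_experiment(
    n_agents: int = 51,
    learning_rate: float = 0.005,
    master_seed: int = 0,
) -> dict:
    """Each agent interacts with accurate, biased and noisy partners, order
    counterbalanced by the three Latin-square rotations.

    Returns per-agent frames keyed for :func:`biasloop.stats.influence_compare`:
    ``induced_bias`` and ``induced_accuracy`` (agent x advisor) plus
    ``baseline_bias`` and ``baseline_error`` vectors.
    """
    orders = latin_square_orders()
    ib, ia, bb, be = [], [], [], []
    for agent_id in range(n_agents):
        rng = spawn_rng(master_seed, "rdk_triad", agent_id)
        agent = default_rdk_agent(rng, learning_rate=learning_rate)
        order = orders[agent_id % len(orders)]
        specs = [AdvisorSpec(k) for k in order]
        log = run_rdk_session(agent, specs, rng)
        tab = rdk_block_table(log).set_index("block")
        inter = tab[tab.phase == "interaction"]
        by_advisor = dict(zip(order, inter.index))
        ib.append({k: inter.loc[b, "induced_bias"] for k, b in by_advisor.items()})
        ia.append({k: inter.loc[b, "induced_accuracy_change"] for k, b in by_advisor.items()})
        base = tab[tab.phase == "baseline"]
        bb.append(base["bias"].mean())
        be.append(base["error"].mean())
    return {
        "induced_bias": pd.DataFrame(ib),
        "induced_accuracy": pd.DataFrame(ia),
        "baseline_bias": np.asarray(bb),
        "baseline_error": np.asarray(be),
    }


def run_emotion_trend_experiment(
    partner_sad_rate: float = 0.65,
    n_agents: int = 50,
    learning_rate: float = 0.1,
    sensitivity_sd: float = 9.7,
    protocol: ProtocolConfig | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Population of emotion agents against a fixed-rate more_sad emitter.

    The partner answers more_sad with probability ``partner_sad_rate``
    independent of the stimulus (0.5 = unbiased partner).  Returns one row
    per agent per block with the rate of the agent's own (pre-advice)
    more_sad classifications.
    """
    protocol = protocol or ProtocolConfig()
    rows = []
    for agent_id in range(n_agents):
        rng = spawn_rng(master_seed, "emotion_trend", agent_id)
        agent = EmotionAgentState(
            sensitivity_sd=sensitivity_sd, learning_rate=learning_rate
        )
        arrays = build_balanced_set(protocol.n_trials // 2 + 1, rng)[: protocol.n_trials]

        def advisor(array, arng, _p=partner_sad_rate):
            return MORE_SAD if arng.random() < _p else 1 - MORE_SAD

        log = run_emotion_session(agent, advisor, protocol, arrays, rng)
        sad = (log["own_class"] == "more_sad").astype(float)
        per_block = sad.groupby(log["block"]).mean()
        phase = log.groupby("block")["phase"].first()
        for b, rate in per_block.items():
            rows.append({
                "agent": agent_id, "block": int(b), "phase": phase[b],
                "own_sad_rate": float(rate),
            })
    return pd.DataFrame(rows)


def estimate_learning_rate(log: pd.DataFrame, task: str) -> float:
    """Least-squares recovery of the delta-rule learning rate from a log.

    For the RDK task the recursion is ``offset_{t+1} - offset_t =
    eta * (partner - own)``; for the emotion task ``criterion_{t+1} -
    criterion_t = eta * (z_partner - z_own) / 2``.  The slope through the
    origin of the observed state increments on the predictors is the
    estimator.
    """
    inter = log[log.phase == "interaction"]
    if task == "rdk":
        state = inter["offset"].to_numpy()
        x = (inter["partner_estimate"] - inter["own_estimate"]).to_numpy()
    elif task == "emotion":
        state = inter["criterion"].to_numpy()
        z = {"more_sad": 1.0, "more_happy": -1.0}
        x = (inter["partner_class"].map(z).to_numpy()
             - inter["own_class"].map(z).to_numpy()) / 2.0
    else:
        raise ValueError("task must be 'rdk' or 'emotion'")
    dstate = np.diff(state)
    x = x[:-1]
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("no disagreement variance; learning rate unidentifiable")
    return float((x @ dstate) / denom)
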