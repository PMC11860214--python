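"""Feedback-loop drift in agent populations (both tasks).

RDK: 30 agents interact with the biased partner for five blocks; their
induced bias grows block by block.  With the accurate partner their
accuracy improves instead.  Emotion task: 20 agents interact with a
65%-more-sad partner; their own sad rate drifts upward.  ~20 seconds.
"""

from biasloop.experiments import (
    run_emotion_trend_experiment,
    run_rdk_trend_experiment,
)
from biasloop.stats import block_trend

for kind, metric in (("biased", "induced_bias"),
                     ("accurate", "induced_accuracy_change")):
    df = run_rdk_trend_experiment(kind, n_agents=30, master_seed=0)
    piv = df.pivot(index="agent", columns="interaction_block", values=metric)
    res = block_trend(piv, n_shuffles=20000, seed=1)
    print(f"{kind:9s} partner: per-block {metric} "
          f"{[round(v, 2) for v in piv.mean().tolist()]}")
    print(f"          mean slope {res.mean_slope:+.2f} pp/block, "
          f"p = {res.test.p_two_sided:.2g}, d = {res.test.cohen_d:.2f}")

em = run_emotion_trend_experiment(n_agents=20, master_seed=0)
inter = em[em.phase == "interaction"]
piv = inter.pivot(index="agent", columns="block", values="own_sad_rate")
res = block_trend(piv, n_shuffles=20000, seed=2)
print(f"\nemotion agents vs 65%-sad partner: block sad rates "
      f"{[round(v, 3) for v in piv.mean().tolist()]}")
print(f"          mean slope {res.mean_slope:+.4f}/block, "
      f"p = {res.test.p_two_sided:.2g}")
print("\nPositive, significant slopes = the agents learn the partner's bias")
print("(or accuracy) into their own independent judgements over time.")
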