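"""Train the convolutional judge under two label regimes (reduced scale).

Trains on 2,000 arrays with objective labels and with random-plus-3%-bias
labels, then evaluates both judges on a balanced 200-array held-out set.
Expect the objective judge to be accurate and nearly unbiased, and the
random-label judge to collapse toward constant more-sad calls while staying
at chance against the objective classes.  At this reduced single-seed scale
the collapse is partial (~90% more-sad); at the full desk scale (4,000
arrays, five seeds) it reaches ~100% (bias ~50 pp).  Takes ~1 minute.
"""

from biasloop import run_table1_experiment

per_seed, mean = run_table1_experiment(
    n_train=2000,
    n_test=200,
    seeds=(0,),
    schemes=("objective", "random_bias3"),
)
print(mean.to_string(index=False))
print("\nbias_pp = (% classified more_sad) - 50 on the balanced held-out set;")
print("a 3 pp label bias embedded in uninformative labels is amplified to a")
print("large majority-class bias - ~50 pp at full desk scale.")
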