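"""Generate balanced face-array stimuli and the four label regimes.

Builds 200 arrays (100 mirror pairs), shows the mirror construction, and
labels the set under each regime, printing the more-sad share and accuracy
against the objective classes for each.
"""

import numpy as np

from biasloop import build_balanced_set, make_label_set, mirror_array

rng_seed = 0
arrays = build_balanced_set(100, np.random.default_rng(rng_seed))

a = arrays[0]
m = mirror_array(a)
print(f"array ranks:  {a.ranks}")
print(f"mirror ranks: {m.ranks}")
print(f"mean ranks {a.mean_rank:.2f} + {m.mean_rank:.2f} = 51, "
      f"classes {a.objective_class} vs {m.objective_class}\n")

for scheme in ("objective", "objective_bias3", "sim_human", "random_bias3"):
    ds = make_label_set(arrays, scheme, rng_seed)
    acc = np.mean(ds.labels == ds.objective_classes)
    print(f"{scheme:16s} more-sad share {ds.sad_share:5.1%}   "
          f"label accuracy {acc:5.1%}")

print("\nThe biased regimes hold the more-sad share at 53% (a 3 pp bias);")
print("label accuracy falls from 100% to ~50% as label noise grows.")
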