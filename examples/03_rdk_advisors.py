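"""The three hard-coded RDK partner algorithms and the joint decision.

Samples each partner's responses over three passes of the 30-trial
evidence schedule and prints their signed and absolute deviation from the
truth, plus the printed worked example of the weighting formula.
"""

import numpy as np

from biasloop import AdvisorSpec, advisor_response, joint_response
from biasloop.stimuli import make_rdk_schedule

rng = np.random.default_rng(0)
schedule = make_rdk_schedule() * 3

for kind in ("accurate", "biased", "noisy"):
    spec = AdvisorSpec(kind)
    devs = [advisor_response(spec, ev, rng) - ev for ev in schedule]
    print(f"{kind:9s} mean offset {np.mean(devs):6.2f} pp   "
          f"mean |error| {np.mean(np.abs(devs)):6.2f} pp")

print("\nThe biased partner is ~24.5 pp high on average; the noisy partner is")
print("error-matched but unbiased (clipping to [0,100] trims both a little).")

print(f"\njoint_response(own=53, partner=73, w=0.4) = "
      f"{joint_response(53, 73, 0.4):.0f}% dots rightward")
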