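"""Saccadic visual search by active inference.

An agent holds three image hypotheses (an upright face-like pattern, its
inverted and rotated variants) and is shown the upright one.  Salience —
the confidence that fictively sampling a location would buy — selects
each saccade target; inhibition of return keeps the eyes moving.  The
run prints the fixation sequence, the evolving posterior over the three
hypotheses, and the stepwise shrinkage of uncertainty about the true
stimulus.
"""

import numpy as np

from actinf import FovealSampler, run_visual_search
from actinf.fixtures import default_hypotheses

result = run_visual_search(default_hypotheses(), FovealSampler(), seed=1)

print("fixation sequence (gaze units, origin = image centre):")
for j, (fx, fy) in enumerate(result.fixations):
    print(f"  saccade {j}: ({fx:+.2f}, {fy:+.2f})")

labels = ["upright", "inverted", "rotated"]
final = result.hypothesis_weights[-1]
print("\nfinal posterior weights:")
for name, w in zip(labels, final):
    print(f"  {name:9s} {w:.4f}")

seq = np.concatenate([[result.initial_uncertainty],
                      result.fixation_end_uncertainty()])
print("\nuncertainty about the true stimulus (start, then each fixation end):")
print("  " + "  ".join(f"{u:.3f}" for u in seq))
print()
print("The upright hypothesis supervenes over its competitors and the")
print("confidence interval shrinks saccade by saccade as salient locations")
print("are sampled; transient increases occur only mid-flight.")
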