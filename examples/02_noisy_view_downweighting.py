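"""Watch the fusion step discount an uninformative view.

Three informative views plus a fourth whose cluster assignment was shuffled
before generation (it has internal structure but carries no signal about
the true labels).  The inverse-distance weighting should hand the corrupted
view the smallest weight.
"""

import numpy as np

from lrcmc import BlobSpec, LRCMCConfig, accuracy, fit, make_multiview_blobs

spec = BlobSpec(m=4, dims=(10, 10, 10, 10), corrupt_views=frozenset({3}), seed=3)
views, truth = make_multiview_blobs(spec)
labels, state = fit(views, LRCMCConfig(c=3, k=10))

w = state.weights.w
for v, wv in enumerate(w):
    tag = " (corrupted)" if v == 3 else ""
    print(f"view {v}: weight {wv:.3e}{tag}")
print(f"corrupted view has minimum weight: {int(np.argmin(w)) == 3}")
print(f"ACC despite the bad view: {accuracy(truth.labels, labels.labels):.4f}")

# The informative views agree with the consensus and end up far above the
# corrupted one, so the bad view barely moves the consensus and the
# clustering stays perfect.
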