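"""Propagate template cluster labels to a jittered analysis tractogram.

A labeled template (planted bundles) transfers its labels to a new subject
by maximum similarity: each target streamline takes the label of the
MDF-nearest template streamline.  With jitter well below the inter-bundle
gap the planted labels are recovered exactly, including for reversed copies.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from tractreli import LabeledTemplate, propagate_labels, resample_all, subsample_template

rng = np.random.default_rng(1)
streams, truth = [], []
for b in range(3):
    base = np.stack([np.linspace(0, 60, 50), np.full(50, 30.0 * b), np.zeros(50)], axis=1)
    for _ in range(60):
        streams.append(base + rng.normal(0, 1.0, size=3))
        truth.append(b)
template = LabeledTemplate(resample_all(streams, 20), np.array(truth))

# at scale one keeps a 20,000-streamline labeled subsample; here 90 of 180
sub = subsample_template(template, 90, seed=0)
print(f"template: {len(template)} streamlines -> subsample {len(sub)}")

target = template.streamlines + rng.normal(0, 0.8, size=(len(template), 1, 3))
target[::2] = target[::2, ::-1]  # reverse half to exercise flip invariance
labeling, dists = propagate_labels(sub, target)
print("propagation ARI vs planted:", adjusted_rand_score(truth, labeling.labels))
print(f"mean MDF to nearest template streamline: {dists.mean():.2f} mm")
# ARI 1.0: every jittered (and reversed) streamline found its home bundle.
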