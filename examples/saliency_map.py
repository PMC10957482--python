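"""Smooth guided back-propagation saliency for a fine-tuned task model.

Fine-tunes a small classifier briefly on a synthetic cohort, then attributes
the predicted class logit of one case back to its input voxels by averaging
guided gradients over noisy copies of the patch.
"""

import warnings

import numpy as np

from lesionfm import (EncoderConfig, FineTuneConfig, fine_tune,
                      make_classification_cohort, smooth_guided_saliency)
from lesionfm.pipeline import cohort_patches

warnings.filterwarnings("ignore")

cohort = make_classification_cohort(n=30, K=3, rng=np.random.default_rng(0))
labels = [r.site_class for r in cohort.lesions]
patches = cohort_patches(cohort, edge_voxels=24)

model, trace = fine_tune(None, patches, labels, n_classes=3,
                         encoder_config=EncoderConfig(),
                         config=FineTuneConfig(epochs=8),
                         rng=np.random.default_rng(1))
print(f"fine-tuning loss: {trace.loss.iloc[0]:.2f} -> {trace.loss.iloc[-1]:.2f}")

sal = smooth_guided_saliency(model, patches[0], n_noise=10, noise_sd=0.1,
                             rng=np.random.default_rng(2))
v = sal.values
center = v[8:16, 8:16, 8:16].mean()   # lesion neighbourhood
border = np.concatenate([v[:4].ravel(), v[-4:].ravel()]).mean()
print(f"predicted class: {sal.meta['target_class']}")
print(f"mean |saliency| near the lesion centre: {center:.2e}")
print(f"mean |saliency| at the patch border:    {border:.2e}")

# Attribution concentrated around the lesion (centre >> border) indicates
# the model bases its prediction on lesion voxels rather than background.
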