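"""Compare the three thresholding schemes on the vertebral echoes.

The deep part of a vertebral echo is barely brighter than muscle, so a
threshold at the image mean (average binarization) clips it, and Otsu's
two-class assumption splits at the wrong place for this three-tissue scene.
The fuzzy sigma binarizer cuts its membership ramp lower and keeps more of
the echo, which is what anchors the thickness measurement.  Recall below is
the share of true vertebral-echo pixels each foreground recovers, averaged
over 10 phantoms.
"""

import numpy as np

from dcfseg import (
    PhantomParams, average_binarize, crop_roi, ends_in_stretch,
    fuzzy_sigma_binarize, generate_batch, otsu_binarize,
)

recalls = {"average": [], "otsu": [], "fuzzy sigma": []}
for img, truth in generate_batch(10, PhantomParams(), base_seed=1):
    stretched = ends_in_stretch(crop_roi(img, truth.roi))
    vert = truth.vertebra_mask_roi()
    for name, binarizer in (("average", average_binarize),
                            ("otsu", otsu_binarize),
                            ("fuzzy sigma", fuzzy_sigma_binarize)):
        fg = binarizer(stretched) > 0
        recalls[name].append((fg & vert).sum() / vert.sum())

for name, values in recalls.items():
    print(f"{name:12s} vertebra-pixel recall: {100 * np.mean(values):6.2f}%")
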