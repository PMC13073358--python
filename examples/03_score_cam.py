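"""Score-CAM attribution on a trained checkpoint.

Run examples/02_train_and_evaluate.py first (it writes example_tiny.npz).
For a malignant-class test image, this computes the Score-CAM heatmap,
blends it over the frame, and reports how much of the high-activation
region falls inside the ground-truth lesion mask.  A concordant verdict
means the model's evidence sits on the lesion, not the background mucosa.
"""

import numpy as np
from PIL import Image

from ordvit import (
    SeverityParams,
    load_checkpoint,
    overlap_concordance,
    overlay,
    render_image,
    score_cam_model,
)

model = load_checkpoint("example_tiny.npz")
record = render_image(3, SeverityParams.well_separated(image_size=64), np.random.default_rng(7))

heatmap = score_cam_model(model, record.pixels, target_class=3, top_k=64)
blend = overlay(heatmap, record.pixels)
Image.fromarray((blend * 255).round().astype(np.uint8)).save("example_overlay.png")

result = overlap_concordance(heatmap, record.mask, binarize_thresh=0.5, tau=0.5)
print(f"high-activation overlap with lesion mask: {result.overlap_fraction:.2f}")
print(f"concordant (>= tau {result.tau}): {result.concordant}")
print("overlay written to example_overlay.png (warm colors = strong attribution)")
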