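"""Learn a Grassmannian codebook and VLAD-encode two synthetic images.

Builds two classes with well-separated dynamics, fits the point cloud of one
image per class, learns a 4-word codebook from one cloud, and prints the
scalar VLAD codes — images of different classes land on clearly different
codes.
"""

import numpy as np

from grassvlad import encode_image, learn_codebook
from grassvlad.pipeline import PipelineConfig, image_point_cloud
from grassvlad.synthetic import make_class_systems, synth_image

systems, sep = make_class_systems(2, seed=5, class_separation=0.8)
print("class-system subspace separation: %.3f" % sep)

cfg = PipelineConfig(strategy="overlapping", patch_size=8, overlap_fraction=0.5)
clouds = [image_point_cloud(synth_image(s, 64, 8, seed=i), cfg)[0]
          for i, s in enumerate(systems)]
print("points per image:", [c.shape[0] for c in clouds])

book = learn_codebook(np.concatenate(clouds), k=4, seed=0)
print("codebook meta:", book.training_meta)

for i, cloud in enumerate(clouds):
    code = encode_image(cloud, book)
    print("class %d VLAD code: %s  (norm %.3f)"
          % (i, np.round(code.values, 3), np.linalg.norm(code.values)))
print("-> each component is the summed geodesic residual mass near one word;")
print("   class-specific words carry mass for one class only, so the codes")
print("   separate linearly even at k=4.")
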