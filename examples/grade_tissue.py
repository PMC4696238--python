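"""Grade a simulated slide end to end: detect, classify sub-blocks, aggregate.

Trains the color-histogram kNN on simulated annotated images, detects HPFs
on the CD20 rendering, classifies each HPF's 64 x 64 sub-blocks, and applies
the rule hierarchy (sub-block majority vote -> HPF count > 115 -> tissue
>= 50% high) to recover the planted tissue grade.
"""

import flgrade as fg
from flgrade.cli import grade_slide

images, annotations = fg.simulate_training_data(seed=7)
training = fg.build_training_set(images, annotations, seed=7)
print(f"training set: {training.n_cb} centroblast + "
      f"{training.n_noncb} non-centroblast histograms")

slide = fg.simulate_slide(fg.SlideSimConfig(seed=301, n_follicles=3,
                                            n_high_follicles=2))
cands = fg.detect_hpfs_multires(slide.cd20, fg.DetectionConfig(downscale=80))
labels, tissue = grade_slide(slide.he.pixels, cands, training, fg.ClassifierConfig())

for cand, label in zip(cands, labels):
    res = fg.classify_hpf(slide.he.pixels[cand.bbox[0]:cand.bbox[2],
                                          cand.bbox[1]:cand.bbox[3]], training)
    print(f"HPF ({cand.grid_row}, {cand.grid_col}): "
          f"{res.n_cb_blocks}/{res.n_subblocks} CB sub-blocks -> {label}")
print(f"tissue: {tissue.n_high}/{tissue.n_detected} HPFs high "
      f"({tissue.percent_high:.1f}%) -> grade {tissue.grade} "
      f"(planted: {slide.true_grade})")

# The WHO manual-count pathway for the conventional reading arm:
counts = [4, 9, 22, 18, 30, 12, 17, 25, 21, 19]
print(f"manual counts {counts} -> WHO grade {fg.who_grade(counts)}")
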