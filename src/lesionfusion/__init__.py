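"""lesionfusion: two-stream multiscale feature-fusion dermoscopy classifier.

The package implements the full pipeline around a seven-class skin-lesion
classifier: a seeded synthetic dermoscopy generator for desk-scale testing,
preprocessing (black-hat hair removal with inward inpainting, augmentation,
class balancing, stratified splitting), a DenseNet-121 stream and a
residual-augmented VGG-16 stream fused through a multireceptive-field block
with generalized-mean (GeM) pooling, the training protocol, evaluation
(per-class/macro/micro metrics, ROC-AUC, Grad-CAM) and a thresholded
classification service.
"""

from .constants import (CLASS_INDEX, CLASS_NAMES, DEFAULT_GEM_P, INPUT_SIZE, NUM_CLASSES,
                        SERVICE_THRESHOLD)

__version__ = "0.1.0"

__all__ = [
    "CLASS_NAMES", "CLASS_INDEX", "NUM_CLASSES", "INPUT_SIZE",
    "SERVICE_THRESHOLD", "DEFAULT_GEM_P", "__version__",
]
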