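"""Fixed study constants: class order and the ISIC2018 sample distribution.

The seven-class order is the canonical index order used throughout the
package (class indices 0-6): actinic keratosis / intraepithelial carcinoma,
basal cell carcinoma, benign keratosis, dermatofibroma, melanoma,
melanocytic nevus, vascular lesion.
"""

from __future__ import annotations

CLASS_NAMES: tuple[str, ...] = ("Akiec", "Bcc", "Bkl", "Df", "Mel", "Nv", "Vasc")
CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}
NUM_CLASSES = len(CLASS_NAMES)

#: Per-class image totals of the ISIC2018 Task-3 / HAM10000 dataset.
ISIC2018_CLASS_TOTALS: dict[str, int] = {
    "Nv": 6705, "Mel": 1113, "Bkl": 1099, "Bcc": 514,
    "Akiec": 327, "Vasc": 142, "Df": 115,
}

#: The study's published per-class (train, test, val) division of those
#: totals.  The counts are close to, but not exactly, a 7:2:1 split; they
#: are kept verbatim as an override table for reproducing the published
#: bookkeeping.
STUDY_SPLIT_COUNTS: dict[str, tuple[int, int, int]] = {
    "Nv": (4697, 1339, 669),
    "Mel": (780, 222, 111),
    "Bkl": (771, 219, 109),
    "Bcc": (361, 102, 51),
    "Akiec": (230, 65, 32),
    "Vasc": (100, 28, 14),
    "Df": (81, 23, 11),
}

#: Published per-class training-set sizes after augmentation-based
#: balancing (every minority class raised to roughly the Nv count).
BALANCED_TRAIN_TARGETS: dict[str, int] = {
    "Nv": 4697, "Mel": 5439, "Bkl": 5383, "Bcc": 5040,
    "Akiec": 4251, "Vasc": 5600, "Df": 4536,
}

#: Default input resolution of the classifier.
INPUT_SIZE = 224

#: Default confidence threshold of the classification service.
SERVICE_THRESHOLD = 0.9

#: Default GeM pooling exponent (selected by the study's hyperparameter sweep).
DEFAULT_GEM_P = 4.0
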