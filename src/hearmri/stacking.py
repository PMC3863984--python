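"""Second-layer fusion of the structural and functional scores.

The two first-layer classifiers map every subject to a point
``(Csum, fMRI_score)``; a linear SVM with C = 1 trained on the training
subjects' (in-sample) score pairs provides the final decision

    y = w1 * Csum + w2 * fMRI_score + bias,   HI iff y >= eps_i (default 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC


class TrainingError(RuntimeError):
    pass


@dataclass
class SecondLayerModel:
    w1: float
    w2: float
    bias: float
    eps_i: float = 0.0
    C: float = 1.0

    def score(self, csum: float, fmri_score: float) -> float:
        return self.w1 * csum + self.w2 * fmri_score + self.bias

    def classify(self, y: float) -> str:
        return "HI" if y >= self.eps_i else "NH"

    def to_dict(self) -> dict:
        return {"w1": self.w1, "w2": self.w2, "bias": self.bias,
                "eps_i": self.eps_i, "C": self.C}


def train_second_layer(
    score_pairs: np.ndarray, labels_hi: np.ndarray, C: float = 1.0, eps_i: float = 0.0
) -> SecondLayerModel:
    """Fit the linear SVM in the 2-D (Csum, fMRI_score) space.

    Scores are used as-is (no standardization): the space is 2-D and the
    regularization constant is part of the method definition.
    """
    pairs = np.asarray(score_pairs, dtype=float)
    y = np.where(np.asarray(labels_hi, dtype=bool), 1.0, -1.0)
    if len(np.unique(y)) < 2:
        raise TrainingError("second layer needs both classes in training")
    svm = SVC(kernel="linear", C=C)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm.fit(pairs, y)
    w = svm.coef_.ravel()
    return SecondLayerModel(
        w1=float(w[0]), w2=float(w[1]), bias=float(svm.intercept_[0]),
        eps_i=eps_i, C=C,
    )
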