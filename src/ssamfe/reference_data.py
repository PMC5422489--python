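"""Bundled example strength data from a published cadaver validation
experiment of DXA-based FE models.

Two donor femora were mechanically tested to fracture in a single-leg-stance
configuration; FE predictions of femoral strength were obtained for three
model variants (reconstructed BMD on true shape, reconstructed shape with
true BMD, fully reconstructed) from three different reference images each
(a CT projection and two DXA devices), plus a CT-based gold-standard model.
These printed values serve as the worked example for the strength-error
metrics (relative error, standard error of the estimate).
"""

from __future__ import annotations

import numpy as np

# experimentally measured fracture loads, N
EXPERIMENTAL_STRENGTH = {"bone1": 13383.0, "bone2": 7856.0}

# predicted strength, N; keys: model variant -> reference image -> bone
PREDICTED_STRENGTH = {
    "ssam_bmd": {
        "ctproj": {"bone1": 9858.0, "bone2": 7115.0},
        "idxa": {"bone1": 11309.0, "bone2": 7789.0},
        "prodigy": {"bone1": 11007.0, "bone2": 5046.0},
    },
    "ssam_shape": {
        "ctproj": {"bone1": 12776.0, "bone2": 7885.0},
        "idxa": {"bone1": 9301.0, "bone2": 8525.0},
        "prodigy": {"bone1": 10983.0, "bone2": 7445.0},
    },
    "ssam_shape_bmd": {
        "ctproj": {"bone1": 13106.0, "bone2": 9777.0},
        "idxa": {"bone1": 13009.0, "bone2": 9203.0},
        "prodigy": {"bone1": 14820.0, "bone2": 8859.0},
    },
    "ct_based": {
        "ct": {"bone1": 13184.0, "bone2": 7947.0},
    },
}


def paired_strengths(variant: str):
    """(predicted, experimental) arrays for a model variant, pooled over
    reference images, in a stable order."""
    table = PREDICTED_STRENGTH[variant]
    pred, exp = [], []
    for image in sorted(table):
        for bone in sorted(table[image]):
            pred.append(table[image][bone])
            exp.append(EXPERIMENTAL_STRENGTH[bone])
    return np.array(pred), np.array(exp)
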