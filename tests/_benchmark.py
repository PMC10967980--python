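"""Published liver-segmentation benchmark scores used as reference inputs.

Per-case scores of MedSAM liver segmentation on ten LiTS17 CT cases under
three preprocessing variants, as printed in the source benchmark table at
4 decimals, column order (iou, dice, accuracy, precision, recall,
sensitivity, f1, specificity).  ``PRINTED_MEANS`` are the mean rows as
printed; ``PUBLISHED_DELTAS`` are the deltas the benchmark reports between
variant means (computed there from the rounded mean rows, with
inconsistent signs on some entries — compared by magnitude).
"""

PROPOSED_CASES = [
    [0.9635, 0.9814, 0.9970, 0.9948, 0.9683, 0.9683, 0.9814, 0.9996],
    [0.9164, 0.9564, 0.9902, 0.9978, 0.9182, 0.9182, 0.9564, 0.9997],
    [0.7682, 0.8689, 0.9988, 0.8284, 0.9135, 0.9135, 0.8689, 0.9992],
    [0.7752, 0.8734, 0.9923, 0.8915, 0.8559, 0.8559, 0.8734, 0.9967],
    [0.9009, 0.9479, 0.9854, 0.9207, 0.9766, 0.9766, 0.9479, 0.9867],
    [0.8816, 0.9371, 0.9846, 0.9137, 0.9616, 0.9616, 0.9371, 0.9878],
    [0.9367, 0.9673, 0.9920, 0.9894, 0.9462, 0.9462, 0.9673, 0.9986],
    [0.9428, 0.9706, 0.9908, 0.9926, 0.9495, 0.9495, 0.9706, 0.9987],
    [0.9577, 0.9784, 0.9976, 0.9894, 0.9676, 0.9676, 0.9784, 0.9994],
    [0.9594, 0.9793, 0.9933, 0.9804, 0.9782, 0.9782, 0.9793, 0.9962],
]

NORMALIZATION_CASES = [
    [0.9576, 0.9784, 0.9965, 0.9860, 0.9709, 0.9709, 0.9784, 0.9988],
    [0.8668, 0.9286, 0.9828, 0.9053, 0.9532, 0.9532, 0.9286, 0.9867],
    [0.6667, 0.8000, 0.9979, 0.6732, 0.9856, 0.9856, 0.8000, 0.9980],
    [0.5641, 0.7213, 0.9767, 0.5744, 0.9693, 0.9693, 0.7213, 0.9769],
    [0.7928, 0.8844, 0.9661, 0.8265, 0.9511, 0.9511, 0.8844, 0.9685],
    [0.8652, 0.9278, 0.9816, 0.8703, 0.9933, 0.9933, 0.9278, 0.9800],
    [0.8661, 0.9283, 0.9821, 0.9309, 0.9256, 0.9256, 0.9283, 0.9902],
    [0.9315, 0.9646, 0.9885, 0.9474, 0.9824, 0.9824, 0.9646, 0.9896],
    [0.7801, 0.8765, 0.9854, 0.8307, 0.9276, 0.9276, 0.8765, 0.9888],
    [0.9010, 0.9479, 0.9826, 0.9217, 0.9758, 0.9758, 0.9479, 0.9840],
]

WINDOW_CASES = [
    [0.9605, 0.9798, 0.9968, 0.9946, 0.9655, 0.9655, 0.9798, 0.9995],
    [0.8886, 0.9410, 0.9869, 0.9964, 0.8914, 0.8914, 0.9410, 0.9996],
    [0.7224, 0.8389, 0.9986, 0.8454, 0.8324, 0.8324, 0.8389, 0.9994],
    [0.5290, 0.6919, 0.9725, 0.5314, 0.9914, 0.9914, 0.6919, 0.9719],
    [0.8988, 0.9467, 0.9855, 0.9506, 0.9429, 0.9429, 0.9467, 0.9923],
    [0.8887, 0.9411, 0.9857, 0.9246, 0.9581, 0.9581, 0.9411, 0.9895],
    [0.9352, 0.9665, 0.9918, 0.9902, 0.9440, 0.9440, 0.9665, 0.9987],
    [0.9347, 0.9662, 0.9891, 0.9515, 0.9814, 0.9814, 0.9662, 0.9905],
    [0.9526, 0.9757, 0.9973, 0.9939, 0.9582, 0.9582, 0.9757, 0.9997],
    [0.9463, 0.9724, 0.9910, 0.9657, 0.9792, 0.9792, 0.9724, 0.9933],
]

# Mean rows as printed.  The proposed-block dice/f1 and specificity cells
# print 0.9460 / 0.9962 although the per-case values average to
# 0.94607 -> 0.9461 and 0.99626 -> 0.9963 (a rounding slip in the source);
# aggregation tests assert the arithmetic, delta tests use the printed rows.
PRINTED_MEANS = {
    "proposed": [0.9002, 0.9460, 0.9922, 0.9499, 0.9436, 0.9436, 0.9460, 0.9962],
    "normalization": [0.8192, 0.8958, 0.9840, 0.8466, 0.9635, 0.9635, 0.8958, 0.9862],
    "window": [0.8657, 0.9220, 0.9895, 0.9144, 0.9445, 0.9445, 0.9220, 0.9934],
}

# Cells where the printed mean row disagrees with its own per-case values
# by one unit in the last decimal: metric -> arithmetically correct value.
PROPOSED_MEAN_SLIPS = {"dice": 0.9461, "f1": 0.9461, "specificity": 0.9963}

# Published deltas between variant means, keyed (worse, better); magnitudes.
PUBLISHED_DELTAS = {
    ("normalization", "proposed"): [0.0810, 0.0502, 0.0082, 0.1033, 0.0199, 0.0199, 0.0502, 0.0100],
    ("window", "proposed"): [0.0345, 0.0240, 0.0027, 0.0355, 0.0009, 0.0009, 0.0240, 0.0028],
}

# Which of those published deltas are positive (the nominally worse variant
# actually scores higher: recall/sensitivity favor normalization and window).
DELTA_WORSE_WINS = {
    ("normalization", "proposed"): {"recall", "sensitivity"},
    ("window", "proposed"): {"recall", "sensitivity"},
}
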