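"""Worked-example confusion matrices for the column error-rate convention.

Six published 5x5 confusion matrices from a smart-shoe gait benchmark
(the best- and worst-classified participants of an 18-subject study) are
shipped as plain data.  They serve as fixed inputs for validating
:func:`shoegait.classify.column_error_rates`: rows are true classes,
columns predicted classes, in the order (normal, unstable left, unstable
right, toe-out, toe-in).
"""

from __future__ import annotations

import numpy as np

from .classify import ConfusionMatrix

_RAW: dict[int, list[list[int]]] = {
    3: [[132, 35, 11, 0, 0],
        [37, 21, 0, 0, 2],
        [19, 0, 37, 0, 0],
        [17, 0, 0, 38, 0],
        [0, 3, 0, 0, 50]],
    5: [[142, 1, 3, 0, 1],
        [1, 48, 0, 1, 0],
        [0, 1, 55, 1, 1],
        [11, 3, 0, 37, 0],
        [1, 2, 3, 0, 44]],
    8: [[123, 5, 2, 3, 10],
        [23, 23, 0, 1, 0],
        [1, 6, 42, 1, 0],
        [1, 3, 0, 46, 0],
        [8, 0, 0, 1, 40]],
    13: [[140, 1, 0, 1, 0],
         [0, 54, 0, 0, 0],
         [0, 0, 52, 0, 0],
         [0, 0, 0, 52, 0],
         [1, 0, 0, 0, 56]],
    15: [[111, 9, 0, 9, 0],
         [0, 13, 30, 0, 6],
         [0, 0, 49, 0, 0],
         [15, 3, 0, 22, 0],
         [1, 2, 0, 0, 14]],
    18: [[130, 0, 0, 0, 0],
         [1, 53, 0, 0, 0],
         [2, 1, 54, 0, 0],
         [0, 0, 0, 52, 0],
         [0, 0, 0, 0, 56]],
}


def worked_example_matrices() -> dict[int, ConfusionMatrix]:
    """Participant id -> published confusion matrix."""
    return {pid: ConfusionMatrix(np.array(m)) for pid, m in _RAW.items()}
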