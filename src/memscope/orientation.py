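"""Capsid orientation tracking via a body-fixed residue pair vector.

The unit vector from one chosen residue's backbone bead to another's
(a chord roughly parallel to the capsid diameter) is compared to its
first-frame direction; the angle is ``arccos`` of the clamped dot
product, in degrees.  Rotations about the axis parallel to the
reference vector are invisible to this single-vector measure.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .frame import BeadFrame, BB_BEAD_NAMES

__all__ = ["orientation_angles"]


def _bb_position(frame: BeadFrame, resid: int) -> np.ndarray:
    idx = np.flatnonzero((frame.resids == resid)
                         & np.isin(frame.names, BB_BEAD_NAMES))
    if not len(idx):
        raise ValueError(f"frame {frame.index}: residue {resid} has no "
                         "BB bead")
    return frame.coordinates[idx[0]]


def orientation_angles(frames: Iterable[BeadFrame], residue_a: int,
                       residue_b: int) -> pd.DataFrame:
    """Angle (degrees, in [0, 180]) between the residue-pair vector in
    each frame and in the first frame.

    Vectors are normalized before the dot product, which is clamped to
    [-1, 1] so round-off cannot leave the arccos domain.  A zero-length
    vector in any frame raises.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    v0 = None
    rows = []
    for fr in frames:
        v = _bb_position(fr, residue_b) - _bb_position(fr, residue_a)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"frame {fr.index}: residues {residue_a} and "
                             f"{residue_b} coincide (zero-length vector)")
        v = v / norm
        if v0 is None:
            v0 = v
        angle = float(np.degrees(np.arccos(np.clip(np.dot(v, v0), -1.0, 1.0))))
        rows.append({"frame": fr.index, "time_ps": fr.time,
                     "angle_deg": angle})
    return pd.DataFrame(rows)
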