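"""Trial-length standardization by linear interpolation.

Variable-length trials (reading is self-paced) are mapped onto a common
sample count — 1300 for study-conformant data, the maximum observed
trial length — by evaluating each channel's piecewise-linear interpolant
on a uniform grid with pinned endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .labeling import LabeledTrial


@dataclass(frozen=True)
class StandardizedTrial:
    """A labeled trial resampled to a fixed length."""

    trial_id: str
    participant_id: str
    chromophore: str
    data: np.ndarray  # (n_channels, target_len)
    label: str
    strategy: str


def interpolate_to_length(x: Sequence[float], target_len: int) -> np.ndarray:
    """Linearly map a length-m sequence onto target_len uniform positions.

    Index space [0, m-1] maps uniformly onto [0, target_len-1]; the first
    and last samples are preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    m = x.shape[-1]
    if m < 2:
        raise ValueError(f"need at least 2 samples to interpolate, got {m}")
    if target_len < 2:
        raise ValueError(f"target_len must be >= 2, got {target_len}")
    if target_len == m:
        return x.copy()
    pos = np.linspace(0.0, m - 1, target_len)
    out = np.interp(pos, np.arange(m), x) if x.ndim == 1 else np.vstack(
        [np.interp(pos, np.arange(m), row) for row in x]
    )
    # pin endpoints against floating-point grid error
    if x.ndim == 1:
        out[0], out[-1] = x[0], x[-1]
    else:
        out[:, 0], out[:, -1] = x[:, 0], x[:, -1]
    return out


def standardize_set(
    labeled: Sequence[LabeledTrial], target_len: Optional[int] = None
) -> list[StandardizedTrial]:
    """Interpolate every channel of every trial to one common length.

    ``target_len`` defaults to the maximum sample count over the set
    (the study rule; 1300 for the study's recordings) and can be
    overridden for scaled-down runs.
    """
    if not labeled:
        return []
    if target_len is None:
        target_len = max(lt.trial.n_samples for lt in labeled)
    out = []
    for lt in labeled:
        t = lt.trial
        out.append(
            StandardizedTrial(
                trial_id=t.trial_id,
                participant_id=t.participant_id,
                chromophore=t.chromophore,
                data=interpolate_to_length(t.data, target_len),
                label=lt.label,
                strategy=lt.strategy,
            )
        )
    return out
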