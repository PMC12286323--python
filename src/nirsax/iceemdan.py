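"""EMD and ICEEMDAN decomposition into intrinsic mode functions.

ICEEMDAN (improved complete ensemble EMD with adaptive noise) estimates
each residue as the average local mean of noise-perturbed copies of the
previous residue, where the perturbation at stage j is the j-th EMD mode
of a white-noise realization, scaled to a target signal-to-noise ratio:

    r_1   = <M(x + b0 * E_1(w_i))>_i          IMF_1 = x - r_1
    r_j   = <M(r_{j-1} + b_{j-1} * E_j(w_i))>_i   IMF_j = r_{j-1} - r_j

with b0 = eps0 * std(x) / std(E_1(w_i)) per realization and
b_j = eps0 * std(r_j) for j >= 1.  M is the envelope local-mean operator
and E_k the k-th EMD mode operator.  The same L seeded noise sequences
are reused across stages, so the telescoping identity
x = sum(IMF_j) + residue holds to floating-point precision.

Defaults eps0=0.2, L=100 are the standard biomedical-signal settings.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _emd_core as _core

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmdConfig:
    """Sifting internals: Cauchy stop threshold, iteration cap, and the
    (fixed) envelope conventions — cubic-spline envelopes through local
    extrema with mirrored boundary extrema."""

    max_siftings: int = 100
    sift_tolerance: float = 0.2
    boundary: str = "mirror"
    envelope: str = "cubic_spline"

    def __post_init__(self) -> None:
        if self.sift_tolerance <= 0:
            raise ValueError("sift_tolerance must be positive")
        if self.max_siftings < 1:
            raise ValueError("max_siftings must be >= 1")
        if self.boundary != "mirror" or self.envelope != "cubic_spline":
            raise ValueError("only mirror boundaries with cubic splines supported")


@dataclass(frozen=True)
class IceemdanConfig:
    epsilon0: float = 0.2
    n_realizations: int = 100
    max_imfs: int = 8
    seed: int = 0
    emd: EmdConfig = field(default_factory=EmdConfig)

    def __post_init__(self) -> None:
        if self.epsilon0 <= 0:
            raise ValueError("epsilon0 must be positive")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the final residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_len: int

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out

    def to_matrix(self) -> np.ndarray:
        """Rows IMF_1..IMF_J then the residue (for CSV dumps)."""
        return np.vstack(self.imfs + [self.residue]) if self.imfs else self.residue[None, :]


def derive_seed(global_seed: int, *keys) -> int:
    """Stable per-(trial, channel, ...) sub-seed below 2**31.

    Counter-based: hashing the key tuple keeps parallel and serial
    executions, and re-ordered batches, in agreement.
    """
    tag = "/".join(str(k) for k in keys)
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(tag.encode())) % (2**31)


def local_mean(x: Sequence[float]) -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes of ``x``.

    Signals without an interior maximum and minimum are their own trend
    and are returned unchanged.
    """
    x = np.ascontiguousarray(x, dtype=float)
    m, _, _ = _core.envelope_mean(x)
    return m


def emd(
    x: Sequence[float], cfg: Optional[EmdConfig] = None, k_max: int = 8
) -> IMFSet:
    """Classical EMD of ``x`` into up to ``k_max`` modes plus residue."""
    cfg = cfg or EmdConfig()
    x = np.ascontiguousarray(x, dtype=float)
    modes, k, residue = _core.emd_all(
        x, cfg.sift_tolerance, cfg.max_siftings, int(k_max)
    )
    return IMFSet([modes[j].copy() for j in range(k)], residue, x.shape[0])


def _n_extrema(x: np.ndarray) -> int:
    imax, imin = _core.local_extrema(x)
    return imax.shape[0] + imin.shape[0]


def iceemdan(
    x: Sequence[float],
    cfg: Optional[IceemdanConfig] = None,
    seed: Optional[int] = None,
) -> IMFSet:
    """ICEEMDAN decomposition of ``x``.

    ``seed`` overrides ``cfg.seed``; identical (x, cfg, seed) give a
    bit-identical decomposition.
    """
    cfg = cfg or IceemdanConfig()
    x = np.ascontiguousarray(x, dtype=float)
    n = x.shape[0]
    if n < 4 or _n_extrema(x) < 3:
        return IMFSet([], x.copy(), n)

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L = cfg.n_realizations
    tol, max_sift = cfg.emd.sift_tolerance, cfg.emd.max_siftings

    # One noise bank, decomposed once; stage j perturbs with mode E_j(w_i).
    noise_modes: list[np.ndarray] = []
    noise_counts: list[int] = []
    for _ in range(L):
        w = rng.standard_normal(n)
        modes, k, _ = _core.emd_all(w, tol, max_sift, cfg.max_imfs)
        noise_modes.append(modes)
        noise_counts.append(k)

    sx = float(np.std(x))
    imfs: list[np.ndarray] = []
    prev = x
    for j in range(1, cfg.max_imfs + 1):
        acc = np.zeros(n)
        beta_j = None if j == 1 else cfg.epsilon0 * float(np.std(prev))
        for i in range(L):
            if j == 1:
                # b0 uses the realization's own first-mode std (Eq form)
                e1 = noise_modes[i][0] if noise_counts[i] >= 1 else None
                se1 = float(np.std(e1)) if e1 is not None else 0.0
                if se1 > 0:
                    pert = prev + (cfg.epsilon0 * sx / se1) * e1
                else:
                    pert = prev
            elif noise_counts[i] >= j:
                pert = prev + beta_j * noise_modes[i][j - 1]
            else:
                pert = prev
            m, _, _ = _core.envelope_mean(np.ascontiguousarray(pert))
            acc += m
        r = acc / L
        imfs.append(prev - r)
        prev = r
        if _n_extrema(prev) < 3:
            break
    return IMFSet(imfs, prev, n)


def select_imf(s: IMFSet, j: int) -> np.ndarray:
    """Return IMF_j (1-based).

    Requesting an index beyond the extracted count returns an all-zero
    sequence and logs a warning, so batch runs over heterogeneous
    decompositions keep going.
    """
    if j < 1:
        raise ValueError(f"IMF index must be >= 1, got {j}")
    if j <= len(s.imfs):
        return s.imfs[j - 1]
    logger.warning(
        "requested IMF_%d but only %d modes extracted; returning zeros", j, len(s.imfs)
    )
    return np.zeros(s.source_len)
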