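"""Symbolic aggregate approximation (SAX) and triple window shifting.

SAX turns a real sequence into a short word over a small alphabet:
z-normalize, block-average down to w segments (piecewise aggregate
approximation), then bin each segment mean into one of ``a``
equiprobable intervals of the standard Gaussian.  Symbols map to
numerals A=1, B=2, ..., so downstream statistics operate on integer
sequences.  The triple-window-shifting step augments each symbolic
trial into three overlapping windows.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class SaxConfig:
    """Word length (n_segments), alphabet size, and the z-norm guard.

    The study grid uses n_segments in {100, 650, 1300} and alphabet
    sizes 5-8.
    """

    n_segments: int
    alphabet_size: int = 8
    znorm_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not (2 <= self.alphabet_size <= 26):
            raise ValueError("alphabet_size must be in [2, 26]")
        if self.znorm_epsilon <= 0:
            raise ValueError("znorm_epsilon must be positive")


@dataclass(frozen=True)
class SymbolicSeries:
    """A SAX word with its 1-based numeric encoding."""

    symbols: str
    numeric: np.ndarray  # int64, values in 1..alphabet_size
    config: SaxConfig

    def __len__(self) -> int:
        return len(self.numeric)


def znorm(y: Sequence[float], epsilon: float = 1e-12) -> np.ndarray:
    """(y - mean) / population std; all zeros for (near-)constant input."""
    y = np.asarray(y, dtype=float)
    mu = y.mean()
    sigma = y.std()  # population (1/n) convention, classical SAX
    if sigma < epsilon:
        return np.zeros_like(y)
    return (y - mu) / sigma


def paa(y: Sequence[float], w: int) -> np.ndarray:
    """Piecewise aggregate approximation to ``w`` segment means.

    When w divides n each output is a plain block mean; otherwise each
    sample's weight is split proportionally across the segments its
    index interval overlaps (fractional-boundary PAA).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if w > n:
        raise ValueError(f"n_segments={w} exceeds sequence length {n}")
    if w == n:
        return y.copy()
    if n % w == 0:
        return y.reshape(w, n // w).mean(axis=1)
    # F(t): integral of the sample step function on [0, n], piecewise linear
    cs = np.concatenate(([0.0], np.cumsum(y)))

    def F(t: np.ndarray) -> np.ndarray:
        i = np.clip(np.floor(t).astype(int), 0, n - 1)
        return cs[i] + (t - i) * y[i]

    edges = np.linspace(0.0, float(n), w + 1)
    seg = n / w
    return (F(edges[1:]) - F(edges[:-1])) / seg


def breakpoints(a: int) -> np.ndarray:
    """Gaussian equiprobable breakpoints b_i = Phi^-1(i/a), i = 1..a-1.

    Built antisymmetric by construction (b_i = -b_{a-i} exactly).
    """
    if a < 2:
        raise ValueError("alphabet size must be >= 2")
    b = np.empty(a - 1)
    for i in range(1, a):
        if 2 * i < a:
            b[i - 1] = norm.ppf(i / a)
        elif 2 * i == a:
            b[i - 1] = 0.0
        else:
            b[i - 1] = -b[a - i - 1]
    return b


def symbolize(y: Sequence[float], cfg: SaxConfig) -> SymbolicSeries:
    """Full SAX: znorm -> PAA -> equiprobable binning.

    A segment mean lying exactly on a breakpoint takes the lower symbol
    (right-closed bins), a measure-zero but deterministic convention.
    """
    z = znorm(y, cfg.znorm_epsilon)
    vals = paa(z, cfg.n_segments)
    bp = breakpoints(cfg.alphabet_size)
    idx = np.searchsorted(bp, vals, side="left")  # value == bp -> lower bin
    numeric = (idx + 1).astype(np.int64)
    symbols = "".join(string.ascii_uppercase[i] for i in idx)
    return SymbolicSeries(symbols, numeric, cfg)


def triple_window_shift(
    s: SymbolicSeries | Sequence[int],
    mode: Literal["augment", "concat"] = "augment",
    stride: Optional[int] = None,
) -> list[np.ndarray]:
    """Three equal windows at offsets 0, stride, 2*stride.

    mode="augment" returns the three windows as separate instances (each
    inheriting the trial's label downstream); mode="concat" returns one
    concatenated sequence.  Default stride is 10% of the word length,
    giving 80%-length windows.
    """
    numeric = s.numeric if isinstance(s, SymbolicSeries) else np.asarray(s)
    n = numeric.shape[0]
    if stride is None:
        stride = n // 10
    if stride < 0:
        raise ValueError("stride must be >= 0")
    win = n - 2 * stride
    if win < 1:
        raise ValueError(f"stride {stride} too large for word length {n}")
    windows = [numeric[off : off + win].copy() for off in (0, stride, 2 * stride)]
    if mode == "augment":
        return windows
    if mode == "concat":
        return [np.concatenate(windows)]
    raise ValueError(f"unknown mode {mode!r}")


def export_words(words: dict[str, SymbolicSeries]) -> str:
    """Plain-text dump: one ``trial_id<TAB>word`` line per trial."""
    return "\n".join(f"{tid}\t{s.symbols}" for tid, s in words.items()) + "\n"
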