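"""Synthetic labeled fNIRS trial sets with controllable class separation.

Each trial is built from components a temporal-lobe fNIRS recording of a
self-paced reading episode would plausibly contain:

* a hemodynamic response: the neural drive is a boxcar spanning the
  reading interval [S1, S2) plus discrete event transients at jittered
  sentence boundaries (integration effort peaks at the end of each
  sentence during self-paced reading), convolved with a canonical
  difference-of-gammas kernel (peak ~6 s, undershoot ~16 s).  Event
  times are shared across channels; event gains are channel-specific;
* physiological oscillations (Mayer waves ~0.1 Hz, cardiac ~1 Hz) with
  random phases;
* a random-walk drift and white measurement noise.

The class signal lives in trial-level response amplitude: on the
informative channels, "understood" trials scale the response by
(1 + effect_size).  OxyHb carries the positive response, DeoxyHb an
inverted, smaller one; TotalHb is their sum.  Self-assessment scores and
multiple-choice correctness are drawn consistently with the true class
except with probability ``sas_noise`` each, so labeling strategies can
disagree the way real participants do.

The generator is deterministic under its seed, with independent
per-participant substreams, and the same seed produces consistent
OxyHb/DeoxyHb pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .trial_io import Trial, TrialSet

STUDY_FS = 10.1725
STUDY_MAX_LEN = 1300


@dataclass(frozen=True)
class NoiseConfig:
    """Amplitudes of the non-response components (signal units)."""

    drift_amplitude: float = 0.35
    oscillations: tuple[tuple[float, float], ...] = ((0.1, 0.2), (1.0, 0.25))
    white_std: float = 0.4


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int = 15
    trials_per_participant: int = 30
    n_channels: int = 20
    fs: float = STUDY_FS
    length_range: tuple[int, int] = (400, STUDY_MAX_LEN)
    effect_size: float = 1.0
    informative_channels: Optional[tuple[int, ...]] = None
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    response_amplitude: float = 1.0
    #: sentence count range per text (events per trial), inclusive
    events_range: tuple[int, int] = (4, 8)
    #: impulse weight of one sentence-boundary event relative to the
    #: sustained boxcar drive
    event_gain: float = 2.0
    p_understood: float = 0.55
    sas_noise: float = 0.15
    blank_prob: float = 0.0
    chromophore: str = "OxyHb"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.length_range[0] < 4 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        info = self.informative_channels
        if info is not None and any(
            not (0 <= c < self.n_channels) for c in info
        ):
            raise ValueError("informative_channels outside channel range")

    @property
    def informative(self) -> tuple[int, ...]:
        if self.informative_channels is not None:
            return self.informative_channels
        # every fifth channel by default
        return tuple(range(0, self.n_channels, 5))


def hrf_kernel(fs: float, duration: float = 32.0) -> np.ndarray:
    """Canonical difference-of-gammas hemodynamic response, peak-normalized."""
    t = np.arange(0.0, duration, 1.0 / fs)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.max()


def _episode(
    rng: np.random.Generator, cfg: SynthConfig, understood: bool, kernel: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """One reading episode: (oxy matrix, deoxy matrix, s1, s2)."""
    n = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    pad = max(1, int(round(cfg.fs)))
    pad = min(pad, (n - 2) // 2)
    s1, s2 = pad, n - pad
    box = np.zeros(n)
    box[s1:s2] = 1.0
    peak = np.convolve(box, kernel)[:n].max()
    # sentence-boundary events: shared times, channel-specific gains
    lo, hi = cfg.events_range
    n_ev = int(rng.integers(lo, hi + 1))
    last = max(s1 + 1, s2 - int(6 * cfg.fs))
    times = np.linspace(s1, last, n_ev + 1)[1:]
    times = (times + rng.uniform(-0.08, 0.08, size=n_ev) * n).clip(s1, s2 - 1)
    times = times.astype(int)

    t = np.arange(n) / cfg.fs
    oxy = np.empty((cfg.n_channels, n))
    deoxy = np.empty((cfg.n_channels, n))
    info = set(cfg.informative)
    nz = cfg.noise
    for c in range(cfg.n_channels):
        amp = cfg.response_amplitude * (1.0 + rng.normal(0.0, 0.1))
        if understood and c in info:
            amp *= 1.0 + cfg.effect_size
        events = np.zeros(n)
        for tt in times:
            events[tt] += cfg.event_gain * (1.0 + abs(rng.normal(0.0, 0.3)))
        resp = np.convolve(box + events, kernel)[:n]
        if peak > 0:
            resp = resp / peak
        for mat, sign, scale in ((oxy, 1.0, 1.0), (deoxy, -1.0, 0.4)):
            osc = np.zeros(n)
            for freq, a in nz.oscillations:
                osc += a * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            drift = np.cumsum(rng.standard_normal(n))
            drift *= nz.drift_amplitude / max(np.abs(drift).max(), 1e-12)
            white = nz.white_std * rng.standard_normal(n)
            mat[c] = sign * scale * amp * resp + osc + drift + white
    return oxy, deoxy, s1, s2


def generate(cfg: SynthConfig) -> TrialSet:
    """Generate a labeled synthetic trial set for ``cfg.chromophore``.

    Calling again with the same seed but another chromophore yields the
    paired view of the same episodes (identical metadata and markers).
    """
    kernel = hrf_kernel(cfg.fs)
    trials: list[Trial] = []
    for p in range(cfg.n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, p]))
        pid = f"p{p + 1:02d}"
        for i in range(cfg.trials_per_participant):
            understood = rng.random() < cfg.p_understood
            oxy, deoxy, s1, s2 = _episode(rng, cfg, understood, kernel)
            if rng.random() < cfg.sas_noise:
                sas = int(rng.integers(1, 11))
            elif understood:
                sas = int(rng.integers(8, 11))
            else:
                sas = int(rng.integers(1, 5))
            mc = understood if rng.random() >= cfg.sas_noise else not understood
            mc_correct: Optional[bool] = mc
            sas_out: Optional[int] = sas
            if cfg.blank_prob > 0 and rng.random() < cfg.blank_prob:
                mc_correct = None
            if cfg.chromophore == "OxyHb":
                data = oxy
            elif cfg.chromophore == "DeoxyHb":
                data = deoxy
            elif cfg.chromophore == "TotalHb":
                data = oxy + deoxy
            else:
                raise ValueError(f"unknown chromophore {cfg.chromophore!r}")
            trials.append(
                Trial(
                    trial_id=f"{pid}t{i + 1:02d}",
                    participant_id=pid,
                    chromophore=cfg.chromophore,
                    data=data,
                    fs=cfg.fs,
                    s1=s1,
                    s2=s2,
                    sas=sas_out,
                    mc_correct=mc_correct,
                )
            )
    return TrialSet(trials, [f"ch{i + 1:02d}" for i in range(cfg.n_channels)])


def study_shaped(seed: int, chromophore: str = "DeoxyHb", **overrides) -> TrialSet:
    """Convenience preset matching the study's shape.

    15 participants x 30 trials = 450 trials, 20 channels at
    10.1725 Hz, trial lengths up to 1300 samples.
    """
    cfg = SynthConfig(seed=seed, chromophore=chromophore, **overrides)
    return generate(cfg)
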