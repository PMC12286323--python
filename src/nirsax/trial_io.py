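"""fNIRS trial containers and their on-disk CSV format.

A trial is one reading episode: a channels x samples matrix of
concentration changes plus metadata (participant, chromophore,
self-assessment score, multiple-choice correctness, the S1/S2 text
onset/offset markers, and the sampling rate).  A trial set is written as
one header-less CSV matrix per trial (rows = channels) next to a single
``metadata.csv`` keyed by trial id; ``channels.csv`` optionally stores
channel labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

CHROMOPHORES = ("OxyHb", "DeoxyHb", "TotalHb")

METADATA_COLUMNS = [
    "trial_id",
    "participant_id",
    "chromophore",
    "sas",
    "mc_correct",
    "s1",
    "s2",
    "fs",
]


class TrialFormatError(ValueError):
    """Malformed matrix, metadata, or a violated trial invariant."""


@dataclass
class Trial:
    """One reading episode: signal matrix plus metadata.

    ``sas`` (self-assessment score, 1-10) and ``mc_correct``
    (multiple-choice correctness) may be absent (None): participants
    could leave answers blank.
    """

    trial_id: str
    participant_id: str
    chromophore: str
    data: np.ndarray  # (n_channels, n_samples), float64
    fs: float
    s1: int
    s2: int
    sas: Optional[int] = None
    mc_correct: Optional[bool] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise TrialFormatError(
                f"trial {self.trial_id}: data must be a 2-D channels x samples matrix"
            )
        if not np.all(np.isfinite(self.data)):
            raise TrialFormatError(f"trial {self.trial_id}: non-finite values in data")
        if self.chromophore not in CHROMOPHORES:
            raise TrialFormatError(
                f"trial {self.trial_id}: unknown chromophore {self.chromophore!r}"
            )
        if self.sas is not None and not (1 <= int(self.sas) <= 10):
            raise TrialFormatError(
                f"trial {self.trial_id}: sas={self.sas} outside 1..10"
            )
        n = self.data.shape[1]
        if not (0 <= self.s1 < self.s2 < n):
            raise TrialFormatError(
                f"trial {self.trial_id}: markers s1={self.s1}, s2={self.s2} "
                f"must satisfy 0 <= s1 < s2 < n_samples={n}"
            )
        if not (self.fs > 0):
            raise TrialFormatError(f"trial {self.trial_id}: fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """An ordered collection of trials sharing channels and sampling rate."""

    trials: list[Trial] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trials and not self.channel_names:
            self.channel_names = [
                f"ch{i + 1:02d}" for i in range(self.trials[0].n_channels)
            ]
        seen: set[str] = set()
        for t in self.trials:
            if t.trial_id in seen:
                raise TrialFormatError(f"duplicate trial_id {t.trial_id!r}")
            seen.add(t.trial_id)
            if t.n_channels != len(self.channel_names):
                raise TrialFormatError(
                    f"trial {t.trial_id}: {t.n_channels} channels, "
                    f"set has {len(self.channel_names)}"
                )
            if not math.isclose(t.fs, self.trials[0].fs):
                raise TrialFormatError(
                    f"trial {t.trial_id}: fs differs from the rest of the set"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def subset(self, trial_ids: Iterable[str]) -> "TrialSet":
        wanted = set(trial_ids)
        return TrialSet(
            [t for t in self.trials if t.trial_id in wanted],
            list(self.channel_names),
        )

    def by_chromophore(self, chromophore: str) -> "TrialSet":
        return TrialSet(
            [t for t in self.trials if t.chromophore == chromophore],
            list(self.channel_names),
        )


def _parse_optional_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return int(v)


def _parse_optional_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "1.0"):
        return True
    if s in ("false", "0", "0.0"):
        return False
    raise TrialFormatError(f"unparseable mc_correct value {v!r}")


def read_trials(path: str | Path) -> TrialSet:
    """Load a trial set from a directory written by :func:`write_trials`."""
    path = Path(path)
    meta_path = path / "metadata.csv"
    if not meta_path.exists():
        raise TrialFormatError(f"no metadata.csv in {path}")
    meta = pd.read_csv(meta_path, dtype={"trial_id": str, "participant_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TrialFormatError(f"metadata.csv lacks columns {missing}")

    channel_names: list[str] = []
    ch_path = path / "channels.csv"
    if ch_path.exists():
        channel_names = [
            line.strip() for line in ch_path.read_text().splitlines() if line.strip()
        ]

    matrix_files = {p.stem: p for p in path.glob("*.csv")}
    for reserved in ("metadata", "channels"):
        matrix_files.pop(reserved, None)

    trials: list[Trial] = []
    for row in meta.itertuples(index=False):
        tid = str(row.trial_id)
        mpath = matrix_files.pop(tid, None)
        if mpath is None:
            raise TrialFormatError(f"metadata row {tid!r} has no matrix file")
        try:
            data = np.loadtxt(mpath, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise TrialFormatError(f"trial {tid}: malformed matrix ({exc})") from exc
        trials.append(
            Trial(
                trial_id=tid,
                participant_id=str(row.participant_id),
                chromophore=str(row.chromophore),
                data=data,
                fs=float(row.fs),
                s1=int(row.s1),
                s2=int(row.s2),
                sas=_parse_optional_int(row.sas),
                mc_correct=_parse_optional_bool(row.mc_correct),
            )
        )
    if matrix_files:
        extras = sorted(matrix_files)
        raise TrialFormatError(f"matrix files without metadata rows: {extras}")
    return TrialSet(trials, channel_names)


def write_trials(ts: TrialSet, path: str | Path) -> None:
    """Write a trial set to ``path`` in the layout read_trials expects.

    Matrix values are serialized with repr precision so a round trip is
    numerically exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in ts:
        np.savetxt(path / f"{t.trial_id}.csv", t.data, delimiter=",", fmt="%.17g")
        rows.append(
            {
                "trial_id": t.trial_id,
                "participant_id": t.participant_id,
                "chromophore": t.chromophore,
                "sas": "" if t.sas is None else t.sas,
                "mc_correct": "" if t.mc_correct is None else t.mc_correct,
                "s1": t.s1,
                "s2": t.s2,
                "fs": repr(t.fs),
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path / "metadata.csv", index=False
    )
    if ts.channel_names:
        (path / "channels.csv").write_text("\n".join(ts.channel_names) + "\n")


def total_hb(oxy: Trial, deoxy: Trial) -> Trial:
    """TotalHb trial as the elementwise sum OxyHb + DeoxyHb.

    Both trials must describe the same episode (id, shape, fs, markers).
    The returned trial keeps the shared metadata and gets
    chromophore="TotalHb".
    """
    if oxy.trial_id != deoxy.trial_id:
        raise TrialFormatError(
            f"total_hb: trial ids {oxy.trial_id!r} vs {deoxy.trial_id!r} differ"
        )
    if oxy.data.shape != deoxy.data.shape:
        raise TrialFormatError("total_hb: shape mismatch")
    if (oxy.s1, oxy.s2) != (deoxy.s1, deoxy.s2) or not math.isclose(oxy.fs, deoxy.fs):
        raise TrialFormatError("total_hb: marker or fs mismatch")
    return replace(
        oxy,
        chromophore="TotalHb",
        data=oxy.data + deoxy.data,
    )
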