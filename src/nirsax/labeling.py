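"""Trial labeling strategies.

Three ways of turning metadata into class labels:

* strategy 1 — by multiple-choice correctness (understood / not_understood);
* strategy 2 — by self-assessment score, three classes
  (1-4 -> class1 "not understood", 5-7 -> class2 "a little understood",
  8-10 -> class3 "understood");
* strategy 3 — double-validated: understood needs SAS >= 8 AND a correct
  answer, not_understood needs SAS <= 4 AND an incorrect answer; every
  other trial (mid SAS, disagreement, missing field) is excluded.

Each function returns the labeled trials plus an exclusion report
(trial_id, reason) so the shrinking trial counts stay auditable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .trial_io import Trial, TrialSet

UNDERSTOOD = "understood"
NOT_UNDERSTOOD = "not_understood"

BlankPolicy = Literal["exclude", "incorrect"]


@dataclass(frozen=True)
class LabeledTrial:
    trial: Trial
    label: str
    strategy: str

    @property
    def trial_id(self) -> str:
        return self.trial.trial_id


@dataclass(frozen=True)
class Exclusion:
    trial_id: str
    reason: str


def write_exclusions(exclusions: list[Exclusion], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "reason"])
        for e in exclusions:
            w.writerow([e.trial_id, e.reason])


def label_strategy1(
    ts: TrialSet, blank_policy: BlankPolicy = "exclude"
) -> tuple[list[LabeledTrial], list[Exclusion]]:
    """Label by multiple-choice correctness.

    Blank answers are excluded by default (participants were told they
    could leave answers blank); ``blank_policy="incorrect"`` instead
    counts them as wrong answers.
    """
    labeled: list[LabeledTrial] = []
    excluded: list[Exclusion] = []
    for t in ts:
        mc = t.mc_correct
        if mc is None:
            if blank_policy == "exclude":
                excluded.append(Exclusion(t.trial_id, "mc_correct missing"))
                continue
            mc = False
        label = UNDERSTOOD if mc else NOT_UNDERSTOOD
        labeled.append(LabeledTrial(t, label, "S1_mc"))
    return labeled, excluded


def label_strategy2(ts: TrialSet) -> tuple[list[LabeledTrial], list[Exclusion]]:
    """Label into three classes by self-assessment score."""
    labeled: list[LabeledTrial] = []
    excluded: list[Exclusion] = []
    for t in ts:
        if t.sas is None:
            excluded.append(Exclusion(t.trial_id, "sas missing"))
            continue
        if t.sas <= 4:
            label = "class1"
        elif t.sas <= 7:
            label = "class2"
        else:
            label = "class3"
        labeled.append(LabeledTrial(t, label, "S2_sas"))
    return labeled, excluded


def label_strategy3(ts: TrialSet) -> tuple[list[LabeledTrial], list[Exclusion]]:
    """Double-validated labels: SAS and answer correctness must agree.

    understood: sas >= 8 and a correct answer; not_understood: sas <= 4
    and an incorrect answer.  Mid-range SAS (5-7), disagreements and
    missing fields are excluded, each with a reason.
    """
    labeled: list[LabeledTrial] = []
    excluded: list[Exclusion] = []
    for t in ts:
        if t.sas is None:
            excluded.append(Exclusion(t.trial_id, "sas missing"))
            continue
        if t.mc_correct is None:
            excluded.append(Exclusion(t.trial_id, "mc_correct missing"))
            continue
        if t.sas >= 8 and t.mc_correct:
            labeled.append(LabeledTrial(t, UNDERSTOOD, "S3_double"))
        elif t.sas <= 4 and not t.mc_correct:
            labeled.append(LabeledTrial(t, NOT_UNDERSTOOD, "S3_double"))
        elif 5 <= t.sas <= 7:
            excluded.append(Exclusion(t.trial_id, "sas in 5..7"))
        else:
            excluded.append(Exclusion(t.trial_id, "sas and mc_correct disagree"))
    return labeled, excluded


def label_trials(
    ts: TrialSet, strategy: int, blank_policy: BlankPolicy = "exclude"
) -> tuple[list[LabeledTrial], list[Exclusion]]:
    if strategy == 1:
        return label_strategy1(ts, blank_policy)
    if strategy == 2:
        return label_strategy2(ts)
    if strategy == 3:
        return label_strategy3(ts)
    raise ValueError(f"unknown labeling strategy {strategy}")
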