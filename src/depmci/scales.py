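"""Instrument scoring and outcome labeling.

Depression: 10-item CES-D short form, each item 0-3, total 0-30; a total of
10 or more marks depressive symptoms.  The scorer sums items as administered;
an optional switch reverse-codes the two positively worded items (indices 5
and 8, 1-based) for surveys that store them unreversed — off by default.

Cognition: episodic memory (immediate + delayed 10-word recall, 0-20) plus
global mental status (temporal orientation 0-5, serial subtraction 0-5,
pentagon copy 0-1), total 0-31.  Mild cognitive impairment (MCI) is labeled
age-normatively: within 5-year age strata starting at 60, a participant is
MCI when the cognition total falls strictly below the stratum mean minus one
sample standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CESD_COLUMNS, COG_COLUMNS, COG_RANGES

__all__ = [
    "CognitionScores",
    "AgeStratum",
    "DEPRESSION_CUTOFF",
    "score_cesd10",
    "classify_depression",
    "score_cognition",
    "assign_age_stratum",
    "label_mci",
    "annotate_cohort",
]

DEPRESSION_CUTOFF = 10
#: 1-based indices of the positively worded CES-D items ("hopeful", "happy").
POSITIVE_ITEMS = (5, 8)


@dataclass(frozen=True)
class CognitionScores:
    imm_recall: int
    del_recall: int
    orientation: int
    calculation: int
    pentagon: int

    @property
    def episodic_memory(self) -> int:
        return self.imm_recall + self.del_recall

    @property
    def mental_status(self) -> int:
        return self.orientation + self.calculation + self.pentagon

    @property
    def total(self) -> int:
        return self.episodic_memory + self.mental_status


@dataclass(frozen=True)
class AgeStratum:
    """Closed 5-year age band [lower, upper]; the top band is open-ended."""

    lower: int
    upper: float  # inclusive; math.inf for the open-ended top stratum

    def __contains__(self, age) -> bool:
        return self.lower <= age <= self.upper


def score_cesd10(items: Sequence[int], reverse_code: bool = False) -> int:
    """Sum the ten CES-D items (0-3 each) into a 0-30 total."""
    items = list(items)
    if len(items) != 10:
        raise ValueError(f"expected 10 items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if v not in (0, 1, 2, 3):
            raise ValueError(f"item {i} value {v!r} outside 0..3")
    if reverse_code:
        items = [3 - v if i in POSITIVE_ITEMS else v for i, v in enumerate(items, 1)]
    return int(sum(items))


def classify_depression(total: int) -> str:
    """'depressed' for totals >= 10, 'normal' below."""
    if not 0 <= total <= 30:
        raise ValueError(f"CES-D total {total} outside 0..30")
    return "depressed" if total >= DEPRESSION_CUTOFF else "normal"


def score_cognition(imm_recall: int, del_recall: int, orientation: int,
                    calculation: int, pentagon: int) -> CognitionScores:
    parts = {
        "imm_recall": imm_recall,
        "del_recall": del_recall,
        "orientation": orientation,
        "calculation": calculation,
        "pentagon": pentagon,
    }
    for name, value in parts.items():
        lo, hi = COG_RANGES[name]
        if not lo <= value <= hi:
            raise ValueError(f"{name} value {value!r} outside {lo}..{hi}")
    return CognitionScores(**{k: int(v) for k, v in parts.items()})


def assign_age_stratum(age, top: int = 85) -> AgeStratum:
    """5-year stratum containing ``age``; ages >= ``top`` share the open top band."""
    if age < 60:
        raise ValueError(f"age {age} below the inclusion age of 60")
    if age >= top:
        return AgeStratum(top, math.inf)
    lower = 60 + 5 * int((age - 60) // 5)
    return AgeStratum(lower, lower + 4)


def label_mci(scores: Iterable[tuple], top: int = 85) -> dict:
    """Age-normed MCI labels for ``(participant, age, cognition_total)`` triples.

    Within each 5-year stratum the threshold is mean - 1 sample SD (ddof=1);
    a participant is MCI iff its total is strictly below the threshold.
    Strata with fewer than two members have no defined SD: their members are
    labeled 'normal' and a warning is emitted.
    """
    triples = list(scores)
    by_stratum: dict[AgeStratum, list[int]] = {}
    for idx, (_, age, total) in enumerate(triples):
        by_stratum.setdefault(assign_age_stratum(age, top=top), []).append(idx)

    labels: dict = {}
    for stratum, idxs in by_stratum.items():
        totals = np.array([triples[i][2] for i in idxs], dtype=float)
        if len(totals) < 2:
            warnings.warn(
                f"stratum [{stratum.lower},{stratum.upper}] has <2 members; "
                "SD undefined, labeling its members 'normal'",
                stacklevel=2,
            )
            for i in idxs:
                labels[triples[i][0]] = "normal"
            continue
        threshold = totals.mean() - totals.std(ddof=1)
        for i in idxs:
            labels[triples[i][0]] = "MCI" if triples[i][2] < threshold else "normal"
    return labels


def annotate_cohort(df: pd.DataFrame, reverse_code: bool = False,
                    top_stratum: int = 85) -> pd.DataFrame:
    """Add ``cesd_total``, ``depressed``, ``cog_total`` and ``mci`` columns.

    Depression status is per record; MCI labels are normed within each
    (wave, age-stratum) cell so that secular drift between waves does not
    shift the age-specific thresholds.
    """
    out = df.copy()
    items = out[CESD_COLUMNS].to_numpy()
    if reverse_code:
        items = items.copy()
        for i in POSITIVE_ITEMS:
            items[:, i - 1] = 3 - items[:, i - 1]
    out["cesd_total"] = items.sum(axis=1).astype(np.int64)
    out["depressed"] = (out["cesd_total"] >= DEPRESSION_CUTOFF).astype(np.int64)
    out["cog_total"] = out[COG_COLUMNS].sum(axis=1).astype(np.int64)

    mci = np.zeros(len(out), dtype=np.int64)
    for _, wave_idx in out.groupby("wave").indices.items():
        triples = [
            (int(i), int(out["age"].iat[i]), int(out["cog_total"].iat[i]))
            for i in wave_idx
        ]
        labels = label_mci(triples, top=top_stratum)
        for i, lab in labels.items():
            mci[i] = 1 if lab == "MCI" else 0
    out["mci"] = mci
    return out
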