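"""Similarity score (SiSc) computation from catFISH cell-classification tallies.

In two-epoch Arc catFISH, each counted neuron carries one of four labels:
negative, nuclear (intranuclear transcription foci; activity in the epoch
just before sacrifice), cytoplasmic (perinuclear Arc mRNA; activity ~25-30
min earlier), or double (both).  From the four tallies the similarity score
measures the overlap between the two recruited ensembles:

    epoch1     = (cyt + dob) / total
    epoch2     = (nuc + dob) / total
    leastEpoch = min(epoch1, epoch2)
    p(E1E2)    = epoch1 * epoch2
    diff(E1E2) = dob/total - p(E1E2)
    SiSc       = diff(E1E2) / (leastEpoch - p(E1E2))

SiSc ~ 1 means a single population was faithfully reactivated in both
epochs; SiSc ~ 0 means the two epoch ensembles are statistically
independent.  Negative values (fewer doubles than chance) are reported
as-is, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CellCounts",
    "SiScResult",
    "UndefinedScoreError",
    "epoch_proportions",
    "similarity_score",
    "sisc_table",
]


class UndefinedScoreError(ValueError):
    """Raised when a score or proportion is undefined for the given counts."""


@dataclass(frozen=True)
class CellCounts:
    """Per-unit (animal x region) classification tallies.

    ``neg``, ``nuc``, ``cyt``, ``dob`` are the counts of Arc-negative,
    nuclear-only, cytoplasmic-only and double-labeled neurons; the total is
    their sum by construction.
    """

    neg: int
    nuc: int
    cyt: int
    dob: int
    animal_id: Optional[str] = None
    region: Optional[str] = None        # e.g. CA1 / CA3
    condition: Optional[str] = None     # AA / AA' / AB / CC
    pretreatment: Optional[str] = None  # IC / SC / WM

    def __post_init__(self) -> None:
        for name in ("neg", "nuc", "cyt", "dob"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"count {name!r} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.neg + self.nuc + self.cyt + self.dob

    def __add__(self, other: "CellCounts") -> "CellCounts":
        """Pool two tallies of the same unit (metadata must agree)."""
        meta = {}
        for f in ("animal_id", "region", "condition", "pretreatment"):
            a, b = getattr(self, f), getattr(other, f)
            if a is not None and b is not None and a != b:
                raise ValueError(f"cannot pool counts with differing {f}: {a!r} vs {b!r}")
            meta[f] = a if a is not None else b
        return CellCounts(
            self.neg + other.neg, self.nuc + other.nuc,
            self.cyt + other.cyt, self.dob + other.dob, **meta,
        )


@dataclass(frozen=True)
class SiScResult:
    """Full SiSc formula chain for one tally."""

    epoch1: float
    epoch2: float
    least_epoch: float
    p_e1e2: float
    diff_e1e2: float
    sisc: float            # NaN when undefined
    defined: bool = True
    reason: Optional[str] = None


def epoch_proportions(counts: CellCounts) -> tuple[float, float]:
    """Proportion of neurons active in each epoch.

    Epoch 1 (earlier exploration) is read out from cytoplasmic staining,
    epoch 2 (later) from intranuclear foci; double-labeled cells count in
    both.
    """
    total = counts.total
    if total == 0:
        raise UndefinedScoreError("epoch proportions undefined for an empty tally (total=0)")
    return (counts.cyt + counts.dob) / total, (counts.nuc + counts.dob) / total


def similarity_score(counts: CellCounts) -> SiScResult:
    """Compute the similarity score chain for one tally.

    When ``leastEpoch == p(E1E2)`` (e.g. an epoch with zero or full
    activation) the score is undefined; a :class:`SiScResult` with
    ``defined=False`` and ``sisc=nan`` is returned rather than a silent
    division by zero.
    """
    e1, e2 = epoch_proportions(counts)
    least = min(e1, e2)
    p = e1 * e2
    diff = counts.dob / counts.total - p
    denom = least - p
    if denom == 0.0:
        return SiScResult(e1, e2, least, p, diff, math.nan, defined=False,
                          reason="leastEpoch equals p(E1E2); score undefined")
    return SiScResult(e1, e2, least, p, diff, diff / denom)


def sisc_table(counts_list: Iterable[CellCounts], *, exclude_conditions: tuple[str, ...] = ("CC",)) -> pd.DataFrame:
    """One SiSc row per (animal, region, condition, pretreatment) unit.

    Cage-control (CC) animals are excluded by default: with a single
    exploration there is no second ensemble to overlap.  Duplicate keys are
    an integrity error -- counts must be pooled per unit beforehand.
    """
    rows = []
    seen: set[tuple] = set()
    for c in counts_list:
        if c.condition in exclude_conditions:
            continue
        key = (c.animal_id, c.region, c.condition, c.pretreatment)
        if key in seen:
            raise ValueError(f"duplicate unit key {key}; pool counts per unit first")
        seen.add(key)
        r = similarity_score(c)
        rows.append({
            "animal_id": c.animal_id, "region": c.region,
            "condition": c.condition, "pretreatment": c.pretreatment,
            "neg": c.neg, "nuc": c.nuc, "cyt": c.cyt, "dob": c.dob, "total": c.total,
            "epoch1": r.epoch1, "epoch2": r.epoch2, "least_epoch": r.least_epoch,
            "p_e1e2": r.p_e1e2, "diff_e1e2": r.diff_e1e2, "sisc": r.sisc,
            "defined": r.defined,
        })
    cols = ["animal_id", "region", "condition", "pretreatment", "neg", "nuc", "cyt",
            "dob", "total", "epoch1", "epoch2", "least_epoch", "p_e1e2",
            "diff_e1e2", "sisc", "defined"]
    return pd.DataFrame(rows, columns=cols)
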