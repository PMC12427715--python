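"""Panel-release decision rules on microbial counts.

Ready-to-eat, low-moisture dates are released to a sensory panel only
when their total viable count (TVC) and yeast enumeration (YE), in
log10 CFU/g, fall under conservative acceptance limits:

    TVC: accept <= 5.0 < hold <= 6.0 < reject
    YE:  accept <= 4.0 < hold <= 5.0 < reject

Counts exactly at an acceptance limit are accepted (<= semantics); the
two analytes combine by worst case.  A batch containing any rejected
composite is excluded; any held composite flags the batch for
re-plating and review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "MicrobialCount",
    "ReleaseDecision",
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "release_decision",
    "screen_batch",
    "screen_csv",
]

ACCEPT, HOLD, REJECT = "accept", "hold", "reject"
_SEVERITY = {ACCEPT: 0, HOLD: 1, REJECT: 2}


@dataclass(frozen=True)
class MicrobialCount:
    tvc_log: float
    ye_log: float

    def __post_init__(self) -> None:
        for name in ("tvc_log", "ye_log"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class Thresholds:
    """Per-analyte (accept_limit, reject_limit); hold is the half-open
    band (accept_limit, reject_limit]."""

    tvc_accept: float = 5.0
    tvc_reject: float = 6.0
    ye_accept: float = 4.0
    ye_reject: float = 5.0


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class ReleaseDecision:
    category: str
    reasons: tuple[str, ...] = ()


def _categorize(value: float, accept: float, reject: float, analyte: str):
    if value <= accept:
        return ACCEPT, None
    if value <= reject:
        return HOLD, f"{analyte} {value:.2f} log CFU/g in hold band ({accept}, {reject}]"
    return REJECT, f"{analyte} {value:.2f} log CFU/g above reject limit {reject}"


def release_decision(
    count: MicrobialCount, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> ReleaseDecision:
    """Worst-of-two-analytes release category for one composite sample."""
    cat_t, why_t = _categorize(
        count.tvc_log, thresholds.tvc_accept, thresholds.tvc_reject, "TVC"
    )
    cat_y, why_y = _categorize(
        count.ye_log, thresholds.ye_accept, thresholds.ye_reject, "YE"
    )
    category = cat_t if _SEVERITY[cat_t] >= _SEVERITY[cat_y] else cat_y
    reasons = tuple(w for w in (why_t, why_y) if w is not None)
    return ReleaseDecision(category=category, reasons=reasons)


@dataclass(frozen=True)
class BatchReport:
    released: bool
    flagged_for_retest: bool
    n_samples: int
    n_accept: int
    n_hold: int
    n_reject: int
    decisions: tuple[ReleaseDecision, ...]


def screen_batch(
    counts: Iterable[MicrobialCount], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> BatchReport:
    """Batch-level screening: any reject excludes the batch; any hold
    flags it for re-plating; only all-accept batches are released."""
    decisions = tuple(release_decision(c, thresholds) for c in counts)
    if not decisions:
        raise ValueError("batch must contain at least one count")
    cats = [d.category for d in decisions]
    n_reject = cats.count(REJECT)
    n_hold = cats.count(HOLD)
    return BatchReport(
        released=(n_reject == 0 and n_hold == 0),
        flagged_for_retest=(n_reject == 0 and n_hold > 0),
        n_samples=len(decisions),
        n_accept=cats.count(ACCEPT),
        n_hold=n_hold,
        n_reject=n_reject,
        decisions=decisions,
    )


def screen_csv(path_in, path_out=None, thresholds: Thresholds = DEFAULT_THRESHOLDS):
    """CSV in (sample_id, tvc_log, ye_log) -> CSV out with category/reasons."""
    df = pd.read_csv(path_in)
    decisions = [
        release_decision(MicrobialCount(t, y), thresholds)
        for t, y in zip(df["tvc_log"], df["ye_log"])
    ]
    out = df.copy()
    out["category"] = [d.category for d in decisions]
    out["reasons"] = ["; ".join(d.reasons) for d in decisions]
    if path_out is not None:
        out.to_csv(path_out, index=False)
    return out
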