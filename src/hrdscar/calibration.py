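"""HRD-positive threshold calibration.

Two complementary routes fix the threshold:

* a *sensitivity rule* on a discovery cohort with known BRCA status —
  candidate cutoffs are those detecting at least 95% of BRCA-deficient
  samples, and the (lower) median candidate is chosen; and
* a *Cox cutoff scan* on a treatment cohort with progression-free
  survival — each integer cutoff in a window is used to dichotomize the
  cohort and a univariate proportional-hazards model is fitted; the cutoff
  with the smallest p-value is the survival-supported choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "CutoffScanRow",
    "candidate_cutoffs",
    "cox_cutoff_scan",
    "select_cutoff",
    "sensitivity_at_cutoff",
]


@dataclass(frozen=True)
class CutoffScanRow:
    cutoff: int
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError("hazard ratio must lie inside its confidence interval")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must be in [0, 1]")


def sensitivity_at_cutoff(
    scores: Sequence[int], deficient_flags: Sequence[bool], t: int
) -> float:
    """Fraction of BRCA-deficient samples with HRD score >= t."""
    scores = np.asarray(scores)
    flags = np.asarray(deficient_flags, dtype=bool)
    if scores.shape != flags.shape:
        raise ValueError("scores and deficient_flags must have equal length")
    n_def = int(flags.sum())
    if n_def == 0:
        raise ValueError("no BRCA-deficient samples; sensitivity undefined")
    return float((scores[flags] >= t).sum() / n_def)


def candidate_cutoffs(
    scores: Sequence[int],
    deficient_flags: Sequence[bool],
    min_sensitivity: float = 0.95,
    search_range: tuple[int, int] | None = None,
    mode: str = "tightest",
) -> list[int]:
    """Integer cutoffs meeting the sensitivity requirement, sorted ascending.

    Because HRD scores are discrete, sensitivity is a step function of the
    cutoff: many consecutive cutoffs attain the same sensitivity level.
    With ``mode="tightest"`` (default) the candidates are the cutoffs
    attaining the *smallest* sensitivity level still at or above
    ``min_sensitivity`` — the plateau just above the requirement, bounded
    on both sides, which is how a discovery-cohort threshold band like
    36-41 arises.  ``mode="at_least"`` returns every cutoff in the range
    whose sensitivity meets the requirement (a downward-closed set, since
    sensitivity is non-increasing in the cutoff).
    """
    if mode not in ("tightest", "at_least"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = np.asarray(scores)
    if search_range is None:
        search_range = (0, int(scores.max()) + 1)
    lo, hi = search_range
    sens = {t: sensitivity_at_cutoff(scores, deficient_flags, t) for t in range(lo, hi + 1)}
    passing = [t for t in sorted(sens) if sens[t] >= min_sensitivity]
    if not passing or mode == "at_least":
        return passing
    level = min(sens[t] for t in passing)
    return [t for t in passing if sens[t] == level]


def select_cutoff(candidates: Sequence[int], rule: str = "lower_median") -> int:
    """The median candidate cutoff; even-sized sets take the lower median."""
    if rule != "lower_median":
        raise ValueError(f"unknown selection rule {rule!r}")
    if len(candidates) == 0:
        raise ValueError("no candidate cutoffs to select from")
    ordered = sorted(candidates)
    return ordered[(len(ordered) - 1) // 2]


def cox_cutoff_scan(
    scores: Sequence[int],
    pfs_days: Sequence[float],
    event_flags: Sequence[bool],
    t_range: tuple[int, int] = (35, 45),
) -> tuple[list[CutoffScanRow], int]:
    """Univariate Cox PH fits of PFS on (score >= t) for each integer cutoff.

    Ties in day-granularity survival times are handled with Efron's method
    (the lifelines default).  Cutoffs leaving fewer than two samples in
    either arm are skipped with a warning.  Returns the full scan table and
    the cutoff with the smallest p-value.
    """
    scores = np.asarray(scores)
    df = pd.DataFrame(
        {
            "pfs": np.asarray(pfs_days, dtype=float),
            "event": np.asarray(event_flags, dtype=bool).astype(int),
        }
    )
    rows: list[CutoffScanRow] = []
    for t in range(t_range[0], t_range[1] + 1):
        positive = (scores >= t).astype(int)
        if positive.sum() < 2 or (1 - positive).sum() < 2:
            warnings.warn(f"cutoff {t}: fewer than 2 samples in one arm; skipped")
            continue
        fit_df = df.assign(hrd_positive=positive)
        cph = CoxPHFitter()
        cph.fit(fit_df, duration_col="pfs", event_col="event")
        summ = cph.summary.loc["hrd_positive"]
        rows.append(
            CutoffScanRow(
                cutoff=t,
                hazard_ratio=float(summ["exp(coef)"]),
                ci_low=float(summ["exp(coef) lower 95%"]),
                ci_high=float(summ["exp(coef) upper 95%"]),
                p_value=float(summ["p"]),
            )
        )
    if not rows:
        raise ValueError("all cutoffs in range were degenerate (an arm had < 2 samples)")
    best = min(rows, key=lambda r: r.p_value)
    return rows, best.cutoff
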