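"""Cohort-level statistics around HRD status.

Per-sample HRD results, BRCA status, clinical covariates, and a binary
gene-alteration matrix are joined into one table (:class:`CohortTable`),
which feeds:

* rank-sum comparison of HRD scores between groups (e.g. platinum-sensitive
  vs -resistant),
* Kaplan-Meier progression-free survival with the log-rank test,
* multivariate Cox proportional hazards (HRD status, stage, residual
  tumour),
* Fisher's-exact enrichment of concurrent alterations between HRD-positive
  and -negative samples, and
* cross-method concordance (Pearson r on scores, Cohen's kappa on calls).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import cohen_kappa_score, confusion_matrix

__all__ = [
    "CohortTable",
    "EnrichmentRow",
    "compare_scores",
    "concordance",
    "cox_multivariate",
    "enrichment_scan",
    "fisher_test",
    "km_logrank",
    "status_concordance",
]

CLINICAL_COLUMNS = [
    "sample_id",
    "hrd_total",
    "hrd_positive",
    "brca_status",
    "cancer_type",
    "pt_response",
    "pfs_days",
    "pfs_event",
    "stage",
    "residual",
]


@dataclass(frozen=True)
class CohortTable:
    """One row per sample: HRD result + clinical covariates.

    ``pt_response`` is "sensitive" when the platinum-free interval exceeds
    six months, "resistant" otherwise, "unknown" when not evaluable.
    ``residual`` is the post-surgery residual tumour grade (R0 none, R1
    <= 1 cm, R2 > 1 cm); ``stage`` is III, IV, or other.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing column(s): {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("cohort table must have one row per sample")
        if (self.data["pfs_days"].dropna() < 0).any():
            raise ValueError("pfs_days must be non-negative")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class EnrichmentRow:
    alteration: str
    freq_pos: float
    freq_neg: float
    p_value: float
    enriched_in: str  # "positive" | "negative"
    odds_ratio: float


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p).  This is the p-value path used by
    :func:`enrichment_scan`.
    """
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def compare_scores(
    group_a: Sequence[float], group_b: Sequence[float], test: str = "rank_sum"
) -> tuple[float, float, float]:
    """Medians of both groups and the two-sided Wilcoxon rank-sum p-value."""
    if test != "rank_sum":
        raise ValueError(f"unknown test {test!r}")
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return float(np.median(a)), float(np.median(b)), float(p)


def km_logrank(
    cohort: CohortTable, group_by: str = "hrd_positive"
) -> tuple[dict[str, float | None], float]:
    """Kaplan-Meier median PFS per group and the log-rank p-value.

    A group whose survival curve never crosses 0.5 has no estimable median
    and is reported as None ("not reached").
    """
    df = cohort.data
    groups = df[group_by]
    if groups.nunique() < 2:
        raise ValueError(f"log-rank needs >= 2 groups; {group_by!r} has {groups.nunique()}")
    if int(df["pfs_event"].sum()) == 0 or df["pfs_days"].nunique() == 1:
        raise ValueError("degenerate survival data: no events or a single common time")
    medians: dict[str, float | None] = {}
    for label, sub in df.groupby(group_by, sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["pfs_days"], sub["pfs_event"].astype(bool))
        med = kmf.median_survival_time_
        medians[str(label)] = None if np.isinf(med) else float(med)
    res = multivariate_logrank_test(df["pfs_days"], groups, df["pfs_event"].astype(bool))
    return medians, float(res.p_value)


def cox_multivariate(
    cohort: CohortTable,
    covariates: Sequence[str] = ("hrd_positive", "stage", "residual"),
) -> pd.DataFrame:
    """Multivariate Cox PH fit of PFS on HRD status and clinical covariates.

    Categorical covariates are dummy-coded against the reference levels
    HRD-negative, stage III, and R0.  Returns one row per non-reference
    level with columns ``hazard_ratio, ci_low, ci_high, p_value``.
    """
    df = cohort.data
    design = pd.DataFrame({"pfs": df["pfs_days"].astype(float), "event": df["pfs_event"].astype(int)})
    for cov in covariates:
        if df[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant; remove it from the model")
        if cov == "hrd_positive":
            design["hrd_positive"] = df[cov].astype(int)
        elif cov == "stage":
            design["stage_IV"] = (df[cov] == "IV").astype(int)
        elif cov == "residual":
            design["residual_R1"] = (df[cov] == "R1").astype(int)
            design["residual_R2"] = (df[cov] == "R2").astype(int)
        else:
            design[cov] = pd.to_numeric(df[cov])
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="pfs", event_col="event")
    except Exception as exc:  # convergence failure / separation
        raise ValueError(f"Cox model could not be fitted: {exc}") from exc
    summ = cph.summary
    return pd.DataFrame(
        {
            "hazard_ratio": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p_value": summ["p"],
        }
    )


def enrichment_scan(
    matrix: pd.DataFrame,
    hrd_flags: Sequence[bool],
    min_freq: float = 0.05,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[EnrichmentRow]:
    """Alterations differentially present in HRD-positive vs -negative samples.

    ``matrix`` is samples x alterations, binary; mutation, copy loss and
    amplification of one gene are distinct columns.  Each alteration with
    overall frequency above ``min_freq`` is tested with a two-sided
    Fisher's exact test; rows with p <= alpha are returned, most
    significant first.  ``correction="bh"`` applies Benjamini-Hochberg to
    the tested p-values before the alpha filter (off by default).
    """
    flags = np.asarray(hrd_flags, dtype=bool)
    if len(flags) != len(matrix):
        raise ValueError("hrd_flags length does not match the alteration matrix")
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("alteration matrix must be binary")
    n_pos, n_neg = int(flags.sum()), int((~flags).sum())
    tested: list[tuple[str, float, float, float, float]] = []
    for col in matrix.columns:
        x = matrix[col].to_numpy().astype(bool)
        if x.mean() <= min_freq:
            continue
        a, b = int((x & flags).sum()), n_pos - int((x & flags).sum())
        c, d = int((x & ~flags).sum()), n_neg - int((x & ~flags).sum())
        odds, p = fisher_test(a, b, c, d)
        tested.append((col, a / n_pos if n_pos else 0.0, c / n_neg if n_neg else 0.0, p, odds))
    if correction == "bh" and tested:
        raw = [t[3] for t in tested]
        adj = _benjamini_hochberg(raw)
        tested = [(c, fp, fn, q, o) for (c, fp, fn, _, o), q in zip(tested, adj)]
    rows = [
        EnrichmentRow(
            alteration=c,
            freq_pos=fp,
            freq_neg=fn,
            p_value=p,
            enriched_in="positive" if fp >= fn else "negative",
            odds_ratio=o,
        )
        for c, fp, fn, p, o in tested
        if p <= alpha and fp != fn
    ]
    return sorted(rows, key=lambda r: r.p_value)


def _benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def concordance(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Pearson correlation between two HRD score vectors of the same samples."""
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a score vector; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def status_concordance(
    calls_a: Sequence[bool], calls_b: Sequence[bool]
) -> tuple[float, pd.DataFrame]:
    """Unweighted Cohen's kappa on binary HRD calls, plus the 2x2 contingency."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    kappa = float(cohen_kappa_score(a, b))
    table = pd.DataFrame(
        confusion_matrix(a, b, labels=[True, False]),
        index=pd.Index(["a_positive", "a_negative"]),
        columns=pd.Index(["b_positive", "b_negative"]),
    )
    return kappa, table
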