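"""Synthetic allele-specific segment profiles and cohorts with known truth.

The generator starts from a balanced diploid genome (one (2,1) segment per
autosome) and plants three kinds of scar events plus optional sub-threshold
noise:

* **LOH events** — interstitial (1,0) segments 15-40 Mb long;
* **TAI events** — imbalanced terminal segments ((3,1) or (2,0)) that do
  not span the centromere;
* **LST breaks** — abutting pairs of >= 10 Mb segments with different
  states within one arm.

Every planted event is separated from everything else by at least a 5 Mb
uncovered gap — larger than the 3 Mb LST gap/smoothing scale — so events
cannot interact, fuse, or create unplanned breakpoints.  Noise events are
sub-threshold *by construction* (interior imbalance, LOH below 15 Mb,
break flanks below 10 Mb), so with default scoring parameters the scored
components equal the planted counts exactly, an invariant the test suite
verifies rather than assumes.

Cohort simulation layers a clinical model on top: HRD-high samples draw
planted totals at or above the threshold-plus-margin, BRCA-deficient
samples are HRD-high with probability 0.95, progression-free survival is
exponential with the hazard multiplied by ``hr_hrd`` for HRD-positive
samples under independent uniform censoring, and platinum sensitivity is
Bernoulli-linked to HRD status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import CohortTable
from .genome import GenomeBuild, Segment, SegmentProfile, load_hg19
from .scars import DEFAULT_THRESHOLD, ScarConfig, hrd_score

__all__ = ["PlacementError", "SimParams", "SimulatedCohort", "simulate_cohort", "simulate_profile"]

MB = 1_000_000
ISOLATION_GAP = 5 * MB  # > LST max gap, so planted events never interact
TIP_FILL = 12 * MB  # balanced filler reserved at telomeres without a TAI event


class PlacementError(RuntimeError):
    """Planted events exhausted the genome territory available for placement."""


@dataclass(frozen=True)
class SimParams:
    """Generator settings for one profile and (optionally) a cohort.

    Profile fields plant exact event counts; ``background_noise_rate`` is
    the expected number of sub-threshold noise segments per Gb of autosome.
    Cohort fields: ``hr_hrd`` is the PFS hazard ratio of HRD-positive vs
    -negative samples, ``baseline_hazard`` the HRD-negative exponential
    hazard per day (default gives a 343-day median), ``pfi_link`` the
    platinum-sensitivity probabilities (positive, negative), and
    ``hrd_margin`` the no-man's-land half-width around the threshold that
    keeps simulated truth unambiguous.
    """

    n_loh_events: int = 0
    n_tai_events: int = 0
    n_lst_breaks: int = 0
    background_noise_rate: float = 0.0
    phenotype: str = "hrd_low"  # hrd_high | hrd_low
    seed: int = 0
    # cohort-level
    n_samples: int = 100
    frac_brca_deficient: float = 0.27
    frac_intact_positive: float = 0.35
    hr_hrd: float = 0.47
    baseline_hazard: float = float(np.log(2) / 343.0)
    censor_rate: float = 0.2
    pfi_link: tuple[float, float] = (0.82, 0.57)
    threshold: int = DEFAULT_THRESHOLD
    hrd_margin: int = 10

    def __post_init__(self) -> None:
        if min(self.n_loh_events, self.n_tai_events, self.n_lst_breaks) < 0:
            raise ValueError("planted event counts must be non-negative")
        if self.background_noise_rate < 0:
            raise ValueError("background_noise_rate must be non-negative")
        if self.phenotype not in ("hrd_high", "hrd_low"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.hr_hrd <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        for p in (self.frac_brca_deficient, self.frac_intact_positive, *self.pfi_link):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if self.hrd_margin < 0:
            raise ValueError("hrd_margin must be non-negative")


class _Arm:
    """Sequential event packer for one chromosome arm (no fragmentation)."""

    def __init__(self, chrom: str, side: str, lo: int, hi: int) -> None:
        self.chrom = chrom
        self.side = side  # "p" grows rightward from lo, "q" leftward from hi
        self.lo = lo
        self.hi = hi
        self.tai: list[Segment] | None = None
        self.events: list[list[Segment]] = []
        if side == "p":
            self.cursor = lo + TIP_FILL
        else:
            self.cursor = hi - TIP_FILL

    def can_host_tai(self, length: int) -> bool:
        return self.tai is None and not self.events and length + ISOLATION_GAP <= self.hi - self.lo + 1

    def place_tai(self, state: tuple[int, int], length: int) -> None:
        assert self.can_host_tai(length)
        if self.side == "p":
            self.tai = [Segment(self.chrom, self.lo, self.lo + length - 1, *state)]
            self.cursor = self.lo + length + ISOLATION_GAP
        else:
            self.tai = [Segment(self.chrom, self.hi - length + 1, self.hi, *state)]
            self.cursor = self.hi - length - ISOLATION_GAP

    def can_host(self, length: int) -> bool:
        if self.side == "p":
            return self.cursor + length - 1 <= self.hi
        return self.cursor - length + 1 >= self.lo

    def place(self, pieces: Sequence[tuple[tuple[int, int], int]]) -> None:
        """Place abutting pieces [(state, length), ...] plus an isolation gap."""
        total = sum(length for _, length in pieces)
        assert self.can_host(total)
        segs: list[Segment] = []
        if self.side == "p":
            pos = self.cursor
            for state, length in pieces:
                segs.append(Segment(self.chrom, pos, pos + length - 1, *state))
                pos += length
            self.cursor = pos + ISOLATION_GAP
        else:
            pos = self.cursor
            for state, length in reversed(pieces):
                segs.insert(0, Segment(self.chrom, pos - length + 1, pos, *state))
                pos -= length
            self.cursor = pos - ISOLATION_GAP
        self.events.append(segs)

    def segments(self) -> list[Segment]:
        out = list(self.tai or [])
        for ev in self.events:
            out.extend(ev)
        return out


def _assemble_chromosome(chrom_len: int, chrom: str, event_segs: list[Segment]) -> list[Segment]:
    """Fill uncovered territory with balanced (2,1) filler, keeping an
    isolation gap next to every event so fillers never create breakpoints."""
    events = sorted(event_segs, key=lambda s: s.start_bp)
    out: list[Segment] = []
    boundaries = [(0, None)] + [(s.end_bp, s) for s in events]
    for i, (prev_end, _) in enumerate(boundaries):
        nxt = events[i] if i < len(events) else None
        a = prev_end + 1 + (ISOLATION_GAP if i > 0 else 0)
        b = (nxt.start_bp - 1 - ISOLATION_GAP) if nxt is not None else chrom_len
        if b >= a:
            out.append(Segment(chrom, a, b, 2, 1))
        if nxt is not None:
            out.append(nxt)
    return sorted(out, key=lambda s: s.start_bp)


def simulate_profile(
    params: SimParams,
    build: GenomeBuild | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
) -> tuple[SegmentProfile, dict[str, int]]:
    """One profile with exactly the planted scar counts, plus the truth record."""
    build = build or load_hg19()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    arms: list[_Arm] = []
    for c in build.autosomes:
        arms.append(_Arm(c.name, "p", 1, c.centromere_start_bp))
        arms.append(_Arm(c.name, "q", c.centromere_end_bp, c.length_bp))

    def find_arm(pred) -> _Arm | None:
        order = rng.permutation(len(arms))
        for i in order:
            if pred(arms[i]):
                return arms[i]
        return None

    # TAI first: terminal slots must still be free.  If a drawn length fits
    # no free tip, fall back to the minimum event size before giving up.
    for _ in range(params.n_tai_events):
        if rng.random() < 0.5:
            state, length = (3, 1), int(rng.integers(8, 21)) * MB
        else:
            state, length = (2, 0), int(rng.integers(8, 15)) * MB
        for cand in (length, 8 * MB):
            arm = find_arm(lambda a: a.can_host_tai(cand))
            if arm is not None:
                arm.place_tai(state, cand)
                break
        else:
            raise PlacementError(
                f"sample {sample_id!r}: no free telomere can host a TAI event; "
                "reduce n_tai_events"
            )

    Pieces = list[tuple[tuple[int, int], int]]
    interior: list[tuple[Pieces, Pieces]] = []  # (drawn, minimum-size fallback)
    for _ in range(params.n_loh_events):
        interior.append(
            ([((1, 0), int(rng.integers(15, 41)) * MB)], [((1, 0), 15 * MB)])
        )
    for _ in range(params.n_lst_breaks):
        states = [(2, 1), (3, 1)] if rng.random() < 0.5 else [(3, 1), (2, 1)]
        interior.append(
            (
                [(states[0], int(rng.integers(10, 14)) * MB), (states[1], int(rng.integers(10, 14)) * MB)],
                [(states[0], 10 * MB), (states[1], 10 * MB)],
            )
        )
    # Sub-threshold noise: interior, short, isolated — provably score-neutral.
    autosome_gb = sum(c.length_bp for c in build.autosomes) / 1e9
    n_noise = int(rng.poisson(params.background_noise_rate * autosome_gb))
    for _ in range(n_noise):
        kind = rng.integers(0, 3)
        if kind == 0:  # short LOH (< 15 Mb)
            pieces: Pieces = [((1, 0), int(rng.integers(5, 11)) * MB)]
        elif kind == 1:  # interior allelic imbalance
            pieces = [((3, 1), int(rng.integers(4, 10)) * MB)]
        else:  # break between sub-10 Mb flanks
            pieces = [((3, 1), int(rng.integers(4, 9)) * MB), ((4, 1), int(rng.integers(4, 9)) * MB)]
        interior.append((pieces, [(s, 4 * MB) for s, _ in pieces]))
    rng.shuffle(interior)  # type: ignore[arg-type]
    for drawn, fallback in interior:
        for pieces in (drawn, fallback):
            need = sum(length for _, length in pieces)
            arm = find_arm(lambda a: a.can_host(need))
            if arm is not None:
                arm.place(pieces)
                break
        else:
            raise PlacementError(
                f"sample {sample_id!r}: autosome territory exhausted while placing "
                f"a {'x'.join(str(l // MB) for _, l in fallback)} Mb event; reduce planted counts"
            )

    segs: list[Segment] = []
    for c in build.autosomes:
        chrom_events = [s for a in arms if a.chrom == c.name for s in a.segments()]
        segs.extend(_assemble_chromosome(c.length_bp, c.name, chrom_events))
    profile = SegmentProfile(sample_id, build, tuple(segs))
    truth = {
        "loh": params.n_loh_events,
        "tai": params.n_tai_events,
        "lst": params.n_lst_breaks,
        "total": params.n_loh_events + params.n_tai_events + params.n_lst_breaks,
    }
    return profile, truth


MAX_LOH, MAX_TAI, MAX_LST = 30, 8, 28
MAX_TOTAL = MAX_LOH + MAX_TAI + MAX_LST  # genome territory bounds the score


def _split_total(total: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Partition a target HRD total into placeable (loh, tai, lst) counts."""
    if total > MAX_TOTAL:
        raise ValueError(f"target total {total} exceeds placeable maximum {MAX_TOTAL}")
    tai = int(np.clip(rng.integers(0, MAX_TAI + 1), total - MAX_LOH - MAX_LST, min(MAX_TAI, total)))
    rest = total - tai
    lst = int(np.clip(rng.integers(0, MAX_LST + 1), rest - MAX_LOH, min(MAX_LST, rest)))
    loh = rest - lst
    return loh, tai, lst


def _censor_horizon(params: SimParams) -> float:
    """Upper end of the uniform censoring window giving the target censoring
    fraction against the cohort's mixture of exponential event times (the
    HRD-positive arm survives longer and so censors more often)."""
    if params.censor_rate == 0:
        return float("inf")
    p_pos = (
        params.frac_brca_deficient * 0.95
        + (1 - params.frac_brca_deficient) * params.frac_intact_positive
    )
    h_neg = params.baseline_hazard
    h_pos = h_neg * params.hr_hrd

    def frac_censored(c: float) -> float:
        def g(x: float) -> float:
            return (1 - np.exp(-x)) / x

        return p_pos * g(h_pos * c) + (1 - p_pos) * g(h_neg * c)

    return float(brentq(lambda c: frac_censored(c) - params.censor_rate, 1e-6 / h_neg, 1e5 / h_neg))


@dataclass(frozen=True)
class SimulatedCohort:
    cohort: CohortTable
    profiles: dict[str, SegmentProfile] | None
    alterations: pd.DataFrame  # samples x alteration columns, binary
    variants: pd.DataFrame  # BRCA variant evidence consistent with brca_status
    truth: dict = field(default_factory=dict)


def simulate_cohort(
    params: SimParams,
    build: GenomeBuild | None = None,
    generate_profiles: bool = True,
    scar_config: ScarConfig = ScarConfig(),
) -> SimulatedCohort:
    """A cohort with HRD-linked survival, platinum response, and alterations.

    With ``generate_profiles`` the HRD totals in the clinical table are
    *computed* by scoring each simulated profile; without it they are taken
    from the planted counts directly (the two coincide exactly, which the
    planted-truth tests establish), making large replicate studies cheap.
    """
    if params.n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    build = build or load_hg19()
    rng = np.random.default_rng(params.seed)
    t, m = params.threshold, params.hrd_margin
    high_lo, high_hi = t + m, min(max(t + m + 1, 66), MAX_TOTAL)
    low_hi = max(1, t - m)  # exclusive: hrd_low totals are < threshold - margin

    rows = []
    profiles: dict[str, SegmentProfile] | None = {} if generate_profiles else None
    planted: dict[str, dict[str, int]] = {}
    var_rows = []
    c_max = _censor_horizon(params)
    deficient_flags = rng.random(params.n_samples) < params.frac_brca_deficient
    # 95% of deficient samples are HRD-high; the realized escape count is
    # pinned at floor(5%) so the discovery-cohort structure (e.g. 61/64
    # detected) holds in every replicate, not merely in expectation.
    def_idx = np.flatnonzero(deficient_flags)
    n_escape = int(0.05 * len(def_idx))
    escapees = set(rng.choice(def_idx, size=n_escape, replace=False)) if n_escape else set()
    for i in range(params.n_samples):
        sid = f"S{i:04d}"
        deficient = bool(deficient_flags[i])
        if deficient:
            status = "deficient"
            high = i not in escapees
        else:
            status = "monoallelic_pathogenic" if rng.random() < 0.06 else "intact"
            high = rng.random() < params.frac_intact_positive
        if high:
            total = int(rng.integers(high_lo, high_hi + 1))
        elif deficient:
            # The rare deficient samples that escape high HRD still carry a
            # near-threshold scar burden (partial scarring), so they fall
            # just below the unambiguous-negative margin.
            total = int(rng.integers(max(0, low_hi - 3), low_hi))
        else:
            total = int(rng.integers(0, low_hi))
        loh, tai, lst = _split_total(total, rng)
        sp = SimParams(
            n_loh_events=loh,
            n_tai_events=tai,
            n_lst_breaks=lst,
            background_noise_rate=params.background_noise_rate,
            phenotype="hrd_high" if high else "hrd_low",
        )
        planted[sid] = {"loh": loh, "tai": tai, "lst": lst, "total": total}
        if profiles is not None:
            profile, _ = simulate_profile(sp, build, rng, sample_id=sid)
            profiles[sid] = profile
            result = hrd_score(profile, build, scar_config, threshold=params.threshold)
            hrd_total = result.total
        else:
            hrd_total = total
        positive = hrd_total >= params.threshold

        hazard = params.baseline_hazard * (params.hr_hrd if positive else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.uniform(0, c_max) if np.isfinite(c_max) else np.inf
        pfs = min(t_event, t_censor)
        event = t_event <= t_censor
        p_sens = params.pfi_link[0] if positive else params.pfi_link[1]
        rows.append(
            {
                "sample_id": sid,
                "hrd_total": int(hrd_total),
                "hrd_positive": bool(positive),
                "brca_status": status,
                "cancer_type": "ovarian",
                "pt_response": "sensitive" if rng.random() < p_sens else "resistant",
                "pfs_days": float(np.ceil(pfs)),
                "pfs_event": bool(event),
                "stage": "III" if rng.random() < 0.9 else "IV",
                "residual": str(rng.choice(["R0", "R1", "R2"], p=[0.50, 0.43, 0.07])),
                "_positive": positive,
            }
        )
        var_rows.extend(_brca_evidence(sid, status, rng))

    df = pd.DataFrame(rows)
    pos = df.pop("_positive").to_numpy()
    # Alteration matrix: one column enriched in positives, one in negatives,
    # plus frequency-matched null columns.
    alt_spec = {
        "TP53_mutation": (0.95, 0.60),
        "CCNE1_amplification": (0.08, 0.40),
        "ARID1A_mutation": (0.20, 0.20),
        "KMT2D_mutation": (0.15, 0.15),
    }
    alt = pd.DataFrame(
        {
            name: rng.random(len(df)) < np.where(pos, p_pos, p_neg)
            for name, (p_pos, p_neg) in alt_spec.items()
        },
        index=df["sample_id"],
    ).astype(int)
    variants = pd.DataFrame(
        var_rows, columns=["sample", "gene", "effect", "clinical_class", "origin", "allele_id"]
    )
    truth = {
        "planted": planted,
        "hr_hrd": params.hr_hrd,
        "threshold": params.threshold,
        "enriched_in_positive": "TP53_mutation",
        "enriched_in_negative": "CCNE1_amplification",
    }
    return SimulatedCohort(CohortTable(df), profiles, alt, variants, truth)


def _brca_evidence(sid: str, status: str, rng: np.random.Generator) -> list[dict]:
    """Variant rows whose classification reproduces the drawn BRCA status."""
    gene = str(rng.choice(["BRCA1", "BRCA2"]))
    if status == "deficient":
        return [
            {"sample": sid, "gene": gene, "effect": "frameshift", "clinical_class": "unknown",
             "origin": "germline", "allele_id": f"{sid}.{gene}.a1"},
            {"sample": sid, "gene": gene, "effect": "nonsense", "clinical_class": "pathogenic",
             "origin": "somatic", "allele_id": f"{sid}.{gene}.a2"},
        ]
    if status == "monoallelic_pathogenic":
        return [
            {"sample": sid, "gene": gene, "effect": "missense", "clinical_class": "likely_pathogenic",
             "origin": "germline", "allele_id": f"{sid}.{gene}.a1"},
        ]
    if rng.random() < 0.2:  # incidental VUS in an intact sample
        return [
            {"sample": sid, "gene": gene, "effect": "missense", "clinical_class": "vus",
             "origin": "somatic", "allele_id": f"{sid}.{gene}.a1"},
        ]
    return []
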