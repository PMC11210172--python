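"""Cohort-level reporting on a set of MRD calls.

Reproduces the standard analyses run on a liquid-biopsy MRD cohort:
paired cfDNA-vs-CTC correlation (OLS R-squared), fraction comparison
(Mann-Whitney U), concordance of the sequencing calls with multiparametric
flow cytometry, and per-patient marker kinetics with clearance flags.
Two-sided tests throughout; significance at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedObservation", "R2Result", "MannWhitneyResult",
    "ConcordanceTable", "paired_r2", "compare_fractions",
    "concordance_table", "kinetics_table",
]


@dataclass(frozen=True)
class PairedObservation:
    """One timepoint's MRD measurements across fractions/methods."""

    patient_id: str
    timepoint: object = 0
    cfdna_vaf: Optional[float] = None
    ctc_vaf: Optional[float] = None
    mfc_positive: Optional[bool] = None

    def __post_init__(self):
        if self.cfdna_vaf is None and self.ctc_vaf is None \
                and self.mfc_positive is None:
            raise ValueError("at least one measurement must be present")
        for v in (self.cfdna_vaf, self.ctc_vaf):
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"VAF must be in [0,1], got {v}")

    @property
    def complete_pair(self) -> bool:
        return self.cfdna_vaf is not None and self.ctc_vaf is not None


@dataclass(frozen=True)
class R2Result:
    r2: float
    p_value: float
    slope: float
    intercept: float
    n: int
    n_dropped: int


def paired_r2(pairs: Sequence[PairedObservation],
              log_transform: bool = False,
              epsilon: float = 1e-6) -> R2Result:
    """OLS R-squared of CTC VAF on cfDNA VAF over complete pairs.

    Incomplete pairs are dropped (their count is reported). The p-value is
    the two-sided test on the slope. With ``log_transform`` both series are
    mapped through log10(x + epsilon) first, useful because MRD spans
    several orders of magnitude; the default is the untransformed scale.
    """
    complete = [p for p in pairs if p.complete_pair]
    n_dropped = len(pairs) - len(complete)
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 complete pairs, got {len(complete)} "
            f"({n_dropped} incomplete dropped)")
    x = np.array([p.cfdna_vaf for p in complete], dtype=float)
    y = np.array([p.ctc_vaf for p in complete], dtype=float)
    if log_transform:
        x = np.log10(x + epsilon)
        y = np.log10(y + epsilon)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("a constant series has no linear relationship")
    fit = stats.linregress(x, y)
    return R2Result(r2=fit.rvalue ** 2, p_value=fit.pvalue, slope=fit.slope,
                    intercept=fit.intercept, n=len(complete),
                    n_dropped=n_dropped)


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str  # "exact" | "asymptotic"


def compare_fractions(cfdna_values: Sequence[float],
                      ctc_values: Sequence[float],
                      exact_max_n: int = 12) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of two VAF groups.

    Exact enumeration when the combined sample is small (n <= 12) and
    tie-free; the tie-corrected normal approximation otherwise. Group
    medians are reported alongside.
    """
    a = np.asarray(cfdna_values, dtype=float)
    b = np.asarray(ctc_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= exact_max_n and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        n_a=int(a.size), n_b=int(b.size), method=method)


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 agreement between sequencing-based and flow-cytometry MRD calls."""

    pos_pos: int
    neg_neg: int
    pos_neg: int  # NGS positive, MFC negative
    neg_pos: int
    unmatched_ngs: tuple[str, ...] = ()
    unmatched_mfc: tuple[str, ...] = ()

    @property
    def concordant(self) -> int:
        return self.pos_pos + self.neg_neg

    @property
    def discordant(self) -> int:
        return self.pos_neg + self.neg_pos

    @property
    def n(self) -> int:
        return self.concordant + self.discordant

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.pos_pos, self.pos_neg], [self.neg_pos, self.neg_neg]],
            index=pd.Index(["NGS+", "NGS-"]),
            columns=pd.Index(["MFC+", "MFC-"]))


def concordance_table(ngs_calls: dict[str, bool],
                      mfc_calls: dict[str, bool]) -> ConcordanceTable:
    """Cross-tabulate binary MRD calls joined on patient/sample id."""
    for name, calls in (("ngs", ngs_calls), ("mfc", mfc_calls)):
        if len(calls) != len(set(calls)):  # dicts cannot actually duplicate
            raise ValueError(f"duplicate ids in {name} calls")
    shared = sorted(set(ngs_calls) & set(mfc_calls))
    cells = {(True, True): 0, (False, False): 0,
             (True, False): 0, (False, True): 0}
    for pid in shared:
        cells[(bool(ngs_calls[pid]), bool(mfc_calls[pid]))] += 1
    return ConcordanceTable(
        pos_pos=cells[(True, True)], neg_neg=cells[(False, False)],
        pos_neg=cells[(True, False)], neg_pos=cells[(False, True)],
        unmatched_ngs=tuple(sorted(set(ngs_calls) - set(mfc_calls))),
        unmatched_mfc=tuple(sorted(set(mfc_calls) - set(ngs_calls))),
    )


def kinetics_table(calls: pd.DataFrame,
                   threshold: float = 1e-4) -> pd.DataFrame:
    """Longitudinal per-patient per-marker VAF table with clearance flags.

    ``calls`` needs columns patient_id, marker_id, fraction, timepoint, vaf.
    Adds per-row ``status`` (positive/negative vs threshold) and, per
    (patient, marker, fraction) series ordered by timepoint: ``cleared``
    (last VAF below threshold) and ``non_clearance`` (every VAF at or above
    threshold — the persistent-marker pattern that suggests treatment
    resistance).
    """
    required = {"patient_id", "marker_id", "fraction", "timepoint", "vaf"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"kinetics input missing columns: {sorted(missing)}")
    df = calls.copy().sort_values(
        ["patient_id", "marker_id", "fraction", "timepoint"],
        kind="mergesort").reset_index(drop=True)
    df["status"] = np.where(df["vaf"] >= threshold, "positive", "negative")
    grp = df.groupby(["patient_id", "marker_id", "fraction"], sort=False)
    df["cleared"] = grp["vaf"].transform(lambda s: s.iloc[-1] < threshold)
    df["non_clearance"] = grp["vaf"].transform(lambda s: (s >= threshold).all())
    return df
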