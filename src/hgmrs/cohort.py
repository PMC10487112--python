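"""Cohort-level validation statistics.

Works on the packaged 11-patient clinical table (in vivo Glx3 percentage
elevations paired with ex vivo GC-MS 2-HG concentrations from resected
tissue) and on synthetic cohorts: Pearson correlation with case-resampling
bootstrap, positive/negative predictive values of the >0 % elevation cut-off
against IDH genotype, subgroup means by IDH1 mutation subtype (R132H vs
non-R132H), median/IQR, and a Monte-Carlo power check for the Pearson test
at small n.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hgquant import classify

__all__ = ["PatientRecord", "PredictiveValues", "CohortStats",
           "load_table1", "pearson", "bootstrap_r", "predictive_values",
           "subgroup_means", "median_iqr", "run_paper_analysis", "power_check"]

#: sha256 of the packaged clinical table; load_table1 refuses altered copies.
TABLE1_SHA256 = "e4c6e01db16ab232d81adaddb1352fbbab231184e1f62f4168e44aa4ccf10f9d"

MUTANT_SUBTYPES = {"R132H", "R132C", "R132S", "R132G", "R132L"}


@dataclass(frozen=True)
class PatientRecord:
    """One clinical-table row."""

    patient: int
    age: int
    sex: str
    idh: str                  # R132H / R132C / R132S / WT
    histology: str
    grade: str
    location: str
    mrs_elevation_pct: float
    exvivo_hg: float          # mmoles/kg
    exvivo_over_mrs: float
    pv_label: str             # TP / TN / FP / FN

    def __post_init__(self) -> None:
        call = classify(self.mrs_elevation_pct)
        mutant = self.idh in MUTANT_SUBTYPES
        expected = {
            (True, "positive"): "TP",
            (True, "negative"): "FN",
            (False, "positive"): "FP",
            (False, "negative"): "TN",
        }[(mutant, call)]
        if self.pv_label != expected:
            raise ValueError(
                f"patient {self.patient}: pv_label {self.pv_label!r} inconsistent with "
                f"idh={self.idh!r} and elevation {self.mrs_elevation_pct} (expected {expected!r})")

    @property
    def idh_mutant(self) -> bool:
        return self.idh in MUTANT_SUBTYPES


@dataclass
class PredictiveValues:
    ppv_pct: float | None
    npv_pct: float | None
    counts: dict = field(default_factory=dict)   # TP/FP/TN/FN tallies
    flags: list[str] = field(default_factory=list)


@dataclass
class CohortStats:
    """Summary statistics of one cohort analysis run."""

    pearson_r: float
    pearson_p: float
    r_ci: tuple[float, float]
    ppv_pct: float | None
    npv_pct: float | None
    counts: dict
    n_positive: int
    mean_nonR132H: float
    mean_R132H: float
    group_p: float
    median_exvivo: float
    iqr_exvivo: tuple[float, float]
    n_patients: int

    def to_text(self) -> str:
        lines = [
            f"n patients                 {self.n_patients}",
            f"positive 2-HG calls        {self.n_positive}",
            f"Pearson r (MRS vs ex vivo) {self.pearson_r:.2f} (p = {self.pearson_p:.3f})",
            f"bootstrap 95% CI for r     [{self.r_ci[0]:.2f}, {self.r_ci[1]:.2f}]",
            f"PPV                        {self.ppv_pct:.0f}%",
            f"NPV                        {self.npv_pct:.0f}%",
            f"2x2 counts                 {self.counts}",
            f"mean ex vivo, non-R132H    {self.mean_nonR132H:.2f} mmoles/kg",
            f"mean ex vivo, R132H        {self.mean_R132H:.2f} mmoles/kg",
            f"subgroup Welch p           {self.group_p:.3f}",
            f"median ex vivo             {self.median_exvivo:.2f} mmoles/kg "
            f"(IQR {self.iqr_exvivo[0]:.2f}-{self.iqr_exvivo[1]:.2f})",
        ]
        return "\n".join(lines)


def _read_fixture_bytes() -> bytes:
    return (resources.files("hgmrs") / "data" / "table1.csv").read_bytes()


def load_table1() -> list[PatientRecord]:
    """Load and checksum-verify the packaged 11-patient clinical table."""
    raw = _read_fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValueError(f"table1.csv checksum mismatch: {digest}")
    df = pd.read_csv(pd.io.common.BytesIO(raw))
    records = [
        PatientRecord(
            patient=int(r.patient), age=int(r.age), sex=str(r.sex), idh=str(r.idh),
            histology=str(r.histology), grade=str(r.grade), location=str(r.location),
            mrs_elevation_pct=float(r.mrs_elevation_pct), exvivo_hg=float(r.exvivo_hg),
            exvivo_over_mrs=float(r.exvivo_over_mrs), pv_label=str(r.pv_label),
        )
        for r in df.itertuples()
    ]
    if len(records) != 11:
        raise ValueError(f"expected 11 records, got {len(records)}")
    return records


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    return float(stats.pearsonr(x, y).statistic)


def bootstrap_r(x: Sequence[float], y: Sequence[float], n_resamples: int = 10_000,
                seed: int = 0, ci: float = 95.0):
    """Case-resampling bootstrap of the Pearson coefficient.

    Returns (point estimate, (lo, hi) percentile interval, n_degenerate),
    where degenerate resamples (constant in either variable) are skipped
    and counted. Seeded and reproducible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_hat = pearson(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    rs = []
    n_degenerate = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        xs, ys = x[idx], y[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            n_degenerate += 1
            continue
        rs.append(stats.pearsonr(xs, ys).statistic)
    if not rs:
        raise ValueError("all bootstrap resamples were degenerate")
    a = (100.0 - ci) / 2.0
    lo, hi = np.percentile(rs, [a, 100.0 - a])
    return r_hat, (float(lo), float(hi)), n_degenerate


def predictive_values(records: Iterable[PatientRecord]) -> PredictiveValues:
    """PPV/NPV of the >0 % elevation cut-off against IDH genotype.

    A predictive value with an empty denominator is reported as None with a
    flag rather than raising.
    """
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for r in records:
        positive = classify(r.mrs_elevation_pct) == "positive"
        if positive:
            counts["TP" if r.idh_mutant else "FP"] += 1
        else:
            counts["FN" if r.idh_mutant else "TN"] += 1
    flags = []
    pos = counts["TP"] + counts["FP"]
    neg = counts["TN"] + counts["FN"]
    ppv = 100.0 * counts["TP"] / pos if pos else None
    npv = 100.0 * counts["TN"] / neg if neg else None
    if ppv is None:
        flags.append("ppv_undefined")
    if npv is None:
        flags.append("npv_undefined")
    return PredictiveValues(ppv_pct=ppv, npv_pct=npv, counts=counts, flags=flags)


def subgroup_means(records: Iterable[PatientRecord], equal_var: bool = False):
    """Mean ex vivo [2-HG] among IDH1-mutant cases, split R132H vs non-R132H.

    Wild-type records are excluded. Returns (mean_nonR132H, mean_R132H, p)
    with a Welch two-sample t-test by default (Student's via equal_var).
    """
    non, r132h = [], []
    for r in records:
        if not r.idh_mutant:
            continue
        (r132h if r.idh == "R132H" else non).append(r.exvivo_hg)
    if not non or not r132h:
        raise ValueError("both subgroups must be non-empty")
    t = stats.ttest_ind(non, r132h, equal_var=equal_var)
    return float(np.mean(non)), float(np.mean(r132h)), float(t.pvalue)


def median_iqr(values: Sequence[float]):
    """Sample median and quartiles: (median, q1, q3)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median_iqr needs at least one value")
    return (float(np.median(values)),
            float(np.percentile(values, 25)),
            float(np.percentile(values, 75)))


def run_paper_analysis(records: list[PatientRecord] | None = None,
                       n_resamples: int = 10_000, seed: int = 0) -> CohortStats:
    """Full validation analysis of the clinical table (or a substitute cohort)."""
    records = records if records is not None else load_table1()
    elev = [r.mrs_elevation_pct for r in records]
    exvivo = [r.exvivo_hg for r in records]
    r_hat, ci, _ = bootstrap_r(elev, exvivo, n_resamples=n_resamples, seed=seed)
    p_val = float(stats.pearsonr(elev, exvivo).pvalue)
    pv = predictive_values(records)
    mean_non, mean_r132h, group_p = subgroup_means(records)
    med, q1, q3 = median_iqr(exvivo)
    n_pos = sum(1 for r in records if classify(r.mrs_elevation_pct) == "positive")
    return CohortStats(
        pearson_r=r_hat, pearson_p=p_val, r_ci=ci,
        ppv_pct=pv.ppv_pct, npv_pct=pv.npv_pct, counts=pv.counts,
        n_positive=n_pos, mean_nonR132H=mean_non, mean_R132H=mean_r132h,
        group_p=group_p, median_exvivo=med, iqr_exvivo=(q1, q3),
        n_patients=len(records),
    )


def power_check(r_true: float, n: int, alpha: float = 0.05,
                n_sims: int = 2000, seed: int = 0):
    """Monte-Carlo power of the two-sided Pearson test on bivariate-normal data.

    Returns (power, monte_carlo_se). At r_true = 0 the power estimates the
    test's size and should sit at alpha.
    """
    if n < 4:
        raise ValueError("need n >= 4 observations per simulation")
    if not -1.0 < r_true < 1.0:
        raise ValueError("r_true must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    cov = [[1.0, r_true], [r_true, 1.0]]
    hits = 0
    for _ in range(n_sims):
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        if stats.pearsonr(xy[:, 0], xy[:, 1]).pvalue < alpha:
            hits += 1
    power = hits / n_sims
    se = float(np.sqrt(power * (1.0 - power) / n_sims))
    return power, se
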