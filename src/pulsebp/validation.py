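"""Cohort agreement statistics: Bland-Altman, Pearson, ISO 81060-2 checks.

Differences are defined as estimate - reference throughout.  Criterion 1
is the cohort-level bound (|mean| <= 5 mmHg, SD <= 8 mmHg, inclusive);
criterion 2 bounds the SD of per-subject mean differences by the normal
tolerance form of the 85%-within-10-mmHg requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, UsageError

#: Inclusive criterion-1 bounds, mmHg.
C1_MEAN_BOUND = 5.0
C1_SD_BOUND = 8.0

MEASURES = ("sbp", "dbp", "map")


@dataclass(frozen=True)
class MeasureStats:
    """Agreement statistics for one pressure measure."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    n: int
    criterion1_pass: bool
    criterion2_bound: float | None
    criterion2_sd: float | None
    criterion2_pass: bool | None


@dataclass(frozen=True)
class ValidationReport:
    sbp: MeasureStats
    dbp: MeasureStats
    map: MeasureStats
    n: int
    method: str = ""

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "method": self.method,
            **{m: asdict(getattr(self, m)) for m in MEASURES},
        }


def bland_altman(estimates, references) -> tuple[float, float, tuple[float, float]]:
    """Mean difference, sample SD (n-1) and 1.96-SD limits of agreement."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise UsageError(f"length mismatch: {est.shape} vs {ref.shape}")
    if est.size < 2:
        raise UsageError("need at least 2 paired readings")
    d = est - ref
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return mean, sd, (mean - 1.96 * sd, mean + 1.96 * sd)


def pearson(estimates, references) -> float:
    """Sample Pearson correlation coefficient."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise UsageError("length mismatch")
    if est.size < 3:
        raise UsageError("need at least 3 paired readings")
    if np.std(est) == 0 or np.std(ref) == 0:
        raise DataError("Pearson correlation undefined: zero variance")
    return float(stats.pearsonr(est, ref).statistic)


def iso_criterion1(mean_diff: float, sd_diff: float,
                   mean_bound: float = C1_MEAN_BOUND,
                   sd_bound: float = C1_SD_BOUND) -> tuple[bool, float, float]:
    """Criterion-1 check; returns (pass, mean margin, sd margin).

    Bounds are inclusive: |mean| <= 5 and SD <= 8 both pass.
    """
    mean_margin = mean_bound - abs(mean_diff)
    sd_margin = sd_bound - sd_diff
    return (mean_margin >= 0 and sd_margin >= 0), mean_margin, sd_margin


def iso_criterion2_bound(mean_diff: float) -> float:
    """SD bound on per-subject mean differences for a given cohort mean.

    Solves ``Phi((10 - m)/s) - Phi((-10 - m)/s) = 0.85`` for s by
    bisection to 1e-6; for m = 0 this is the closed form
    ``10 / Phi^-1(0.925)``.  No feasible bound exists for |m| >= 10.
    """
    m = float(mean_diff)
    if abs(m) >= 10.0:
        raise DataError(f"|mean_diff| = {abs(m):.2f} >= 10 mmHg: no feasible bound")

    def coverage(s: float) -> float:
        return stats.norm.cdf((10.0 - m) / s) - stats.norm.cdf((-10.0 - m) / s)

    # coverage is decreasing in s; bracket and bisect
    return float(optimize.bisect(lambda s: coverage(s) - 0.85,
                                 1e-9, 100.0, xtol=1e-6))


def _measure_stats(est: np.ndarray, ref: np.ndarray,
                   subject_ids: np.ndarray | None) -> MeasureStats:
    mean, sd, (lo, hi) = bland_altman(est, ref)
    r = pearson(est, ref) if est.size >= 3 and np.std(est) > 0 and np.std(ref) > 0 else float("nan")
    c1, _, _ = iso_criterion1(mean, sd)
    c2_bound = c2_sd = c2_pass = None
    if subject_ids is not None:
        d = est - ref
        per_subject = pd.Series(d).groupby(pd.Series(subject_ids)).mean()
        if per_subject.size >= 2 and abs(float(per_subject.mean())) < 10.0:
            c2_sd = float(per_subject.std(ddof=1))
            c2_bound = iso_criterion2_bound(float(per_subject.mean()))
            c2_pass = c2_sd <= c2_bound
    return MeasureStats(
        mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi, pearson_r=r,
        n=int(est.size), criterion1_pass=c1, criterion2_bound=c2_bound,
        criterion2_sd=c2_sd, criterion2_pass=c2_pass,
    )


def validation_report(cohort: pd.DataFrame, method: str = "") -> ValidationReport:
    """Build a full report from a cohort table.

    Expected columns: ``subject_id``, ``est_sbp``, ``est_dbp``, ``est_map``,
    ``ref_sbp``, ``ref_dbp``, ``ref_map`` (one row per reading).  When a
    ``method`` column is present and ``method`` is given, rows are filtered.
    """
    df = cohort
    if method and "method" in df.columns:
        df = df[df["method"] == method]
    if df.empty:
        raise DataError("no readings to validate")
    ids = df["subject_id"].to_numpy() if "subject_id" in df.columns else None
    per = {
        m: _measure_stats(df[f"est_{m}"].to_numpy(dtype=float),
                          df[f"ref_{m}"].to_numpy(dtype=float), ids)
        for m in MEASURES
    }
    return ValidationReport(sbp=per["sbp"], dbp=per["dbp"], map=per["map"],
                            n=int(len(df)), method=method)


def bland_altman_scatter(estimates, references) -> pd.DataFrame:
    """(mean, difference) pairs for a Bland-Altman scatter plot."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise UsageError("length mismatch")
    return pd.DataFrame({"mean": (est + ref) / 2.0, "difference": est - ref})
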