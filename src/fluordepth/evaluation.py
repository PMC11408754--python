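"""Error statistics over predicted depth/concentration maps.

Per-sample errors are mean absolute per-pixel differences over an evaluation
support (by default the ground-truth tumor footprint); cohorts report
mean +/- SD, and paired model comparisons use the two-sided Wilcoxon
signed-rank test (exact for small n), with a paired t-test available behind
a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import DepthConcPrediction
from .shapes import GroundTruthMaps

__all__ = ["SampleError", "CohortReport", "sample_error", "cohort_stats", "paired_test"]


@dataclass
class SampleError:
    """Mean absolute depth (mm) and concentration (ug/mL) error, one sample."""

    depth_error_mm: float
    conc_error_ugml: float
    sample_id: str = ""
    support: str = "footprint"


@dataclass
class CohortReport:
    """Cohort mean +/- sample SD of per-sample errors."""

    n: int
    depth_mean_mm: float
    depth_sd_mm: float
    conc_mean_ugml: float
    conc_sd_ugml: float
    errors: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": e.sample_id,
                    "depth_error_mm": e.depth_error_mm,
                    "conc_error_ugml": e.conc_error_ugml,
                    "support": e.support,
                }
                for e in self.errors
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortReport":
        errors = [
            SampleError(
                depth_error_mm=row.depth_error_mm,
                conc_error_ugml=row.conc_error_ugml,
                sample_id=row.sample_id,
                support=row.support,
            )
            for row in df.itertuples()
        ]
        return cohort_stats(errors)


def _support_mask(truth: GroundTruthMaps, pred: DepthConcPrediction, support: str):
    if support == "footprint":
        return truth.depth_mm > 0
    if support == "union":
        return (truth.depth_mm > 0) | (pred.depth_mm > 0)
    if support == "full":
        return np.ones_like(truth.depth_mm, dtype=bool)
    raise ValueError(f"unknown support {support!r}")


def sample_error(
    pred: DepthConcPrediction,
    truth: GroundTruthMaps,
    support: str = "footprint",
    sample_id: str = "",
) -> SampleError:
    """Mean absolute per-pixel error over the evaluation support."""
    if pred.depth_mm.shape != truth.depth_mm.shape:
        raise ValueError("prediction and truth are not co-registered")
    mask = _support_mask(truth, pred, support)
    if not mask.any():
        raise ValueError("empty evaluation support")
    return SampleError(
        depth_error_mm=float(np.abs(pred.depth_mm - truth.depth_mm)[mask].mean()),
        conc_error_ugml=float(
            np.abs(pred.concentration - truth.concentration)[mask].mean()
        ),
        sample_id=sample_id,
        support=support,
    )


def cohort_stats(errors: list, ddof: int = 1) -> CohortReport:
    """Mean +/- SD over a cohort (sample SD, divisor n - ddof)."""
    if not errors:
        raise ValueError("need at least one sample error")
    d = np.array([e.depth_error_mm for e in errors])
    c = np.array([e.conc_error_ugml for e in errors])
    sd_d = float(d.std(ddof=ddof)) if d.size > ddof else 0.0
    sd_c = float(c.std(ddof=ddof)) if c.size > ddof else 0.0
    return CohortReport(
        n=len(errors),
        depth_mean_mm=float(d.mean()),
        depth_sd_mm=sd_d,
        conc_mean_ugml=float(c.mean()),
        conc_sd_ugml=sd_c,
        errors=list(errors),
    )


def paired_test(errors_a, errors_b, method: str = "wilcoxon") -> float:
    """Two-sided paired significance test on per-sample errors.

    ``errors_a`` / ``errors_b`` are equal-length sequences of per-sample
    scalars (e.g. depth errors of two models on the same cohort).  The
    default is the Wilcoxon signed-rank test, exact for n < 25; a paired
    t-test is available with ``method="ttest"``.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    diff = a - b
    if np.all(diff == 0.0):
        warnings.warn("all paired differences are zero (ties); p = 1")
        return 1.0
    if method == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)
    if method != "wilcoxon":
        raise ValueError(f"unknown method {method!r}")
    mode = "exact" if a.size < 25 else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=mode)
    return float(res.pvalue)
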