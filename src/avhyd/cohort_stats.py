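"""Cohort summaries: mean ± SEM and the exact Wilcoxon signed-rank test.

The in-vivo comparison is paired and small (n = 10 volunteers), so the
signed-rank test is computed exactly: zero differences are dropped
(Wilcoxon's original procedure), tied absolute differences receive average
ranks, and the null distribution of W+ is obtained by full enumeration of
all 2^n sign assignments.  The two-sided p-value doubles the smaller tail
probability, capped at 1.  No normal approximation is offered — exactness is
the point at these sample sizes, and enumeration is capped at n = 15.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateSampleError, DomainError, UnsupportedSizeError
from .geometry_synth import SubjectGeometry

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "CohortSummary",
    "wilcoxon_signed_rank_exact",
    "mean_sem",
    "three_timepoint_table",
    "TIMEPOINTS",
]

_ENUM_LIMIT = 15
TIMEPOINTS = ("end_diastole", "end_systole", "mid_diastasis")


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements, e.g. VSA and ASA of the same subjects at one timepoint."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape or x.size < 1:
            raise DomainError("paired sample requires equal-length 1-d arrays of length >= 1")

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y


@dataclass(frozen=True)
class WilcoxonResult:
    """Exact signed-rank result: W+ statistic, effective n, two-sided p."""

    w_plus: float
    n_eff: int
    p_two_sided: float


def wilcoxon_signed_rank_exact(sample: PairedSample | Sequence[float], y=None) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired data.

    Accepts a :class:`PairedSample`, or ``(x, y)`` arrays, or a single array
    of precomputed differences.  W+ is the sum of ranks of the positive
    differences among the ranked absolute differences (ties averaged); the
    p-value enumerates every sign assignment, so it is exact under the null
    hypothesis of symmetric differences about zero.
    """
    if isinstance(sample, PairedSample):
        d = sample.differences
    elif y is not None:
        d = np.asarray(sample, dtype=float) - np.asarray(y, dtype=float)
    else:
        d = np.asarray(sample, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero; the test is undefined")
    if n > _ENUM_LIMIT:
        raise UnsupportedSizeError(
            f"exact enumeration supports n_eff <= {_ENUM_LIMIT}, got {n}"
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    # all 2^n sign assignments as a bit matrix; W+ for each assignment
    masks = (np.arange(2**n, dtype=np.uint32)[:, None] >> np.arange(n)) & 1
    w_all = masks @ ranks
    eps = 1e-9
    p_le = np.mean(w_all <= w_plus + eps)
    p_ge = np.mean(w_all >= w_plus - eps)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(w_plus=w_plus, n_eff=n, p_two_sided=float(p))


def mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (sample sd / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError(f"SEM requires n >= 2, got n = {v.size}")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass(frozen=True)
class CohortSummary:
    """Per-timepoint, per-measure mean ± SEM with paired signed-rank results."""

    table: pd.DataFrame  # columns: timepoint, measure, mean, sem, n, w_plus, p_two_sided

    def row(self, timepoint: str, measure: str) -> pd.Series:
        m = (self.table["timepoint"] == timepoint) & (self.table["measure"] == measure)
        if not m.any():
            raise DomainError(f"no row for ({timepoint}, {measure})")
        return self.table[m].iloc[0]

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")


def three_timepoint_table(cohort: Sequence[SubjectGeometry]) -> CohortSummary:
    """Paired VSA-vs-ASA comparison at end diastole, end systole and diastasis.

    For each timepoint and each ventricular definition (endocardial and
    epicardial) the per-subject area difference VSA − ASA is summarized as
    mean ± SEM together with the exact signed-rank test against zero.  With a
    single subject the SEM is undefined (reported as NaN) and the test runs
    on one difference (p = 1 unless degenerate).
    """
    if len(cohort) == 0:
        raise DomainError("cohort must contain at least one subject")
    phases = cohort[0].phases
    t_of = {"end_diastole": 0.0, "end_systole": phases.t_es, "mid_diastasis": phases.t_dd}
    rows = []
    for tp, t in t_of.items():
        asa = np.array([s.asa.area_at(t) for s in cohort])
        for measure, chamber in (("delta_endo", "vsa_endo"), ("delta_epi", "vsa_epi")):
            vsa = np.array([s.curve(chamber).area_at(t) for s in cohort])
            diff = vsa - asa
            if diff.size >= 2:
                mean, sem = mean_sem(diff)
            else:
                mean, sem = float(diff.mean()), float("nan")
            try:
                wr = wilcoxon_signed_rank_exact(PairedSample(vsa, asa))
                w_plus, p = wr.w_plus, wr.p_two_sided
            except (DegenerateSampleError, UnsupportedSizeError):
                w_plus, p = float("nan"), float("nan")
            rows.append(
                {"timepoint": tp, "measure": measure, "mean": mean, "sem": sem,
                 "n": diff.size, "w_plus": w_plus, "p_two_sided": p}
            )
    return CohortSummary(table=pd.DataFrame(rows))
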