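"""Replicate summaries and significance testing across conditions.

Mirrors the reporting convention of small-n cytometry studies: per-phase
mean +/- sample SD over independent replicate analyses, and classical
one-way ANOVA across conditions for each phase.  No multiple-testing
correction is applied; per-phase tests are reported as-is.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cytometry import PhaseFractions

__all__ = ["ReplicateSummary", "replicate_stats", "one_way_anova"]

_PHASE_KEYS = ("p_g1", "p_s", "p_g2m", "p_ungated")


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-phase mean and sample SD (n-1 denominator) over replicates."""

    n_replicates: int
    mean: dict
    sd: dict | None  # None when only one replicate is available

    def as_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "mean": self.mean,
            "sd": self.sd,
        }


def replicate_stats(replicates: list[PhaseFractions]) -> ReplicateSummary:
    """Summarise phase fractions over independent replicate analyses."""
    if not replicates:
        raise ValueError("no replicates given")
    values = {k: [getattr(r, k) for r in replicates] for k in _PHASE_KEYS}
    mean = {k: float(np.mean(v)) for k, v in values.items()}
    if len(replicates) < 2:
        warnings.warn("single replicate: SD omitted", stacklevel=2)
        return ReplicateSummary(1, mean, None)
    sd = {k: float(np.std(v, ddof=1)) for k, v in values.items()}
    return ReplicateSummary(len(replicates), mean, sd)


def one_way_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and p with (k-1, N-k) degrees of freedom.

    Degenerate zero-within-variance inputs are handled as limits: p = 1
    when every value is identical, p = 0 when group means differ with no
    within-group spread.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if ss_within == 0.0:
        return (0.0, 1.0) if ss_between == 0.0 else (math.inf, 0.0)
    if ss_between == 0.0:
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)
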