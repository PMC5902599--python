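"""Repertoire-adequacy quality control (ECDF of |NES|).

Whether a given interactome repertoire is suitable for analysing an
unknown ("orphan") tissue is judged from the empirical cumulative
distribution of |NES| across all scored proteins of a sample: a repertoire
whose regulons poorly represent the profiled context produces a null-like
|NES| distribution, a clear outlier against a reference panel of
adequately scored profiles.

The decision rule is self-calibrating: the sample's Kolmogorov-Smirnov
distance to the pooled reference is compared with the conformal
``alpha``-quantile of the leave-one-out distances among the reference
profiles themselves (the ceil(alpha * (n + 1))-th order statistic), which
guarantees a false-alarm rate of at most ``1 - alpha`` under
exchangeability without any tuned constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import ks_2samp
from statsmodels.distributions.empirical_distribution import ECDF

from .interactome import ValidationError

MIN_PROTEINS = 100


@dataclass
class AdequacyReport:
    sample_id: str
    ecdf: ECDF
    ks_distance: float
    threshold: float
    flag: str  # "adequate" | "inadequate"
    loo_distances: np.ndarray
    reference_summary: str

    @property
    def adequate(self) -> bool:
        return self.flag == "adequate"


def ecdf_abs_nes(activity_column: np.ndarray) -> ECDF:
    """Empirical CDF of |NES| over all scored proteins of one sample."""
    vals = np.abs(np.asarray(activity_column, dtype=float))
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_PROTEINS:
        raise ValidationError(
            f"need >= {MIN_PROTEINS} scored proteins for a stable ECDF, got {vals.size}"
        )
    return ECDF(vals)


def _conformal_quantile(values: np.ndarray, alpha: float) -> float:
    """ceil(alpha * (n + 1))-th order statistic (capped at the maximum)."""
    k = int(np.ceil(alpha * (values.size + 1)))
    k = min(k, values.size)
    return float(np.sort(values)[k - 1])


def adequacy_score(
    sample_activity: np.ndarray,
    reference_activities: Sequence[np.ndarray],
    alpha_quantile: float = 0.95,
    sample_id: str = "sample",
) -> AdequacyReport:
    """Flag a sample's |NES| distribution against a reference panel.

    ``ks_distance`` is the two-sample KS statistic between the sample's
    |NES| values and the pooled reference (all reference |NES| values
    concatenated); the sample is flagged inadequate when it exceeds the
    conformal ``alpha_quantile`` of the leave-one-out distances among the
    reference profiles.
    """
    if len(reference_activities) < 5:
        raise ValidationError("need >= 5 reference activity profiles")
    if not 0.5 < alpha_quantile < 1.0:
        raise ValidationError("alpha_quantile must be in (0.5, 1)")
    sample = np.abs(np.asarray(sample_activity, dtype=float))
    sample = sample[np.isfinite(sample)]
    if sample.size < MIN_PROTEINS:
        raise ValidationError(f"sample has < {MIN_PROTEINS} scored proteins")
    refs = [np.abs(np.asarray(r, dtype=float)) for r in reference_activities]
    refs = [r[np.isfinite(r)] for r in refs]
    if any(r.size == 0 for r in refs):
        raise ValidationError("degenerate (empty) reference profile")
    pooled = np.concatenate(refs)
    if np.ptp(pooled) == 0:
        raise ValidationError("degenerate reference: zero spread")

    ks = float(ks_2samp(sample, pooled, method="asymp").statistic)
    loo = np.empty(len(refs))
    for i, r in enumerate(refs):
        others = np.concatenate([x for j, x in enumerate(refs) if j != i])
        loo[i] = ks_2samp(r, others, method="asymp").statistic
    threshold = _conformal_quantile(loo, alpha_quantile)
    flag = "adequate" if ks <= threshold else "inadequate"
    return AdequacyReport(
        sample_id=sample_id,
        ecdf=ecdf_abs_nes(sample),
        ks_distance=ks,
        threshold=threshold,
        flag=flag,
        loo_distances=loo,
        reference_summary=(
            f"{len(refs)} reference profiles, {pooled.size} pooled |NES| values, "
            f"pooled median {np.median(pooled):.3f}"
        ),
    )
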