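"""Gene-expression signatures.

A signature is a genes x samples matrix of signed differential-expression
scores — each sample scored against a reference distribution.  Signatures
are the input to regulon enrichment: since enrichment is rank-based, only
the within-sample ordering of scores matters downstream.

Three scoring methods are provided:

``zscore``
    (x - mean_ref) / sd_ref per gene.  Default for bulk profiles.
``mad``
    (x - median_ref) / (1.4826 * MAD_ref) per gene; robust to heavy tails
    and dropout-inflated variance.  Default for single cells.
``rank``
    within-sample fractional ranks mapped to standard-normal quantiles
    (no reference moments used beyond the gene universe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .interactome import ValidationError
from .matrices import ExpressionMatrix

METHODS = ("zscore", "mad", "rank")

_MAD_SCALE = 1.4826  # consistency factor: MAD -> sd under normality


@dataclass
class GeneSignature:
    """Genes x samples signed differential-expression scores."""

    data: pd.DataFrame
    method_tag: str = "zscore"
    flagged_genes: list = field(default_factory=list)
    degenerate_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in signature")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValidationError("signature contains non-finite values")
        # samples whose scores are all identical carry no ranking information
        vals = self.data.to_numpy(dtype=float)
        if vals.shape[0] > 0:
            degenerate = np.ptp(vals, axis=0) == 0
            self.degenerate_samples = list(self.data.columns[degenerate])

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def rank_quantile_transform(values: np.ndarray) -> np.ndarray:
    """Map per-gene scores to standard-normal quantiles of fractional ranks.

    ``q_g = ndtri(rank(s_g) / (N + 1))`` with ties given their mean rank.
    Strictly monotone in the input; for a tie-free input of size N the
    output is exactly the normal-scores grid ``ndtri(i / (N + 1))``.

    Raises
    ------
    ValidationError
        If the input has fewer than 2 distinct values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValidationError("expected a 1-D signature column")
    if np.unique(values).size < 2:
        raise ValidationError("degenerate signature: all values identical")
    ranks = rankdata(values, method="average")
    return ndtri(ranks / (values.size + 1))


def signature_vs_reference(
    test: ExpressionMatrix,
    reference: ExpressionMatrix,
    method: str = "zscore",
) -> GeneSignature:
    """Score each test sample against a reference expression matrix.

    Genes are intersected between test and reference (dropped genes are
    recorded on the result).  Genes with zero reference dispersion get
    score 0 and are flagged.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown signature method {method!r}")
    shared = test.genes.intersection(reference.genes)
    if len(shared) == 0:
        raise ValidationError("empty gene intersection between test and reference")
    if method in ("zscore", "mad") and reference.shape[1] < 3:
        raise ValidationError(f"method {method!r} needs >= 3 reference samples")

    x = test.data.loc[shared].to_numpy(dtype=float)
    ref = reference.data.loc[shared].to_numpy(dtype=float)
    flagged: list = []

    if method == "rank":
        scores = _columnwise_normal_scores(x)
    else:
        if method == "zscore":
            center = ref.mean(axis=1)
            disp = ref.std(axis=1, ddof=1)
        else:
            center = np.median(ref, axis=1)
            disp = _MAD_SCALE * np.median(np.abs(ref - np.median(ref, axis=1, keepdims=True)), axis=1)
        zero = disp == 0
        flagged = list(shared[zero])
        disp = np.where(zero, 1.0, disp)
        scores = (x - center[:, None]) / disp[:, None]
        scores[zero, :] = 0.0

    sig = GeneSignature(
        pd.DataFrame(scores, index=shared, columns=test.samples),
        method_tag=method,
    )
    sig.flagged_genes = flagged
    return sig


def internal_signature(
    cells: ExpressionMatrix,
    method: str = "mad",
    leave_self_out: bool = True,
) -> GeneSignature:
    """Score each cell against the remaining cells of the same matrix.

    The per-cell reference is all *other* cells (leave-self-out), avoiding
    self-contamination of the reference moments; pass
    ``leave_self_out=False`` for the simpler all-cells reference.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown signature method {method!r}")
    n = cells.shape[1]
    if n < 10:
        raise ValidationError(
            "internal signatures need >= 10 cells; provide an explicit reference"
        )
    x = cells.values
    if method == "rank":
        scores = _columnwise_normal_scores(x)
        return GeneSignature(
            pd.DataFrame(scores, index=cells.genes, columns=cells.samples),
            method_tag=method,
        )

    scores = np.empty_like(x)
    flagged_any: set = set()
    for j in range(n):
        ref = np.delete(x, j, axis=1) if leave_self_out else x
        if method == "zscore":
            center = ref.mean(axis=1)
            disp = ref.std(axis=1, ddof=1)
        else:
            center = np.median(ref, axis=1)
            disp = _MAD_SCALE * np.median(
                np.abs(ref - np.median(ref, axis=1, keepdims=True)), axis=1
            )
        zero = disp == 0
        flagged_any.update(np.flatnonzero(zero).tolist())
        disp = np.where(zero, 1.0, disp)
        col = (x[:, j] - center) / disp
        col[zero] = 0.0
        scores[:, j] = col
    sig = GeneSignature(
        pd.DataFrame(scores, index=cells.genes, columns=cells.samples),
        method_tag=method,
    )
    sig.flagged_genes = list(cells.genes[sorted(flagged_any)])
    return sig


def _columnwise_normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = rankdata(x, method="average", axis=0)
    return ndtri(ranks / (x.shape[0] + 1))
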