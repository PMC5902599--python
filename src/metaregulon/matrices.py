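"""Expression and mutation matrix containers.

Thin, validated wrappers around a genes x samples pandas DataFrame.  The
analysis code works on the underlying ndarray; the containers exist to keep
gene/sample label bookkeeping and invariants in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import ValidationError


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dupes = labels[labels.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (counts or normalized)."""

    data: pd.DataFrame
    layer_tag: str = "normalized"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if self.layer_tag not in ("counts", "normalized"):
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cpm(self, scale: float = 1e6) -> "ExpressionMatrix":
        """Counts-per-total scaling (library-size normalization only)."""
        totals = self.data.sum(axis=0)
        if (totals <= 0).any():
            raise ValidationError("cannot scale sample with zero total counts")
        return ExpressionMatrix(self.data / totals * scale, layer_tag="normalized")


@dataclass
class MutationMatrix:
    """Genes x samples binary mutation indicators."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mutation matrix entries must be 0/1")
        self.data = self.data.astype(np.int8)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def recurrence(self) -> pd.Series:
        """Per-gene number of mutated samples (row sum)."""
        return self.data.sum(axis=1).astype(int)

    def mutated_samples(self, gene: str) -> list[str]:
        row = self.data.loc[gene]
        return list(row.index[row.to_numpy() == 1])
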