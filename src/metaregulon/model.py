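"""Model/Results front end for protein-activity inference.

`ProteinActivity` is the user-facing estimator: construct it from a
signature (or an expression matrix plus reference) and an interactome
repertoire, call :meth:`fit` and inspect the returned
:class:`ProteinActivityResults` — NES estimates, their two-sided
p-values, per-cell evidence counts, and a text ``summary()``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .adequacy import AdequacyReport, adequacy_score
from .enrichment import DEFAULT_MIN_TARGETS, EnrichmentError
from .interactome import Interactome
from .matrices import ExpressionMatrix
from .metaviper import METHODS, IntegrationResult, leave_one_out, metaviper
from .signatures import GeneSignature, signature_vs_reference


class ProteinActivity:
    """Protein-activity model for a signature and an interactome repertoire.

    Parameters
    ----------
    signature : GeneSignature
        Per-sample differential-expression scores on a common gene
        universe.
    interactomes : Interactome or sequence of Interactome
        The regulon repertoire.  A single interactome gives a plain
        single-network analysis; several are integrated by the method
        chosen at fit time.
    min_targets : int
        Minimum usable targets for a regulon to be scored.

    Examples
    --------
    >>> model = ProteinActivity(signature, [net_a, net_b])
    >>> res = model.fit(method="NESScore")
    >>> res.nes.head()
    """

    def __init__(
        self,
        signature: GeneSignature,
        interactomes: Interactome | Sequence[Interactome],
        min_targets: int = DEFAULT_MIN_TARGETS,
    ) -> None:
        if isinstance(interactomes, Interactome):
            interactomes = [interactomes]
        self.signature = signature
        self.interactomes = list(interactomes)
        if not self.interactomes:
            raise EnrichmentError("need at least one interactome")
        self.min_targets = int(min_targets)

    @classmethod
    def from_expression(
        cls,
        test: ExpressionMatrix,
        reference: ExpressionMatrix,
        interactomes: Interactome | Sequence[Interactome],
        signature_method: str = "zscore",
        min_targets: int = DEFAULT_MIN_TARGETS,
    ) -> "ProteinActivity":
        """Build the model from raw expression plus a reference cohort."""
        sig = signature_vs_reference(test, reference, method=signature_method)
        return cls(sig, interactomes, min_targets=min_targets)

    def fit(
        self,
        method: str = "NESScore",
        match_name: str | None = None,
        seed: int | None = None,
    ) -> "ProteinActivityResults":
        """Integrate per-network enrichment into one activity profile."""
        if method not in METHODS:
            raise EnrichmentError(f"unknown method {method!r}; choose from {METHODS}")
        integration = metaviper(
            self.signature,
            self.interactomes,
            method=method,
            match_name=match_name,
            seed=seed,
            min_targets=self.min_targets,
        )
        return ProteinActivityResults(self, integration)

    def fit_leave_one_out(
        self, held_out_name: str, method: str = "NESScore", seed: int | None = None
    ) -> "ProteinActivityResults":
        """Fit with one named interactome excluded (orphan-tissue protocol)."""
        integration = leave_one_out(
            self.signature,
            self.interactomes,
            held_out_name,
            method=method,
            seed=seed,
            min_targets=self.min_targets,
        )
        return ProteinActivityResults(self, integration)


class ProteinActivityResults:
    """Fitted protein-activity profile.

    Attributes
    ----------
    nes : DataFrame
        Regulators x samples normalized enrichment scores.
    pvalues : DataFrame
        Two-sided normal p-values, ``2 (1 - Phi(|NES|))``.
    n_networks : DataFrame
        Per-cell count of interactomes contributing evidence.
    """

    def __init__(self, model: ProteinActivity, integration: IntegrationResult) -> None:
        self.model = model
        self.integration = integration
        self.method = integration.method
        self.nes = integration.nes
        self.pvalues = integration.pvalues
        self.n_networks = integration.n_networks
        self.activity = integration.activity

    def top_regulators(self, sample: str | None = None, n: int = 10) -> pd.DataFrame:
        """Strongest |NES| regulators, per sample or across all samples."""
        if sample is not None:
            scores = self.nes[sample]
        else:
            scores = self.nes.abs().max(axis=1) * np.sign(
                self.nes.to_numpy()[
                    np.arange(len(self.nes)), self.nes.abs().to_numpy().argmax(axis=1)
                ]
            )
        order = scores.abs().sort_values(ascending=False).index[:n]
        out = pd.DataFrame(
            {
                "nes": scores.loc[order],
                "p_two_sided": 2.0
                * (1.0 - pd.Series(_ndtr(scores.loc[order].abs()), index=order)),
                "n_targets": self.activity.n_targets.reindex(order),
            }
        )
        out.index.name = "regulator"
        return out

    def adequacy(
        self,
        reference_results: Sequence["ProteinActivityResults"] | Sequence[np.ndarray],
        sample: str | None = None,
        alpha_quantile: float = 0.95,
    ) -> AdequacyReport:
        """Repertoire-adequacy check of one sample against references."""
        col = self.nes.iloc[:, 0] if sample is None else self.nes[sample]
        refs = [
            r.nes.to_numpy().ravel() if isinstance(r, ProteinActivityResults) else np.asarray(r)
            for r in reference_results
        ]
        return adequacy_score(
            col.to_numpy(), refs, alpha_quantile=alpha_quantile, sample_id=str(col.name)
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        n_sig = int((self.pvalues.to_numpy() < 0.05).sum())
        lines = [
            "Protein activity inference",
            "==========================",
            f"integration method : {self.method}",
            f"interactomes       : {self.activity.source}",
            f"signature method   : {self.model.signature.method_tag}",
            f"regulators scored  : {self.nes.shape[0]}",
            f"samples            : {self.nes.shape[1]}",
            f"min targets        : {self.model.min_targets}",
            f"cells with p<0.05  : {n_sig}",
            "",
            "Top regulators (max |NES| across samples):",
            self.top_regulators(n=5).to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ProteinActivityResults method={self.method} "
            f"shape={self.nes.shape[0]}x{self.nes.shape[1]}>"
        )


def _ndtr(x: pd.Series) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(x.to_numpy(dtype=float))
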