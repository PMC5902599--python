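"""Regulon enrichment engine.

Quantifies the enrichment of a regulon in a gene-expression signature as a
Normalized Enrichment Score (NES) on the standard-normal scale, so that
``p = 2 * (1 - Phi(|NES|))`` is the two-sided significance under the null
of a randomly placed regulon.  NES is used throughout as a proxy for
differential protein activity.

The statistic is analytic and rank-based.  For one signature column with
N genes let ``r_g = rank(s_g) / (N + 1)`` and

* ``q_g  = ndtri(r_g)``                 — signed normal scores,
* ``q1_g = ndtri(1/2 + |r_g - 1/2|)``   — folded (one-tailed) scores >= 0.

Over the used targets t with mode ``m_t`` and likelihood ``w_t``:

* two-tail part (sign-informative weight ``w|m|``)::

      ES2  = sum w m q,            NES2 = ES2 / sqrt(sum (w m)^2)

* one-tail part (mode-uncertain weight ``w (1 - |m|)``), standardized by
  the half-normal moments mu1 = sqrt(2/pi), var1 = 1 - 2/pi of q1 under
  the null::

      ES1  = sum w (1-|m|) q1
      NES1 = (ES1 - mu1 * sum w(1-|m|)) / sqrt(var1 * sum (w(1-|m|))^2)

* combination, with ``alpha = sum w|m|`` and ``beta = sum w(1-|m|)``::

      NES = (alpha * NES2 + beta * sign(NES2) * NES1) / sqrt(alpha^2 + beta^2)

  (``beta = 0`` -> NES2; ``alpha = 0`` -> |NES1|, sign undefined, flagged).

A permutation oracle (`permutation_nes`) recomputes the combined statistic
under gene-label permutations and z-scores the observed value against that
null; it is the binding contract for the analytic formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .interactome import Interactome, Regulon, ValidationError
from .signatures import GeneSignature

DEFAULT_MIN_TARGETS = 25

_MU1 = np.sqrt(2.0 / np.pi)
_VAR1 = 1.0 - 2.0 / np.pi


class EnrichmentError(ValidationError):
    pass


@dataclass
class NESResult:
    """Enrichment of one regulon in one signature column."""

    regulator: str
    nes: float
    n_targets_used: int
    sign_undefined: bool = False

    @property
    def p_two_sided(self) -> float:
        return float(2.0 * (1.0 - ndtr(abs(self.nes))))


@dataclass
class ActivityMatrix:
    """Regulators x samples NES values with provenance.

    ``n_targets`` records, per regulator, how many targets intersected the
    signature's gene universe (constant across samples of one signature).
    ``skipped`` maps regulators that never passed ``min_targets`` to the
    reason they were dropped.
    """

    nes: pd.DataFrame
    n_targets: pd.Series
    source: str
    method_tag: str = "viper"
    skipped: dict[str, str] = field(default_factory=dict)
    sign_undefined: list = field(default_factory=list)

    @property
    def regulators(self) -> pd.Index:
        return self.nes.index

    @property
    def samples(self) -> pd.Index:
        return self.nes.columns

    @property
    def pvalues(self) -> pd.DataFrame:
        return 2.0 * (1.0 - pd.DataFrame(
            ndtr(np.abs(self.nes.to_numpy())), index=self.nes.index, columns=self.nes.columns
        ))


def signature_scores(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise signed (q) and folded (q1) normal scores of a signature."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    degenerate = np.ptp(values, axis=0) == 0
    if degenerate.any():
        raise EnrichmentError(
            f"degenerate signature column(s) at positions {np.flatnonzero(degenerate).tolist()}"
        )
    r = rankdata(values, method="average", axis=0) / (n + 1)
    q = ndtri(r)
    q1 = ndtri(0.5 + np.abs(r - 0.5))
    return q, q1


def _combined_nes(
    q_t: np.ndarray, q1_t: np.ndarray, mode: np.ndarray, likelihood: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Combined NES for one regulon; vectorized over signature columns.

    ``q_t``/``q1_t`` are (n_targets, n_samples) slices of the score
    matrices at the regulon's target rows.
    """
    wm = likelihood * mode
    wu = likelihood * (1.0 - np.abs(mode))
    alpha = float(np.sum(likelihood * np.abs(mode)))
    beta = float(np.sum(wu))

    sign_undefined = False
    if alpha > 0:
        nes2 = wm @ q_t / np.sqrt(np.sum(wm**2))
    else:
        nes2 = np.zeros(q_t.shape[1])
    if beta > 0:
        es1 = wu @ q1_t
        nes1 = (es1 - _MU1 * beta) / np.sqrt(_VAR1 * np.sum(wu**2))
    else:
        nes1 = np.zeros(q_t.shape[1])

    if beta == 0:
        nes = nes2
    elif alpha == 0:
        # fully mode-uncertain regulon: direction is undefined; report
        # the one-tail magnitude as positive and flag it
        nes = np.abs(nes1)
        sign_undefined = True
    else:
        s2 = np.where(nes2 >= 0, 1.0, -1.0)
        nes = (alpha * nes2 + beta * s2 * nes1) / np.sqrt(alpha**2 + beta**2)
    return nes, sign_undefined


def nes_for_regulon(
    signature_column: np.ndarray | pd.Series,
    regulon: Regulon,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> NESResult:
    """Enrichment of one regulon in one signature column.

    ``signature_column`` must be a pandas Series indexed by gene (the
    analysis universe); targets outside the universe are ignored.
    """
    if not isinstance(signature_column, pd.Series):
        raise EnrichmentError("signature_column must be a pandas Series indexed by gene")
    idx = signature_column.index.get_indexer(regulon.targets)
    used = idx >= 0
    if used.sum() < min_targets:
        raise EnrichmentError(
            f"regulon {regulon.regulator!r}: {int(used.sum())} usable targets "
            f"< min_targets={min_targets}"
        )
    q, q1 = signature_scores(signature_column.to_numpy(dtype=float))
    rows = idx[used]
    nes, sign_undef = _combined_nes(
        q[rows, :], q1[rows, :], regulon.mode[used], regulon.likelihood[used]
    )
    return NESResult(
        regulator=regulon.regulator,
        nes=float(nes[0]),
        n_targets_used=int(used.sum()),
        sign_undefined=sign_undef,
    )


def viper(
    signature: GeneSignature,
    interactome: Interactome,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> ActivityMatrix:
    """Regulon enrichment of every regulator, for every signature column."""
    if signature.degenerate_samples:
        raise EnrichmentError(
            f"degenerate signature samples: {signature.degenerate_samples[:5]}"
        )
    genes = signature.genes
    q, q1 = signature_scores(signature.values)

    rows: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    skipped: dict[str, str] = {}
    sign_undefined: list[str] = []
    for reg in interactome:
        idx = genes.get_indexer(reg.targets)
        used = idx >= 0
        n = int(used.sum())
        if n < min_targets:
            skipped[reg.regulator] = f"{n} usable targets < min_targets={min_targets}"
            continue
        sel = idx[used]
        nes, sign_undef = _combined_nes(
            q[sel, :], q1[sel, :], reg.mode[used], reg.likelihood[used]
        )
        rows[reg.regulator] = nes
        n_used[reg.regulator] = n
        if sign_undef:
            sign_undefined.append(reg.regulator)
    if not rows:
        raise EnrichmentError(
            f"no regulon of interactome {interactome.name!r} passed min_targets={min_targets}"
        )
    nes_df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    nes_df.columns = signature.samples
    return ActivityMatrix(
        nes=nes_df,
        n_targets=pd.Series(n_used, dtype=int),
        source=interactome.name,
        method_tag=f"viper:{signature.method_tag}",
        skipped=skipped,
        sign_undefined=sign_undefined,
    )


def permutation_nes(
    signature_column: pd.Series,
    regulon: Regulon,
    n_perm: int = 10_000,
    seed: int | None = None,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> float:
    """Permutation z-score validating the analytic NES.

    Recomputes the combined enrichment statistic on ``n_perm`` gene-label
    permutations of the signature (equivalently: targets placed uniformly
    at random without replacement) and returns
    ``(NES_obs - mean_perm) / sd_perm``.
    """
    if n_perm < 1000:
        raise EnrichmentError("n_perm must be >= 1000")
    obs = nes_for_regulon(signature_column, regulon, min_targets=min_targets)
    q, q1 = signature_scores(signature_column.to_numpy(dtype=float))
    q, q1 = q[:, 0], q1[:, 0]
    idx = signature_column.index.get_indexer(regulon.targets)
    used = idx >= 0
    mode = regulon.mode[used]
    likelihood = regulon.likelihood[used]
    n_t, n_genes = int(used.sum()), q.size

    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        rows = rng.choice(n_genes, size=n_t, replace=False)
        nes_b, _ = _combined_nes(q[rows, None], q1[rows, None], mode, likelihood)
        perm[b] = nes_b[0]
    sd = perm.std(ddof=1)
    if sd == 0:
        raise EnrichmentError("zero permutation spread; cannot standardize")
    return float((obs.nes - perm.mean()) / sd)
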