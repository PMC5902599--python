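"""Ground-truth generators for end-to-end testing without downloads.

The generators emulate the study conditions the method was designed for:

* a "master" interactome of signed, weighted regulons (the true regulatory
  architecture);
* context-specific interactomes that conserve only a fraction of each
  regulon (``fidelity``) — the knob behind the "partial regulon
  conservation" premise of multi-network integration;
* expression signatures generated from planted regulator activities plus
  i.i.d. noise (signature-space generation: enrichment is rank-based, so
  only relative structure matters for bulk tests);
* sparse single-cell counts with depth-driven dropout (gamma-Poisson
  expression, multinomially thinned to a per-cell read depth);
* recurrent mutation calls coupled to planted activity shifts.

Every generator takes an explicit seed and records it in the returned
:class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import Interactome, Regulon, ValidationError
from .matrices import ExpressionMatrix, MutationMatrix
from .signatures import GeneSignature


@dataclass
class SyntheticTruth:
    """Planted ground truth accumulated across generator calls."""

    master: Interactome
    genes: pd.Index
    context_fidelity: dict[str, float] = field(default_factory=dict)
    planted_activity: pd.DataFrame | None = None  # regulators x samples (theta)
    mutation_coupling: dict[str, float] = field(default_factory=dict)
    seeds: list[tuple[str, int | None]] = field(default_factory=list)

    @property
    def regulators(self) -> list[str]:
        return self.master.regulators


def _likelihoods(rng: np.random.Generator, size: int) -> np.ndarray:
    # Uniform(0.5, 1]: 1 - U[0, 0.5)
    return 1.0 - rng.uniform(0.0, 0.5, size=size)


def _modes(rng: np.random.Generator, size: int, frac_negative: float) -> np.ndarray:
    return np.where(rng.uniform(size=size) < frac_negative, -1.0, 1.0)


def make_master_interactome(
    n_regulators: int = 100,
    n_genes: int = 3000,
    targets_per_regulon: int = 50,
    mode_mix: float = 0.3,
    seed: int | None = None,
    name: str = "master",
) -> tuple[Interactome, SyntheticTruth]:
    """Random master interactome: the planted regulatory architecture.

    Targets are drawn without replacement per regulon, modes are +/-1 with
    a ``mode_mix`` fraction of repressions, likelihoods ~ Uniform(0.5, 1].
    Regulator identifiers (``TF``-prefixed) are disjoint from the target
    gene universe (``G``-prefixed).
    """
    if n_genes < targets_per_regulon:
        raise ValidationError(
            f"n_genes={n_genes} too small for regulons of {targets_per_regulon} targets"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = pd.Index([f"G{i:0{width}d}" for i in range(1, n_genes + 1)])
    regulons: dict[str, Regulon] = {}
    for r in range(1, n_regulators + 1):
        regulator = f"TF{r:04d}"
        targets = rng.choice(genes.to_numpy(), size=targets_per_regulon, replace=False)
        regulons[regulator] = Regulon(
            regulator=regulator,
            targets=targets,
            mode=_modes(rng, targets_per_regulon, mode_mix),
            likelihood=_likelihoods(rng, targets_per_regulon),
        )
    master = Interactome(name=name, regulons=regulons, provenance="synthetic master")
    truth = SyntheticTruth(master=master, genes=genes)
    truth.context_fidelity[name] = 1.0
    truth.seeds.append(("make_master_interactome", seed))
    return master, truth


def derive_context_interactome(
    master: Interactome,
    fidelity: float,
    seed: int | None = None,
    name: str | None = None,
    gene_pool: pd.Index | None = None,
    truth: SyntheticTruth | None = None,
) -> Interactome:
    """Partially conserved context interactome.

    Per regulon, ``ceil(fidelity * size)`` original targets are kept
    (random subset); the rest are replaced by random genes with random
    modes and fresh likelihoods.  Regulon sizes are preserved.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValidationError("fidelity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if gene_pool is None:
        if truth is not None:
            gene_pool = truth.genes
        else:
            gene_pool = pd.Index(
                sorted({t for reg in master for t in reg.targets.tolist()})
            )
    pool = gene_pool.to_numpy()
    if name is None:
        name = f"{master.name}-f{fidelity:g}"
    regulons: dict[str, Regulon] = {}
    for reg in master:
        n_keep = int(np.ceil(fidelity * reg.size))
        keep = rng.choice(reg.size, size=n_keep, replace=False) if n_keep else np.array([], int)
        kept_targets = reg.targets[keep]
        n_new = reg.size - n_keep
        # replacements are drawn outside the *original* target set, so the
        # conserved fraction is exactly ceil(fidelity * size) / size
        candidates = pool[~np.isin(pool, reg.targets)]
        new_targets = rng.choice(candidates, size=n_new, replace=False)
        regulons[reg.regulator] = Regulon(
            regulator=reg.regulator,
            targets=np.concatenate([kept_targets, new_targets]),
            mode=np.concatenate([reg.mode[keep], _modes(rng, n_new, 0.5)]),
            likelihood=np.concatenate([reg.likelihood[keep], _likelihoods(rng, n_new)]),
        )
    ctx = Interactome(
        name=name,
        regulons=regulons,
        provenance=f"synthetic context derived from {master.name!r}, fidelity={fidelity:g}",
    )
    if truth is not None:
        truth.context_fidelity[name] = float(fidelity)
        truth.seeds.append((f"derive_context_interactome:{name}", seed))
    return ctx


def signatures_from_activity(
    truth: SyntheticTruth,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> GeneSignature:
    """Expression signatures implied by the recorded planted activities.

    Per sample j, gene score ``s_g = sum_r theta_rj * m_rg * w_rg +
    Normal(0, noise_sd)`` over the master regulons of the active
    regulators.
    """
    if truth.planted_activity is None:
        raise ValidationError("truth has no planted activity; call simulate_signatures")
    rng = np.random.default_rng(seed)
    theta = truth.planted_activity
    genes = truth.genes
    values = rng.normal(0.0, noise_sd, size=(len(genes), theta.shape[1]))
    for regulator, row in theta.iterrows():
        active = row.to_numpy() != 0
        if not active.any():
            continue
        reg = truth.master[regulator]
        rows = genes.get_indexer(reg.targets)
        ok = rows >= 0
        contrib = np.outer(
            reg.mode[ok] * reg.likelihood[ok], row.to_numpy()[active]
        )
        values[np.ix_(rows[ok], np.flatnonzero(active))] += contrib
    truth.seeds.append(("signatures_from_activity", seed))
    return GeneSignature(
        pd.DataFrame(values, index=genes, columns=theta.columns),
        method_tag="synthetic",
    )


def simulate_signatures(
    truth: SyntheticTruth,
    n_samples: int = 200,
    n_active_per_sample: int = 5,
    effect_theta: float = 0.5,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> GeneSignature:
    """Plant per-sample regulator activities and generate signatures.

    Each sample gets ``n_active_per_sample`` active regulators (drawn
    without replacement) with activity ``theta = +/- effect_theta``
    (random sign); the planted matrix is stored on ``truth``.
    """
    if effect_theta < 0:
        raise ValidationError("effect_theta must be >= 0")
    rng = np.random.default_rng(seed)
    regulators = truth.regulators
    samples = [f"S{j:04d}" for j in range(1, n_samples + 1)]
    theta = np.zeros((len(regulators), n_samples))
    for j in range(n_samples):
        active = rng.choice(len(regulators), size=n_active_per_sample, replace=False)
        theta[active, j] = effect_theta * np.where(rng.uniform(size=active.size) < 0.5, -1, 1)
    truth.planted_activity = pd.DataFrame(theta, index=regulators, columns=samples)
    truth.seeds.append(("simulate_signatures", seed))
    sub_seed = None if seed is None else int(rng.integers(2**31))
    return signatures_from_activity(truth, noise_sd=noise_sd, seed=sub_seed)


def simulate_sc_counts(
    mean_expression: pd.Series,
    n_cells: int,
    depth_per_cell: int | np.ndarray,
    dispersion: float = 0.3,
    seed: int | None = None,
    cell_prefix: str = "C",
) -> ExpressionMatrix:
    """Sparse single-cell counts with depth-driven dropout.

    Per cell, expected expression is gamma-perturbed around
    ``mean_expression`` (negative-binomial over-dispersion ``dispersion``)
    and the cell's reads are multinomially allocated to genes in
    proportion — zeros arise naturally from low depth, with no explicit
    zero-inflation parameter.
    """
    mu = mean_expression.to_numpy(dtype=float)
    if np.any(mu <= 0):
        raise ValidationError("mean_expression must be strictly positive")
    depths = np.broadcast_to(np.asarray(depth_per_cell, dtype=int), (n_cells,))
    if np.any(depths < 1000):
        raise ValidationError("depth_per_cell must be >= 1000 reads")
    if dispersion <= 0:
        raise ValidationError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    shape = 1.0 / dispersion
    counts = np.empty((mu.size, n_cells), dtype=np.int64)
    for j in range(n_cells):
        lam = mu * rng.gamma(shape, scale=dispersion, size=mu.size)
        counts[:, j] = rng.multinomial(int(depths[j]), lam / lam.sum())
    cells = [f"{cell_prefix}{j:04d}" for j in range(1, n_cells + 1)]
    return ExpressionMatrix(
        pd.DataFrame(counts, index=mean_expression.index, columns=cells),
        layer_tag="counts",
    )


def cluster_mean_expression(
    truth: SyntheticTruth,
    active_regulators: list[str],
    effect_log: float = 1.0,
    base_mean: pd.Series | None = None,
    seed: int | None = None,
) -> pd.Series:
    """Per-gene mean expression for a cluster driven by active regulators.

    A lognormal baseline is multiplied by ``exp(effect_log * m * w)`` for
    the targets of each active regulator — the count-space counterpart of
    the signature-space generator.
    """
    rng = np.random.default_rng(seed)
    if base_mean is None:
        base_mean = pd.Series(
            np.exp(rng.normal(1.0, 1.0, size=len(truth.genes))), index=truth.genes
        )
    mean = base_mean.copy()
    for regulator in active_regulators:
        reg = truth.master[regulator]
        rows = truth.genes.get_indexer(reg.targets)
        ok = rows >= 0
        mean.iloc[rows[ok]] *= np.exp(effect_log * reg.mode[ok] * reg.likelihood[ok])
    return mean


def plant_mutations(
    truth: SyntheticTruth,
    n_samples: int | None = None,
    n_coupled_genes: int = 50,
    recurrence_range: tuple[int, int] = (3, 30),
    effect_shift: float = 2.0,
    seed: int | None = None,
) -> MutationMatrix:
    """Recurrent mutation calls, a subset coupled to planted activity.

    Every regulator gene receives a recurrence drawn uniformly from
    ``recurrence_range`` and that many mutated samples chosen uniformly.
    For the ``n_coupled_genes`` coupled genes, the planted activity of the
    mutated samples is shifted by ``effect_shift``; the remaining genes'
    mutations are independent of activity.
    """
    if truth.planted_activity is None:
        if n_samples is None:
            raise ValidationError("n_samples required when no activity is planted yet")
        samples = [f"S{j:04d}" for j in range(1, n_samples + 1)]
        truth.planted_activity = pd.DataFrame(
            0.0, index=truth.regulators, columns=samples
        )
    theta = truth.planted_activity
    samples = list(theta.columns)
    lo, hi = recurrence_range
    if not 1 <= lo <= hi <= len(samples):
        raise ValidationError("recurrence_range must fit within the sample count")
    if n_coupled_genes > len(truth.regulators):
        raise ValidationError("more coupled genes than regulators")
    rng = np.random.default_rng(seed)
    coupled = set(
        rng.choice(np.array(truth.regulators, dtype=object), size=n_coupled_genes, replace=False)
    )
    calls = np.zeros((len(truth.regulators), len(samples)), dtype=np.int8)
    for i, gene in enumerate(truth.regulators):
        recurrence = int(rng.integers(lo, hi + 1))
        mutated = rng.choice(len(samples), size=recurrence, replace=False)
        calls[i, mutated] = 1
        if gene in coupled:
            theta.iloc[i, mutated] += effect_shift
            truth.mutation_coupling[gene] = float(effect_shift)
        else:
            truth.mutation_coupling[gene] = 0.0
    truth.seeds.append(("plant_mutations", seed))
    return MutationMatrix(pd.DataFrame(calls, index=truth.regulators, columns=samples))
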