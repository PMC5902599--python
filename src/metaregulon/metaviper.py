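"""Evidence integration across a repertoire of interactomes.

A regulon that poorly represents a protein's true targets in the profiled
context produces no significant enrichment, so integrating the per-network
NES over many non-matched interactomes recovers protein activity even when
no tissue-matched network exists.  Five strategies are provided:

``maxScore``
    the NES with the largest absolute value across networks (ties broken
    by input order, logged);
``avgScore``
    the arithmetic mean of the available NES values;
``NESScore``
    |z|-weighted Stouffer combination ``sum(|z_i| z_i) / sqrt(sum z_i^2)``
    — concordant evidence from k networks is amplified by sqrt(k);
``NESmean``
    the plain |z|-weighted mean ``sum(|z_i| z_i) / sum |z_i|`` (alternate
    reading of the weighted average, tagged distinctly);
``tissueMatch``
    the single named matched interactome's NES (plain single-network
    analysis);
``randomMatch``
    one interactome drawn uniformly at random per sample (baseline
    negative control).

Integration is per (regulator, sample) over the networks where that
regulon passed ``min_targets``; no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import DEFAULT_MIN_TARGETS, ActivityMatrix, EnrichmentError, viper
from .interactome import Interactome
from .signatures import GeneSignature

METHODS = ("maxScore", "avgScore", "NESScore", "NESmean", "tissueMatch", "randomMatch")


def combine_nes(z_values: Sequence[float], method: str = "NESScore") -> float:
    """Combine the NES values of one (regulator, sample) cell across networks.

    The scalar kernel behind `metaviper`; NaN entries (regulon not scored
    in that network) are ignored.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise EnrichmentError("no finite NES values to combine")
    if z.size == 1 and method in ("avgScore", "maxScore", "NESScore", "NESmean"):
        return float(z[0])  # single evidence: exact identity, no round-off
    if method == "avgScore":
        return float(z.mean())
    if method == "maxScore":
        return float(z[np.argmax(np.abs(z))])  # first occurrence wins ties
    if method == "NESScore":
        den = np.sqrt(np.sum(z**2))
        return float(np.sum(np.abs(z) * z) / den) if den > 0 else 0.0
    if method == "NESmean":
        den = np.sum(np.abs(z))
        return float(np.sum(np.abs(z) * z) / den) if den > 0 else 0.0
    raise EnrichmentError(f"combine_nes does not apply to method {method!r}")


@dataclass
class IntegrationResult:
    """Integrated activity plus per-cell evidence counts."""

    activity: ActivityMatrix
    n_networks: pd.DataFrame
    method: str
    dropped_regulators: dict[str, str] = field(default_factory=dict)
    max_score_ties: list = field(default_factory=list)
    chosen_network: pd.Series | None = None  # randomMatch: per-sample draw

    @property
    def nes(self) -> pd.DataFrame:
        return self.activity.nes

    @property
    def pvalues(self) -> pd.DataFrame:
        return self.activity.pvalues


def _stack(
    per_network: dict[str, ActivityMatrix], samples: pd.Index
) -> tuple[np.ndarray, pd.Index, list[str]]:
    """(k, R, S) NES array over the union of regulators, NaN = not scored."""
    regulators: list[str] = []
    seen: set[str] = set()
    for am in per_network.values():
        for r in am.regulators:
            if r not in seen:
                seen.add(r)
                regulators.append(r)
    reg_index = pd.Index(regulators)
    names = list(per_network)
    z = np.full((len(names), len(reg_index), len(samples)), np.nan)
    for i, name in enumerate(names):
        am = per_network[name]
        rows = reg_index.get_indexer(am.regulators)
        z[i, rows, :] = am.nes.to_numpy()
    return z, reg_index, names


def metaviper(
    signature: GeneSignature,
    interactomes: Sequence[Interactome],
    method: str = "NESScore",
    match_name: str | None = None,
    seed: int | None = None,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> IntegrationResult:
    """Integrate per-interactome VIPER activity into one profile."""
    if not interactomes:
        raise EnrichmentError("need at least one interactome")
    if method not in METHODS:
        raise EnrichmentError(f"unknown integration method {method!r}")
    names = [net.name for net in interactomes]
    if len(set(names)) != len(names):
        raise EnrichmentError(f"duplicate interactome names: {names}")
    if method == "tissueMatch" and match_name not in names:
        raise EnrichmentError(f"tissueMatch network {match_name!r} not in {names}")
    if method == "randomMatch" and seed is None:
        raise EnrichmentError("randomMatch requires a seed")

    per_network: dict[str, ActivityMatrix] = {}
    skipped_everywhere: dict[str, str] = {}
    for net in interactomes:
        try:
            per_network[net.name] = viper(signature, net, min_targets=min_targets)
        except EnrichmentError:
            continue  # network contributed nothing; integrate over the rest
    if not per_network:
        raise EnrichmentError("no interactome produced any passing regulon")

    z, reg_index, names = _stack(per_network, signature.samples)
    available = np.isfinite(z)
    n_networks = available.sum(axis=0)

    ties: list = []
    chosen: pd.Series | None = None
    if len(names) == 1 and method in ("avgScore", "maxScore", "NESScore", "NESmean"):
        nes = z[0].copy()  # single network: exact identity with plain viper
    elif method == "tissueMatch":
        am = per_network[match_name]
        nes = np.full((len(reg_index), len(signature.samples)), np.nan)
        rows = reg_index.get_indexer(am.regulators)
        nes[rows, :] = am.nes.to_numpy()
        n_networks = np.isfinite(nes).astype(int)
    elif method == "randomMatch":
        rng = np.random.default_rng(seed)
        draw = rng.integers(0, len(names), size=len(signature.samples))
        chosen = pd.Series([names[i] for i in draw], index=signature.samples)
        nes = z[draw, :, np.arange(len(signature.samples))].T
        n_networks = np.isfinite(nes).astype(int)
    elif method == "avgScore":
        with np.errstate(invalid="ignore"):
            nes = np.where(n_networks > 0, np.nansum(z, axis=0) / np.maximum(n_networks, 1), np.nan)
    elif method == "maxScore":
        absz = np.where(available, np.abs(z), -np.inf)
        best = absz.argmax(axis=0)  # first occurrence wins on ties
        nes = np.take_along_axis(z, best[None, :, :], axis=0)[0]
        nes[n_networks == 0] = np.nan
        n_tied = (absz == absz.max(axis=0, keepdims=True)).sum(axis=0)
        tie_cells = np.argwhere((n_tied > 1) & (n_networks > 1))
        ties = [
            (reg_index[i], signature.samples[j], names[best[i, j]]) for i, j in tie_cells
        ]
    else:  # NESScore / NESmean
        zz = np.where(available, z, 0.0)
        num = np.sum(np.abs(zz) * zz, axis=0)
        if method == "NESScore":
            den = np.sqrt(np.sum(zz**2, axis=0))
        else:
            den = np.sum(np.abs(zz), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            nes = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        nes[n_networks == 0] = np.nan

    # regulators with no evidence anywhere are absent from the output
    any_evidence = np.isfinite(nes).any(axis=1)
    for r in reg_index[~any_evidence]:
        skipped_everywhere[r] = "no contributing interactome"
    reg_kept = reg_index[any_evidence]

    nes_df = pd.DataFrame(nes[any_evidence], index=reg_kept, columns=signature.samples)
    n_net_df = pd.DataFrame(
        np.asarray(n_networks)[any_evidence], index=reg_kept, columns=signature.samples
    )
    n_targets = pd.Series(
        {
            r: max(
                int(am.n_targets.get(r, 0)) for am in per_network.values()
            )
            for r in reg_kept
        },
        dtype=int,
    )
    activity = ActivityMatrix(
        nes=nes_df,
        n_targets=n_targets,
        source="+".join(per_network),
        method_tag=f"metaviper:{method}",
    )
    return IntegrationResult(
        activity=activity,
        n_networks=n_net_df,
        method=method,
        dropped_regulators=skipped_everywhere,
        max_score_ties=ties,
        chosen_network=chosen,
    )


def leave_one_out(
    signature: GeneSignature,
    interactomes: Sequence[Interactome],
    held_out_name: str,
    method: str = "NESScore",
    seed: int | None = None,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> IntegrationResult:
    """Integration over the repertoire minus one named interactome."""
    names = [net.name for net in interactomes]
    if held_out_name not in names:
        raise EnrichmentError(f"held-out network {held_out_name!r} not in {names}")
    rest = [net for net in interactomes if net.name != held_out_name]
    if not rest:
        raise EnrichmentError("removing the held-out network leaves an empty repertoire")
    return metaviper(
        signature, rest, method=method, seed=seed, min_targets=min_targets
    )
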