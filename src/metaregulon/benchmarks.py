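"""Evaluation procedures, runnable on synthetic or user-supplied data.

Four benchmark families:

* **mutation association** — does inferred activity of a protein separate
  samples carrying recurrent mutations of its gene from the rest?  Each
  protein's activity-across-samples vector is treated as a signature and
  its mutated-sample set as an all-positive regulon, scored with the same
  enrichment engine (min_targets 3); the curve reports the fraction of
  proteins significant at ``p_cutoff`` versus a minimum-recurrence
  threshold, pooled across all samples.
* **orphan holdout** — per-sample Pearson correlation between integrated
  activity with the full repertoire and with the matched network held
  out; high correlation means orphan tissues lose little.
* **synthetic bulk / recapitulation** — average random groups of single
  cells into synthetic bulk profiles, take the top-k differential
  features between two clusters, and count per cell how many are
  recapitulated (same sign, nominal p) against the opposing bulk;
  activity-mode curves dominating expression-mode curves is the dropout
  robustness claim.
* **virtual FACS** — two-feature gating of single cells from an activity
  (or expression) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import pearsonr

from .enrichment import (
    DEFAULT_MIN_TARGETS,
    ActivityMatrix,
    EnrichmentError,
    nes_for_regulon,
)
from .interactome import Interactome, Regulon, ValidationError
from .matrices import ExpressionMatrix, MutationMatrix
from .metaviper import IntegrationResult, leave_one_out, metaviper
from .signatures import GeneSignature


# ---------------------------------------------------------------------------
# mutation association
# ---------------------------------------------------------------------------

@dataclass
class AssociationCurve:
    """Fraction of proteins with activity-mutation association vs recurrence."""

    recurrence_thresholds: list[int]
    fraction_significant: list[float]
    n_proteins_tested: list[int]
    p_cutoff: float
    per_protein: pd.DataFrame = field(default_factory=pd.DataFrame)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "min_recurrence": self.recurrence_thresholds,
                "fraction_significant": self.fraction_significant,
                "n_proteins_tested": self.n_proteins_tested,
            }
        )


def mutation_association(
    activity: ActivityMatrix,
    mutations: MutationMatrix,
    min_recurrence_list: Sequence[int] = (3, 5, 10, 15, 20),
    p_cutoff: float = 0.01,
    min_targets: int = 3,
) -> AssociationCurve:
    """Associate per-protein activity with recurrent mutations of its gene.

    For every protein mutated in at least ``min(min_recurrence_list)``
    shared samples, the mutated-sample set (modes +1, likelihood 1) is
    scored against the protein's activity vector with the enrichment
    engine; the curve gives, per threshold, the share of tested proteins
    with two-sided p below ``p_cutoff``.
    """
    thresholds = sorted(int(t) for t in min_recurrence_list)
    if not thresholds or thresholds[0] < min_targets:
        raise ValidationError(
            f"smallest recurrence threshold must be >= min_targets={min_targets}"
        )
    shared_proteins = activity.regulators.intersection(mutations.genes)
    shared_samples = activity.samples.intersection(mutations.samples)
    if len(shared_proteins) == 0 or len(shared_samples) == 0:
        raise ValidationError("no shared proteins/samples between activity and mutations")

    rows = []
    mut = mutations.data.loc[shared_proteins, shared_samples]
    act = activity.nes.loc[shared_proteins, shared_samples]
    for protein in shared_proteins:
        mutated = shared_samples[mut.loc[protein].to_numpy() == 1]
        recurrence = len(mutated)
        if recurrence < thresholds[0]:
            continue
        signature = act.loc[protein]
        if signature.nunique() < 2:
            continue  # degenerate activity row carries no ranking
        regulon = Regulon(
            regulator=protein,
            targets=np.asarray(mutated, dtype=object),
            mode=np.ones(recurrence),
            likelihood=np.ones(recurrence),
        )
        res = nes_for_regulon(signature, regulon, min_targets=min_targets)
        rows.append(
            {
                "protein": protein,
                "recurrence": recurrence,
                "nes": res.nes,
                "p_two_sided": res.p_two_sided,
            }
        )
    table = pd.DataFrame(rows)
    fractions: list[float] = []
    counts: list[int] = []
    for t in thresholds:
        sub = table[table["recurrence"] >= t] if len(table) else table
        counts.append(len(sub))
        fractions.append(
            float((sub["p_two_sided"] < p_cutoff).mean()) if len(sub) else float("nan")
        )
    if not len(table):
        import warnings

        warnings.warn("no protein reaches the smallest recurrence threshold")
    return AssociationCurve(
        recurrence_thresholds=thresholds,
        fraction_significant=fractions,
        n_proteins_tested=counts,
        p_cutoff=p_cutoff,
        per_protein=table,
    )


# ---------------------------------------------------------------------------
# orphan-tissue holdout
# ---------------------------------------------------------------------------

@dataclass
class HoldoutResult:
    """Per-sample correlation between full and leave-one-out integration."""

    per_sample_r: pd.Series
    held_out: str
    method: str
    dropped_samples: list = field(default_factory=list)
    full: IntegrationResult | None = None
    reduced: IntegrationResult | None = None

    @property
    def median_r(self) -> float:
        return float(self.per_sample_r.median())

    def summary(self) -> pd.Series:
        return self.per_sample_r.describe()


def orphan_holdout(
    signature: GeneSignature,
    interactomes: Sequence[Interactome],
    matched_name: str,
    method: str = "NESScore",
    min_targets: int = DEFAULT_MIN_TARGETS,
    min_shared_proteins: int = 10,
) -> HoldoutResult:
    """Correlate integrated activity with and without the matched network.

    Per sample, Pearson r over the proteins scored by both analyses;
    samples with fewer than ``min_shared_proteins`` shared proteins are
    dropped with a warning.  When the held-out network contributed
    nothing the two profiles are bitwise identical and r is exactly 1.
    """
    full = metaviper(signature, interactomes, method=method, min_targets=min_targets)
    reduced = leave_one_out(
        signature, interactomes, matched_name, method=method, min_targets=min_targets
    )
    shared = full.nes.index.intersection(reduced.nes.index)
    x_all = full.nes.loc[shared]
    y_all = reduced.nes.loc[shared]
    r_by_sample: dict[str, float] = {}
    dropped: list[str] = []
    for sample in signature.samples:
        x = x_all[sample].to_numpy()
        y = y_all[sample].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_shared_proteins:
            dropped.append(sample)
            continue
        xs, ys = x[ok], y[ok]
        if np.array_equal(xs, ys):
            r_by_sample[sample] = 1.0  # identical profiles: exact by definition
        else:
            r_by_sample[sample] = float(pearsonr(xs, ys).statistic)
    if dropped:
        import warnings

        warnings.warn(f"dropped {len(dropped)} samples with < {min_shared_proteins} shared proteins")
    return HoldoutResult(
        per_sample_r=pd.Series(r_by_sample, dtype=float),
        held_out=matched_name,
        method=method,
        dropped_samples=dropped,
        full=full,
        reduced=reduced,
    )


# ---------------------------------------------------------------------------
# synthetic bulk + recapitulation
# ---------------------------------------------------------------------------

def synthetic_bulk(
    cells: ExpressionMatrix,
    labels: pd.Series | Sequence[str],
    n_cells: int = 100,
    n_replicates: int = 5,
    seed: int | None = None,
    clusters: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Average random groups of cells into synthetic bulk replicates.

    Each replicate is the per-gene mean of ``n_cells`` cells drawn without
    replacement from one cluster (with replacement when the cluster is
    smaller, flagged).  Columns are named ``<cluster>|rep<i>``.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=cells.samples)
    if clusters is None:
        clusters = list(dict.fromkeys(labels))
    else:
        unknown = [c for c in clusters if c not in set(labels)]
        if unknown:
            raise ValidationError(f"unknown cluster label(s): {unknown}")
    rng = np.random.default_rng(seed)
    values = cells.values
    cols: dict[str, np.ndarray] = {}
    flagged: list[str] = []
    for cluster in clusters:
        members = np.flatnonzero((labels == cluster).to_numpy())
        replace = members.size < n_cells
        if replace:
            flagged.append(str(cluster))
        for rep in range(1, n_replicates + 1):
            chosen = rng.choice(members, size=n_cells, replace=replace)
            cols[f"{cluster}|rep{rep}"] = values[:, chosen].mean(axis=1)
    bulk = ExpressionMatrix(
        pd.DataFrame(cols, index=cells.genes), layer_tag=cells.layer_tag
    )
    return bulk, flagged


def differential_top_k(
    profiles: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    k: int = 100,
) -> pd.DataFrame:
    """Top-k features by two-sample z (difference of means / pooled SE).

    Returns a DataFrame indexed by feature with columns ``z`` and ``sign``
    (the sign of the a-minus-b difference), sorted by |z| descending;
    features with zero pooled variance get z = 0 and sort last.
    """
    a = profiles.loc[:, list(group_a)].to_numpy(dtype=float)
    b = profiles.loc[:, list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("need >= 2 columns per group")
    pooled_var = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
        na + nb - 2
    )
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    table = pd.DataFrame({"z": z, "sign": np.sign(z)}, index=profiles.index)
    table["absz"] = np.abs(table["z"])
    table = table.sort_values(["absz", "z"], ascending=[False, False], kind="stable")
    if k > len(table):
        import warnings

        warnings.warn(f"k={k} exceeds {len(table)} features; truncating")
        k = len(table)
    return table.head(k).drop(columns="absz")


@dataclass
class RecapitulationCurve:
    """Per-cell fraction of top-k bulk features recapitulated."""

    per_cell_fraction: pd.Series
    mode: str  # "single" | "pair"
    k: int
    p_cutoff: float
    missing_features: list = field(default_factory=list)

    def one_minus_ecdf(self, grid: np.ndarray) -> np.ndarray:
        """Fraction of cells recapitulating at least x of the features."""
        frac = self.per_cell_fraction.to_numpy()
        return np.array([(frac >= x).mean() for x in np.asarray(grid, dtype=float)])


def recapitulation_curve(
    single_profiles: pd.DataFrame,
    other_cluster_bulk: pd.DataFrame,
    top_features: pd.DataFrame,
    mode: str = "single",
    p_cutoff: float = 0.05,
) -> RecapitulationCurve:
    """Count, per cell, the top bulk features recapitulated vs another bulk.

    A feature is recapitulated in a cell when its cell-minus-bulk
    difference has the bulk sign and the one-vs-group z test (using the
    bulk replicates' dispersion) is nominally significant at
    ``p_cutoff``.  Features missing from the cell profiles count as not
    recapitulated (dropout semantics).  ``pair`` mode requires both
    members of a feature pair to be recapitulated and reports the
    fraction over all C(k, 2) pairs.
    """
    if mode not in ("single", "pair"):
        raise ValidationError(f"unknown mode {mode!r}")
    features = list(top_features.index)
    k = len(features)
    if k == 0:
        raise ValidationError("empty top-feature list")
    signs = top_features["sign"].to_numpy(dtype=float)
    present = [f for f in features if f in single_profiles.index and f in other_cluster_bulk.index]
    missing = [f for f in features if f not in present]

    recap = np.zeros((k, single_profiles.shape[1]), dtype=bool)
    if present:
        pos = [features.index(f) for f in present]
        bulk = other_cluster_bulk.loc[present].to_numpy(dtype=float)
        n_rep = bulk.shape[1]
        center = bulk.mean(axis=1)
        sd = bulk.std(axis=1, ddof=1)
        se = sd * np.sqrt(1.0 + 1.0 / n_rep)
        x = single_profiles.loc[present].to_numpy(dtype=float)
        diff = x - center[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            zcell = np.where(se[:, None] > 0, diff / np.where(se[:, None] > 0, se[:, None], 1.0), np.inf * np.sign(diff))
        p = 2.0 * (1.0 - ndtr(np.abs(zcell)))
        sign_match = np.sign(diff) == signs[pos, None]
        recap[pos, :] = sign_match & (p < p_cutoff) & (diff != 0)

    m = recap.sum(axis=0).astype(float)
    if mode == "single":
        frac = m / k
    else:
        n_pairs = k * (k - 1) / 2.0
        frac = (m * (m - 1) / 2.0) / n_pairs
    return RecapitulationCurve(
        per_cell_fraction=pd.Series(frac, index=single_profiles.columns),
        mode=mode,
        k=k,
        p_cutoff=p_cutoff,
        missing_features=missing,
    )


# ---------------------------------------------------------------------------
# virtual FACS
# ---------------------------------------------------------------------------

@dataclass
class FacsResult:
    """Two-marker gating of single cells."""

    coords: pd.DataFrame  # cells x (x, y)
    gate_counts: pd.DataFrame  # rows x+/x-, cols y+/y-
    feature_x: str
    feature_y: str
    thresholds: tuple[float, float]

    def gate_members(self, gate: str) -> list[str]:
        """Cells in a gate named like 'x+y-'."""
        tx, ty = self.thresholds
        gx = self.coords["x"] > tx if "x+" in gate else self.coords["x"] <= tx
        gy = self.coords["y"] > ty if "y+" in gate else self.coords["y"] <= ty
        return list(self.coords.index[gx & gy])


def virtual_facs(
    matrix: pd.DataFrame,
    feature_x: str,
    feature_y: str,
    thresholds: tuple[float, float] = (0.0, 0.0),
) -> FacsResult:
    """Gate cells on two features of an activity or expression matrix."""
    for f in (feature_x, feature_y):
        if f not in matrix.index:
            preview = ", ".join(map(str, matrix.index[:10]))
            raise ValidationError(
                f"feature {f!r} not in matrix; available (first 10): {preview}"
            )
    tx, ty = thresholds
    x = matrix.loc[feature_x].to_numpy(dtype=float)
    y = matrix.loc[feature_y].to_numpy(dtype=float)
    coords = pd.DataFrame({"x": x, "y": y}, index=matrix.columns)
    xp, yp = x > tx, y > ty
    counts = pd.DataFrame(
        [
            [int((xp & yp).sum()), int((xp & ~yp).sum())],
            [int((~xp & yp).sum()), int((~xp & ~yp).sum())],
        ],
        index=pd.Index(["x+", "x-"], name=feature_x),
        columns=pd.Index(["y+", "y-"], name=feature_y),
    )
    return FacsResult(
        coords=coords,
        gate_counts=counts,
        feature_x=feature_x,
        feature_y=feature_y,
        thresholds=(float(tx), float(ty)),
    )
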