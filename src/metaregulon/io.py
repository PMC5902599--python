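"""Readers and writers for regulon tables, expression/mutation matrices,
signatures and activity matrices; import of ARACNe-style network output.

All on-disk formats are plain text:

* regulon table — TSV with header ``regulator\ttarget\tmode\tlikelihood``;
* expression — dense TSV (gene column + sample-ID header) or Matrix
  Market triplet (.mtx) with ``genes.txt`` / ``barcodes.txt`` label files;
* mutation matrix — 0/1 TSV, genes x samples;
* signatures — dense TSV with a ``# method=`` comment header;
* activity — dense TSV plus a sidecar TSV of per-regulator target counts
  and source tags.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix
from scipy.stats import spearmanr

from .enrichment import ActivityMatrix
from .interactome import Interactome, Regulon, ValidationError
from .matrices import ExpressionMatrix, MutationMatrix
from .signatures import GeneSignature

logger = logging.getLogger("metaregulon")

REGULON_COLUMNS = ["regulator", "target", "mode", "likelihood"]


class FormatError(ValidationError):
    pass


# ---------------------------------------------------------------------------
# regulon tables
# ---------------------------------------------------------------------------

def read_regulon_table(path: str | Path, name: str | None = None) -> Interactome:
    """Read a 4-column regulon TSV into an Interactome.

    Rows with identical (regulator, target) are collapsed keeping the
    maximum likelihood; values are validated against the regulon
    invariants with the offending row number reported.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(table.columns) != REGULON_COLUMNS:
        raise FormatError(
            f"{path}: expected header {REGULON_COLUMNS}, got {list(table.columns)}"
        )
    table["__row"] = np.arange(2, len(table) + 2)  # 1-based file rows incl. header
    bad_mode = ~table["mode"].between(-1, 1) | ~np.isfinite(table["mode"])
    if bad_mode.any():
        row = int(table.loc[bad_mode, "__row"].iloc[0])
        raise ValidationError(f"{path}: mode outside [-1, 1] at file row {row}")
    bad_lik = (
        ~np.isfinite(table["likelihood"])
        | (table["likelihood"] <= 0)
        | (table["likelihood"] > 1)
    )
    if bad_lik.any():
        row = int(table.loc[bad_lik, "__row"].iloc[0])
        raise ValidationError(f"{path}: likelihood outside (0, 1] at file row {row}")

    # duplicate (regulator, target): keep the max-likelihood row
    table = table.sort_values("likelihood", kind="stable").drop_duplicates(
        ["regulator", "target"], keep="last"
    ).sort_values("__row", kind="stable")

    regulons: dict[str, Regulon] = {}
    for regulator, grp in table.groupby("regulator", sort=False):
        regulons[str(regulator)] = Regulon(
            regulator=str(regulator),
            targets=grp["target"].to_numpy(dtype=object),
            mode=grp["mode"].to_numpy(dtype=float),
            likelihood=grp["likelihood"].to_numpy(dtype=float),
        )
    return Interactome(name=name or path.stem, regulons=regulons)


def write_regulon_table(interactome: Interactome, path: str | Path) -> None:
    """Write an interactome as a 4-column TSV (round-trips with the reader)."""
    rows = [
        (reg.regulator, t, m, w)
        for reg in interactome
        for t, m, w in zip(reg.targets, reg.mode, reg.likelihood)
    ]
    pd.DataFrame(rows, columns=REGULON_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def import_aracne(
    network_path: str | Path,
    expr: ExpressionMatrix,
    min_targets: int = 25,
    name: str | None = None,
) -> Interactome:
    """Import a 3-column (regulator, target, MI) network file.

    Modes are estimated as the Spearman rank correlation between
    regulator and target expression across the samples of ``expr``;
    likelihoods are each edge's mutual information divided by the maximum
    MI within its regulon (so every regulon's top edge has likelihood 1).
    Edges whose regulator or target is absent from ``expr`` are dropped
    with a logged count; regulons left with fewer than ``min_targets``
    targets are dropped and reported in the log.
    """
    network_path = Path(network_path)
    net = pd.read_csv(network_path, sep="\t", dtype={0: str, 1: str})
    if net.shape[1] != 3:
        raise FormatError(f"{network_path}: expected 3 columns, got {net.shape[1]}")
    net.columns = ["regulator", "target", "mi"]
    if (net["mi"] < 0).any() or not np.isfinite(net["mi"]).all():
        raise ValidationError(f"{network_path}: negative or non-finite mutual information")

    known = set(expr.genes)
    usable = net["regulator"].isin(known) & net["target"].isin(known)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "import_aracne: dropped %d edges with regulator/target absent from expression",
            n_dropped,
        )
    net = net[usable]
    # collapse duplicate edges, keeping the max MI
    net = (
        net.sort_values("mi", kind="stable")
        .drop_duplicates(["regulator", "target"], keep="last")
        .sort_values(["regulator", "target"], kind="stable")
    )

    values = expr.data
    regulons: dict[str, Regulon] = {}
    dropped_regulons: list[str] = []
    for regulator, grp in net.groupby("regulator", sort=True):
        if len(grp) < min_targets:
            dropped_regulons.append(str(regulator))
            continue
        reg_expr = values.loc[regulator].to_numpy(dtype=float)
        modes = np.empty(len(grp))
        for i, target in enumerate(grp["target"]):
            rho = spearmanr(reg_expr, values.loc[target].to_numpy(dtype=float)).statistic
            modes[i] = 0.0 if np.isnan(rho) else rho
        mi = grp["mi"].to_numpy(dtype=float)
        max_mi = mi.max()
        if max_mi <= 0:
            dropped_regulons.append(str(regulator))
            continue
        regulons[str(regulator)] = Regulon(
            regulator=str(regulator),
            targets=grp["target"].to_numpy(dtype=object),
            mode=modes,
            likelihood=mi / max_mi if mi.min() > 0 else np.maximum(mi / max_mi, 1e-12),
        )
    if dropped_regulons:
        logger.warning(
            "import_aracne: dropped %d regulons below min_targets=%d: %s",
            len(dropped_regulons),
            min_targets,
            ", ".join(dropped_regulons[:10]),
        )
    return Interactome(
        name=name or network_path.stem,
        regulons=regulons,
        provenance=f"imported from {network_path.name}; {n_dropped} edges dropped",
    )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    dialect: str = "dense-tsv",
    layer_tag: str = "normalized",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix (dense TSV or Matrix Market triplet).

    For the sparse dialect, ``genes_path``/``barcodes_path`` default to
    ``genes.txt`` / ``barcodes.txt`` next to the .mtx file.
    """
    path = Path(path)
    if dialect == "dense-tsv":
        table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return ExpressionMatrix(table, layer_tag=layer_tag)
    if dialect == "sparse-triplet":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.txt"
        barcodes_path = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.txt"
        genes = genes_path.read_text().split()
        barcodes = barcodes_path.read_text().split()
        mat = mmread(path).tocoo()
        if mat.shape[0] != len(genes) or mat.shape[1] != len(barcodes):
            raise FormatError(
                f"{path}: declared shape {mat.shape} does not match label files "
                f"({len(genes)} genes, {len(barcodes)} barcodes)"
            )
        dense = np.asarray(mat.todense(), dtype=float)
        return ExpressionMatrix(
            pd.DataFrame(dense, index=pd.Index(genes), columns=pd.Index(barcodes)),
            layer_tag=layer_tag,
        )
    raise FormatError(f"unknown dialect {dialect!r}")


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    dialect: str = "dense-tsv",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> None:
    path = Path(path)
    if dialect == "dense-tsv":
        expr.data.to_csv(path, sep="\t", float_format="%.10g")
        return
    if dialect == "sparse-triplet":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.txt"
        barcodes_path = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.txt"
        mmwrite(path, coo_matrix(expr.values), precision=10)
        genes_path.write_text("\n".join(map(str, expr.genes)) + "\n")
        barcodes_path.write_text("\n".join(map(str, expr.samples)) + "\n")
        return
    raise FormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# mutation matrices
# ---------------------------------------------------------------------------

def read_mutations(path: str | Path) -> MutationMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return MutationMatrix(table)


def write_mutations(mutations: MutationMatrix, path: str | Path) -> None:
    mutations.data.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def read_signature(path: str | Path) -> GeneSignature:
    path = Path(path)
    method = "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# method="):
            method = first.strip().split("=", 1)[1]
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return GeneSignature(table, method_tag=method)


def write_signature(signature: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# method={signature.method_tag}\n")
        signature.data.to_csv(fh, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# activity matrices
# ---------------------------------------------------------------------------

def write_activity(activity: ActivityMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write NES TSV plus a sidecar of target counts and source tags."""
    prefix = Path(prefix)
    nes_path = prefix.with_suffix(".nes.tsv")
    meta_path = prefix.with_suffix(".meta.tsv")
    activity.nes.to_csv(nes_path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {
            "n_targets_used": activity.n_targets.reindex(activity.regulators),
            "source": activity.source,
            "method": activity.method_tag,
        }
    )
    meta.index.name = "regulator"
    meta.to_csv(meta_path, sep="\t")
    return nes_path, meta_path


def read_activity(nes_path: str | Path, meta_path: str | Path | None = None) -> ActivityMatrix:
    nes = pd.read_csv(nes_path, sep="\t", index_col=0)
    n_targets = pd.Series(0, index=nes.index, dtype=int)
    source, method = "unknown", "unknown"
    if meta_path is not None and Path(meta_path).exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        n_targets = meta["n_targets_used"].astype(int)
        source = str(meta["source"].iloc[0])
        method = str(meta["method"].iloc[0])
    return ActivityMatrix(nes=nes, n_targets=n_targets, source=source, method_tag=method)
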