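"""Reading and writing the package's on-disk formats.

Matrices travel as labeled CSV/TSV (header row of column labels, first
column of row labels); counts additionally as MTX triplets; stratification
profiles as museum-style JSON; fit results as factor CSVs plus a JSON
metadata sidecar; edge lists as four-column TSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    BilinearFactors,
    CellFeatureMatrix,
    ConnectivityMatrix,
    FitConfig,
    FitResult,
    TypeFeatureMatrix,
    WeightMatrix,
)
from .preprocess import CountMatrix
from .scm import EdgeList


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_labeled_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    return df


def write_labeled_matrix(values, row_ids, col_ids, path) -> None:
    pd.DataFrame(np.asarray(values), index=row_ids, columns=col_ids) \
        .to_csv(path, sep=_sep(path))


def read_cell_matrix(path, labels_path=None) -> CellFeatureMatrix:
    """Cells x features CSV/TSV; optional sidecar mapping cell_id -> type."""
    df = read_labeled_matrix(path)
    type_labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep=_sep(labels_path), index_col=0)
        mapping = lab.iloc[:, 0].to_dict()
        missing = [c for c in df.index if c not in mapping]
        if missing:
            raise ValueError(f"{labels_path}: no type label for cells {missing[:5]}")
        type_labels = [mapping[c] for c in df.index]
    return CellFeatureMatrix(df.values, cell_ids=list(df.index),
                             type_labels=type_labels or [],
                             feature_ids=list(df.columns))


def write_cell_matrix(X: CellFeatureMatrix, path, labels_path=None) -> None:
    write_labeled_matrix(X.values, X.cell_ids, X.feature_ids, path)
    if labels_path is not None:
        pd.DataFrame({"type": X.type_labels}, index=pd.Index(X.cell_ids, name="cell_id")) \
            .to_csv(labels_path, sep=_sep(labels_path))


def read_type_matrix(path, scale_applied: bool = False) -> TypeFeatureMatrix:
    df = read_labeled_matrix(path)
    return TypeFeatureMatrix(df.values, type_ids=list(df.index),
                             feature_ids=list(df.columns),
                             scale_applied=scale_applied)


def write_type_matrix(T: TypeFeatureMatrix, path) -> None:
    write_labeled_matrix(T.values, T.type_ids, T.feature_ids, path)


def read_connectivity(path, level: str = "cell") -> ConnectivityMatrix:
    df = read_labeled_matrix(path)
    return ConnectivityMatrix(df.values, pre_ids=list(df.index),
                              post_ids=[str(c) for c in df.columns], level=level)


def write_connectivity(Z: ConnectivityMatrix, path) -> None:
    write_labeled_matrix(Z.values, Z.pre_ids, Z.post_ids, path)


def read_weight_matrix(path) -> WeightMatrix:
    return WeightMatrix(read_labeled_matrix(path).values)


def write_weight_matrix(W: WeightMatrix, path, row_ids=None, col_ids=None) -> None:
    n, m = W.shape
    write_labeled_matrix(W.values, row_ids or range(n), col_ids or range(m), path)


def read_counts_mtx(mtx_path, cells_path, genes_path,
                    labels_path=None) -> CountMatrix:
    """MTX triplet: matrix (cells x genes), row labels, column labels."""
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    cells = Path(cells_path).read_text().split()
    genes = Path(genes_path).read_text().split()
    type_labels = []
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep=_sep(labels_path), index_col=0)
        mapping = lab.iloc[:, 0].to_dict()
        type_labels = [mapping[c] for c in cells]
    return CountMatrix(np.asarray(mat), cell_ids=cells, gene_ids=genes,
                       type_labels=type_labels)


def read_counts_csv(path, labels_path=None) -> CountMatrix:
    df = read_labeled_matrix(path)
    type_labels = []
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep=_sep(labels_path), index_col=0)
        mapping = lab.iloc[:, 0].to_dict()
        type_labels = [mapping[c] for c in df.index]
    return CountMatrix(df.values, cell_ids=list(df.index),
                       gene_ids=list(df.columns), type_labels=type_labels)


def read_alignment_table(path) -> dict:
    """Two-column table: transcriptomic_type -> connectomic_type."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: alignment table needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_edge_list(path) -> EdgeList:
    """TSV with columns pre_id, post_id, connectivity, contact."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"pre_id", "post_id", "connectivity", "contact"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    return EdgeList(pre_cells=df["pre_id"].astype(str).tolist(),
                    post_cells=df["post_id"].astype(str).tolist(),
                    observed=df["connectivity"].to_numpy(float),
                    in_contact=df["contact"].to_numpy(bool))


def write_edge_list(edges: EdgeList, path) -> None:
    pd.DataFrame({
        "pre_id": edges.pre_cells,
        "post_id": edges.post_cells,
        "connectivity": edges.observed,
        "contact": edges.in_contact.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_stratification_json(path):
    """Museum-style JSON: a list of per-cell records."""
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ValueError(f"{path}: expected a JSON array of cell records")
    return records


def write_stratification_json(records, path) -> None:
    with open(path, "w") as fh:
        json.dump(records, fh)


def save_fit_result(result: FitResult, outdir, pre_feature_ids=None,
                    post_feature_ids=None) -> None:
    """Serialize a FitResult as factor CSVs plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = result.factors.d
    cols = [f"dim{k + 1}" for k in range(d)]
    p, q = result.factors.A.shape[0], result.factors.B.shape[0]
    write_labeled_matrix(result.factors.A,
                         pre_feature_ids or [f"f{m}" for m in range(p)],
                         cols, outdir / "factor_A.csv")
    write_labeled_matrix(result.factors.B,
                         post_feature_ids or [f"f{m}" for m in range(q)],
                         cols, outdir / "factor_B.csv")
    meta = {
        "config": asdict(result.config),
        "n_iter": result.n_iter,
        "final_loss": float(result.loss_trajectory[-1]),
        "converged": bool(result.converged),
    }
    with open(outdir / "fit_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_fit_result(outdir) -> FitResult:
    outdir = Path(outdir)
    A = read_labeled_matrix(outdir / "factor_A.csv").values
    B = read_labeled_matrix(outdir / "factor_B.csv").values
    with open(outdir / "fit_metadata.json") as fh:
        meta = json.load(fh)
    return FitResult(
        factors=BilinearFactors(A, B),
        loss_trajectory=np.array([meta["final_loss"]]),
        converged=meta["converged"],
        n_iter=meta["n_iter"],
        config=FitConfig(**meta["config"]),
    )


def write_discrepancy_report(report, outdir, row_ids=None, col_ids=None) -> None:
    """Write DS values as labeled CSV and the flags as a separate boolean CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n, m = report.ds_values.shape
    rows = row_ids or [f"r{i}" for i in range(n)]
    cols = col_ids or [f"c{j}" for j in range(m)]
    write_labeled_matrix(report.ds_values, rows, cols, outdir / "ds_values.csv")
    write_labeled_matrix(report.flagged.astype(int), rows, cols,
                         outdir / "ds_flags.csv")
    with open(outdir / "ds_thresholds.json", "w") as fh:
        json.dump({"ds_threshold": report.thresholds[0],
                   "magnitude_floor": report.thresholds[1]}, fh)


def load_celegans_dataset(expression_path, connectivity_path, contact_path):
    """Load a neuron-level gap-junction dataset from labeled CSV/TSV files.

    ``expression_path``: neurons x genes matrix; ``connectivity_path`` and
    ``contact_path``: neurons x neurons matrices on the same neuron order.
    Returns (X, Z, contact) as package containers.
    """
    X = read_cell_matrix(expression_path)
    # each neuron is its own type
    X.type_labels = list(X.cell_ids)
    Z = read_connectivity(connectivity_path, level="cell")
    Wdf = read_labeled_matrix(contact_path)
    if list(Z.pre_ids) != list(X.cell_ids) or list(Wdf.index) != list(X.cell_ids):
        raise ValueError("expression, connectivity and contact matrices must "
                         "share the same neuron order")
    return X, Z, WeightMatrix(Wdf.values)


def validate_celegans_metadata(X, contact: WeightMatrix) -> dict:
    """Dataset summary: neuron count and number of unordered contact pairs.

    Contact is undirected, so pairs are counted above the diagonal of the
    symmetrized mask (self-contacts excluded).
    """
    C = contact.values > 0
    C = C | C.T
    n_pairs = int(np.triu(C, k=1).sum())
    return {"n_neurons": X.n_cells, "n_contact_pairs": n_pairs}
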