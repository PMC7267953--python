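"""Delimited-text readers and writers for every pipeline artifact.

All formats are TSV: coordinates (node_id, x, y, z), square symmetric
matrices (header row/index = node ids), node partitions (node_id, label),
expression matrices (rows = node ids, columns = gene ids), edge
classifications (node_i, node_j, class) and Betti curves (density,
beta0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .homology import BettiCurve
from .nng import EdgeClassification

__all__ = [
    "read_coords", "write_coords",
    "read_matrix", "write_matrix",
    "read_partition", "write_partition",
    "read_expression", "write_expression",
    "read_classification", "write_classification",
    "write_betti_curve",
]


def write_coords(path, coords: np.ndarray) -> None:
    df = pd.DataFrame(np.asarray(coords, dtype=float),
                      columns=["x", "y", "z"])
    df.insert(0, "node_id", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def read_coords(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").sort_values("node_id")
    return df[["x", "y", "z"]].to_numpy()


def write_matrix(path, M: np.ndarray) -> None:
    n = M.shape[0]
    pd.DataFrame(M, index=np.arange(n), columns=np.arange(n)).to_csv(
        path, sep="\t"
    )


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()


def write_partition(path, labels) -> None:
    pd.DataFrame({"node_id": np.arange(len(labels)),
                  "label": labels}).to_csv(path, sep="\t", index=False)


def read_partition(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").sort_values("node_id")
    return df["label"].to_numpy()


def write_expression(path, X: pd.DataFrame) -> None:
    X = X.copy()
    X.index.name = "node_id"
    X.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_classification(path, cls: EdgeClassification) -> None:
    rows = (
        [(i, j, "optimal") for i, j in sorted(cls.optimal)]
        + [(i, j, "nonoptimal") for i, j in sorted(cls.nonoptimal)]
        + [(i, j, "false_positive") for i, j in sorted(cls.false_positive)]
    )
    pd.DataFrame(rows, columns=["node_i", "node_j", "class"]).to_csv(
        path, sep="\t", index=False
    )


def read_classification(path) -> EdgeClassification:
    df = pd.read_csv(path, sep="\t")
    groups = {name: set() for name in
              ("optimal", "nonoptimal", "false_positive")}
    for _, row in df.iterrows():
        groups[row["class"]].add((int(row["node_i"]), int(row["node_j"])))
    return EdgeClassification(
        optimal=groups["optimal"],
        nonoptimal=groups["nonoptimal"],
        false_positive=groups["false_positive"],
        n_nng_edges=len(groups["optimal"]) + len(groups["false_positive"]),
    )


def write_betti_curve(path, curve: BettiCurve) -> None:
    pd.DataFrame({"density": curve.densities,
                  "beta0": curve.beta0}).to_csv(path, sep="\t", index=False)
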