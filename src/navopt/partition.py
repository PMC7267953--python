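"""Distribution of optimal connections over a node partition.

Given an edge classification and a partition of nodes into networks
(e.g. the seven canonical cortical networks), compute the fraction of
intra- and inter-network structural connections that are game-optimal,
and the per-node regional optimality (RO) score.

False-positive edges are excluded throughout: they do not exist in the
real network, so they enter no denominator.  Zero denominators are
reported as NaN ("no edges" is not "no optimal edges").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nng import EdgeClassification

__all__ = ["ROVector", "intra_ratios", "inter_ratios", "regional_optimality"]


@dataclass
class ROVector:
    """Per-node regional optimality.

    raw = optimal degree − nonoptimal degree; normalized = raw divided by
    total structural degree (in [−1, 1]); NaN for isolated nodes.
    """

    raw: np.ndarray
    normalized: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": np.arange(len(self.raw)),
             "raw": self.raw, "normalized": self.normalized}
        )


def _check_partition(partition, n: int) -> np.ndarray:
    partition = np.asarray(partition)
    if partition.shape[0] != n:
        raise ValueError("every node must carry a partition label")
    if pd.isna(partition).any():
        raise ValueError("unlabeled node in partition")
    return partition


def intra_ratios(
    cls: EdgeClassification, S: np.ndarray, partition
) -> pd.Series:
    """Per-label fraction of intra-network structural edges that are optimal."""
    S = np.asarray(S, dtype=float)
    partition = _check_partition(partition, S.shape[0])
    labels = np.unique(partition)
    structural = cls.optimal | cls.nonoptimal
    out = {}
    for lab in labels:
        intra = [e for e in structural
                 if partition[e[0]] == lab and partition[e[1]] == lab]
        opt = [e for e in intra if e in cls.optimal]
        out[lab] = len(opt) / len(intra) if intra else np.nan
    return pd.Series(out, name="intra_optimal_ratio")


def inter_ratios(
    cls: EdgeClassification, S: np.ndarray, partition
) -> tuple[pd.DataFrame, pd.Series]:
    """Label×label optimal-connection ratios over cross-network edges.

    Returns the symmetric table of pairwise ratios (unordered label
    pairs; NaN where no cross edges exist) and the per-label mean over
    its k−1 partners.
    """
    S = np.asarray(S, dtype=float)
    partition = _check_partition(partition, S.shape[0])
    labels = np.unique(partition)
    structural = cls.optimal | cls.nonoptimal
    table = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a_i, a in enumerate(labels):
        for b in labels[a_i + 1:]:
            cross = [e for e in structural
                     if {partition[e[0]], partition[e[1]]} == {a, b}]
            opt = [e for e in cross if e in cls.optimal]
            r = len(opt) / len(cross) if cross else np.nan
            table.loc[a, b] = table.loc[b, a] = r
    per_label = table.mean(axis=1, skipna=True)
    per_label.name = "mean_inter_optimal_ratio"
    return table, per_label


def regional_optimality(cls: EdgeClassification, S: np.ndarray) -> ROVector:
    """Per-node optimal minus nonoptimal degree, raw and degree-normalized."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    deg_opt = np.zeros(n)
    deg_non = np.zeros(n)
    for i, j in cls.optimal:
        deg_opt[i] += 1
        deg_opt[j] += 1
    for i, j in cls.nonoptimal:
        deg_non[i] += 1
        deg_non[j] += 1
    total = deg_opt + deg_non
    raw = deg_opt - deg_non
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(total > 0, raw / total, np.nan)
    return ROVector(raw=raw, normalized=normalized)
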