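"""Partial least squares of regional gene expression against regional
optimality.

The response y is the per-node normalized regional-optimality score and
the predictor block X is a ROI×gene expression matrix.  A PLS1 regression
extracts components (linear combinations of genes) that maximize
covariance with y; the first component is the reported one.  Significance
is assessed by permuting the ROI labels of y and recomputing the variance
explained in y by component 1, with the add-one permutation p-value
p = (1 + #{null ≥ observed}) / (1 + n_perm).  A 10-fold cross-validated
predictive R² per component count is reported as a diagnostic only; it
does not select the component.

Gene columns are z-scored by default (microarray scales are
heterogeneous); disable with ``scale=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = ["ExpressionPLS", "PLSResults", "pls_fit", "pls_permutation_test"]


def _prepare(X, y, scale: bool):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("rows of X must align with y")
    if np.ptp(y) == 0:
        raise ValueError("constant response y")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    yc = y - y.mean()
    return Xc, yc


def _component1_r2(Xc: np.ndarray, Yc: np.ndarray) -> np.ndarray:
    """Variance in y explained by PLS component 1, vectorized over the
    columns of Yc (each column a centered response).

    The first PLS1 weight vector is w ∝ Xᵀy; the score is t = Xw, and
    the variance explained is corr(t, y)².
    """
    W = Xc.T @ Yc                       # genes × responses
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    T = Xc @ (W / norms)                # rois × responses
    tn = np.linalg.norm(T, axis=0)
    yn = np.linalg.norm(Yc, axis=0)
    denom = np.maximum(tn * yn, 1e-300)
    r = np.einsum("ij,ij->j", T, Yc) / denom
    return r**2


class ExpressionPLS:
    """PLS1 model of gene expression vs regional optimality.

    Parameters
    ----------
    X : (rois, genes) expression matrix (array or DataFrame; column
        names become gene ids).
    y : (rois,) normalized regional-optimality vector.
    n_components : number of PLS components to extract.
    scale : z-score gene columns before fitting (default True).
    """

    def __init__(self, X, y, n_components: int = 2, scale: bool = True):
        if isinstance(X, pd.DataFrame):
            self.gene_ids = list(X.columns)
            X = X.to_numpy()
        else:
            X = np.asarray(X, dtype=float)
            self.gene_ids = [f"g{j}" for j in range(X.shape[1])]
        max_nc = min(X.shape[0] - 1, X.shape[1])
        if not 1 <= n_components <= max_nc:
            raise ValueError(f"n_components must be in [1, {max_nc}]")
        self.Xc, self.yc = _prepare(X, y, scale)
        self.n_components = int(n_components)
        self.scale = scale

    def fit(self) -> "PLSResults":
        pls = PLSRegression(n_components=self.n_components, scale=False)
        pls.fit(self.Xc, self.yc)
        T = pls.x_scores_
        # variance explained in y by components 1..j (nested OLS on scores)
        ss_y = float(self.yc @ self.yc)
        r2_cum = []
        for j in range(1, self.n_components + 1):
            beta, *_ = np.linalg.lstsq(T[:, :j], self.yc, rcond=None)
            resid = self.yc - T[:, :j] @ beta
            r2_cum.append(1.0 - float(resid @ resid) / ss_y)
        r2_cum = np.asarray(r2_cum)
        r2_per = np.diff(np.concatenate([[0.0], r2_cum]))
        # variance explained in X per component
        ss_x = float((self.Xc**2).sum())
        x_var = np.asarray([
            float((np.outer(T[:, j], pls.x_loadings_[:, j]) ** 2).sum()) / ss_x
            for j in range(self.n_components)
        ])
        rho, rho_p = stats.spearmanr(T[:, 0], self.yc)
        return PLSResults(
            model=self,
            _sk=pls,
            x_scores=T,
            y_loadings=pls.y_loadings_.ravel(),
            gene_weights=pls.x_weights_,
            y_variance_explained=r2_per,
            x_variance_explained=x_var,
            spearman_rho=float(rho),
            spearman_p=float(rho_p),
        )


@dataclass
class PLSResults:
    """Fitted components, variance decomposition and inference helpers."""

    model: ExpressionPLS
    _sk: PLSRegression = field(repr=False)
    x_scores: np.ndarray = field(repr=False)
    y_loadings: np.ndarray = field(repr=False)
    gene_weights: np.ndarray = field(repr=False)
    y_variance_explained: np.ndarray
    x_variance_explained: np.ndarray
    spearman_rho: float
    spearman_p: float

    @property
    def component1_scores(self) -> np.ndarray:
        return self.x_scores[:, 0]

    @property
    def component1_y_r2(self) -> float:
        return float(self.y_variance_explained[0])

    def ranked_genes(self) -> pd.DataFrame:
        """Component-1 gene weights, strongest first (for enrichment
        tools downstream)."""
        w = self.gene_weights[:, 0]
        order = np.argsort(-np.abs(w))
        return pd.DataFrame(
            {"gene": np.asarray(self.model.gene_ids)[order],
             "weight": w[order]}
        )

    def permutation_test(self, n_perm: int = 1000, seed: int = 0) -> float:
        """Permutation p for component 1 (see module docstring)."""
        return pls_permutation_test(
            self.model.Xc, self.model.yc, n_perm=n_perm, seed=seed,
            scale=False,
        )

    def cross_val_r2(self, n_splits: int = 10, seed: int = 0) -> np.ndarray:
        """10-fold predictive R² for 1..n_components components."""
        Xc, yc = self.model.Xc, self.model.yc
        out = []
        for nc in range(1, self.model.n_components + 1):
            press, ss = 0.0, 0.0
            kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
            for tr, te in kf.split(Xc):
                p = PLSRegression(n_components=nc, scale=False)
                p.fit(Xc[tr], yc[tr])
                pred = p.predict(Xc[te]).ravel()
                press += float(((yc[te] - pred) ** 2).sum())
                ss += float(((yc[te] - yc[tr].mean()) ** 2).sum())
            out.append(1.0 - press / ss)
        return np.asarray(out)

    def summary(self) -> str:
        lines = [
            "PLS: gene expression vs regional optimality",
            "=" * 46,
            f"ROIs: {self.model.Xc.shape[0]}   genes: {self.model.Xc.shape[1]}"
            f"   components: {self.model.n_components}",
            "",
            "comp   %var(y)   %var(X)",
        ]
        for j, (vy, vx) in enumerate(
            zip(self.y_variance_explained, self.x_variance_explained), 1
        ):
            lines.append(f"{j:4d}   {100*vy:7.2f}   {100*vx:7.2f}")
        lines += [
            "",
            f"component-1 Spearman rho vs y: {self.spearman_rho:.4f} "
            f"(p = {self.spearman_p:.3g})",
        ]
        return "\n".join(lines)


def pls_fit(X, y, n_components: int = 2, scale: bool = True) -> PLSResults:
    """Convenience wrapper: ``ExpressionPLS(X, y, n_components).fit()``."""
    return ExpressionPLS(X, y, n_components=n_components, scale=scale).fit()


def pls_permutation_test(
    X, y, n_perm: int = 1000, seed: int = 0, scale: bool = True
) -> float:
    """Permutation p-value for the component-1 variance explained in y.

    Rows of y are permuted ``n_perm`` times; the null statistic is the
    variance in (permuted) y explained by PLS component 1, and
    p = (1 + #{null ≥ observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Xc, yc = _prepare(X, y, scale)
    rng = np.random.default_rng(seed)
    observed = float(_component1_r2(Xc, yc[:, None])[0])
    Yp = np.column_stack(
        [yc[rng.permutation(len(yc))] for _ in range(n_perm)]
    )
    null = _component1_r2(Xc, Yp)
    return float((1 + np.sum(null >= observed)) / (1 + n_perm))
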