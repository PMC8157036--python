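"""Multiplicative decomposition of gene branch lengths.

The observed branch length of gene g on branch j is modelled as

    b_{g,j} = R_j * r_g * e_{g,j}

where R_j is the branch effect (genome-wide rate multiplier, driven by
generation length and mutagen exposure), r_g the gene effect (the gene's
level of functional constraint) and e_{g,j} the gene-branch interaction,
the residual rate fluctuation specific to one gene on one branch.  On the
log scale this is an additive two-way layout fitted by least squares:
row/column means for complete data, alternating row/column centering for
incomplete data.  Identifiability is fixed by mean_g log r_g = 0 and
mean_j log R_j = grand mean of log(b + eps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneBranchMatrix

logger = logging.getLogger(__name__)

__all__ = ["RateDecomposition", "InteractionFeatures", "decompose", "interaction_features"]


@dataclass
class RateDecomposition:
    """Branch effects, gene effects and gene-branch interactions.

    All three components are multiplicative (stored on the natural scale);
    ``log_interactions`` additionally exposes log e_{g,j} as genes x branches
    with NaN where the input was missing.
    """

    branch_effects: pd.Series  # R_j > 0, indexed by branch id
    gene_effects: pd.Series  # r_g > 0, indexed by gene id
    log_interactions: pd.DataFrame  # log e_{g,j}, genes x branches
    pseudocount: float
    n_iterations: int
    max_residual_change: float

    @property
    def interactions(self) -> pd.DataFrame:
        return np.exp(self.log_interactions)

    def reconstruct(self) -> pd.DataFrame:
        """R_j * r_g * e_{g,j} (equals b + pseudocount at observed cells)."""
        log_b = (
            self.log_interactions
            + np.log(self.branch_effects)
            + np.log(self.gene_effects).to_numpy()[:, None]
        )
        return np.exp(log_b)


@dataclass
class InteractionFeatures:
    """Standardized log-interaction feature matrix, branches x genes.

    Standardization constants are computed on ``fit_branches`` only and
    applied to every row, so ancestral branches share the terminal scale.
    """

    X: pd.DataFrame  # branches x genes, no missing entries
    fit_branches: list[str]
    means: pd.Series  # per-gene mean of filled log e over fit_branches
    sds: pd.Series  # per-gene sd (ddof=0) over fit_branches
    fill_policy: str
    standardized: bool = True
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.X.columns)

    @property
    def branches(self) -> list[str]:
        return list(self.X.index)


def _twoway_fit(Y: np.ndarray, tol: float = 1e-10, max_iter: int = 500):
    """Least-squares additive fit of an incomplete two-way layout.

    Alternating row/column centering (Gauss-Seidel on the normal equations);
    returns row effects, column effects and iteration diagnostics.  Fitted
    values alpha_g + beta_j are the unique least-squares fit even though the
    parametrization itself is only identified up to a constant.
    """
    obs = ~np.isnan(Y)
    G, J = Y.shape
    alpha = np.zeros(G)
    beta = np.zeros(J)
    Y0 = np.where(obs, Y, 0.0)
    row_n = obs.sum(axis=1)
    col_n = obs.sum(axis=0)
    it, change = 0, np.inf
    for it in range(1, max_iter + 1):
        new_alpha = (Y0 - np.where(obs, beta, 0.0)).sum(axis=1) / row_n
        new_beta = (Y0 - np.where(obs, new_alpha[:, None], 0.0)).sum(axis=0) / col_n
        change = max(
            np.abs(new_alpha - alpha).max(), np.abs(new_beta - beta).max()
        )
        alpha, beta = new_alpha, new_beta
        if change <= tol:
            break
    return alpha, beta, it, change


def decompose(
    M: GeneBranchMatrix,
    pseudocount: float = 1e-9,
    tol: float = 1e-10,
    max_iter: int = 500,
    method: str = "least-squares",
) -> RateDecomposition:
    """Decompose b_{g,j} into branch effect, gene effect and interaction.

    Parameters
    ----------
    M : GeneBranchMatrix
    pseudocount : float
        Added to every entry before the log so zero-length branches (common
        in gene trees) stay in the fit; recorded in the result.
    method : {"least-squares", "median-polish"}
        Median polish trades exact least-squares optimality for robustness
        to outlying cells.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    data = M.data.to_numpy(dtype=float)
    obs = ~np.isnan(data)
    empty_genes = [g for g, n in zip(M.genes, obs.sum(axis=1)) if n == 0]
    empty_branches = [b for b, n in zip(M.branches, obs.sum(axis=0)) if n == 0]
    if empty_genes:
        raise ValueError(f"genes with no observed entries: {empty_genes[:5]}")
    if empty_branches:
        raise ValueError(f"branches with no observed entries: {empty_branches[:5]}")

    Y = np.where(obs, np.log(data + pseudocount), np.nan)
    grand = np.nanmean(Y)

    if method == "median-polish":
        alpha, beta, it, change = _median_polish(Y, tol=tol, max_iter=max_iter)
    elif method == "least-squares":
        if obs.all():
            alpha = Y.mean(axis=1)
            beta = Y.mean(axis=0) - grand
            alpha = alpha - grand
            it, change = 1, 0.0
        else:
            alpha, beta, it, change = _twoway_fit(Y, tol=tol, max_iter=max_iter)
            if change > tol:
                raise RuntimeError(
                    f"two-way fit did not converge in {max_iter} iterations "
                    f"(last change {change:.3e})"
                )
    else:
        raise ValueError(f"unknown method {method!r}")

    # identification: mean log r = 0; mean log R = grand mean of log(b+eps)
    log_r = alpha - alpha.mean()
    log_R = beta - beta.mean() + grand
    log_e = Y - log_R[None, :] - log_r[:, None]

    return RateDecomposition(
        branch_effects=pd.Series(np.exp(log_R), index=M.branches, name="R"),
        gene_effects=pd.Series(np.exp(log_r), index=M.genes, name="r"),
        log_interactions=pd.DataFrame(log_e, index=M.genes, columns=M.branches),
        pseudocount=pseudocount,
        n_iterations=it,
        max_residual_change=float(change),
    )


def _median_polish(Y: np.ndarray, tol: float = 1e-10, max_iter: int = 500):
    obs = ~np.isnan(Y)
    alpha = np.zeros(Y.shape[0])
    beta = np.zeros(Y.shape[1])
    R = np.where(obs, Y, np.nan)
    change = np.inf
    for it in range(1, max_iter + 1):
        rm = np.nanmedian(R, axis=1)
        alpha = alpha + rm
        R = R - rm[:, None]
        cm = np.nanmedian(R, axis=0)
        beta = beta + cm
        R = R - cm[None, :]
        change = max(np.abs(rm).max(), np.abs(cm).max())
        if change <= tol:
            break
    return alpha, beta, it, change


def interaction_features(
    D: RateDecomposition,
    fit_branches: list[str],
    fill: str = "zero-log",
    standardize: bool = True,
) -> InteractionFeatures:
    """Arrange log interactions as a branches x genes feature matrix.

    Missing entries are filled before standardization: ``zero-log`` sets
    log e = 0 (no deviation, unbiased under the centering constraint);
    ``gene-mean`` uses the gene's mean log interaction over observed cells.
    Per-gene means and sds are computed on ``fit_branches`` only and applied
    to all branches.  Genes with zero variance on the fitting subset cannot
    be standardized and are dropped with a warning.
    """
    X = D.log_interactions.T.copy()  # branches x genes
    missing = [b for b in fit_branches if b not in X.index]
    if missing:
        raise KeyError(f"fit branches absent from decomposition: {missing[:5]}")
    if fill == "zero-log":
        X = X.fillna(0.0)
    elif fill == "gene-mean":
        X = X.fillna(X.mean(axis=0))
    else:
        raise ValueError(f"unknown fill policy {fill!r}")

    sub = X.loc[fit_branches]
    means = sub.mean(axis=0)
    sds = sub.std(axis=0, ddof=0)
    dropped = list(sds.index[sds == 0.0])
    if dropped:
        logger.warning(
            "%d genes dropped: zero variance on the fitting branches", len(dropped)
        )
        X = X.drop(columns=dropped)
        means = means.drop(index=dropped)
        sds = sds.drop(index=dropped)
    if standardize:
        X = (X - means) / sds
    return InteractionFeatures(
        X=X,
        fit_branches=list(fit_branches),
        means=means,
        sds=sds,
        fill_policy=fill,
        standardized=standardize,
        dropped_genes=dropped,
    )
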