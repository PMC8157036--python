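"""Sparse trait models on gene-branch interaction features.

Traits observed at terminal branches are regressed on the standardized log
interactions with an L1 (LASSO) penalty: continuous traits on the natural
log scale with squared-error loss, binary traits with logistic deviance.
The penalty shrinks non-informative genes exactly to zero, so the surviving
coefficients name the genes whose rate fluctuations track the trait.
Applying a fitted model to the interaction features of internal branches
predicts ancestral states; applying it to terminal branches with missing
observations imputes them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

from .decomposition import InteractionFeatures
from .io import TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "FittedTraitModel",
    "AncestralPrediction",
    "fit_continuous_trait",
    "fit_discrete_trait",
    "predict_branches",
    "impute_missing_terminals",
    "selected_genes",
]


@dataclass
class CVConfig:
    """Cross-validation settings for choosing the penalty strength."""

    folds: int = 10
    seed: int = 0
    one_se: bool = True
    n_alphas: int = 100


@dataclass
class FittedTraitModel:
    """A fitted sparse trait model.

    Coefficients are on the standardized-feature scale (features have unit
    sd on the fitting branches).  For continuous traits the response is the
    natural log of the trait; predictions are back-transformed with exp.
    """

    trait: str
    family: str  # "linear-on-log" | "logistic"
    intercept: float
    coef: pd.Series  # over genes, standardized scale
    penalty_lambda: float
    cv: CVConfig
    fit_branches: list[str]
    feature_means: pd.Series
    feature_sds: pd.Series
    transform: str = "log"  # "log" for continuous, "identity" for binary
    cv_rmse: float | None = None  # root mean CV error at the chosen penalty

    def n_selected(self) -> int:
        return int((self.coef != 0).sum())

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        Z = X[self.coef.index]
        return pd.Series(
            self.intercept + Z.to_numpy() @ self.coef.to_numpy(), index=X.index
        )

    # -- JSON round trip (CLI artifact format) -----------------------------

    def to_json(self, path: str | Path) -> None:
        obj = {
            "trait": self.trait,
            "family": self.family,
            "intercept": self.intercept,
            "genes": list(self.coef.index),
            "coef": [float(c) for c in self.coef],
            "penalty_lambda": self.penalty_lambda,
            "cv": {
                "folds": self.cv.folds,
                "seed": self.cv.seed,
                "one_se": self.cv.one_se,
                "n_alphas": self.cv.n_alphas,
            },
            "fit_branches": self.fit_branches,
            "feature_means": [float(m) for m in self.feature_means],
            "feature_sds": [float(s) for s in self.feature_sds],
            "transform": self.transform,
            "cv_rmse": self.cv_rmse,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedTraitModel":
        obj = json.loads(Path(path).read_text())
        genes = obj["genes"]
        return cls(
            trait=obj["trait"],
            family=obj["family"],
            intercept=obj["intercept"],
            coef=pd.Series(obj["coef"], index=genes),
            penalty_lambda=obj["penalty_lambda"],
            cv=CVConfig(**obj["cv"]),
            fit_branches=obj["fit_branches"],
            feature_means=pd.Series(obj["feature_means"], index=genes),
            feature_sds=pd.Series(obj["feature_sds"], index=genes),
            transform=obj["transform"],
            cv_rmse=obj.get("cv_rmse"),
        )


@dataclass
class AncestralPrediction:
    """Per-branch predictions of a trait on its original scale.

    Continuous: exp of the linear predictor (> 0).  Binary: probability in
    [0,1] plus a hard 0/1 call at 0.5.
    """

    trait: str
    values: pd.Series  # original scale (continuous) or probability (binary)
    hard_calls: pd.Series | None = None
    provenance: str = "predicted-ancestral"


def _usable_branches(
    X: InteractionFeatures, traits: TraitTable, trait: str
) -> list[str]:
    """Terminal branches with an observed trait value and interaction data.

    Branches with a missing trait value are excluded from fitting entirely;
    they still carry a full feature row, so the model can later impute them.
    """
    obs = traits.observed_rows(trait)
    return [b for b in obs if b in X.X.index]


def _resolve_folds(n: int, cv: CVConfig) -> int:
    if n < cv.folds:
        logger.warning(
            "only %d usable branches; reducing CV folds from %d to %d",
            n, cv.folds, max(2, n),
        )
        return max(2, min(n, cv.folds))
    return cv.folds


def _lambda_1se(alphas: np.ndarray, mse_path: np.ndarray) -> float:
    """Largest penalty whose mean CV error is within one SE of the minimum."""
    mean = mse_path.mean(axis=1)
    se = mse_path.std(axis=1, ddof=1) / np.sqrt(mse_path.shape[1])
    i_min = int(np.argmin(mean))
    ok = mean <= mean[i_min] + se[i_min]
    return float(alphas[ok].max())


def fit_continuous_trait(
    X: InteractionFeatures,
    traits: TraitTable,
    trait: str,
    cv: CVConfig | None = None,
) -> FittedTraitModel:
    """LASSO fit of log trait value on interaction features.

    The penalty is chosen by k-fold cross-validation minimizing mean squared
    error (optionally the one-standard-error rule).  Requires at least 10
    terminal branches with an observed value.
    """
    cv = cv or CVConfig()
    branches = _usable_branches(X, traits, trait)
    if len(branches) < 10:
        raise ValueError(
            f"only {len(branches)} branches with observed {trait!r}; need >= 10"
        )
    Z = X.X.loc[branches]
    y = np.log(traits.values.loc[branches, trait].to_numpy(dtype=float))

    if np.ptp(y) == 0.0:
        logger.warning("trait %r constant on fitting branches; intercept-only model", trait)
        return _intercept_only(X, trait, "linear-on-log", float(y[0]), branches, cv)

    folds = _resolve_folds(len(branches), cv)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=cv.seed)
    lcv = LassoCV(alphas=cv.n_alphas, cv=splitter, max_iter=2000, tol=1e-4)
    lcv.fit(Z.to_numpy(), y)
    lam = float(lcv.alpha_)
    if cv.one_se:
        lam = _lambda_1se(lcv.alphas_, lcv.mse_path_)
    idx = int(np.argmin(np.abs(lcv.alphas_ - lam)))
    cv_rmse = float(np.sqrt(lcv.mse_path_[idx].mean()))
    final = Lasso(alpha=lam, max_iter=100000, tol=1e-8)
    final.fit(Z.to_numpy(), y)

    return FittedTraitModel(
        trait=trait,
        family="linear-on-log",
        intercept=float(final.intercept_),
        coef=pd.Series(final.coef_, index=Z.columns),
        penalty_lambda=lam,
        cv=CVConfig(folds=folds, seed=cv.seed, one_se=cv.one_se, n_alphas=cv.n_alphas),
        fit_branches=branches,
        feature_means=X.means.copy(),
        feature_sds=X.sds.copy(),
        transform="log",
        cv_rmse=cv_rmse,
    )


def fit_discrete_trait(
    X: InteractionFeatures,
    traits: TraitTable,
    trait: str,
    cv: CVConfig | None = None,
) -> FittedTraitModel:
    """L1-penalized logistic fit of a binary trait on interaction features."""
    cv = cv or CVConfig()
    branches = _usable_branches(X, traits, trait)
    if len(branches) < 10:
        raise ValueError(
            f"only {len(branches)} branches with observed {trait!r}; need >= 10"
        )
    Z = X.X.loc[branches]
    y = traits.values.loc[branches, trait].to_numpy(dtype=float).astype(int)

    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        logger.warning("trait %r constant on fitting branches; intercept-only model", trait)
        p = counts[1] / counts.sum()
        icpt = np.inf if p == 1.0 else (-np.inf if p == 0.0 else np.log(p / (1 - p)))
        return _intercept_only(X, trait, "logistic", icpt, branches, cv)
    if counts.max() / counts.min() > 9:
        logger.warning(
            "trait %r class imbalance %d:%d exceeds 9:1", trait, counts.max(), counts.min()
        )

    folds = min(_resolve_folds(len(branches), cv), int(counts.min()))
    splitter = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=cv.seed)
    n = len(y)
    Cs = np.logspace(-3, 3, cv.n_alphas // 2)
    lrcv = LogisticRegressionCV(
        Cs=Cs, cv=splitter, l1_ratios=[1.0], solver="liblinear",
        scoring="neg_log_loss", max_iter=5000, refit=True,
        use_legacy_attributes=False, random_state=cv.seed,
    )
    lrcv.fit(Z.to_numpy(), y)
    C = float(np.ravel(lrcv.C_)[0])
    lam = 1.0 / (C * n)  # per-observation penalty strength
    final = LogisticRegression(
        C=C, l1_ratio=1.0, solver="liblinear", max_iter=10000, tol=1e-8,
        random_state=cv.seed,
    )
    final.fit(Z.to_numpy(), y)

    return FittedTraitModel(
        trait=trait,
        family="logistic",
        intercept=float(final.intercept_[0]),
        coef=pd.Series(final.coef_[0], index=Z.columns),
        penalty_lambda=lam,
        cv=CVConfig(folds=max(2, folds), seed=cv.seed, one_se=cv.one_se, n_alphas=cv.n_alphas),
        fit_branches=branches,
        feature_means=X.means.copy(),
        feature_sds=X.sds.copy(),
        transform="identity",
    )


def _intercept_only(X, trait, family, intercept, branches, cv) -> FittedTraitModel:
    return FittedTraitModel(
        trait=trait,
        family=family,
        intercept=intercept,
        coef=pd.Series(0.0, index=X.X.columns),
        penalty_lambda=np.inf,
        cv=cv,
        fit_branches=branches,
        feature_means=X.means.copy(),
        feature_sds=X.sds.copy(),
        transform="log" if family == "linear-on-log" else "identity",
    )


def predict_branches(
    model: FittedTraitModel,
    X: InteractionFeatures,
    branches: list[str],
    provenance: str = "predicted-ancestral",
) -> AncestralPrediction:
    """Apply a fitted model to the feature rows of the requested branches."""
    missing = [b for b in branches if b not in X.X.index]
    if missing:
        raise KeyError(f"branches absent from feature matrix: {missing[:5]}")
    eta = model.linear_predictor(X.X.loc[branches])
    if model.family == "linear-on-log":
        return AncestralPrediction(model.trait, np.exp(eta), None, provenance)
    prob = 1.0 / (1.0 + np.exp(-eta))
    calls = (prob >= 0.5).astype(int)
    return AncestralPrediction(model.trait, prob, calls, provenance)


def impute_missing_terminals(
    model: FittedTraitModel,
    X: InteractionFeatures,
    traits: TraitTable,
) -> TraitTable:
    """Fill missing terminal trait cells from the fitted model.

    Only cells of ``model.trait`` that are missing and whose branch has a
    feature row are filled; observed cells are never touched.  Filled cells
    are flagged ``imputed``.
    """
    out = traits.copy()
    col = out.values[model.trait]
    targets = [b for b in out.values.index[col.isna()] if b in X.X.index]
    if not targets:
        return out
    pred = predict_branches(model, X, targets, provenance="imputed")
    vals = pred.values if model.family == "linear-on-log" else pred.hard_calls.astype(float)
    out.values.loc[targets, model.trait] = vals
    out.provenance.loc[targets, model.trait] = "imputed"
    out.validate()
    return out


def selected_genes(model: FittedTraitModel) -> list[tuple[str, float]]:
    """Genes with non-zero coefficients, by decreasing |coefficient|.

    Ties are broken by gene id so the ordering is deterministic.
    """
    nz = model.coef[model.coef != 0.0]
    return sorted(
        ((g, float(c)) for g, c in nz.items()),
        key=lambda t: (-abs(t[1]), t[0]),
    )
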