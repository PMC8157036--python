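"""Correlated evolution of two binary traits on a time tree.

The joint trait pair evolves as a 4-state continuous-time Markov chain over
(00, 01, 10, 11) in which simultaneous changes of both traits are
forbidden.  Under the independent model each trait has its own gain and
loss rate regardless of the other's state (4 parameters); the dependent
model lets every allowed transition have its own rate (8 parameters).
Likelihoods come from Felsenstein's pruning algorithm with per-branch
transition matrices expm(Q*t); rates are in events per million years since
branch durations are in Ma.  Inference is by maximum likelihood (multi-start
L-BFGS on log rates) or by fixed-dimension Metropolis-Hastings MCMC with
exponential priors on the rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .io import SpeciesTree

logger = logging.getLogger(__name__)

STATES = ("00", "01", "10", "11")
INDEPENDENT_RATES = ("qA01", "qA10", "qB01", "qB10")
DEPENDENT_RATES = (
    "q00_10", "q00_01", "q01_11", "q01_00",
    "q10_11", "q10_00", "q11_01", "q11_10",
)
# (from, to, which trait flips) for each of the 8 allowed transitions
TRANSITIONS = (
    ("00", "10", "A"), ("00", "01", "B"),
    ("01", "11", "A"), ("01", "00", "B"),
    ("10", "00", "A"), ("10", "11", "B"),
    ("11", "01", "A"), ("11", "10", "B"),
)

__all__ = [
    "STATES", "INDEPENDENT_RATES", "DEPENDENT_RATES", "TRANSITIONS",
    "CoevolutionFit", "McmcTrace",
    "build_rate_matrix", "independent_to_dependent", "pruning_loglik",
    "fit_ml", "likelihood_ratio_test", "run_mcmc", "transition_rate_report",
]


def independent_to_dependent(params: dict[str, float]) -> dict[str, float]:
    """Embed 4 independent rates into the 8-rate parametrization."""
    return {
        "q00_10": params["qA01"], "q00_01": params["qB01"],
        "q01_11": params["qA01"], "q01_00": params["qB10"],
        "q10_11": params["qB01"], "q10_00": params["qA10"],
        "q11_01": params["qA10"], "q11_10": params["qB10"],
    }


def build_rate_matrix(params: dict[str, float], model: str) -> np.ndarray:
    """4x4 generator over (00, 01, 10, 11) with dual transitions forbidden."""
    if model == "independent":
        expected = INDEPENDENT_RATES
    elif model == "dependent":
        expected = DEPENDENT_RATES
    else:
        raise ValueError(f"unknown model {model!r}")
    missing = set(expected) - set(params)
    if missing:
        raise ValueError(f"missing rates: {sorted(missing)}")
    neg = [k for k in expected if params[k] < 0]
    if neg:
        raise ValueError(f"negative rates: {neg}")
    dep = params if model == "dependent" else independent_to_dependent(params)
    idx = {s: i for i, s in enumerate(STATES)}
    Q = np.zeros((4, 4))
    for (frm, to, _), name in zip(TRANSITIONS, _TRANSITION_KEYS):
        Q[idx[frm], idx[to]] = dep[name]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


_TRANSITION_KEYS = (
    "q00_10", "q00_01", "q01_11", "q01_00", "q10_00", "q10_11", "q11_01", "q11_10",
)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


@dataclass
class _PruningWorkspace:
    """Precomputed tree structure so repeated likelihood evaluations are cheap."""

    durations: np.ndarray  # (n_branches,) in postorder
    is_leaf: np.ndarray  # bool per postorder branch
    tip_state: np.ndarray  # state index per postorder branch, -1 if internal/missing
    child_slots: list[list[int]]  # postorder position(s) of each branch's children
    root_slots: list[int]
    n_dropped: int


def _tip_state_index(state) -> int:
    a, b = int(state[0]), int(state[1])
    return 2 * a + b


def _build_workspace(tree: SpeciesTree, tips: dict) -> _PruningWorkspace:
    if not tree.time_calibrated:
        raise ValueError("coevolution analysis requires a time-calibrated tree")
    order = tree.postorder_branches()
    pos = {b: i for i, b in enumerate(order)}
    durations = np.array([tree.duration(b) for b in order], dtype=float)
    is_leaf = np.zeros(len(order), dtype=bool)
    tip_state = np.full(len(order), -1, dtype=int)
    child_slots: list[list[int]] = []
    n_dropped = 0
    for i, b in enumerate(order):
        kids = tree.children(b)
        child_slots.append([pos[k] for k in kids])
        if not kids:
            is_leaf[i] = True
            st = tips.get(b)
            if st is None or any(pd.isna(x) for x in st):
                n_dropped += 1
            else:
                tip_state[i] = _tip_state_index(st)
    if n_dropped:
        logger.warning("%d taxa with missing states marginalized out", n_dropped)
    root_slots = [pos[k] for k in tree.children(None)]
    return _PruningWorkspace(durations, is_leaf, tip_state, child_slots, root_slots, n_dropped)


def _transition_matrices(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """P(t_j) = expm(Q t_j) for all branches, via eigendecomposition when
    well-conditioned, scipy.linalg.expm otherwise."""
    w, V = np.linalg.eig(Q)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        Vinv = np.linalg.inv(V)
        E = np.exp(np.outer(t, w))  # (J, 4)
        P = np.einsum("ab,jb,bc->jac", V, E, Vinv)
        P = np.real(P)
    else:
        P = np.stack([expm(Q * tj) for tj in t])
    # zero-duration branches get the exact identity, so impossible tip
    # configurations yield likelihood exactly 0 instead of rounding noise
    P[t == 0.0] = np.eye(4)
    return P


def _pruning_loglik_ws(ws: _PruningWorkspace, Q: np.ndarray, pi: np.ndarray) -> float:
    P = _transition_matrices(Q, ws.durations)
    n = len(ws.durations)
    L = np.empty((n, 4))
    logscale = 0.0
    for i in range(n):
        if ws.is_leaf[i]:
            if ws.tip_state[i] < 0:
                L[i] = 1.0
            else:
                L[i] = 0.0
                L[i, ws.tip_state[i]] = 1.0
        else:
            vec = np.ones(4)
            for c in ws.child_slots[i]:
                vec = vec * (P[c] @ L[c])
            m = vec.max()
            if m <= 0.0:
                return -np.inf
            L[i] = vec / m
            logscale += np.log(m)
    root = np.ones(4)
    for c in ws.root_slots:
        root = root * (P[c] @ L[c])
    lik = float(pi @ root)
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik) + logscale)


def pruning_loglik(
    tree: SpeciesTree,
    tips: dict[str, tuple[int, int]],
    Q: np.ndarray,
    pi: np.ndarray | None = None,
) -> float:
    """Log-likelihood of joint tip states under generator Q.

    ``tips`` maps taxon name to its (trait A, trait B) pair.  Taxa with a
    missing state are marginalized out (equivalent to pruning them).  The
    root state is averaged over ``pi`` (uniform by default).
    """
    pi = np.full(4, 0.25) if pi is None else np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("root distribution must sum to 1")
    ws = _build_workspace(tree, tips)
    return _pruning_loglik_ws(ws, Q, pi)


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class CoevolutionFit:
    model: str
    rates: dict[str, float]  # events per Ma
    loglik: float
    converged: bool
    n_restarts: int
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    @property
    def n_params(self) -> int:
        return len(self.rates)


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    A = np.vstack([Q.T, np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def fit_ml(
    tree: SpeciesTree,
    tips: dict[str, tuple[int, int]],
    model: str = "dependent",
    restarts: int = 3,
    seed: int = 0,
    pi: np.ndarray | None = None,
) -> CoevolutionFit:
    """Maximum-likelihood transition rates by multi-start L-BFGS on log rates.

    Starting points are log-uniform in [1e-3, 10] events/Ma; the best
    converged solution across restarts is returned.
    """
    names = INDEPENDENT_RATES if model == "independent" else DEPENDENT_RATES
    if model not in ("independent", "dependent"):
        raise ValueError(f"unknown model {model!r}")
    n_taxa = sum(1 for v in tips.values() if v is not None)
    if n_taxa < 10:
        logger.warning("only %d taxa; rate estimates will be unstable", n_taxa)
    pi = np.full(4, 0.25) if pi is None else np.asarray(pi, dtype=float)
    ws = _build_workspace(tree, tips)
    k = len(names)

    def negloglik(logrates: np.ndarray) -> float:
        params = dict(zip(names, np.exp(logrates)))
        Q = build_rate_matrix(params, model)
        ll = _pruning_loglik_ws(ws, Q, pi)
        return 1e10 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    bounds = [(np.log(1e-8), np.log(1e3))] * k
    best, failures = None, []
    for _ in range(max(1, restarts)):
        x0 = rng.uniform(np.log(1e-3), np.log(10.0), size=k)
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            failures.append(res)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {restarts} restarts failed: {failures}")
    rates = dict(zip(names, np.exp(best.x)))
    return CoevolutionFit(
        model=model,
        rates={k_: float(v) for k_, v in rates.items()},
        loglik=float(-best.fun),
        converged=bool(best.success),
        n_restarts=restarts,
        pi=pi,
    )


def likelihood_ratio_test(
    tree: SpeciesTree,
    tips: dict[str, tuple[int, int]],
    restarts: int = 3,
    seed: int = 0,
    pi: np.ndarray | None = None,
) -> dict:
    """Dependent vs independent model: 2*delta-loglik against chi2(df=4)."""
    indep = fit_ml(tree, tips, "independent", restarts=restarts, seed=seed, pi=pi)
    dep = fit_ml(tree, tips, "dependent", restarts=restarts, seed=seed + 1, pi=pi)
    stat = max(0.0, 2.0 * (dep.loglik - indep.loglik))
    return {
        "independent": indep,
        "dependent": dep,
        "statistic": stat,
        "df": 4,
        "pvalue": float(chi2.sf(stat, 4)),
    }


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


@dataclass
class McmcTrace:
    rates: pd.DataFrame  # iterations x rate names, natural scale
    loglik: np.ndarray
    seed: int
    proposal_scale: np.ndarray
    acceptance_rate: float
    burn_in: int

    def posterior_mean(self) -> pd.Series:
        return self.rates.iloc[self.burn_in:].mean(axis=0)


def run_mcmc(
    tree: SpeciesTree,
    tips: dict[str, tuple[int, int]],
    model: str = "dependent",
    prior_mean: float = 1.0,
    iterations: int = 2000,
    seed: int = 0,
    burn_in: int | None = None,
    pi: np.ndarray | None = None,
) -> McmcTrace:
    """Metropolis-Hastings over transition rates with Exponential priors.

    One iteration is a full sweep of log-normal random-walk updates, one
    rate at a time.  Proposal scales adapt toward ~30% acceptance during
    burn-in only, so the post-burn-in chain is a valid fixed-kernel sampler
    and the whole run is deterministic given the seed.
    """
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    if prior_mean <= 0:
        raise ValueError("prior mean must be positive")
    names = INDEPENDENT_RATES if model == "independent" else DEPENDENT_RATES
    burn_in = iterations // 5 if burn_in is None else burn_in
    pi = np.full(4, 0.25) if pi is None else np.asarray(pi, dtype=float)
    ws = _build_workspace(tree, tips)
    k = len(names)
    rng = np.random.default_rng(seed)

    def log_target(logrates: np.ndarray) -> float:
        rates = np.exp(logrates)
        Q = build_rate_matrix(dict(zip(names, rates)), model)
        ll = _pruning_loglik_ws(ws, Q, pi)
        if not np.isfinite(ll):
            return -np.inf
        # Exponential(prior_mean) density on rates + log-Jacobian of the
        # log parametrization
        return ll - rates.sum() / prior_mean + logrates.sum()

    x = np.log(np.full(k, prior_mean))
    cur = log_target(x)
    scale = np.full(k, 0.5)
    trace = np.empty((iterations, k))
    lls = np.empty(iterations)
    accepted = np.zeros(k)
    proposed = np.zeros(k)
    acc_post = 0
    n_post = 0
    for it in range(iterations):
        for j in range(k):
            prop = x.copy()
            prop[j] += rng.normal(0.0, scale[j])
            new = log_target(prop)
            proposed[j] += 1
            if np.log(rng.uniform()) < new - cur:
                x, cur = prop, new
                accepted[j] += 1
                if it >= burn_in:
                    acc_post += 1
            if it >= burn_in:
                n_post += 1
        if it < burn_in and (it + 1) % 50 == 0:
            rate = accepted / np.maximum(proposed, 1)
            scale *= np.exp(rate - 0.3)
            scale = np.clip(scale, 1e-3, 10.0)
            accepted[:] = 0
            proposed[:] = 0
        trace[it] = np.exp(x)
        rates_d = dict(zip(names, np.exp(x)))
        lls[it] = _pruning_loglik_ws(ws, build_rate_matrix(rates_d, model), pi)
    return McmcTrace(
        rates=pd.DataFrame(trace, columns=list(names)),
        loglik=lls,
        seed=seed,
        proposal_scale=scale,
        acceptance_rate=acc_post / max(n_post, 1),
        burn_in=burn_in,
    )


def transition_rate_report(
    fit: CoevolutionFit, trace: McmcTrace | None = None
) -> pd.DataFrame:
    """All 8 allowed transitions with their rates in events per Ma.

    Dual transitions (both traits changing at once) are structurally absent.
    Includes posterior means when an MCMC trace is supplied.
    """
    dep = fit.rates if fit.model == "dependent" else independent_to_dependent(fit.rates)
    post = None
    if trace is not None:
        pm = trace.posterior_mean().to_dict()
        post = pm if fit.model == "dependent" else independent_to_dependent(pm)
    rows = []
    for (frm, to, trait), key in zip(TRANSITIONS, _TRANSITION_KEYS):
        row = {
            "transition": key,
            "from_state": frm,
            "to_state": to,
            "changing_trait": trait,
            "rate_per_Ma": float(dep[key]),
        }
        if post is not None:
            row["posterior_mean_per_Ma"] = float(post[key])
        rows.append(row)
    return pd.DataFrame(rows)
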