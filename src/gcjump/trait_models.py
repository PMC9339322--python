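"""Maximum-likelihood Brownian and Ornstein-Uhlenbeck trait models.

Both models treat tip GC% as one draw from a multivariate normal whose
covariance is induced by the tree.  Under Brownian motion (BM) the
covariance of tips *i, j* is ``sigma2 * C_ij`` with ``C_ij`` the shared
root-to-MRCA path length; the BM fit is closed-form (GLS mean, ML — not
REML — rate).  The single-optimum Ornstein-Uhlenbeck (OU) model adds a pull
of strength ``alpha_ou`` toward an optimum ``theta``; the root state is
constrained to the optimum, and because the trees here are non-ultrametric
the fixed-root (non-stationary) covariance is used:

    Cov(i,j) = sigma2/(2*alpha_ou) * exp(-alpha_ou*(d_i + d_j - 2*t_a))
               * (1 - exp(-2*alpha_ou*t_a)),   t_a = MRCA depth.

As ``alpha_ou -> 0`` this reduces continuously to BM, which is the regime
observed for bacterial GC content (the OU fit collapses onto BM).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

from ._pruning import PruneArrays, gauss_loglik, prune_stats
from .errors import GCJumpError, OptimizationError
from .phylo_core import (
    Phylogeny,
    node_depths,
    shared_path_matrix,
    validate_traits,
)

__all__ = [
    "BMParams",
    "OUParams",
    "ModelComparison",
    "bm_loglik",
    "fit_bm",
    "ou_loglik",
    "fit_ou",
    "lrt",
    "P_FLOOR",
    "fit_report",
]

#: Reported p-values are clamped below at this floor.
P_FLOOR = 1e-16


@dataclass
class BMParams:
    """Brownian-motion parameters: rate (GC%^2 per unit branch length) and
    root state (GC%)."""

    sigma2: float
    x0: float


@dataclass
class OUParams:
    sigma2: float
    alpha_ou: float
    theta: float


@dataclass
class ModelComparison:
    """Log-likelihoods of the three candidate models plus the LRT of the
    jumps model against Brownian motion."""

    loglik_bm: float
    loglik_ou: float
    loglik_levy: float
    lrt_stat: float
    df: int
    p_value: float


def _diagnose_singular(tree: Phylogeny) -> str:
    depths = node_depths(tree)
    # two tips at zero patristic distance share a zero-height ancestor path
    for v in range(tree.n_nodes):
        if tree.is_tip[v] or len(tree.children[v]) < 2:
            continue
        kids = tree.children[v]
        for ai in range(len(kids)):
            for bi in range(ai + 1, len(kids)):
                ta = tree.subtree_tips(kids[ai])
                tb = tree.subtree_tips(kids[bi])
                for i in ta:
                    for j in tb:
                        if depths[i] + depths[j] - 2 * depths[v] <= 0:
                            return (
                                f"tips '{tree.labels[i]}' and '{tree.labels[j]}' "
                                "are at zero patristic distance"
                            )
    return "duplicate zero-distance tips"


def bm_loglik(tree: Phylogeny, traits: dict[str, float], params: BMParams) -> float:
    """Log-likelihood of tip GC% under Brownian motion with given params."""
    if params.sigma2 <= 0:
        raise GCJumpError("sigma2 must be > 0")
    pa = PruneArrays(tree, traits)
    ll = gauss_loglik(
        pa.parent,
        pa.child1,
        pa.child2,
        pa.blen,
        pa.tipval,
        pa.n_tips,
        params.x0,
        params.sigma2,
    )
    if np.isnan(ll):
        raise GCJumpError(f"singular tip covariance: {_diagnose_singular(tree)}")
    return float(ll)


def fit_bm(tree: Phylogeny, traits: dict[str, float]) -> tuple[BMParams, float]:
    """Closed-form ML Brownian fit: GLS root state and ML (not REML) rate."""
    if tree.n_tips < 2:
        raise GCJumpError("Brownian fit requires at least 2 tips")
    pa = PruneArrays(tree, traits)
    slog, ssq, mu_root, v_root, ok = prune_stats(
        pa.parent, pa.child1, pa.child2, pa.blen, pa.tipval
    )
    if not ok:
        raise GCJumpError(f"singular tip covariance: {_diagnose_singular(tree)}")
    n = pa.n_tips
    sigma2 = ssq / n
    if sigma2 <= 0:
        raise GCJumpError(
            "zero phylogenetic variance: all tips equal given the tree; the "
            "Brownian rate is not identifiable"
        )
    ll = -0.5 * (
        n * (np.log(2 * np.pi * sigma2)) + slog + np.log(v_root) + n
    )
    return BMParams(sigma2=float(sigma2), x0=float(mu_root)), float(ll)


# ---------------------------------------------------------------------- #
# OU
# ---------------------------------------------------------------------- #
def _bm_covariance(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Dense shared-path-length matrix C over tips, plus tip depths."""
    C = shared_path_matrix(tree)
    d = np.diag(C).copy()
    labels = [tree.labels[int(t)] for t in tree.tip_indices()]
    return C, d, labels


def _ou_cov(C: np.ndarray, d: np.ndarray, a: float) -> np.ndarray:
    if a < 1e-10:
        return C.copy()
    dd = d[:, None] + d[None, :]
    return (1.0 / (2 * a)) * np.exp(-a * (dd - 2 * C)) * -np.expm1(-2 * a * C)


def _profile_gaussian(V: np.ndarray, x: np.ndarray):
    """Profile (mean level, rate) out of N(m*1, s2*V); returns (ll, m, s2)."""
    n = x.size
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ones = np.ones(n)
    iVx = np.linalg.solve(L.T, np.linalg.solve(L, x))
    iV1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
    m = (ones @ iVx) / (ones @ iV1)
    r = x - m
    q = r @ np.linalg.solve(L.T, np.linalg.solve(L, r))
    if q <= 0:
        return -np.inf, m, 0.0
    s2 = q / n
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return float(ll), float(m), float(s2)


def ou_loglik(
    tree: Phylogeny, traits: dict[str, float], params: OUParams
) -> float:
    """OU log-likelihood with the fixed-root covariance and root at the
    optimum (mean vector ``theta * 1``)."""
    x = validate_traits(tree, traits)
    C, d, _ = _bm_covariance(tree)
    V = _ou_cov(C, d, params.alpha_ou) * params.sigma2
    n = x.size
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise GCJumpError("singular OU covariance") from exc
    r = x - params.theta
    q = r @ np.linalg.solve(L.T, np.linalg.solve(L, r))
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + q))


def fit_ou(
    tree: Phylogeny,
    traits: dict[str, float],
    n_restarts: int = 5,
) -> tuple[OUParams, float]:
    """Numeric ML fit of the single-optimum OU model.

    ``theta`` and ``sigma2`` are profiled in closed form for each candidate
    constraint strength; ``alpha_ou`` is searched in log-space over
    ``[1e-8, 10/tree_height]`` (grid scan + bounded refinement from several
    dispersed starts).  On Brownian-like data the fit collapses to
    ``alpha_ou ~ 0`` with the OU maximum likelihood equal to the BM one.
    """
    x = validate_traits(tree, traits)
    C, d, _ = _bm_covariance(tree)
    height = float(d.max())
    if height <= 0:
        raise GCJumpError("tree height must be positive for an OU fit")
    lo, hi = 1e-8, 10.0 / height

    def nll(log_a: float) -> float:
        ll, _, _ = _profile_gaussian(_ou_cov(C, d, np.exp(log_a)), x)
        return -ll

    grid = np.linspace(np.log(lo), np.log(hi), 5 * n_restarts)
    vals = np.array([nll(g) for g in grid])
    if not np.any(np.isfinite(vals)):
        raise OptimizationError("OU likelihood not finite anywhere on the grid")
    best_i = int(np.nanargmin(vals))
    a_lo = grid[max(0, best_i - 1)]
    a_hi = grid[min(len(grid) - 1, best_i + 1)]
    res = optimize.minimize_scalar(
        nll, bounds=(a_lo, a_hi), method="bounded", options={"xatol": 1e-10}
    )
    cand = [(vals[best_i], grid[best_i])]
    if res.success and np.isfinite(res.fun):
        cand.append((res.fun, res.x))
    fun, log_a = min(cand, key=lambda t: t[0])
    a = float(np.exp(log_a))
    # the Brownian boundary (alpha_ou = 0) is part of the parameter space;
    # evaluate it exactly so the OU fit is never spuriously below BM
    ll0, theta0, s20 = _profile_gaussian(C, x)
    ll, theta, s2 = _profile_gaussian(_ou_cov(C, d, a), x)
    if ll0 >= ll:
        a, ll, theta, s2 = 0.0, ll0, theta0, s20
    if not np.isfinite(ll):
        raise OptimizationError(
            "OU optimization failed to converge", best=OUParams(np.nan, a, np.nan)
        )
    return OUParams(sigma2=s2, alpha_ou=a, theta=theta), float(ll)


# ---------------------------------------------------------------------- #
# likelihood-ratio test
# ---------------------------------------------------------------------- #
def lrt(
    loglik_alt: float,
    loglik_null: float,
    df: int,
    clamp: bool = False,
) -> float:
    """Chi-square likelihood-ratio p-value for nested models.

    ``loglik_alt`` below ``loglik_null`` (beyond 1e-9) raises, since with
    nested models it signals a broken optimization; pass ``clamp=True`` for
    Monte-Carlo-estimated alternative log-likelihoods, where small negative
    excursions are estimator noise and the statistic is clamped at 0.
    Reported p-values are floored at :data:`P_FLOOR`.
    """
    if df < 1:
        raise GCJumpError("df must be a positive integer")
    delta = loglik_alt - loglik_null
    if delta < -1e-9:
        if not clamp:
            raise GCJumpError(
                f"alternative loglik {loglik_alt:.6f} is below null "
                f"{loglik_null:.6f}; nested-model optimization is broken"
            )
        delta = 0.0
    stat = max(0.0, 2.0 * delta)
    p = float(stats.chi2.sf(stat, df))
    return max(p, P_FLOOR)


def fit_report(model: str, params, loglik: float, n_tips: int,
               converged: bool = True, seed=None) -> dict:
    """Machine-readable fit summary with fixed keys (diffable JSON)."""
    return {
        "model": model,
        "params": asdict(params) if hasattr(params, "__dataclass_fields__") else dict(params),
        "loglik": float(loglik),
        "n_tips": int(n_tips),
        "converged": bool(converged),
        "seed": seed,
    }
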