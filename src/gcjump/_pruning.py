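"""Numba kernels: pruning likelihoods and jump-count MCMC.

Everything here works on a flat binary-tree encoding (``child1``/``child2``
of -1 marks a tip).  The Gaussian likelihood of tip values under Brownian
motion with per-branch *effective* lengths ``t_i + alpha * n_i`` is computed
by Felsenstein's pruning algorithm in O(n) — the jump model with a known
jump configuration is exactly Brownian motion on a stretched tree, so one
kernel serves the Brownian, exact-enumeration, Monte-Carlo and MCMC paths.

The Metropolis-Hastings sampler proposes single-branch +/-1 changes to the
jump counts; a proposal only perturbs the pruning quantities on the path
from the branch to the root, so each evaluation costs O(tree depth) rather
than O(n).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .phylo_core import Phylogeny, resolve_polytomies, validate_traits

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------- #
# flat encoding
# ---------------------------------------------------------------------- #
class PruneArrays:
    """Flat binary encoding of (tree, traits) for the numba kernels.

    If the input tree is not binary it is resolved internally with
    zero-length branches; ``orig_node`` maps encoded nodes back to the
    original node indices (-1 for nodes introduced by the resolution, which
    have zero branch length and therefore can never carry a jump).
    """

    def __init__(self, tree: Phylogeny, traits: dict[str, float] | None = None):
        if tree.is_binary():
            work = tree
            orig = np.arange(tree.n_nodes, dtype=np.int64)
        else:
            work, orig = _resolve_with_map(tree)
        self.tree = work
        self.orig_node = orig
        n = work.n_nodes
        self.parent = work.parent.astype(np.int64)
        self.child1 = np.full(n, -1, dtype=np.int64)
        self.child2 = np.full(n, -1, dtype=np.int64)
        for v in range(n):
            kids = work.children[v]
            if kids:
                self.child1[v], self.child2[v] = kids
        self.blen = work.blen.astype(np.float64)
        self.n_tips = work.n_tips
        self.tipval = np.zeros(n)
        if traits is not None:
            x = validate_traits(work, traits)
            self.tipval[work.tip_indices()] = x

    def map_to_original(self, per_node: np.ndarray) -> np.ndarray:
        """Project a per-encoded-node array onto original node indexing."""
        out = np.zeros(np.max(self.orig_node) + 1, dtype=per_node.dtype)
        for i, o in enumerate(self.orig_node):
            if o >= 0:
                out[o] = per_node[i]
        return out


def _resolve_with_map(tree: Phylogeny):
    """Zero-length binary resolution that tracks original node identity."""
    parent_out: list[int] = []
    blen_out: list[float] = []
    labels_out: list[str | None] = []
    orig_out: list[int] = []

    def add(parent_idx, blen, label, orig):
        parent_out.append(parent_idx)
        blen_out.append(blen)
        labels_out.append(label)
        orig_out.append(orig)
        return len(parent_out) - 1

    def build(v, parent_idx, blen):
        me = add(parent_idx, blen, tree.labels[v], v)
        kids = tree.children[v]
        if len(kids) <= 2:
            for c in kids:
                build(c, me, tree.blen[c])
            return
        host = me
        for c in kids[:-2]:
            build(c, host, tree.blen[c])
            host = add(host, 0.0, None, -1)
        build(kids[-2], host, tree.blen[kids[-2]])
        build(kids[-1], host, tree.blen[kids[-1]])

    build(0, -1, 0.0)
    new = Phylogeny(np.array(parent_out), np.array(blen_out), labels_out)
    return new, np.array(orig_out, dtype=np.int64)


# ---------------------------------------------------------------------- #
# pruning pass
# ---------------------------------------------------------------------- #
@njit(cache=True)
def _prune_full(parent, child1, child2, teff, tipval, mu, delta, clogs, cssq):
    """One full postorder pruning pass.

    Fills the per-node work arrays and returns
    ``(sum_log_S, sum_ssq, mu_root, v_root, ok)`` where the restricted
    log-likelihood of tip values x under N(x0*1, sigma2*V(teff)) is

        -0.5 * (n_tips*log(2*pi*sigma2) + sum_log_S + log(v_root)
                + (sum_ssq + (mu_root - x0)**2 / v_root) / sigma2)
    """
    n = parent.shape[0]
    slog = 0.0
    sssq = 0.0
    ok = True
    for v in range(n - 1, -1, -1):
        a = child1[v]
        if a == -1:
            mu[v] = tipval[v]
            delta[v] = 0.0
        else:
            b = child2[v]
            va = delta[a] + teff[a]
            vb = delta[b] + teff[b]
            s = va + vb
            if s <= 0.0:
                ok = False
                s = 1.0
            clogs[v] = math.log(s)
            u = mu[a] - mu[b]
            cssq[v] = u * u / s
            slog += clogs[v]
            sssq += cssq[v]
            mu[v] = (mu[a] * vb + mu[b] * va) / s
            delta[v] = va * vb / s
    return slog, sssq, mu[0], delta[0], ok


@njit(cache=True)
def _gauss_loglik_from_stats(n_tips, slog, sssq, mu_root, v_root, x0, sigma2):
    q = sssq
    pen = 0.0
    if v_root > 0.0:
        q += (mu_root - x0) ** 2 / v_root
        pen = math.log(v_root)
    elif mu_root != x0:
        return -np.inf
    return -0.5 * (n_tips * (LOG2PI + math.log(sigma2)) + slog + pen + q / sigma2)


@njit(cache=True)
def gauss_loglik(parent, child1, child2, teff, tipval, n_tips, x0, sigma2):
    """Gaussian log-density of the tip values for given effective lengths."""
    n = parent.shape[0]
    mu = np.empty(n)
    delta = np.empty(n)
    clogs = np.zeros(n)
    cssq = np.zeros(n)
    slog, sssq, mr, vr, ok = _prune_full(
        parent, child1, child2, teff, tipval, mu, delta, clogs, cssq
    )
    if not ok:
        return np.nan
    return _gauss_loglik_from_stats(n_tips, slog, sssq, mr, vr, x0, sigma2)


@njit(cache=True)
def prune_stats(parent, child1, child2, teff, tipval):
    """(sum_log_S, ssq_at_GLS_root, gls_root_mean, v_root, ok)."""
    n = parent.shape[0]
    mu = np.empty(n)
    delta = np.empty(n)
    clogs = np.zeros(n)
    cssq = np.zeros(n)
    return _prune_full(parent, child1, child2, teff, tipval, mu, delta, clogs, cssq)


# ---------------------------------------------------------------------- #
# exact enumeration over jump configurations
# ---------------------------------------------------------------------- #
@njit(cache=True)
def enumerate_configs(
    parent,
    child1,
    child2,
    blen,
    tipval,
    n_tips,
    alpha,
    lam,
    sigma2,
    x0,
    nmax,  # per-node truncation (0 for root / zero-length branches)
):
    """Sum the joint density over all truncated jump configurations.

    Returns ``(log_marginal, log_pp_num)`` where ``log_pp_num[i]`` is the
    log of the weight summed over configurations with ``n_i >= 1`` — i.e.
    the unnormalized per-branch posterior of one-or-more jumps.
    """
    n = parent.shape[0]
    mu = np.empty(n)
    delta = np.empty(n)
    clogs = np.zeros(n)
    cssq = np.zeros(n)
    teff = blen.copy()
    counts = np.zeros(n, dtype=np.int64)
    # free branches = nodes with nmax > 0
    free = np.flatnonzero(nmax > 0)
    nb = free.shape[0]

    m = -np.inf  # running max of config log-weights
    s = 0.0  # sum of exp(lw - m)
    sb = np.zeros(n)  # per-branch sums of exp(lw - m) over configs n_i >= 1

    while True:
        # log prior of current config
        lp = 0.0
        for j in range(n):
            if j == 0:
                continue
            rate = lam * blen[j]
            c = counts[j]
            if rate > 0.0:
                lp += c * math.log(rate) - rate - math.lgamma(c + 1.0)
            elif c > 0:
                lp = -np.inf
        slog, sssq, mr, vr, ok = _prune_full(
            parent, child1, child2, teff, tipval, mu, delta, clogs, cssq
        )
        if ok and lp > -np.inf:
            lw = lp + _gauss_loglik_from_stats(n_tips, slog, sssq, mr, vr, x0, sigma2)
        else:
            lw = -np.inf
        if lw > -np.inf:
            if lw > m:
                scale = math.exp(m - lw) if m > -np.inf else 0.0
                s = s * scale + 1.0
                for j in range(n):
                    sb[j] *= scale
                m = lw
                w = 1.0
            else:
                w = math.exp(lw - m)
                s += w
            for j in range(n):
                if counts[j] >= 1:
                    sb[j] += w

        # odometer increment over free branches
        k = 0
        while k < nb:
            j = free[k]
            if counts[j] < nmax[j]:
                counts[j] += 1
                teff[j] = blen[j] + alpha * counts[j]
                break
            counts[j] = 0
            teff[j] = blen[j]
            k += 1
        if k == nb:
            break

    log_marg = m + math.log(s) if s > 0.0 else -np.inf
    log_num = np.full(n, -np.inf)
    for j in range(n):
        if sb[j] > 0.0:
            log_num[j] = m + math.log(sb[j])
    return log_marg, log_num


# ---------------------------------------------------------------------- #
# Monte-Carlo helper: Gaussian loglik for a batch of configurations
# ---------------------------------------------------------------------- #
@njit(cache=True)
def gauss_loglik_batch(
    parent, child1, child2, blen, tipval, n_tips, alpha, x0, sigma2, configs
):
    ns = configs.shape[0]
    n = parent.shape[0]
    out = np.empty(ns)
    teff = np.empty(n)
    mu = np.empty(n)
    delta = np.empty(n)
    clogs = np.zeros(n)
    cssq = np.zeros(n)
    for k in range(ns):
        for j in range(n):
            teff[j] = blen[j] + alpha * configs[k, j]
        slog, sssq, mr, vr, ok = _prune_full(
            parent, child1, child2, teff, tipval, mu, delta, clogs, cssq
        )
        if ok:
            out[k] = _gauss_loglik_from_stats(n_tips, slog, sssq, mr, vr, x0, sigma2)
        else:
            out[k] = np.nan
    return out


# ---------------------------------------------------------------------- #
# MCMC over jump configurations (empirical Bayes: parameters fixed)
# ---------------------------------------------------------------------- #
@njit(cache=True)
def mcmc_jump_counts(
    parent,
    child1,
    child2,
    blen,
    tipval,
    n_tips,
    alpha,
    lam,
    sigma2,
    x0,
    n_init,
    n_sweeps,
    burn_sweeps,
    sample_every,
    seed,
):
    """Metropolis-Hastings over per-branch jump counts.

    Single-branch +/-1 proposals (a -1 proposal at 0 is rejected, keeping
    the kernel symmetric on the non-negative lattice).  One sweep makes one
    proposal per proposable branch.  Samples are the configurations after
    burn-in, thinned to every ``sample_every`` sweeps; alongside each sample
    the pruning statistics (ssq, gls_mean, v_root, sum_log_S) needed by the
    EM M-step are recorded.

    Returns ``(samples, stats, accept_rate)``.
    """
    np.random.seed(seed)
    n = parent.shape[0]
    mu = np.empty(n)
    delta = np.empty(n)
    clogs = np.zeros(n)
    cssq = np.zeros(n)

    counts = n_init.copy()
    teff = np.empty(n)
    for j in range(n):
        teff[j] = blen[j] + alpha * counts[j]

    slog, sssq, mr, vr, ok = _prune_full(
        parent, child1, child2, teff, tipval, mu, delta, clogs, cssq
    )
    gll = _gauss_loglik_from_stats(n_tips, slog, sssq, mr, vr, x0, sigma2)

    prop = np.flatnonzero((blen > 0.0) & (np.arange(n) > 0))
    nb = prop.shape[0]
    n_keep = (n_sweeps - burn_sweeps) // sample_every
    samples = np.zeros((n_keep, n), dtype=np.int64)
    stats = np.zeros((n_keep, 4))
    kept = 0
    accepted = 0
    proposed = 0

    # path buffers for incremental restore
    path = np.empty(n, dtype=np.int64)
    old_mu = np.empty(n)
    old_delta = np.empty(n)
    old_clogs = np.empty(n)
    old_cssq = np.empty(n)

    for sweep in range(n_sweeps):
        for _ in range(nb):
            j = prop[np.random.randint(nb)]
            step = 1 if np.random.random() < 0.5 else -1
            proposed += 1
            cj = counts[j]
            if cj + step < 0:
                continue
            rate = lam * blen[j]
            if rate <= 0.0:
                continue
            if step == 1:
                dprior = math.log(rate) - math.log(cj + 1.0)
            else:
                dprior = math.log(cj) - math.log(rate)

            # apply: update path j -> root
            teff_old = teff[j]
            teff[j] = blen[j] + alpha * (cj + step)
            plen = 0
            v = parent[j]
            new_slog = slog
            new_sssq = sssq
            bad = False
            while v != -1:
                path[plen] = v
                old_mu[plen] = mu[v]
                old_delta[plen] = delta[v]
                old_clogs[plen] = clogs[v]
                old_cssq[plen] = cssq[v]
                plen += 1
                a = child1[v]
                b = child2[v]
                va = delta[a] + teff[a]
                vb = delta[b] + teff[b]
                ssum = va + vb
                if ssum <= 0.0:
                    bad = True
                    break
                cl = math.log(ssum)
                u = mu[a] - mu[b]
                cs = u * u / ssum
                new_slog += cl - clogs[v]
                new_sssq += cs - cssq[v]
                clogs[v] = cl
                cssq[v] = cs
                mu[v] = (mu[a] * vb + mu[b] * va) / ssum
                delta[v] = va * vb / ssum
                v = parent[v]

            if bad:
                new_gll = -np.inf
            else:
                new_gll = _gauss_loglik_from_stats(
                    n_tips, new_slog, new_sssq, mu[0], delta[0], x0, sigma2
                )
            if math.log(np.random.random() + 1e-300) < dprior + new_gll - gll:
                counts[j] = cj + step
                slog = new_slog
                sssq = new_sssq
                gll = new_gll
                accepted += 1
            else:
                teff[j] = teff_old
                for k in range(plen - 1, -1, -1):
                    v = path[k]
                    mu[v] = old_mu[k]
                    delta[v] = old_delta[k]
                    clogs[v] = old_clogs[k]
                    cssq[v] = old_cssq[k]

        if sweep >= burn_sweeps and (sweep - burn_sweeps) % sample_every == 0:
            if kept < n_keep:
                for j in range(n):
                    samples[kept, j] = counts[j]
                stats[kept, 0] = sssq
                stats[kept, 1] = mu[0]
                stats[kept, 2] = delta[0]
                stats[kept, 3] = slog
                kept += 1

    acc = accepted / proposed if proposed > 0 else 0.0
    return samples[:kept], stats[:kept], acc
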