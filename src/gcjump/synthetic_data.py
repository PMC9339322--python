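"""Seeded generators for trees, traits, truth, and ecological annotations.

The generators emulate the statistical shape of an order-level bacterial
clade as used throughout the pipeline: a few hundred tips, non-ultrametric
branch lengths in substitutions per site, GC% evolving by Brownian motion
plus Poisson jumps, an optional reflecting constraint on the observable GC
range, and per-jump lifestyle annotations whose association with jump
direction is a configurable effect (0 = independence) so that both null
and power behaviour of the ecology tests can be exercised.

Everything is deterministic given (seed, configuration); the simulation
truth is written to a JSON sidecar that inference stages never read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ecology import EcologyAnnotation, write_annotation_table
from .errors import GCJumpError
from .levy_model import JumpConfiguration, LevyParams, simulate_levy
from .phylo_core import (
    Phylogeny,
    node_depths,
    write_newick,
    write_trait_table,
)

__all__ = [
    "SyntheticDataset",
    "simulate_yule_tree",
    "default_clade_params",
    "generate_dataset",
]

#: Defaults emulating one order-level clade: jump rate at the low end of
#: the fitted 2.5-6 jumps per unit branch length spread, per-jump standard
#: deviation ~6 GC% (individually visible jumps, like the detected ones),
#: jump variance contribution lam*alpha = 2 within the observed ~0.5-3x
#: range relative to the Brownian rate, and a mid-range ancestral GC.
_DEFAULT_SIGMA2_0 = 50.0  # GC%^2 per substitution per site
_DEFAULT_LAM = 2.5  # jumps per substitution per site
_DEFAULT_ALPHA = 0.8
_DEFAULT_X0 = 50.0
#: Mean root-to-tip depth, substitutions per site, typical of an order-level
#: subtree of a genome phylogeny.
DEFAULT_TREE_HEIGHT = 0.5


def default_clade_params() -> LevyParams:
    return LevyParams(
        sigma2_0=_DEFAULT_SIGMA2_0,
        lam=_DEFAULT_LAM,
        alpha=_DEFAULT_ALPHA,
        x0=_DEFAULT_X0,
    )


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    jitter_sd: float = 0.0,
    mean_tip_depth: float | None = None,
) -> Phylogeny:
    """Pure-birth tree with ``n_tips`` extant tips.

    ``jitter_sd`` applies independent multiplicative lognormal noise (log
    sd, median 1) per branch, breaking ultrametricity the way substitution
    rate variation does in real genome trees.  ``mean_tip_depth`` rescales
    all branch lengths so the mean root-to-tip path equals it (applied
    after jitter).  Deterministic from ``seed``.
    """
    if n_tips < 2:
        raise GCJumpError("a Yule tree needs at least 2 tips")
    if birth_rate <= 0:
        raise GCJumpError("birth_rate must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    # grow from a root bifurcation; after the n-th birth, run one more
    # exponential waiting time so pendant edges are strictly positive
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        v = active[i]
        c1 = len(parent)
        parent.extend([v, v])
        birth.extend([t, t])
        active[i] = c1
        active.append(c1 + 1)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    blen = np.zeros(len(parent))
    split_time = dict.fromkeys(range(len(parent)), t)  # default: tip ends now
    for v in range(len(parent)):
        p = parent[v]
        if p >= 0:
            split_time[p] = birth[v]
    for v in range(1, len(parent)):
        blen[v] = split_time[v] - birth[v]
    width = max(4, len(str(n_tips)))
    labels: list[str | None] = [None] * len(parent)
    k = 0
    children = [[] for _ in parent]
    for v in range(1, len(parent)):
        children[parent[v]].append(v)
    for v in range(len(parent)):
        if not children[v]:
            k += 1
            labels[v] = f"t{k:0{width}d}"
    tree = Phylogeny(np.array(parent), blen, labels)
    if jitter_sd > 0:
        nrng = np.random.default_rng(np.random.SeedSequence([int(seed), 74]))
        factors = np.exp(nrng.normal(0.0, jitter_sd, size=tree.n_nodes))
        blen = tree.blen * factors
        blen[0] = 0.0
        tree = Phylogeny(tree.parent, blen, tree.labels)
    if mean_tip_depth is not None:
        depths = node_depths(tree)[tree.tip_indices()]
        mean_depth = float(depths.mean())
        if mean_depth <= 0:
            raise GCJumpError("degenerate tree: zero mean tip depth")
        tree = Phylogeny(
            tree.parent, tree.blen * (mean_tip_depth / mean_depth), tree.labels
        )
    return tree


@dataclass
class SyntheticDataset:
    """A simulated clade: tree, tip traits, the hidden truth, and per-jump
    ecological annotations."""

    tree: Phylogeny
    traits: dict[str, float]
    truth: JumpConfiguration
    params: LevyParams
    annotations: dict[tuple[str, int], EcologyAnnotation]
    seed: int
    clade_id: str = "synthetic"

    def write(self, outdir) -> None:
        """Write tree/traits/annotations in the pipeline's input formats,
        and the truth to a JSON sidecar that inference never reads."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_newick(self.tree, path=out / "tree.nwk")
        write_trait_table(self.traits, out / "gc.tsv")
        if self.annotations:
            write_annotation_table(self.annotations, out / "annotations.tsv")
        sidecar = {
            "seed": self.seed,
            "params": {
                "sigma2_0": self.params.sigma2_0,
                "lam": self.params.lam,
                "alpha": self.params.alpha,
                "x0": self.params.x0,
            },
            "jump_counts": {str(k): v for k, v in self.truth.as_dict().items() if v},
            "jump_disp": {
                str(b): float(self.truth.jump_disp[b])
                for b in self.tree.branches()
                if self.truth.counts[b]
            },
        }
        (out / "truth.json").write_text(json.dumps(sidecar, indent=1))


def _annotate_jumps(
    tree: Phylogeny,
    truth: JumpConfiguration,
    ecology_effect: float,
    rng: np.random.Generator,
    clade_id: str,
) -> dict[tuple[str, int], EcologyAnnotation]:
    """Lifestyle annotations for planted jumps.

    Each jump branch is assigned a host-switch pattern whose probability of
    being a free-living -> host-associated gain is tilted by
    ``ecology_effect`` toward downward jumps (and the reverse for losses);
    at 0 the direction and the switch are independent, giving a null for
    the exact test.  Marine flags and oxygen classes are independent noise.
    """
    if not -1.0 <= ecology_effect <= 1.0:
        raise GCJumpError("ecology_effect must lie in [-1, 1]")
    annotations: dict[tuple[str, int], EcologyAnnotation] = {}
    idx = 0
    for b in truth.branches_with_jumps():
        idx += 1
        s = 1.0 if truth.jump_disp[int(b)] < 0 else -1.0  # +1 tilts gains to down
        p_gain = 0.25 * (1.0 + ecology_effect * s)
        p_loss = 0.25 * (1.0 - ecology_effect * s)
        u = rng.random()
        if u < p_gain:
            host_a, host_s = "host_associated", "not_host_dependent"
        elif u < p_gain + p_loss:
            host_a, host_s = "not_host_dependent", "host_associated"
        else:
            host_a = host_s = "not_host_dependent"
        oxy = ["anaerobic", "facultative", "aerobic", "obligately_aerobic"]
        annotations[(clade_id, idx)] = EcologyAnnotation(
            host_status_affected=host_a,
            host_status_sister=host_s,
            marine=bool(rng.random() < 0.5),
            oxygen_affected=oxy[rng.integers(4)],
            oxygen_sister=oxy[rng.integers(4)],
        )
    return annotations


def generate_dataset(
    n_tips: int = 300,
    params: LevyParams | None = None,
    gc_bounds: tuple[float, float] | None = None,
    ecology_effect: float = 0.0,
    seed: int = 0,
    birth_rate: float = 1.0,
    jitter_sd: float = 0.3,
    mean_tip_depth: float | None = DEFAULT_TREE_HEIGHT,
    clade_id: str = "synthetic",
) -> SyntheticDataset:
    """One synthetic order-level clade with planted jumps and annotations.

    The tree is a branch-length-jittered Yule tree rescaled to a typical
    order-clade depth; traits follow :func:`~gcjump.levy_model.simulate_levy`
    under ``params`` (defaults: :func:`default_clade_params`), with
    reflecting boundaries when ``gc_bounds`` is given.  Deterministic from
    ``seed``.
    """
    params = params if params is not None else default_clade_params()
    ss = np.random.SeedSequence(int(seed))
    tree_seed, sim_seed, ann_seed = ss.generate_state(3, dtype=np.uint32).tolist()
    tree = simulate_yule_tree(
        n_tips,
        birth_rate=birth_rate,
        seed=tree_seed,
        jitter_sd=jitter_sd,
        mean_tip_depth=mean_tip_depth,
    )
    traits, truth = simulate_levy(tree, params, seed=sim_seed, gc_bounds=gc_bounds)
    annotations = _annotate_jumps(
        tree, truth, ecology_effect, np.random.default_rng(ann_seed), clade_id
    )
    return SyntheticDataset(
        tree=tree,
        traits=traits,
        truth=truth,
        params=params,
        annotations=annotations,
        seed=seed,
        clade_id=clade_id,
    )
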