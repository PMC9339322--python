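"""Jump calls, sister-clade magnitudes, direction tallies, and the
branch-depth null.

A branch is called as having experienced a jump when its posterior
probability strictly exceeds the calibrated threshold.  The magnitude of a
called jump is approximated as the median GC% of the tips descending from
the called branch minus the median GC% of the tips descending from its
sister branch; tips lying under *other* called branches nested within
either side are excluded first, so that one jump does not contaminate the
baseline of another.  The "toward the tips" visual impression is tested
against a null in which the same number of jumps is placed on branches
with probability proportional to branch length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import ChosenThreshold
from .errors import GCJumpError, MagnitudeUnavailableError, PolytomyError
from .levy_model import BranchPosteriors
from .phylo_core import Phylogeny, node_depths, validate_traits

__all__ = [
    "JumpCall",
    "JumpMagnitude",
    "DirectionSummary",
    "call_jumps",
    "jump_magnitude",
    "jump_magnitudes",
    "direction_summary",
    "depth_randomization_test",
    "jump_table",
]


@dataclass
class JumpCall:
    """A called branch: id (node index below the branch), its pp, and a
    serial "jump index" unique within the clade (preorder order)."""

    branch: int
    pp: float
    jump_index: int


@dataclass
class JumpMagnitude:
    branch: int
    delta_gc: float
    direction: str  # "up" | "down" | "zero"
    n_affected_tips: int
    n_sister_tips: int


@dataclass
class DirectionSummary:
    n_down: int
    n_up: int
    n_zero: int
    median_abs_down: float
    median_abs_up: float


def call_jumps(
    posteriors: BranchPosteriors, threshold: ChosenThreshold | float
) -> list[JumpCall]:
    """Branches with pp strictly greater than the threshold, indexed in
    preorder traversal order (jump_index 1, 2, ...)."""
    thr = threshold.threshold if isinstance(threshold, ChosenThreshold) else float(threshold)
    if not 0.0 <= thr <= 1.0:
        raise GCJumpError("threshold must lie in [0, 1]")
    tree = posteriors.tree
    calls = []
    for b in tree.branches():  # node order is preorder
        if posteriors.pp[b] > thr:
            calls.append(JumpCall(int(b), float(posteriors.pp[b]), len(calls) + 1))
    return calls


def _descendant_or_self(tree: Phylogeny, ancestor: int, node: int) -> bool:
    v = node
    while v != -1:
        if v == ancestor:
            return True
        v = tree.parent[v]
    return False


def _clade_tips_excluding(
    tree: Phylogeny, top: int, excluded_branches: list[int]
) -> np.ndarray:
    """Tips under ``top`` minus tips under any excluded branch strictly
    nested inside ``top``'s clade."""
    tips = set(int(t) for t in tree.subtree_tips(top))
    for b in excluded_branches:
        if b != top and _descendant_or_self(tree, top, b):
            tips -= set(int(t) for t in tree.subtree_tips(b))
    return np.array(sorted(tips), dtype=np.int64)


def jump_magnitude(
    tree: Phylogeny,
    traits: dict[str, float],
    call: JumpCall,
    all_calls: list[JumpCall],
) -> JumpMagnitude:
    """Sister-clade median estimate of a called jump's direction/size.

    ``delta_gc = median(affected tips) - median(sister tips)`` after
    removing, on both sides, tips that descend from any *other* called
    branch nested within that side (nested-jump exclusion).  Raises
    :class:`PolytomyError` when the called branch's parent is not binary,
    and :class:`MagnitudeUnavailableError` when either side is empty after
    exclusion.
    """
    validate_traits(tree, traits)
    b = call.branch
    if b <= 0 or b >= tree.n_nodes:
        raise GCJumpError(f"call branch {b} is not a branch of the tree")
    sister = tree.sister(b)  # raises PolytomyError on non-binary parent
    other = [c.branch for c in all_calls if c.branch != b]
    affected = _clade_tips_excluding(tree, b, other)
    sister_tips = _clade_tips_excluding(tree, sister, other)
    if affected.size == 0 or sister_tips.size == 0:
        side = "affected" if affected.size == 0 else "sister"
        raise MagnitudeUnavailableError(
            f"jump {call.jump_index} (branch {b}): {side} tip set empty "
            "after nested-jump exclusion"
        )
    med_a = float(np.median([traits[tree.labels[t]] for t in affected]))
    med_s = float(np.median([traits[tree.labels[t]] for t in sister_tips]))
    delta = med_a - med_s
    direction = "up" if delta > 0 else ("down" if delta < 0 else "zero")
    return JumpMagnitude(
        branch=b,
        delta_gc=delta,
        direction=direction,
        n_affected_tips=int(affected.size),
        n_sister_tips=int(sister_tips.size),
    )


def jump_magnitudes(
    tree: Phylogeny, traits: dict[str, float], calls: list[JumpCall]
) -> tuple[list[JumpMagnitude], list[JumpCall]]:
    """Magnitudes for all calls; calls whose magnitude is unavailable
    (empty side after exclusion) are returned separately, never dropped
    silently."""
    out = []
    unavailable = []
    for c in calls:
        try:
            out.append(jump_magnitude(tree, traits, c, calls))
        except MagnitudeUnavailableError:
            unavailable.append(c)
    return out, unavailable


def direction_summary(magnitudes: list[JumpMagnitude]) -> DirectionSummary:
    """Tallies of downward/upward jumps and their median absolute sizes.

    Exact zero deltas are counted separately and excluded from both
    medians.
    """
    if not magnitudes:
        raise GCJumpError("direction_summary requires at least one magnitude")
    down = [abs(m.delta_gc) for m in magnitudes if m.direction == "down"]
    up = [abs(m.delta_gc) for m in magnitudes if m.direction == "up"]
    zero = sum(1 for m in magnitudes if m.direction == "zero")
    return DirectionSummary(
        n_down=len(down),
        n_up=len(up),
        n_zero=zero,
        median_abs_down=float(np.median(down)) if down else float("nan"),
        median_abs_up=float(np.median(up)) if up else float("nan"),
    )


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    # two-sample KS distance; small-n friendly, no ties assumption
    allv = np.concatenate([a, b])
    allv.sort()
    ca = np.searchsorted(np.sort(a), allv, side="right") / a.size
    cb = np.searchsorted(np.sort(b), allv, side="right") / b.size
    return float(np.max(np.abs(ca - cb)))


def depth_randomization_test(
    tree: Phylogeny,
    calls: list[JumpCall],
    n_random: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo test of call depths against length-proportional
    placement.

    Observed statistic: branch-midpoint depths of the calls.  Null: the
    same number of branches drawn (with replacement) with probability
    proportional to branch length, ``n_random`` times.  The p-value is the
    fraction of null draws whose KS distance to the pooled null is at
    least the observed one (add-one Monte-Carlo correction); it is
    two-sided in the sense that any distributional difference — tipward or
    rootward concentration — inflates the KS distance.
    """
    if not calls:
        raise GCJumpError("depth_randomization_test requires at least one call")
    depths = node_depths(tree)
    mid = np.array([depths[c.branch] - 0.5 * tree.blen[c.branch] for c in calls])
    branches = tree.branches()
    w = tree.blen[branches]
    if w.sum() <= 0:
        raise GCJumpError("tree has zero total branch length")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(branches, size=(n_random, len(calls)), p=p)
    null_depths = depths[draws] - 0.5 * tree.blen[draws]
    pooled = null_depths.ravel()
    if np.unique(pooled).size <= 1 and np.unique(mid).size <= 1:
        return 1.0
    d_obs = _ks_distance(mid, pooled)
    d_null = np.array([_ks_distance(null_depths[i], pooled) for i in range(n_random)])
    return float((1 + np.sum(d_null >= d_obs)) / (n_random + 1))


def jump_table(
    clade_id: str,
    calls: list[JumpCall],
    magnitudes: list[JumpMagnitude],
) -> pd.DataFrame:
    """Flat per-jump table (TSV-ready) combining calls and magnitudes."""
    mag_by_branch = {m.branch: m for m in magnitudes}
    rows = []
    for c in calls:
        m = mag_by_branch.get(c.branch)
        rows.append(
            {
                "clade_id": clade_id,
                "jump_index": c.jump_index,
                "branch_id": c.branch,
                "pp": c.pp,
                "delta_gc": m.delta_gc if m else np.nan,
                "direction": m.direction if m else "unavailable",
                "n_affected_tips": m.n_affected_tips if m else 0,
                "n_sister_tips": m.n_sister_tips if m else 0,
            }
        )
    return pd.DataFrame(rows)
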