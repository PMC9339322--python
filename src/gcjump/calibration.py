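"""Simulation-based calibration of the posterior-probability threshold.

Because the jump posteriors are continuous, calling jumps requires a pp
cutoff.  The cutoff is chosen by simulating datasets with *known* jumps
under the fitted model parameters, re-running the posterior inference on
the simulated tip values only, and sweeping candidate thresholds: a called
branch is a "true jump estimate" when the simulation planted >= 1 jump
there, otherwise a "false jump estimate".  Precision and recall (both in
percent) are pooled across simulations — numerators and denominators are
summed before dividing — and the chosen threshold is the one with maximum
recall among those reaching the configured minimum precision (default
90%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GCJumpError
from .levy_model import (
    BranchPosteriors,
    JumpConfiguration,
    LevyParams,
    branch_jump_posteriors,
    simulate_levy,
)
from .phylo_core import Phylogeny

__all__ = [
    "CalibrationCurve",
    "ChosenThreshold",
    "default_thresholds",
    "precision_recall",
    "run_calibration",
    "choose_threshold",
]


def default_thresholds() -> np.ndarray:
    """0.05-step grid over (0, 1) plus the conventional 0.75/0.9/0.95."""
    grid = set(np.round(np.arange(0.05, 1.0, 0.05), 10).tolist())
    grid.update([0.75, 0.9, 0.95])
    return np.array(sorted(grid))


@dataclass
class CalibrationCurve:
    """Pooled precision/recall per threshold, with per-simulation curves
    retained for inspection.

    ``pooled`` columns: threshold, precision_pct (NaN when no branch was
    called at that threshold), recall_pct, n_true_est, n_false_est,
    n_sim_jumps.
    """

    pooled: pd.DataFrame
    per_simulation: list[pd.DataFrame] = field(default_factory=list)
    n_simulations: int = 0
    zero_jump_simulations: int = 0

    def to_tsv(self, path) -> None:
        self.pooled.to_csv(path, sep="\t", index=False)


@dataclass
class ChosenThreshold:
    threshold: float
    precision_pct: float
    recall_pct: float
    n_simulations: int
    attainable: bool
    min_precision: float = 90.0

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "precision_pct": self.precision_pct,
            "recall_pct": self.recall_pct,
            "n_simulations": self.n_simulations,
            "attainable": self.attainable,
            "min_precision": self.min_precision,
        }


def _truth_branches(truth: JumpConfiguration, denominator: str) -> tuple[set, int]:
    branches = set(int(b) for b in truth.branches_with_jumps())
    if denominator == "branches":
        denom = len(branches)
    elif denominator == "events":
        denom = truth.total_jumps
    else:
        raise GCJumpError("denominator must be 'branches' or 'events'")
    return branches, denom


def precision_recall(
    inferred: list[set],
    truth: list[JumpConfiguration],
    denominator: str = "branches",
) -> tuple[float | None, float]:
    """Pooled precision and recall in percent.

    ``inferred`` is one set of called branch ids per simulation; ``truth``
    the matching simulated configurations.  A branch counts as a true jump
    estimate when the simulation planted >= 1 jump on it.  The recall
    denominator counts branches carrying >= 1 simulated jump (multiple
    jumps on one branch are one detectable event); pass
    ``denominator='events'`` for raw event counts.  Precision is ``None``
    (undefined, never 0 or 100) when nothing was called.
    """
    if len(inferred) != len(truth):
        raise GCJumpError("inferred and truth must have one entry per simulation")
    tp = fp = denom = 0
    for called, cfg in zip(inferred, truth):
        branches, d = _truth_branches(cfg, denominator)
        denom += d
        for b in called:
            if b in branches:
                tp += 1
            else:
                fp += 1
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    recall = 100.0 * tp / denom if denom > 0 else 0.0
    return precision, recall


def _curve_rows(
    thresholds: np.ndarray,
    posteriors: list[BranchPosteriors],
    truths: list[JumpConfiguration],
    denominator: str,
) -> pd.DataFrame:
    rows = []
    for thr in thresholds:
        tp = fp = denom = 0
        for post, cfg in zip(posteriors, truths):
            called = set(int(b) for b in post.tree.branches() if post.pp[b] > thr)
            branches, d = _truth_branches(cfg, denominator)
            denom += d
            tp += len(called & branches)
            fp += len(called - branches)
        rows.append(
            {
                "threshold": float(thr),
                "precision_pct": 100.0 * tp / (tp + fp) if tp + fp else np.nan,
                "recall_pct": 100.0 * tp / denom if denom else 0.0,
                "n_true_est": tp,
                "n_false_est": fp,
                "n_sim_jumps": denom,
            }
        )
    return pd.DataFrame(rows)


def run_calibration(
    tree: Phylogeny,
    fitted: LevyParams,
    n_simulations: int = 5,
    thresholds: np.ndarray | None = None,
    seed: int = 0,
    denominator: str = "branches",
    mcmc_steps: int = 4000,
    burn_in: int = 1000,
    gc_bounds: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Simulate with known jumps under ``fitted``, re-infer posteriors from
    the simulated tip values only, and tabulate pooled precision/recall.

    The posterior inference uses the same fixed parameters that generated
    the simulations (they play the role of the data fit).  Simulations that
    happen to plant zero jumps are retained — they contribute false calls
    to precision but nothing to the recall denominator — and counted in
    ``zero_jump_simulations``.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise GCJumpError("thresholds must lie strictly inside (0, 1)")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_simulations, dtype=np.uint32).tolist()
    posteriors = []
    truths = []
    zero_jump = 0
    for k in range(n_simulations):
        traits, truth = simulate_levy(
            tree, fitted, seed=seeds[2 * k], gc_bounds=gc_bounds
        )
        if truth.total_jumps == 0:
            zero_jump += 1
            warnings.warn(
                f"calibration simulation {k} planted zero jumps; it "
                "contributes to precision only",
                stacklevel=2,
            )
        post = branch_jump_posteriors(
            tree,
            traits,
            fitted,
            mcmc_steps=mcmc_steps,
            burn_in=burn_in,
            seed=seeds[2 * k + 1],
        )
        posteriors.append(post)
        truths.append(truth)
    pooled = _curve_rows(thresholds, posteriors, truths, denominator)
    per_sim = [
        _curve_rows(thresholds, [p], [t], denominator)
        for p, t in zip(posteriors, truths)
    ]
    return CalibrationCurve(
        pooled=pooled,
        per_simulation=per_sim,
        n_simulations=n_simulations,
        zero_jump_simulations=zero_jump,
    )


def choose_threshold(
    curve: CalibrationCurve, min_precision: float = 90.0
) -> ChosenThreshold:
    """Pick the threshold with maximum pooled recall among those with
    pooled precision >= ``min_precision``; ties break toward the lower
    threshold.  Thresholds where precision is undefined (nothing called)
    are excluded from the rule.  If no threshold qualifies, the
    highest-precision one is returned flagged unattainable.
    """
    df = curve.pooled
    if df.empty:
        raise GCJumpError("calibration curve is empty")
    ok = df[df["precision_pct"] >= min_precision]
    if len(ok):
        best = ok.sort_values(
            ["recall_pct", "threshold"], ascending=[False, True]
        ).iloc[0]
        attainable = True
    else:
        defined = df[df["precision_pct"].notna()]
        if defined.empty:
            best = df.iloc[-1]
            attainable = False
        else:
            best = defined.sort_values(
                ["precision_pct", "threshold"], ascending=[False, True]
            ).iloc[0]
            attainable = False
    return ChosenThreshold(
        threshold=float(best["threshold"]),
        precision_pct=float(best["precision_pct"])
        if np.isfinite(best["precision_pct"])
        else float("nan"),
        recall_pct=float(best["recall_pct"]),
        n_simulations=curve.n_simulations,
        attainable=attainable,
        min_precision=min_precision,
    )
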