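"""End-to-end pipeline: fit models, calibrate a threshold, call jumps,
and summarize their directions, depths, and ecological context.

Stages run strictly in order and each writes its outputs under stable
filenames before the next begins, so a failed run leaves a usable partial
manifest.  No stage reads a later stage's output, and nothing here ever
reads a simulation truth sidecar.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    choose_threshold,
    default_thresholds,
    run_calibration,
)
from .ecology import (
    classify_switch,
    fisher_exact_2x2,
    read_annotation_table,
    tally_directions,
    ContingencyTable2x2,
)
from .errors import GCJumpError
from .jump_analysis import (
    call_jumps,
    depth_randomization_test,
    direction_summary,
    jump_magnitudes,
    jump_table,
)
from .levy_model import branch_jump_posteriors, profile_alpha
from .phylo_core import (
    read_newick,
    read_trait_table,
    subsample_tree,
    validate_traits,
    write_newick,
)
from .trait_models import fit_bm, fit_ou, fit_report, lrt

log = logging.getLogger("gcjump")

__all__ = ["PipelineConfig", "StageError", "run_full_pipeline"]


class StageError(GCJumpError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """Everything a full run needs; echoed verbatim into every output."""

    tree_path: str
    traits_path: str
    out_dir: str
    annotations_path: str | None = None
    clade_id: str = "clade"
    subsample_threshold: float | None = None
    alpha_grid: tuple = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0)
    n_simulations: int = 5
    thresholds: tuple | None = None
    min_precision: float = 90.0
    lrt_df: int = 2
    seed: int = 0
    em_max_iter: int = 100
    em_samples: int = 20
    mcmc_steps: int = 4000
    burn_in: int = 1000
    n_depth_random: int = 1000

    def as_dict(self) -> dict:
        return asdict(self)


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    payload = {"config": config.as_dict(), "gcjump_version": __version__, **payload}
    path.write_text(json.dumps(payload, indent=1, default=str))


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns the result manifest.

    Order: optional de-replication -> BM/OU/Levy fits with alpha profiling
    -> LRT -> branch posteriors -> simulate-and-calibrate threshold ->
    jump calls -> magnitudes/directions -> depth null -> ecology tallies
    and exact test (when annotations are given).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "outputs": {}}
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(8, dtype=np.uint32).tolist()
    stage = "load"

    def finish_stage(name, t0, **info):
        log.info(
            "stage=%s seed=%s wall=%.2fs %s",
            name,
            config.seed,
            time.perf_counter() - t0,
            " ".join(f"{k}={v}" for k, v in info.items()),
        )
        manifest["stages"].append(name)

    try:
        t0 = time.perf_counter()
        tree = read_newick(config.tree_path)
        traits = read_trait_table(config.traits_path)
        if config.subsample_threshold is not None:
            tree = subsample_tree(tree, config.subsample_threshold)
            traits = {k: v for k, v in traits.items() if k in set(tree.tip_labels())}
            write_newick(tree, path=out / "subsampled.nwk")
            manifest["outputs"]["subsampled_tree"] = "subsampled.nwk"
        validate_traits(tree, traits)
        finish_stage(stage, t0, n_tips=tree.n_tips)

        stage = "fit_models"
        t0 = time.perf_counter()
        bm, ll_bm = fit_bm(tree, traits)
        ou, ll_ou = fit_ou(tree, traits)
        levy_fit = profile_alpha(
            tree,
            traits,
            alpha_grid=config.alpha_grid,
            seed=seeds[0],
            em_max_iter=config.em_max_iter,
            n_samples=config.em_samples,
        )
        fits = {
            "bm": fit_report("bm", bm, ll_bm, tree.n_tips),
            "ou": fit_report("ou", ou, ll_ou, tree.n_tips),
            "levy": fit_report(
                "levy", levy_fit.params, levy_fit.loglik, tree.n_tips,
                converged=all(r.converged for r in levy_fit.alpha_grid.values()),
                seed=seeds[0],
            ),
            "levy_alpha_grid": {
                str(a): {"loglik": r.loglik, "loglik_se": r.loglik_se}
                for a, r in levy_fit.alpha_grid.items()
            },
        }
        _write_json(out / "fits.json", fits, config)
        manifest["outputs"]["fits"] = "fits.json"
        finish_stage(stage, t0, best_alpha=levy_fit.best_alpha)

        stage = "lrt"
        t0 = time.perf_counter()
        # the Levy loglik is a stochastic estimate, so clamp noise at 0
        p = lrt(levy_fit.loglik, ll_bm, config.lrt_df, clamp=True)
        comparison = {
            "loglik_bm": ll_bm,
            "loglik_ou": ll_ou,
            "loglik_levy": levy_fit.loglik,
            "lrt_stat": max(0.0, 2 * (levy_fit.loglik - ll_bm)),
            "df": config.lrt_df,
            "p_value": p,
        }
        _write_json(out / "model_comparison.json", comparison, config)
        manifest["outputs"]["model_comparison"] = "model_comparison.json"
        finish_stage(stage, t0, p=p)

        stage = "posteriors"
        t0 = time.perf_counter()
        post = branch_jump_posteriors(
            tree,
            traits,
            levy_fit.params,
            mcmc_steps=config.mcmc_steps,
            burn_in=config.burn_in,
            seed=seeds[1],
        )
        pd.DataFrame(
            {"branch_id": tree.branches(), "pp": post.pp[tree.branches()]}
        ).to_csv(out / "posteriors.tsv", sep="\t", index=False)
        write_newick(tree, branch_annotations=post.as_dict(), path=out / "posteriors.nwk")
        manifest["outputs"]["posteriors"] = "posteriors.tsv"
        manifest["outputs"]["posteriors_tree"] = "posteriors.nwk"
        finish_stage(stage, t0, converged=post.converged)

        stage = "calibrate"
        t0 = time.perf_counter()
        curve = run_calibration(
            tree,
            levy_fit.params,
            n_simulations=config.n_simulations,
            thresholds=np.array(config.thresholds)
            if config.thresholds is not None
            else default_thresholds(),
            seed=seeds[2],
            mcmc_steps=config.mcmc_steps,
            burn_in=config.burn_in,
        )
        chosen = choose_threshold(curve, min_precision=config.min_precision)
        curve.to_tsv(out / "calibration.tsv")
        _write_json(out / "threshold.json", chosen.as_dict(), config)
        manifest["outputs"]["calibration"] = "calibration.tsv"
        manifest["outputs"]["threshold"] = "threshold.json"
        finish_stage(stage, t0, threshold=chosen.threshold, attainable=chosen.attainable)

        stage = "detect"
        t0 = time.perf_counter()
        calls = call_jumps(post, chosen)
        mags, unavailable = jump_magnitudes(tree, traits, calls)
        table = jump_table(config.clade_id, calls, mags)
        table.to_csv(out / "jumps.tsv", sep="\t", index=False)
        manifest["outputs"]["jumps"] = "jumps.tsv"
        finish_stage(stage, t0, n_calls=len(calls), n_unavailable=len(unavailable))

        stage = "summarize"
        t0 = time.perf_counter()
        summary: dict = {"n_calls": len(calls)}
        if mags:
            s = direction_summary(mags)
            summary.update(asdict(s))
        if calls:
            summary["depth_randomization_p"] = depth_randomization_test(
                tree, calls, n_random=config.n_depth_random, seed=seeds[3]
            )
        _write_json(out / "direction_summary.json", summary, config)
        manifest["outputs"]["direction_summary"] = "direction_summary.json"
        finish_stage(stage, t0)

        if config.annotations_path is not None:
            stage = "ecology"
            t0 = time.perf_counter()
            annotations = read_annotation_table(config.annotations_path)
            records = []
            gain = {"down": 0, "up": 0}
            loss = {"down": 0, "up": 0}
            for call, mag in zip(calls, mags):
                ann = annotations.get((config.clade_id, call.jump_index))
                if ann is None or mag.direction == "zero":
                    continue
                labels = classify_switch(ann)
                records.append((mag.direction, labels))
                if "host_gain" in labels:
                    gain[mag.direction] += 1
                if "host_loss" in labels:
                    loss[mag.direction] += 1
            eco: dict = {"n_annotated": len(records)}
            if records:
                tally = tally_directions(records)
                tally.to_csv(out / "ecology_tally.tsv", sep="\t", index=False)
                manifest["outputs"]["ecology_tally"] = "ecology_tally.tsv"
            if sum(gain.values()) + sum(loss.values()) > 0:
                tab = ContingencyTable2x2(
                    gain["down"], gain["up"], loss["down"], loss["up"]
                )
                fr = fisher_exact_2x2(tab)
                eco["host_switch_table"] = [[tab.a, tab.b], [tab.c, tab.d]]
                eco["fisher_p"] = fr.p_two_sided
                eco["odds_ratio"] = fr.odds_ratio
            _write_json(out / "ecology.json", eco, config)
            manifest["outputs"]["ecology"] = "ecology.json"
            finish_stage(stage, t0, n_annotated=len(records))

    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_json(out / "manifest.json", manifest, config)
        raise StageError(stage, exc) from exc

    _write_json(out / "manifest.json", manifest, config)
    manifest["out_dir"] = str(out)
    return manifest
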