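"""End-to-end analysis pipeline.

Orchestrates simulate (or load) -> harmonize -> MRT habitat delimitation
-> indicator species -> plot/habitat SES of MPD & MNTD -> beta diversity
(Dpw/Dnn SES) -> Mantel / partial Mantel partitioning, writing every
stage's tables, a manifest with content hashes, and a timestamped log
into a run directory.  All randomness flows from a single run seed
through named per-stage child seeds, so identical configurations yield
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha, beta, core_io, indicator, mrt, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

_STAGES = ("simulate", "mrt", "indval", "alpha", "beta", "mantel")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed for a named stage (kept below 2^31)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return (int(seed) * 1_000_003 + _STAGES.index(stage) + 1) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``scenario`` (a synthetic-survey specification) or the three
    input paths must be given.  ``n_null_alpha`` follows the common
    999-randomisation convention; ``n_null_beta`` is smaller by default
    because the beta null costs one randomisation per unit pair.
    """

    scenario: synthetic.ScenarioConfig | None = None
    tree_path: str | None = None
    community_path: str | None = None
    environment_path: str | None = None
    predictors: list[str] = field(default_factory=lambda: ["elevation", "latitude"])
    min_leaf: int = 5
    cv_folds: int = 10
    n_cv_reps: int = 50
    n_null_alpha: int = 999
    n_null_beta: int = 199
    n_perm_indval: int = 999
    n_perm_mantel: int = 999
    weighted: bool = False
    null_model: str = "pool"
    hellinger: bool = False
    seed: int = 0
    out_dir: str = "run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scenario is not None:
            d["scenario"] = dataclasses.asdict(self.scenario)
            d["scenario"]["elevation_range"] = list(self.scenario.elevation_range)
            d["scenario"]["latitude_range"] = list(self.scenario.latitude_range)
            d["scenario"]["longitude_range"] = list(self.scenario.longitude_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = d.get("scenario")
        if sc is not None:
            sc = dict(sc)
            for key in ("elevation_range", "latitude_range", "longitude_range"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            d["scenario"] = synthetic.ScenarioConfig(**sc)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class _Run:
    """Output directory with logging and a hashed manifest."""

    def __init__(self, out_dir: Path):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, str] = {}
        self._log_lines: list[str] = []

    def log(self, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        self._log_lines.append(f"{stamp} {msg}")
        logger.info(msg)

    def write_table(self, name: str, df: pd.DataFrame, index_label=None) -> Path:
        path = self.dir / name
        df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
        self._register(path)
        return path

    def write_text(self, name: str, text: str) -> Path:
        path = self.dir / name
        path.write_text(text)
        self._register(path)
        return path

    def _register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.manifest[path.name] = digest

    def finalize(self) -> None:
        (self.dir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )
        (self.dir / "run.log").write_text("\n".join(self._log_lines) + "\n")


def _load_inputs(cfg: RunConfig, run: _Run):
    if cfg.scenario is not None:
        sc = cfg.scenario.with_(seed=stage_seed(cfg.seed, "simulate"))
        run.log(f"simulate: scenario {sc}")
        tree, comm, env, truth = synthetic.simulate_dataset(sc)
        run.write_text("tree.nwk", tree.as_string(schema="newick"))
        run.write_table("community.tsv", comm, index_label="plot_id")
        run.write_table("environment.tsv", env, index_label="plot_id")
        run.write_table("true_habitats.tsv", truth.to_frame(), index_label="plot_id")
        return tree, comm, env
    if not (cfg.tree_path and cfg.community_path and cfg.environment_path):
        raise ValueError("config needs either a scenario or all three input paths")
    run.log(f"load: {cfg.tree_path}, {cfg.community_path}, {cfg.environment_path}")
    tree = core_io.read_phylogeny(cfg.tree_path)
    comm = core_io.read_community(cfg.community_path)
    env = core_io.read_environment(cfg.environment_path)
    return tree, comm, env


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Any stage failure aborts the run with the stage name in the raised
    error message.
    """
    run = _Run(Path(cfg.out_dir))
    cfg.to_yaml(run.dir / "config.yaml")
    stage = "setup"
    try:
        stage = "simulate"
        tree, comm, env = _load_inputs(cfg, run)

        stage = "harmonize"
        tree, comm, env = core_io.harmonize(tree, comm, env)
        gap = core_io.ultrametricity_gap(tree)
        run.log(f"harmonize: {comm.shape[0]} plots x {comm.shape[1]} species; "
                f"ultrametricity gap {gap:.3g}")
        D = core_io.patristic_distances(tree)
        D = D.reorder(list(comm.columns))

        stage = "mrt"
        model = mrt.grow_and_select(
            comm,
            env,
            predictors=cfg.predictors,
            min_leaf=cfg.min_leaf,
            cv_folds=cfg.cv_folds,
            n_cv_reps=cfg.n_cv_reps,
            seed=stage_seed(cfg.seed, "mrt"),
            hellinger=cfg.hellinger,
        )
        run.log(f"mrt: selected {model.n_leaves} leaves, CVRE {model.cvre:.4f}, "
                f"R2 {model.r_squared:.4f}")
        habitats = model.leaf_assignment
        run.write_table("habitat_assignment.tsv", habitats.to_frame(),
                        index_label="plot_id")
        run.write_table("mrt_path.tsv", model.size_path)
        run.write_table("mrt_nodes.tsv", model.to_table())
        run.write_text("mrt_tree.txt", model.to_text() + "\n")
        run.write_table(
            "mrt_summary.tsv",
            pd.DataFrame(
                [{"n_leaves": model.n_leaves, "cvre": model.cvre,
                  "r_squared": model.r_squared}]
            ),
        )

        stage = "indval"
        if model.n_leaves >= 2:
            iv = indicator.indval_test(
                comm, habitats, n_perm=cfg.n_perm_indval,
                seed=stage_seed(cfg.seed, "indval"),
            )
            run.write_table("indval.tsv", iv.to_frame())
            n_sig = len(iv.significant())
            run.log(f"indval: {n_sig} significant indicator species at alpha=0.05")
        else:
            run.log("indval: skipped (single habitat)")

        stage = "alpha"
        seed_a = stage_seed(cfg.seed, "alpha")
        ses_tables = {}
        for metric in ("mpd", "mntd"):
            t = alpha.ses(
                metric, comm, D, n_null=cfg.n_null_alpha, seed=seed_a,
                weighted=cfg.weighted, null_model=cfg.null_model,
            )
            ses_tables[metric] = t
            run.write_table(f"ses_{metric}_plots.tsv", t, index_label="plot_id")
        if model.n_leaves >= 2:
            pooled = alpha.habitat_assemblage(comm, habitats)
            for metric in ("mpd", "mntd"):
                t = alpha.ses(
                    metric, pooled, D, n_null=cfg.n_null_alpha, seed=seed_a,
                    weighted=cfg.weighted, null_model=cfg.null_model,
                )
                run.write_table(f"ses_{metric}_habitats.tsv", t,
                                index_label="habitat")
        reg_rows = []
        for metric in ("mpd", "mntd"):
            for pred in cfg.predictors:
                if pred not in env.columns:
                    continue
                try:
                    reg = alpha.regress_ses(ses_tables[metric], env, pred)
                except ValueError as exc:
                    run.log(f"alpha: regression ses_{metric}~{pred} skipped: {exc}")
                    continue
                reg_rows.append(reg.to_row())
        if reg_rows:
            run.write_table("ses_regressions.tsv", pd.DataFrame(reg_rows))

        stage = "beta"
        seed_b = stage_seed(cfg.seed, "beta")
        space = beta.spatial_distances(env)
        run.write_table("dist_geographic.tsv", space.frame("geographic"))
        run.write_table("dist_elevation.tsv", space.frame("elevation"))
        beta_ses = {}
        for metric in ("dpw", "dnn"):
            bm = beta.ses_beta(
                comm, D, metric=metric, n_null=cfg.n_null_beta, seed=seed_b,
                weighted=cfg.weighted,
            )
            beta_ses[metric] = bm
            run.write_table(f"{metric}_observed.tsv", bm.frame("observed"))
            run.write_table(f"ses_{metric}.tsv", bm.frame("ses"))

        stage = "mantel"
        seed_m = stage_seed(cfg.seed, "mantel")
        rows = []
        for metric, bm in beta_ses.items():
            z = bm.frame("ses").to_numpy()
            z = np.where(np.isnan(z), 0.0, z)
            np.fill_diagonal(z, 0.0)
            z = (z + z.T) / 2.0
            pairs = [
                ("elevation", space.elevation),
                ("geographic", space.geographic),
            ]
            for name, M in pairs:
                rows.append(
                    beta.mantel(
                        z, M, n_perm=cfg.n_perm_mantel, seed=seed_m,
                        names=(f"ses_{metric}", name),
                    ).to_row()
                )
            rows.append(
                beta.partial_mantel(
                    z, space.geographic, space.elevation,
                    n_perm=cfg.n_perm_mantel, seed=seed_m,
                    names=(f"ses_{metric}", "geographic", "elevation"),
                ).to_row()
            )
            rows.append(
                beta.partial_mantel(
                    z, space.elevation, space.geographic,
                    n_perm=cfg.n_perm_mantel, seed=seed_m,
                    names=(f"ses_{metric}", "elevation", "geographic"),
                ).to_row()
            )
        run.write_table("mantel_results.tsv", pd.DataFrame(rows))
    except Exception as exc:
        run.log(f"FAILED at stage {stage}: {exc}")
        run.finalize()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    run.log("done")
    run.finalize()
    return run.dir
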