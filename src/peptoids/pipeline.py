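"""Config-driven orchestration of the three analysis stages.

Stages are individually re-runnable from their persisted inputs and write
deterministic outputs (CSV tables, JSON reports, and a run manifest with
the config hash and seeds — no timestamps, so reruns are byte-identical).

* cluster stage: library -> descriptors, family labels, family profiles.
* design stage: lipid pool -> feasible factor space, D-optimal design,
  design report.
* fit stage: design + screen results -> model report, feasible optimum,
  contour grids.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import WardFamilies, cluster_profile, standardize
from .descriptors import CLUSTER_FEATURES, descriptor_table
from .design_space import candidate_set, count_blocks, default_lipid_pool
from .doe import select_design
from .errors import ValidationError
from .monomers import default_monomer_set, get_monomer, load_monomer_table
from .rsm import contour_grid, find_optimum, fit_rsm
from .sequences import LipidBlockFactors, parse_sequence
from .simulate import default_truth, simulate_screen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration; keys mirror module parameters 1:1."""

    # paths
    monomer_table: str | None = None     # packaged default when None
    library: str | None = None           # library CSV: id,sequence
    screen: str | None = None            # screen CSV: design_id,...,flux
    outdir: str = "."
    # clustering
    k: int = 12
    features: tuple = CLUSTER_FEATURES
    # design
    pool_codes: tuple | None = None
    length_min: int = 3
    length_max: int = 6
    headgroup: str = "Apd"
    n_runs: int = 34
    design_seed: int = 0
    n_starts: int = 20
    # model
    log_response: bool = True
    n_boot: int = 1000
    model_seed: int = 0
    # synthetic screen
    n_replicates: int = 3
    screen_seed: int = 0
    noise_sd: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def monomer_set(self):
        if self.monomer_table:
            return load_monomer_table(self.monomer_table)
        return default_monomer_set()


def _write_manifest(cfg: PipelineConfig, outdir: Path, stage: str,
                    extra: dict | None = None) -> None:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=list)
    manifest = {
        "stage": stage,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": {"design": cfg.design_seed, "model": cfg.model_seed,
                  "screen": cfg.screen_seed},
        "package_version": __version__,
        **(extra or {}),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_library(path, mset) -> tuple[list, list]:
    """Read a library CSV (columns id,sequence) against a monomer set."""
    df = pd.read_csv(path)
    for col in ("id", "sequence"):
        if col not in df.columns:
            raise ValidationError(f"library CSV missing column {col!r}")
    seqs = [parse_sequence(s, mset) for s in df["sequence"]]
    return list(df["id"]), seqs


def run_cluster_stage(cfg: PipelineConfig):
    """Descriptors + Ward family labels + per-family profile."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mset = cfg.monomer_set()
    if cfg.library:
        ids, seqs = load_library(cfg.library, mset)
    else:
        from .simulate import simulate_library
        seqs = simulate_library(mset=mset, seed=cfg.screen_seed)
        ids = list(range(1, len(seqs) + 1))
    desc = descriptor_table(seqs, ids=ids)
    features = list(cfg.features)
    Z = standardize(desc[features])
    wf = WardFamilies(n_clusters=cfg.k).fit(Z)
    labels = pd.DataFrame({"id": ids, "label": wf.labels_})
    profile = cluster_profile(wf.assignment_, desc[list(Z.columns)])
    desc.to_csv(outdir / "descriptors.csv", index=False)
    labels.to_csv(outdir / "clusters.csv", index=False)
    profile.to_csv(outdir / "cluster_profile.csv", index=False)
    _write_manifest(cfg, outdir, "cluster",
                    {"n_rows": len(desc), "k": cfg.k, "features": features})
    logger.info("[cluster] %d rows, k=%d, features=%s",
                len(desc), cfg.k, features)
    return desc, labels, profile


def run_design_stage(cfg: PipelineConfig):
    """Feasible space + D-optimal design + design report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mset = cfg.monomer_set()
    pool = default_lipid_pool(mset, codes=cfg.pool_codes,
                              length_min=cfg.length_min,
                              length_max=cfg.length_max)
    head = get_monomer(mset, cfg.headgroup)
    cands = candidate_set(pool, head)
    feasible = cands.to_frame().rename(columns={"sequence": "example_sequence"})
    design, designer = select_design(cands, cfg.n_runs, seed=cfg.design_seed,
                                     n_starts=cfg.n_starts)
    report = {
        "n_ordered_designs": count_blocks(pool),
        "n_feasible_points": len(cands),
        "n_runs": cfg.n_runs,
        "criterion": designer.criterion_,
        "log10_criterion": float(np.log10(designer.criterion_)),
        "seed": cfg.design_seed,
        "n_starts": cfg.n_starts,
        "columns": list(designer.spec_.terms),
        "ranges": {k: list(v) for k, v in designer.spec_.ranges.items()},
    }
    feasible.to_csv(outdir / "feasible_space.csv", index=False)
    df = design.to_frame()
    df.insert(0, "design_id", range(1, len(df) + 1))
    df.to_csv(outdir / "design.csv", index=False)
    with open(outdir / "design_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_manifest(cfg, outdir, "design", {"criterion": designer.criterion_})
    logger.info("[design] %d feasible points, %d runs, logdet10=%.3f",
                len(cands), cfg.n_runs, report["log10_criterion"])
    return cands, design, designer


def run_simulate_stage(cfg: PipelineConfig, design=None):
    """Synthetic screen for a persisted (or freshly selected) design."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if design is None:
        _, design, _ = run_design_stage(cfg)
    truth = default_truth()
    truth.noise_sd = cfg.noise_sd
    screen = simulate_screen(truth, design, n_replicates=cfg.n_replicates,
                             seed=cfg.screen_seed)
    screen.to_csv(outdir / "screen.csv", index=False)
    _write_manifest(cfg, outdir, "simulate",
                    {"n_designs": len(design), "n_replicates": cfg.n_replicates})
    logger.info("[simulate] %d designs x %d replicates",
                len(design), cfg.n_replicates)
    return screen


def _screen_to_xy(screen: pd.DataFrame, design_points: dict,
                  log_response: bool):
    missing = sorted(set(screen["design_id"]) - set(design_points))
    if missing:
        raise ValidationError(
            f"screen design_ids not in design: {missing}")
    total = (screen.groupby(["design_id", "replicate"], sort=True)["flux"]
             .sum().reset_index())
    pts = [design_points[i] for i in total["design_id"]]
    y = total["flux"].to_numpy(dtype=float)
    if log_response:
        y = np.log10(y)
    return pts, y


def run_fit_stage(cfg: PipelineConfig, cands=None, designer=None):
    """Model fit + feasible optimum + contour grids from persisted CSVs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mset = cfg.monomer_set()
    if cands is None or designer is None:
        cands, _, designer = run_design_stage(cfg)
    design_df = pd.read_csv(outdir / "design.csv")
    design_points = {
        int(r["design_id"]): LipidBlockFactors(
            int(r["n_lipid_monomers"]), int(r["total_lipid_carbons"]),
            int(r["n_nonlinear"]), str(r["nonlinear_id"]))
        for _, r in design_df.iterrows()}
    screen_path = cfg.screen or (outdir / "screen.csv")
    screen = pd.read_csv(screen_path)
    pts, y = _screen_to_xy(screen, design_points, cfg.log_response)
    fit = fit_rsm(pts, y, spec=designer.spec_)
    opt = find_optimum(fit, cands.points, n_boot=cfg.n_boot,
                       seed=cfg.model_seed)
    with open(outdir / "model_report.json", "w") as fh:
        json.dump(fit.report(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    opt.to_frame().to_csv(outdir / "optimum.csv", index=False)
    fixed = {"n_nonlinear": opt.best_point.n_nonlinear,
             "nonlinear_id": opt.best_point.nonlinear_id,
             "n_lipid_monomers": opt.best_point.n_lipid_monomers,
             "total_lipid_carbons": opt.best_point.total_lipid_carbons}
    grid = contour_grid(fit, "n_lipid_monomers", "total_lipid_carbons", fixed)
    grid.to_csv(outdir / "contour_monomers_carbons.csv", index=False)
    grid2 = contour_grid(fit, "total_lipid_carbons", "n_nonlinear", fixed)
    grid2.to_csv(outdir / "contour_carbons_nonlinear.csv", index=False)
    _write_manifest(cfg, outdir, "fit",
                    {"r_squared": fit.r_squared_,
                     "optimum": list(opt.best_point.as_tuple())})
    logger.info("[fit] r2=%.3f optimum=%s", fit.r_squared_,
                opt.best_point.as_tuple())
    return fit, opt
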