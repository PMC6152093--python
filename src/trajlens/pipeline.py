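"""End-to-end analysis pipeline and run comparison.

``run_pipeline`` executes the full workflow — equilibration detection,
RMSD/RMSF profiles, functional mode analysis, RMSD-based clustering and
MM/GBSA binding energies — from one declarative config, writing one CSV or
JSON artifact per stage plus a run log that echoes every effective setting,
so each default is auditable.  ``compare_runs`` builds the paired
wild-type-vs-mutant comparison tables (per-residue RMSF differences,
per-residue binding-energy differences, cluster-population differences)
from two completed run directories.

All stage CSVs are written with a fixed float format, so a re-run with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import platform
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_trajectory
from .fma import (
    FMAResult,
    filter_on_mode,
    fit_fma,
    fit_pca,
    functional_rmsd,
    mode_rmsf,
    project,
)
from .geometry import detect_equilibration, rmsd_series, rmsf_per_residue
from .io import (
    Trajectory,
    make_selection,
    read_parameters,
    read_trajectory,
    write_trajectory,
)
from .mmgbsa import (
    GBSettings,
    per_residue_decomposition,
    trajectory_binding_energy,
)

__all__ = ["AnalysisConfig", "run_pipeline", "compare_runs"]

_FLOAT_FMT = "%.10g"


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    output: str
    trajectory: str | None = None
    dt: float = 1.0
    seed: int = 0
    fit_selection: str = "backbone"
    report_selection: str | None = None
    functional_selection: str | None = None
    equilibration: dict[str, Any] = field(default_factory=dict)
    rmsf: dict[str, Any] = field(default_factory=dict)
    fma: dict[str, Any] | None = None
    clustering: dict[str, Any] | None = None
    mmgbsa: dict[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sel = raw.pop("selections", {})
        return cls(
            output=raw.pop("output"),
            trajectory=raw.pop("trajectory", None),
            dt=raw.pop("dt", 1.0),
            seed=raw.pop("seed", 0),
            fit_selection=sel.get("fit", "backbone"),
            report_selection=sel.get("report"),
            functional_selection=sel.get("functional"),
            equilibration=raw.pop("equilibration", {}) or {},
            rmsf=raw.pop("rmsf", {}) or {},
            fma=raw.pop("fma", None),
            clustering=raw.pop("clustering", None),
            mmgbsa=raw.pop("mmgbsa", None),
        )

    def validate(self) -> None:
        if self.trajectory is not None and not Path(self.trajectory).exists():
            raise FileNotFoundError(self.trajectory)
        if self.mmgbsa is not None:
            for key in ("trajectory", "parameters"):
                if key not in self.mmgbsa:
                    raise ValueError(f"mmgbsa config needs {key!r}")
                if not Path(self.mmgbsa[key]).exists():
                    raise FileNotFoundError(self.mmgbsa[key])
            for key in ("receptor", "ligand"):
                if key not in self.mmgbsa:
                    raise ValueError(f"mmgbsa config needs {key!r}")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_json(obj: Any, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: AnalysisConfig) -> dict[str, Any]:
    """Run every configured stage in order; returns the result bundle.

    Stage artifacts land in ``config.output``; a failure aborts with the
    stage name while earlier artifacts are preserved.
    """
    config.validate()
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {
        "trajlens_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
        "settings": {},
    }
    results: dict[str, Any] = {}
    stage = "load"
    try:
        traj = None
        if config.trajectory is not None:
            traj = read_trajectory(config.trajectory, dt=config.dt)
        if traj is not None:
            fit_sel = make_selection(traj.topology, config.fit_selection)
            rep_sel = (
                make_selection(traj.topology, config.report_selection)
                if config.report_selection
                else fit_sel
            )

            stage = "rmsd"
            t0 = time.perf_counter()
            series = rmsd_series(
                traj, traj.frame_structure(0), fit_sel, rep_sel
            )
            _write_csv(
                pd.DataFrame(
                    {
                        "frame": np.arange(traj.n_frames),
                        "time_ns": traj.times,
                        "rmsd_A": series.values,
                    }
                ),
                out / "rmsd.csv",
            )
            log["stages"]["rmsd"] = round(time.perf_counter() - t0, 3)

            stage = "equilibration"
            eq_cfg = dict(config.equilibration)
            eq_frame = detect_equilibration(
                series,
                window=eq_cfg.get("window"),
                tolerance=eq_cfg.get("tolerance", 0.3),
            )
            _write_json(
                {"equilibrated_frame": int(eq_frame),
                 "tolerance_A": eq_cfg.get("tolerance", 0.3)},
                out / "equilibration.json",
            )
            results["equilibrated_frame"] = eq_frame

            stage = "rmsf"
            t0 = time.perf_counter()
            align_to = config.rmsf.get("align", "mean-structure")
            profile = rmsf_per_residue(traj, rep_sel, align_to=align_to)
            _write_csv(
                pd.DataFrame(
                    {"resid": profile.residue_ids, "rmsf_A": profile.values}
                ),
                out / "rmsf.csv",
            )
            log["stages"]["rmsf"] = round(time.perf_counter() - t0, 3)
            log["settings"]["rmsf_align"] = align_to
            results["rmsf"] = profile

            if config.fma is not None:
                stage = "fma"
                t0 = time.perf_counter()
                results["fma"] = _run_fma_stage(
                    config, traj, fit_sel, out, log
                )
                log["stages"]["fma"] = round(time.perf_counter() - t0, 3)

            if config.clustering is not None:
                stage = "clustering"
                t0 = time.perf_counter()
                results["clustering"] = _run_clustering_stage(
                    config, traj, fit_sel, out, log
                )
                log["stages"]["clustering"] = round(time.perf_counter() - t0, 3)

        if config.mmgbsa is not None:
            stage = "mmgbsa"
            t0 = time.perf_counter()
            results["mmgbsa"] = _run_mmgbsa_stage(config, out, log)
            log["stages"]["mmgbsa"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_json(log, out / "run_log.json")
    return results


def _run_fma_stage(config, traj, fit_sel, out: Path, log) -> FMAResult:
    cfg = dict(config.fma or {})
    if not config.functional_selection:
        raise ValueError("FMA stage needs selections.functional")
    func_sel = make_selection(traj.topology, config.functional_selection)
    model = fit_pca(traj, fit_sel)
    if cfg.get("reference"):
        reference = read_trajectory(cfg["reference"]).frame_structure(0)
    else:
        reference = traj.frame_structure(0)
    f = functional_rmsd(traj, func_sel, reference, fit_sel)
    n_comp = cfg.get("n_components")
    if n_comp is None:
        n_comp = model.n_components_for_variance(cfg.get("variance_fraction", 0.9))
    proj = project(traj, model, np.arange(n_comp))
    result = fit_fma(model, proj, f, n_components=n_comp,
                     split=cfg.get("split", "halves"))
    filtered = filter_on_mode(traj, model, result.ewmcm)
    write_trajectory(filtered, out / "fma_filtered.pdb")
    profile = mode_rmsf(filtered)
    _write_csv(
        pd.DataFrame({"resid": profile.residue_ids, "rmsf_A": profile.values}),
        out / "fma_rmsf.csv",
    )
    _write_json(
        {
            "n_components": int(result.n_components),
            "betas": [float(b) for b in result.betas],
            "intercept": result.intercept,
            "r_train": result.r_train,
            "r_cv": result.r_cv,
        },
        out / "fma.json",
    )
    log["settings"]["fma_n_components"] = int(n_comp)
    log["settings"]["fma_split"] = cfg.get("split", "halves")
    return result


def _run_clustering_stage(config, traj, fit_sel, out: Path, log):
    cfg = dict(config.clustering or {})
    stride = cfg.get("stride")
    if stride is None:
        # aim at roughly 1000-1500 strided frames
        stride = max(1, int(np.ceil(traj.n_frames / 1200)))
    k_range = range(cfg.get("k_min", 1), cfg.get("k_max", 10) + 1)
    result = cluster_trajectory(
        traj,
        fit_sel,
        stride=stride,
        linkage_method=cfg.get("linkage", "average"),
        k_range=k_range,
        plateau_tol=cfg.get("plateau_tol", 0.05),
    )
    rows = []
    for k, labels in sorted(result.labels_by_k.items()):
        for pos, lab in enumerate(labels):
            rows.append((int(result.frame_indices[pos]), k, int(lab)))
    _write_csv(
        pd.DataFrame(rows, columns=["frame", "k", "cluster"]),
        out / "cluster_labels.csv",
    )
    _write_csv(
        pd.DataFrame(
            [
                {"k": k, **{m: v for m, v in result.metrics_by_k[k].items()}}
                for k in sorted(result.metrics_by_k)
            ]
        ),
        out / "cluster_metrics.csv",
    )
    _write_json(
        {
            "chosen_k": int(result.chosen_k),
            "populations": [float(p) for p in result.populations],
            "centroid_frames": [int(c) for c in result.centroids],
            "linkage": result.linkage_method,
            "stride": int(stride),
        },
        out / "populations.json",
    )
    centroid_traj = Trajectory(
        frames=traj.frames[result.centroids],
        times=np.arange(len(result.centroids), dtype=float),
        topology=traj.topology,
    )
    write_trajectory(centroid_traj, out / "centroids.pdb")
    log["settings"]["clustering_stride"] = int(stride)
    log["settings"]["clustering_linkage"] = result.linkage_method
    log["settings"]["plateau_tol"] = cfg.get("plateau_tol", 0.05)
    return result


def _run_mmgbsa_stage(config, out: Path, log):
    cfg = dict(config.mmgbsa or {})
    traj = read_trajectory(cfg["trajectory"], dt=config.dt)
    params = read_parameters(cfg["parameters"], traj.topology)
    receptor = make_selection(traj.topology, cfg["receptor"])
    ligand = make_selection(traj.topology, cfg["ligand"])
    settings = GBSettings(**cfg.get("settings", {}))
    stride = cfg.get("stride", 1)
    start = cfg.get("start", 0)
    result = trajectory_binding_energy(
        traj, receptor, ligand, params, stride=stride, start=start,
        settings=settings,
    )
    _write_csv(
        pd.DataFrame(
            [
                {
                    "frame": int(f),
                    "elec": b.e_elec,
                    "vdw": b.e_vdw,
                    "gb": b.g_gb,
                    "sa": b.g_sa,
                    "internal": b.e_internal,
                    "total": b.total,
                }
                for f, b in zip(result.frame_indices, result.per_frame)
            ]
        ),
        out / "be_totals.csv",
    )
    _write_json(
        {
            "mean_kcal_mol": result.mean,
            "sd_kcal_mol": result.sd,
            "receptor": result.receptor_label,
            "ligand": result.ligand_label,
            "n_frames": int(len(result.per_frame)),
        },
        out / "be_summary.json",
    )
    decomp = per_residue_decomposition(
        traj, receptor, ligand, params, stride=stride, start=start,
        settings=settings,
    )
    _write_csv(decomp.table, out / "be_residues.csv")
    log["settings"]["gb"] = {
        "dielectric_in": settings.dielectric_in,
        "dielectric_solvent": settings.dielectric_solvent,
        "gamma": settings.gamma,
        "beta": settings.beta,
        "probe": settings.probe,
        "n_sphere_points": settings.n_sphere_points,
    }
    return result, decomp


def compare_runs(run_a: str | Path, run_b: str | Path) -> dict[str, Any]:
    """Difference report between two completed run directories.

    Per-residue RMSF differences (B - A), per-residue binding-energy
    differences and cluster-population differences, each aligned on the
    intersection of residues/clusters with a warning when ranges differ.
    """
    run_a, run_b = Path(run_a), Path(run_b)
    report: dict[str, Any] = {}
    for name, fname, key, cols in [
        ("rmsf_diff", "rmsf.csv", "resid", ["rmsf_A"]),
        ("residue_be_diff", "be_residues.csv", "resid",
         ["elec", "vdw", "gb", "sa", "total"]),
    ]:
        fa, fb = run_a / fname, run_b / fname
        if not (fa.exists() and fb.exists()):
            continue
        a = pd.read_csv(fa)
        b = pd.read_csv(fb)
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        if len(merged) < max(len(a), len(b)):
            warnings.warn(
                f"{fname}: residue ranges differ between runs; compared on "
                f"the {len(merged)}-residue intersection",
                stacklevel=2,
            )
        diff = pd.DataFrame({key: merged[key]})
        for c in cols:
            diff[f"d_{c}"] = merged[f"{c}_b"] - merged[f"{c}_a"]
        report[name] = diff
    pa, pb = run_a / "populations.json", run_b / "populations.json"
    if pa.exists() and pb.exists():
        with open(pa) as fh:
            ja = json.load(fh)
        with open(pb) as fh:
            jb = json.load(fh)
        na, nb = len(ja["populations"]), len(jb["populations"])
        n = min(na, nb)
        if na != nb:
            warnings.warn(
                "cluster counts differ between runs; compared the "
                f"{n} most populated clusters",
                stacklevel=2,
            )
        report["population_diff"] = pd.DataFrame(
            {
                "rank": np.arange(1, n + 1),
                "pop_a": ja["populations"][:n],
                "pop_b": jb["populations"][:n],
                "d_pop": np.array(jb["populations"][:n])
                - np.array(ja["populations"][:n]),
            }
        )
        report["chosen_k"] = (ja["chosen_k"], jb["chosen_k"])
    return report
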