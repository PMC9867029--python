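"""Workflow orchestration: trajectory analysis and titration analysis.

A YAML (or dict) config drives each workflow; every stage writes plain CSV
and the run ends with a ``manifest.json`` recording parameters, seeds and a
sha256 checksum per output so a run can be audited and reproduced.

Trajectory workflow stages, in order: superpose -> essential-dynamics PCA
(eigenvalues, projections, RMSF along mode 1) -> residue-pair distance
series and histograms -> ellipsoidal density profile -> salt-bridge series.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import Trajectory, read_structure, read_trajectory, select
from .essential_dynamics import (
    build_subspace,
    project,
    rmsf_along_mode,
    superpose,
    variance_fraction,
)
from .ellipsoid_hydration import density_profile
from .contact_analysis import (
    distance_distribution,
    make_salt_bridge,
    residue_pair_distance,
    salt_bridge_distance,
)
from .binding_titration import TitrationDataset, fit_global

__all__ = ["load_config", "run_trajectory_workflow", "run_titration_workflow"]

log = logging.getLogger("ionshell.pipeline")


def load_config(path_or_dict: str | Path | dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _finish_manifest(outdir: Path, stages: list[str], params: dict) -> Path:
    manifest = {
        "ionshell_version": __version__,
        "stages": stages,
        "parameters": params,
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.suffix == ".csv"
        },
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return mpath


class StageError(RuntimeError):
    """A workflow stage failed; partial outputs are kept on disk."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_trajectory_workflow(config: str | Path | dict, output_dir: str | Path | None = None) -> Path:
    """Run the full structural-dynamics workflow; returns the output directory."""
    cfg = load_config(config)
    tcfg = cfg.get("trajectory")
    if tcfg is None:
        raise ValueError("config lacks a 'trajectory' section")
    outdir = Path(output_dir or cfg.get("output_dir", "ionshell_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    top_path = Path(tcfg["topology"])
    traj_paths = [Path(p) for p in tcfg["trajectories"]]
    for p in [top_path, *traj_paths]:
        if not p.exists():
            raise FileNotFoundError(f"configured input missing: {p}")
    labels = tcfg.get("labels") or [p.stem for p in traj_paths]

    stages: list[str] = []
    t0 = time.time()

    def stage(name):
        stages.append(name)
        log.info("stage %-16s t=%.1fs", name, time.time() - t0)

    stage("read")
    try:
        topology, ref_frames = read_structure(top_path)
        trajs = [read_trajectory(p, topology) for p in traj_paths]
    except Exception as exc:
        raise StageError("read", exc) from exc

    sel_expr = tcfg.get("selection", "name CA and role protein")
    sel = select(topology, sel_expr)

    stage("superpose")
    try:
        reference = trajs[0].frames[0]
        fitted = [superpose(t, sel, reference) for t in trajs]
    except Exception as exc:
        raise StageError("superpose", exc) from exc

    stage("pca")
    try:
        sub = build_subspace(fitted, sel)
        n_modes = int(tcfg.get("modes", 2))
        pd.DataFrame(
            {
                "mode": np.arange(sub.eigenvalues.size),
                "eigenvalue_nm2": sub.eigenvalues,
                "cumulative_variance_fraction": np.cumsum(sub.eigenvalues)
                / max(sub.total_variance, 1e-300),
            }
        ).to_csv(outdir / "eigenvalues.csv", index=False)
        proj_rows = []
        for lab, t in zip(labels, fitted):
            pr = project(t, sub, list(range(n_modes)), label=lab)
            df = pd.DataFrame(
                pr.coordinates, columns=[f"mode{m + 1}_nm" for m in range(n_modes)]
            )
            df.insert(0, "condition", lab)
            df.insert(0, "frame", np.arange(t.n_frames))
            proj_rows.append(df)
        pd.concat(proj_rows, ignore_index=True).to_csv(outdir / "projections.csv", index=False)
        rmsf = rmsf_along_mode(
            Trajectory(topology, [f for t in fitted for f in t.frames], superposed=True),
            sub,
            0,
        )
        pd.DataFrame(
            {"atom_index": sel.indices, "rmsf_mode1_nm": rmsf}
        ).to_csv(outdir / "rmsf_mode1.csv", index=False)
    except Exception as exc:
        raise StageError("pca", exc) from exc

    stage("distances")
    try:
        bin_width = float(tcfg.get("bin_width", 0.05))
        prom = float(tcfg.get("prominence", 0.05))
        for pair in tcfg.get("distance_pairs", []):
            ra, rb = int(pair["resA"]), int(pair["resB"])
            rule = pair.get("rule", "ca")
            for lab, t in zip(labels, fitted):
                series = residue_pair_distance(t, ra, rb, rule)
                tag = f"{ra}_{rb}_{lab}"
                pd.DataFrame(
                    {"frame": np.arange(series.values.size), "distance_nm": series.values}
                ).to_csv(outdir / f"distance_{tag}.csv", index=False)
                if series.values.size >= 100:
                    dist = distance_distribution(series, bin_width, prom)
                    centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
                    pd.DataFrame(
                        {"bin_center_nm": centers, "frequency": dist.frequencies}
                    ).to_csv(outdir / f"distance_hist_{tag}.csv", index=False)
    except Exception as exc:
        raise StageError("distances", exc) from exc

    shell = tcfg.get("shell")
    if shell:
        stage("shell-density")
        try:
            ion_names = shell.get("ions", [])
            for lab, t, raw in zip(labels, fitted, trajs):
                # density profile uses the unfitted frames (boxes intact)
                prof = density_profile(
                    raw,
                    protein_sel=select(topology, shell.get("protein_selection", "role protein")),
                    water_sel=select(topology, "role water"),
                    ion_sels={
                        nm: select(topology, f"resname {nm} and role ion") for nm in ion_names
                    },
                    delta0=float(shell.get("delta0", 0.03)),
                    n_range=(int(shell.get("n_min", 0)), int(shell.get("n_max", 50))),
                )
                prof.table.to_csv(outdir / f"density_profile_{lab}.csv", index=False)
        except Exception as exc:
            raise StageError("shell-density", exc) from exc

    bridges = tcfg.get("salt_bridges", [])
    if bridges:
        stage("salt-bridges")
        try:
            for br in bridges:
                ra, rb = int(br["acid"]), int(br["base"])
                for lab, t in zip(labels, fitted):
                    sb = make_salt_bridge(t, ra, rb)
                    series = salt_bridge_distance(t, sb)
                    pd.DataFrame(
                        {"frame": np.arange(series.values.size), "distance_nm": series.values}
                    ).to_csv(outdir / f"saltbridge_{ra}_{rb}_{lab}.csv", index=False)
        except Exception as exc:
            raise StageError("salt-bridges", exc) from exc

    params = {
        "selection": sel_expr,
        "labels": labels,
        "inputs": [str(top_path)] + [str(p) for p in traj_paths],
        "seed": cfg.get("seed"),
        "trajectory": tcfg,
        "variance_fraction_2_modes": variance_fraction(sub, min(2, sub.eigenvalues.size)),
    }
    _finish_manifest(outdir, stages, params)
    return outdir


def read_titration_csv(path: str | Path) -> TitrationDataset:
    """CSV layout: first column wavelength_nm, remaining headers are [L] in M."""
    df = pd.read_csv(path)
    wl = df.iloc[:, 0].to_numpy(float)
    L = np.array([float(c) for c in df.columns[1:]])
    return TitrationDataset(
        ligand_concentrations=L,
        wavelengths=wl,
        absorbance=df.iloc[:, 1:].to_numpy(float),
    )


def run_titration_workflow(config: str | Path | dict, output_dir: str | Path | None = None) -> Path:
    """Global-fit every configured titration dataset; returns output directory."""
    cfg = load_config(config)
    tcfg = cfg.get("titration")
    if tcfg is None:
        raise ValueError("config lacks a 'titration' section")
    datasets = tcfg.get("datasets")
    if not datasets:
        raise ValueError("titration workflow needs at least one dataset")
    outdir = Path(output_dir or cfg.get("output_dir", "ionshell_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    T = float(tcfg.get("T", 298.0))

    rows = []
    for ds in datasets:
        name = ds["name"]
        data = read_titration_csv(ds["csv"])
        fit = fit_global(data, T=T)
        rows.append(
            {
                "condition": name,
                "KD_M": fit.KD,
                "KD_se_M": fit.KD_se,
                "delta_g_kcal_mol": fit.delta_g,
                "delta_g_se_kcal_mol": fit.delta_g_se,
                "rss_AU2": fit.rss,
                "n_wavelengths": fit.wavelengths.size,
            }
        )
        pd.DataFrame(
            {
                "wavelength_nm": fit.wavelengths,
                "amplitude_AU": fit.amplitudes,
                "amplitude_se_AU": fit.amplitude_se,
            }
        ).to_csv(outdir / f"amplitudes_{name}.csv", index=False)
    pd.DataFrame(rows).to_csv(outdir / "binding_summary.csv", index=False)
    _finish_manifest(outdir, ["titration-fit"], {"T": T, "datasets": datasets})
    return outdir
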