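"""End-to-end orchestration: config, stage ordering, outputs, manifest.

Stages run in dependency order (charge density before potential, which is
auto-inserted when missing). Every run writes TSV stage outputs plus a JSON
run manifest echoing the config, the package version, the seed and a sha256
checksum per output, so identical config + seed reproduces byte-identical
numeric summaries.
"""

from __future__ import annotations

import hashlib
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import Trajectory, resolve_selection
from .diffusion import diffusion_coefficient
from .electrostatics import planar_potential
from .errors import ConfigurationError
from .hbonds import HBondCriteria, hbond_series
from .io import (
    attach_topology,
    read_topology_sidecar,
    read_trajectory,
    write_profile,
    write_run_summary,
)
from .orientation import orientation_summary
from .profiles import charge_density_profile, mass_density_profile

log = logging.getLogger("bilayerlab.pipeline")

STAGES = (
    "orientation",
    "charge_density",
    "potential",
    "mass_density",
    "hbonds",
    "diffusion",
)


@dataclass
class RunConfig:
    trajectory: str
    sidecar: str | None = None
    format: str | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict = field(default_factory=dict)
    outdir: str = "bilayerlab_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigurationError(
                f"unknown stage(s) {sorted(bad)}; valid stages: {STAGES}"
            )
        if not Path(self.trajectory).exists():
            raise ConfigurationError(f"trajectory file not found: {self.trajectory}")
        if self.sidecar is not None and not Path(self.sidecar).exists():
            raise ConfigurationError(f"sidecar file not found: {self.sidecar}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def ordered_stages(self) -> list[str]:
        """Requested stages in canonical order, with dependencies inserted."""
        wanted = set(self.stages)
        if "potential" in wanted:
            wanted.add("charge_density")
        return [s for s in STAGES if s in wanted]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the result bundle dict."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    traj = read_trajectory(config.trajectory, format=config.format)
    if config.sidecar:
        traj = attach_topology(traj, read_topology_sidecar(config.sidecar))

    bundle: dict = {"outputs": [], "summaries": {}}
    timings: dict[str, float] = {}
    shared: dict = {}
    for stage in config.ordered_stages():
        log.info("stage %s: starting", stage)
        t0 = _time.perf_counter()
        try:
            _run_stage(stage, traj, config, outdir, bundle, shared)
        except Exception:
            log.error("stage %s: FAILED", stage)
            _write_manifest(config, outdir, bundle, timings, failed_stage=stage)
            raise
        timings[stage] = _time.perf_counter() - t0
        log.info("stage %s: done (%.2f s)", stage, timings[stage])
    _write_manifest(config, outdir, bundle, timings)
    return bundle


def _stage_params(config: RunConfig, stage: str) -> dict:
    return dict(config.params.get(stage, {}))


def _emit(bundle: dict, path: Path) -> None:
    bundle["outputs"].append(str(path))


def _run_stage(stage, traj: Trajectory, config, outdir: Path, bundle, shared):
    p = _stage_params(config, stage)
    if stage == "orientation":
        series = orientation_summary(
            traj,
            full_circle=p.get("full_circle", False),
            fold_before_mean=p.get("fold_before_mean", True),
        )
        ts_path = outdir / "orientation_series.tsv"
        with open(ts_path, "w") as fh:
            fh.write("time_ps\ttilt_frame_mean_deg\trotational_frame_mean_deg\n")
            for t, th, ph in zip(
                series.times, series.theta_frame_mean, series.phi_frame_mean
            ):
                fh.write(f"{t!r}\t{th!r}\t{ph!r}\n")
        hist_path = outdir / "orientation_hist.tsv"
        _write_angle_hist(series, hist_path)
        summary = dict(
            tilt_mean_deg=series.theta_mean,
            tilt_std_deg=series.theta_std,
            rotational_mean_deg=series.phi_mean,
            rotational_std_deg=series.phi_std,
        )
        js_path = outdir / "orientation_summary.json"
        write_run_summary(summary, js_path)
        bundle["summaries"]["orientation"] = summary
        for path in (ts_path, hist_path, js_path):
            _emit(bundle, path)
    elif stage == "charge_density":
        prof = charge_density_profile(
            traj,
            dz=p.get("dz", 0.5),
            origin_mode=p.get("origin_mode", "solvent_center"),
            symmetrize=p.get("symmetrize", False),
            z0=p.get("z0"),
        )
        shared["charge_profile"] = prof
        path = outdir / "charge_density.tsv"
        write_profile(prof, path)
        _emit(bundle, path)
    elif stage == "potential":
        prof = shared["charge_profile"]
        pot = planar_potential(
            prof, z_m=p.get("z_m"), eps_s=p.get("eps_s", 1.0)
        )
        path = outdir / "potential.tsv"
        with open(path, "w") as fh:
            fh.write(f"# z_m_A: {pot.z_m!r}\n# eps_s: {pot.eps_s!r}\n")
            fh.write("z_A\tcharge_density_e_A3\tpotential_V\n")
            for z, r, v in zip(pot.centers, pot.rho, pot.phi):
                fh.write(f"{z!r}\t{r!r}\t{v!r}\n")
        imin, imax = int(np.argmin(pot.phi)), int(np.argmax(pot.phi))
        n_tail = max(1, len(pot.phi) // 10)
        summary = dict(
            phi_min_V=float(pot.phi[imin]),
            phi_min_z_A=float(pot.centers[imin]),
            phi_max_V=float(pot.phi[imax]),
            phi_max_z_A=float(pot.centers[imax]),
            phi_tail_plateau_V=float(
                0.5 * (pot.phi[:n_tail].mean() + pot.phi[-n_tail:].mean())
            ),
            eps_s=pot.eps_s,
            z_m_A=pot.z_m,
        )
        js_path = outdir / "potential_summary.json"
        write_run_summary(summary, js_path)
        bundle["summaries"]["potential"] = summary
        _emit(bundle, path)
        _emit(bundle, js_path)
    elif stage == "mass_density":
        sel = resolve_selection(traj, p.get("selection", {"role": "drug"}))
        prof = mass_density_profile(
            traj,
            sel,
            dz=p.get("dz", 0.5),
            origin_mode=p.get("origin_mode", "bilayer_midplane"),
            symmetrize=p.get("symmetrize", False),
            z0=p.get("z0"),
        )
        path = outdir / "mass_density.tsv"
        write_profile(prof, path)
        _emit(bundle, path)
    elif stage == "hbonds":
        donors = resolve_selection(traj, p.get("donors", {"role": "drug"}))
        acceptors = resolve_selection(
            traj, p.get("acceptors", {"role": ["head", "tail"]})
        )
        crit = HBondCriteria(**p.get("criteria", {}))
        series = hbond_series(traj, donors, acceptors, crit)
        path = outdir / "hbond_series.tsv"
        with open(path, "w") as fh:
            fh.write("time_ps\tn_hbonds\n")
            for t, c in zip(series.times, series.counts):
                fh.write(f"{t!r}\t{int(c)}\n")
        js_path = outdir / "hbond_summary.json"
        write_run_summary(series.summary, js_path)
        bundle["summaries"]["hbonds"] = series.summary
        _emit(bundle, path)
        _emit(bundle, js_path)
    elif stage == "diffusion":
        sel = resolve_selection(traj, p.get("selection", {"role": "drug"}))
        curve = diffusion_coefficient(
            traj,
            sel,
            mode=p.get("mode", "xyz"),
            max_lag_fraction=p.get("max_lag_fraction", 0.25),
            window=tuple(p.get("window", (0.1, 0.5))),
        )
        path = outdir / "msd.tsv"
        with open(path, "w") as fh:
            fh.write(f"# mode: {curve.mode}\n# n_molecules: {curve.n_molecules}\n")
            fh.write("lag_ps\tmsd_A2\n")
            for t, m in zip(curve.lags, curve.msd):
                fh.write(f"{t!r}\t{m!r}\n")
        summary = dict(
            D_m2_per_s=curve.D,
            r_squared=curve.r_squared,
            fit_window=list(curve.fit_window),
            mode=curve.mode,
            n_molecules=curve.n_molecules,
        )
        js_path = outdir / "diffusion.json"
        write_run_summary(summary, js_path)
        bundle["summaries"]["diffusion"] = summary
        _emit(bundle, path)
        _emit(bundle, js_path)
    else:  # pragma: no cover - guarded by RunConfig validation
        raise ConfigurationError(f"unknown stage {stage}")


def _write_angle_hist(series, path: Path, bin_width: float = 1.0) -> None:
    th = series.theta[~np.isnan(series.theta)]
    ph = series.phi[~np.isnan(series.phi)]
    th_edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    ph_edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    th_hist, _ = np.histogram(th, bins=th_edges)
    ph_hist, _ = np.histogram(ph, bins=ph_edges)
    with open(path, "w") as fh:
        fh.write("angle_deg\ttilt_count\trotational_count\n")
        for i, edge in enumerate(ph_edges[:-1]):
            tc = th_hist[i] if i < len(th_hist) else 0
            fh.write(f"{edge + bin_width / 2.0}\t{int(tc)}\t{int(ph_hist[i])}\n")


def _write_manifest(config, outdir: Path, bundle, timings, failed_stage=None):
    manifest = dict(
        package="bilayerlab",
        version=__version__,
        seed=config.seed,
        config=dict(
            trajectory=config.trajectory,
            sidecar=config.sidecar,
            stages=config.stages,
            params=config.params,
            outdir=config.outdir,
        ),
        stages_executed=list(timings),
        timings_s={k: round(v, 4) for k, v in timings.items()},
        outputs={
            p: _sha256(Path(p)) for p in bundle["outputs"] if Path(p).exists()
        },
        failed_stage=failed_stage,
    )
    write_run_summary(manifest, outdir / "run_manifest.json")
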