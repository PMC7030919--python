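"""End-to-end pipeline: synthetic REUS -> WHAM -> reweighting -> binding
numbers -> states and density maps.

Every stage writes headered whitespace tables under one output directory
and is reproducible bit-for-bit from (config, seed).  A JSON run manifest
records the config snapshot, seeds, package version, SHA-256 digests of
every output file, and any warnings raised (unconverged WHAM, sampling
adequacy, histogram overlap).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .binding import BindingParams, aggregate_well_depths, kd_from_pmf
from .constants import rt
from .membrane import generate_membrane_frames
from .potential import ModelPotential, make_model_potential
from .reweight import FrameWeights, basin_occupancy, fes_2d, frame_weights
from .sampling import run_reus
from .states import (contact_pdf, default_state_definitions, density_map)
from .trajio import (AnalysisConfig, CVTrajectory, apply_burn_in, read_colvar,
                     write_colvar)
from .wham import PMFProfile, align_pmf, find_minima, wham_1d

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "run_family",
           "DEFAULT_MINIMA", "DEFAULT_DEPTHS", "DEFAULT_HOTSPOTS",
           "default_potential"]

#: Default ground-truth geometry: bound and encounter minima (nm) and
#: their depths (kJ/mol) for one anionic lipid per leaflet.
DEFAULT_MINIMA = (0.48, 0.73)
DEFAULT_DEPTHS = (-17.0, -13.0)

#: Default in-plane lipid hotspots (x, y, weight) relative to the protein
#: centre: canonical site, noncanonical site, and the third site.
DEFAULT_HOTSPOTS = ((0.9, 0.3, 0.35), (-0.8, 0.5, 0.30), (0.2, -1.0, 0.25))


def default_potential(n_pip3: int) -> ModelPotential:
    """The repository's default two-well ground truth at a lipid count."""
    return make_model_potential(DEFAULT_MINIMA, DEFAULT_DEPTHS, n_pip3=n_pip3)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: "RunManifest"):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, outputs, digests, warnings."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)
    stages_completed: list[str] = field(default_factory=list)

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        payload = {
            "config": self.config, "seed": self.seed, "version": self.version,
            "outputs": self.outputs, "warnings": self.warnings,
            "stages_completed": self.stages_completed,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# table writers
# ---------------------------------------------------------------------------

_FMT = "%.8g"


def write_pmf_table(path: Path, profile: PMFProfile) -> None:
    """PMF as ``xi1_nm  F_kJ_mol  error_kJ_mol  count``.

    The error column is the leading-order counting estimate
    RT/sqrt(n_bin); undefined bins are omitted.
    """
    kt = rt(profile.temperature)
    n = profile.total_counts()
    with open(path, "w") as fh:
        fh.write(f"# PMF along xi1 ({profile.zero_convention} gauge, "
                 f"T = {profile.temperature:g} K)\n")
        fh.write("# xi1_nm F_kJ_mol error_kJ_mol count\n")
        for x, F, c in zip(profile.bin_centers, profile.free_energy, n):
            if np.isfinite(F):
                err = kt / np.sqrt(c) if c > 0 else np.nan
                fh.write(f"{_FMT % x} {_FMT % F} {_FMT % err} {int(c)}\n")


def write_grid_table(path: Path, x_edges, y_edges, grid, header: str) -> None:
    """Dense labelled matrix: first row y centres, first column x centres."""
    xc = 0.5 * (np.asarray(x_edges)[:-1] + np.asarray(x_edges)[1:])
    yc = 0.5 * (np.asarray(y_edges)[:-1] + np.asarray(y_edges)[1:])
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("# first row: y bin centres; first column: x bin centres\n")
        fh.write("x\\y " + " ".join(_FMT % v for v in yc) + "\n")
        for x, row in zip(xc, np.asarray(grid)):
            fh.write(_FMT % x + " "
                     + " ".join("nan" if not np.isfinite(v) else _FMT % v
                                for v in row) + "\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _simulate_stage(config: AnalysisConfig, outdir: Path, seed: int,
                    manifest: RunManifest) -> list[CVTrajectory]:
    protocol = replace(config.protocol, seed=seed)
    potential = default_potential(config.n_pip3)
    reus = run_reus(potential, protocol)
    for i, tr in enumerate(reus.trajectories):
        p = outdir / f"colvar_window_{i:02d}.dat"
        write_colvar(p, tr)
        manifest.register(p)
    return reus.trajectories


def run_pipeline(config: AnalysisConfig, outdir, seed: int = 0,
                 colvar_files: list[str] | None = None) -> RunManifest:
    """Run every stage and return the manifest.

    With ``colvar_files`` given, the simulate stage is skipped and the
    listed COLVAR files (one per window) are analysed instead; otherwise
    trajectories come from the synthetic REUS generator under the
    configured ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(config), seed=seed)
    protocol = replace(config.protocol, seed=seed)

    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            if colvar_files is None:
                trajs = _simulate_stage(config, outdir, seed, manifest)
            else:
                trajs = [read_colvar(p, window_index=i)
                         for i, p in enumerate(colvar_files)]
            manifest.stages_completed.append(stage)

            stage = "wham"
            post = [apply_burn_in(tr, config) for tr in trajs]
            pmf = wham_1d(post, protocol, config)
            pmf = align_pmf(pmf, config.plateau_region)
            p = outdir / "pmf.dat"
            write_pmf_table(p, pmf)
            manifest.register(p)
            minima = find_minima(pmf)
            p = outdir / "pmf_minima.dat"
            with open(p, "w") as fh:
                fh.write("# position_nm depth_kJ_mol\n")
                for pos, depth in minima.minima:
                    fh.write(f"{_FMT % pos} {_FMT % depth}\n")
            manifest.register(p)
            manifest.stages_completed.append(stage)

            stage = "fes2d"
            weights = frame_weights(post, protocol, pmf)
            for pair in (("xi2", "xi3"), ("xi1", "xi3"), ("xi1", "xi2")):
                fes = fes_2d(post, weights, pair, config)
                p = outdir / f"fes_{pair[0]}_{pair[1]}.dat"
                write_grid_table(
                    p, fes.x_edges, fes.y_edges, fes.free_energy,
                    f"2D free energy (kJ/mol) over ({pair[0]}, {pair[1]}), "
                    "min-zero gauge")
                manifest.register(p)
            manifest.stages_completed.append(stage)

            stage = "kd"
            if config.area_A is None:
                raise ValueError(
                    "config.binding.area_A (membrane x-y area, nm^2) is "
                    "required for the Kd stage")
            params = BindingParams(area_A=config.area_A, b=config.b,
                                   box_Lz=config.box_Lz,
                                   temperature=protocol.temperature)
            res = kd_from_pmf(pmf, params)
            p = outdir / "binding.dat"
            with open(p, "w") as fh:
                fh.write("# n_pip3 depth_kJ_mol Kd_mol_per_L dG_kJ_mol "
                         "integral_nm formula\n")
                fh.write(f"{config.n_pip3} {_FMT % pmf.well_depth()} "
                         f"{res.kd:.2e} {_FMT % res.delta_g} "
                         f"{_FMT % res.integral_nm} {res.formula}\n")
            manifest.register(p)
            manifest.stages_completed.append(stage)

            stage = "states"
            defs = default_state_definitions()
            occ = basin_occupancy(weights, defs, protocol.temperature)
            p = outdir / "states.dat"
            with open(p, "w") as fh:
                fh.write("# state probability free_energy_kJ_mol\n")
                for name, rec in occ.items():
                    fh.write(f"{name} {_FMT % rec['probability']} "
                             f"{_FMT % rec['free_energy']}\n")
            manifest.register(p)
            manifest.stages_completed.append(stage)

            stage = "density"
            for sd in defs[:2]:  # bound orientations only
                frames = generate_membrane_frames(
                    sd.name, max(config.n_pip3, 1), list(DEFAULT_HOTSPOTS),
                    n_frames=200, seed=seed)
                w = np.ones(len(frames))
                mask = np.ones(len(frames), dtype=bool)
                dm = density_map(frames, w, mask, sd.name)
                p = outdir / f"density_{sd.name}.dat"
                write_grid_table(p, dm.x_edges, dm.y_edges, dm.density,
                                 f"max-normalised head-group density, "
                                 f"state {sd.name}")
                manifest.register(p)
                pdf = contact_pdf(frames, w, mask, sd.name)
                p = outdir / f"contact_pdf_{sd.name}.dat"
                with open(p, "w") as fh:
                    fh.write(f"# lipid contact-count PDF, state {sd.name}, "
                             f"cutoff {pdf.cutoff:g} nm\n")
                    fh.write("# n_contacts probability\n")
                    for c, prob in zip(pdf.counts, pdf.probabilities):
                        fh.write(f"{int(c)} {_FMT % prob}\n")
                manifest.register(p)
            manifest.stages_completed.append(stage)

        manifest.warnings = sorted({str(w.message) for w in wrec})
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc, manifest) from exc

    manifest.write(outdir / "manifest.json")
    return manifest


def run_family(config: AnalysisConfig, n_values, outdir, seed: int = 0):
    """Binding table across systems with different lipid counts.

    Runs the simulate + WHAM stages per lipid count (same seed offsets
    per system for reproducibility) and aggregates well depth, Kd and
    Delta G.  Returns the DataFrame and writes ``binding_family.dat``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.area_A is None:
        raise ValueError("config.binding.area_A is required")
    profiles = {}
    for n in n_values:
        protocol = replace(config.protocol, seed=seed + int(n))
        potential = default_potential(int(n))
        reus = run_reus(potential, protocol)
        post = [apply_burn_in(tr, config) for tr in reus.trajectories]
        pmf = align_pmf(wham_1d(post, protocol, config), config.plateau_region)
        profiles[int(n)] = pmf
    params = BindingParams(area_A=config.area_A, b=config.b,
                           box_Lz=config.box_Lz,
                           temperature=config.protocol.temperature)
    table = aggregate_well_depths(profiles, params)
    p = outdir / "binding_family.dat"
    with open(p, "w") as fh:
        fh.write("# n_pip3 depth_kJ_mol Kd_mol_per_L dG_kJ_mol\n")
        for _, row in table.iterrows():
            fh.write(f"{int(row.n_pip3)} {_FMT % row.depth_kj_mol} "
                     f"{row.kd_mol_l:.3e} {_FMT % row.dg_kj_mol}\n")
    return table


def _config_snapshot(config: AnalysisConfig) -> dict:
    proto = config.protocol
    return {
        "protocol": {
            "centers": list(proto.centers),
            "force_constant": proto.force_constant,
            "exchange_interval": proto.exchange_interval,
            "temperature": proto.temperature,
            "n_steps": proto.n_steps,
            "window_time_us": proto.window_time_us,
        },
        "burn_in_fraction": config.burn_in_fraction,
        "xi1_bins": {"min": config.xi1_bin_min, "max": config.xi1_bin_max,
                     "width": config.xi1_bin_width},
        "fes_bins": config.fes_bins,
        "wham_tolerance": config.wham_tolerance,
        "max_iterations": config.max_iterations,
        "plateau_region": list(config.plateau_region),
        "binding": {"b": config.b, "area_A": config.area_A,
                    "box_Lz": None if not np.isfinite(config.box_Lz)
                    else config.box_Lz},
        "n_pip3": config.n_pip3,
    }
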