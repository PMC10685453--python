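"""Pipeline orchestration: config validation, staged runs, reproducible seeds.

A single YAML config drives the full chain: synthetic landscape →
well-tempered metadynamics (one run per protomer) → reweighted,
block-averaged, symmetrized FES → string MFEP → protomer combination →
restrained diffusion windows → ISD permeability.  All randomness flows
from the one config seed through named per-stage substreams, so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np

from . import io as mio
from .dynamics import simulate_overdamped
from .fes import block_error, marginal_z, symmetrize
from .landscapes import (DiffusionModel, FeatureWidths, ModelPotential,
                         make_protomer_pair)
from .metad import run_wtmetad
from .mfep import find_minima, string_mfep
from .permeability import build_D_profile, isd_permeability
from .protomer import aqueous_shift, combine_surfaces, delta_surface, \
    shift_surface
from .units import ThermoState

__all__ = ["validate_config", "stage_seed", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 2024,
    "temperature": 310.0,
    "landscape": {
        "dimensionality": 2,
        "interfacial_min_depth": 15.0,
        "interfacial_min_position": 5.0,
        "core_barrier_height": 6.0,
        "widths": {"well": 2.0, "barrier": 3.0, "coupling": 1.5},
        "coupling_strength": 25.0,
        "z_max": 15.0,
    },
    "protomer": {"core_penalty": 30.0, "pKa": 10.4, "pH": 7.0},
    "diffusion": {"form": "constant", "D_bulk": 0.5, "D_core": 0.5,
                  "transition_width": 3.0},
    "metad": {"dt": 0.02, "n_steps": 600000, "w0": 1.2, "sigma": 0.5,
              "pace": 2.0, "bias_factor_neutral": 20.0,
              "bias_factor_charged": 25.0, "grid_spacing": 0.1,
              "record_every": 10},
    "fes": {"burn_in": 0.1111111111111111, "bin_width": 0.5, "n_blocks": 3,
            "bulk_cut": 12.0},
    "mfep": {"n_images": 48, "tol": 0.5, "max_iter": 2000},
    "permeability": {"window_k": 10.0, "n_windows": 9, "window_steps": 150000,
                     "window_dt": 0.01, "window_record_every": 5},
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31) from the run seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> dict:
    """Merge onto defaults and validate every stage before anything runs."""
    cfg = _merge(DEFAULT_CONFIG, cfg or {})
    if not isinstance(cfg["seed"], int) or cfg["seed"] < 0:
        raise ValueError("seed must be a non-negative integer")
    if not cfg["temperature"] > 0:
        raise ValueError("temperature must be positive")
    ls = cfg["landscape"]
    _potential_from(cfg).validate()
    if not ls["z_max"] > ls["interfacial_min_position"]:
        raise ValueError("z_max must exceed the interfacial minimum position")
    _diffusion_from(cfg).validate()
    md = cfg["metad"]
    for key in ("dt", "w0", "sigma", "pace", "grid_spacing"):
        if not md[key] > 0:
            raise ValueError(f"metad.{key} must be positive")
    if md["n_steps"] < 1 or md["record_every"] < 1:
        raise ValueError("metad.n_steps and record_every must be >= 1")
    for key in ("bias_factor_neutral", "bias_factor_charged"):
        if not md[key] > 1:
            raise ValueError(f"metad.{key} must be > 1")
    fs = cfg["fes"]
    if not 0 <= fs["burn_in"] < 1:
        raise ValueError("fes.burn_in must be in [0, 1)")
    if fs["n_blocks"] < 2:
        raise ValueError("fes.n_blocks must be >= 2")
    if not 0 < fs["bulk_cut"] < ls["z_max"]:
        raise ValueError("fes.bulk_cut must lie inside the CV range")
    mf = cfg["mfep"]
    if mf["n_images"] < 3 or mf["tol"] <= 0 or mf["max_iter"] < 1:
        raise ValueError("invalid mfep parameters")
    pm = cfg["permeability"]
    if pm["n_windows"] < 5:
        raise ValueError("permeability.n_windows must be >= 5")
    if pm["window_k"] <= 0 or pm["window_steps"] < 100 or pm["window_dt"] <= 0:
        raise ValueError("invalid permeability window parameters")
    if cfg["protomer"]["core_penalty"] < 0:
        raise ValueError("protomer.core_penalty must be >= 0")
    return cfg


def _potential_from(cfg) -> ModelPotential:
    ls = cfg["landscape"]
    return ModelPotential(
        dimensionality=ls["dimensionality"],
        interfacial_min_depth=ls["interfacial_min_depth"],
        interfacial_min_position=ls["interfacial_min_position"],
        core_barrier_height=ls["core_barrier_height"],
        widths=FeatureWidths(**ls["widths"]),
        coupling_strength=ls["coupling_strength"],
        tilt=ls.get("tilt", 0.0),
    )


def _diffusion_from(cfg) -> DiffusionModel:
    return DiffusionModel(**cfg["diffusion"])


def _log(outdir: Path, record: dict):
    with open(outdir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run the full chain from one config; returns the summary mapping."""
    from . import __version__

    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = mio.config_hash(cfg)
    log_path = outdir / "run_log.jsonl"
    if log_path.exists():
        log_path.unlink()
    _log(outdir, {"stage": "start", "config_hash": chash,
                  "seed": cfg["seed"], "version": __version__})

    thermo = ThermoState(cfg["temperature"])
    params = _potential_from(cfg)
    diffusion = _diffusion_from(cfg)
    neutral, charged = make_protomer_pair(params,
                                          cfg["protomer"]["core_penalty"])
    md, fs = cfg["metad"], cfg["fes"]
    z_max = cfg["landscape"]["z_max"]
    d = params.dimensionality

    surfaces = {}
    for name, surf, gamma in (
            ("neutral", neutral, md["bias_factor_neutral"]),
            ("charged", charged, md["bias_factor_charged"])):
        traj, ledger, rw = run_wtmetad(
            surf, diffusion, thermo, dt=md["dt"], n_steps=md["n_steps"],
            seed=stage_seed(cfg["seed"], f"metad-{name}"), w0=md["w0"],
            sigma=md["sigma"], pace=md["pace"], bias_factor=gamma,
            grid_spacing=md["grid_spacing"], z_max=z_max,
            record_every=md["record_every"])
        mio.write_colvar(traj, outdir / f"colvar_{name}.dat", chash)
        mio.write_hills(ledger, outdir / f"hills_{name}.dat", chash)
        fes = block_error(traj, ledger, rw, n_blocks=fs["n_blocks"],
                          burn_in=fs["burn_in"],
                          bins=int(round(2 * z_max / fs["bin_width"])),
                          cv_range=z_max, reference="bulk-zero",
                          bulk_cut=fs["bulk_cut"])
        fes = symmetrize(fes).re_reference("bulk-zero", fs["bulk_cut"])
        mio.write_fes(fes, outdir / f"fes_{name}.dat", chash)
        surfaces[name] = fes
        _log(outdir, {"stage": f"metad-{name}", "kernels": len(ledger),
                      "gamma": gamma, "config_hash": chash})

    summary = {"config_hash": chash}
    mf = cfg["mfep"]
    if d == 2:
        fneu = surfaces["neutral"]
        minima = find_minima(fneu)
        deepest = minima[0]
        mirror = -deepest
        path = string_mfep(fneu, mirror, deepest, n_images=mf["n_images"],
                           tol=mf["tol"], max_iter=mf["max_iter"])
        mio.write_path(path, outdir / "mfep_neutral.dat",
                       labels=fneu.labels, config_hash=chash)
        summary["mfep_converged"] = bool(path.converged)
        summary["mfep_barrier_kJ_mol"] = float(path.F_along.max()
                                               - path.F_along.min())
        _log(outdir, {"stage": "mfep", "iterations": path.iterations,
                      "config_hash": chash})

    pr = cfg["protomer"]
    shift = aqueous_shift(pr["pKa"], pr["pH"], thermo)
    f0s = shift_surface(surfaces["neutral"], shift)
    combined = combine_surfaces(f0s, surfaces["charged"],
                                reference="bulk-zero", bulk_cut=fs["bulk_cut"])
    delta = delta_surface(surfaces["charged"], f0s)
    mio.write_fes(combined, outdir / "fes_combined.dat", chash)
    mio.write_fes(delta, outdir / "fes_delta.dat", chash, signed_value=True)
    summary["aqueous_shift_kJ_mol"] = float(shift)
    _log(outdir, {"stage": "combine", "shift_kJ_mol": shift,
                  "config_hash": chash})

    pm = cfg["permeability"]
    base1d = ModelPotential(
        dimensionality=1,
        interfacial_min_depth=params.interfacial_min_depth,
        interfacial_min_position=params.interfacial_min_position,
        core_barrier_height=params.core_barrier_height,
        widths=params.widths, tilt=params.tilt)
    from .landscapes import make_membrane_potential
    surf1d = make_membrane_potential(base1d)
    centers = np.linspace(-z_max + 2.0, z_max - 2.0, pm["n_windows"])
    windows = []
    for i, z0 in enumerate(centers):
        wsurf = surf1d.with_restraint(pm["window_k"], z0)
        wtraj = simulate_overdamped(
            wsurf, diffusion, thermo, dt=pm["window_dt"],
            n_steps=pm["window_steps"],
            seed=stage_seed(cfg["seed"], f"window-{i}"), x0=[z0],
            z_max=z_max, record_every=pm["window_record_every"])
        windows.append((float(z0), wtraj))
    dprof = build_D_profile(windows)
    mio.write_d_profile(dprof, outdir / "d_profile.dat", chash)

    cut = float(fs["bulk_cut"])
    bounds = (-cut, cut)
    for name, fes in (("neutral", surfaces["neutral"]),
                      ("combined", combined)):
        prof = marginal_z(fes, reference="none")
        # reference at the integration boundary: the outermost bins sit
        # against the reflective wall and carry boundary artifacts, so the
        # bulk level is read from a band around ±bulk_cut instead
        band = prof.mask & (np.abs(np.abs(prof.axes[0]) - cut) <= 1.0)
        prof.F = prof.F - np.nanmean(prof.F[band])
        res = isd_permeability(prof, dprof, bounds)
        summary[f"P_{name}_cm_s"] = res.P
        summary[f"P_{name}_err_cm_s"] = res.error
    _log(outdir, {"stage": "permeability", "bounds": list(bounds),
                  "config_hash": chash})

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    _log(outdir, {"stage": "done", "config_hash": chash})
    return summary
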