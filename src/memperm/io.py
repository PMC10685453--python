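"""Text-format readers and writers (PLUMED-dialect) plus run configuration.

All artifacts are whitespace tables with a ``#! FIELDS ...`` header line
and ``#! SET key value`` metadata lines, printed to 12 significant
digits so write∘read round-trips are lossless in practice.  Artifacts
written inside a pipeline run embed the configuration hash, and
:func:`verify_artifact` checks an artifact against a config.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml

from .dynamics import CVTrajectory
from .fes import FreeEnergySurface
from .metad import BiasGrid, GaussianKernel, HillsLedger
from .mfep import StringPath
from .permeability import DiffusionProfile
from .units import ThermoState

__all__ = ["FormatError", "DataError", "read_colvar", "write_colvar",
           "read_hills", "write_hills", "read_fes", "write_fes",
           "write_path", "read_path", "write_d_profile", "read_d_profile",
           "load_config", "config_hash", "verify_artifact"]

_FMT = "%.12g"


class FormatError(ValueError):
    pass


class DataError(ValueError):
    pass


def _parse_header(path):
    """Return (fields, sets, first_data_lineno) from a PLUMED-dialect file."""
    fields = None
    sets = {}
    n_header = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if s.startswith("#!"):
                n_header = lineno
                toks = s[2:].split()
                if not toks:
                    raise FormatError(f"{path}:{lineno}: empty directive")
                if toks[0] == "FIELDS":
                    fields = toks[1:]
                elif toks[0] == "SET":
                    if len(toks) < 3:
                        raise FormatError(f"{path}:{lineno}: malformed SET")
                    sets[toks[1]] = " ".join(toks[2:])
                else:
                    raise FormatError(f"{path}:{lineno}: unknown directive "
                                      f"{toks[0]!r}")
            elif s:
                break
    if fields is None:
        raise FormatError(f"{path}: missing '#! FIELDS' header")
    return fields, sets, n_header


def _read_table(path, fields):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            toks = s.split()
            if len(toks) != len(fields):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(fields)} columns, "
                    f"got {len(toks)}")
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return np.asarray(rows, float).reshape(-1, len(fields))


def _write_header(fh, fields, sets):
    fh.write("#! FIELDS " + " ".join(fields) + "\n")
    for k, v in sets.items():
        if v is not None:
            fh.write(f"#! SET {k} {v}\n")


# --------------------------------------------------------------------------
# COLVAR

def write_colvar(traj: CVTrajectory, path, config_hash: str | None = None):
    fields = ["time", *traj.labels]
    cols = [traj.times] + [traj.values[:, j] for j in range(traj.dimensionality)]
    if traj.v_bias is not None:
        fields.append("metad_bias")
        cols.append(traj.v_bias)
    sets = {"temperature": _FMT % traj.thermo.temperature,
            "stride": _FMT % traj.stride,
            "seed": traj.seed, "config_hash": config_hash}
    with open(path, "w") as fh:
        _write_header(fh, fields, sets)
        np.savetxt(fh, np.column_stack(cols), fmt=_FMT)


def read_colvar(path) -> CVTrajectory:
    """Read a PLUMED-dialect COLVAR file; columns are mapped by header name."""
    fields, sets, _ = _parse_header(path)
    if not fields or fields[0] != "time":
        raise FormatError(f"{path}: first column must be 'time'")
    data = _read_table(path, fields)
    if data.shape[0] == 0:
        raise DataError(f"{path}: no data rows")
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    cv_names = [f for f in fields[1:] if f.startswith("cv_") or f == "z"]
    if not cv_names:
        raise FormatError(f"{path}: no CV columns (cv_*) found")
    values = np.column_stack([data[:, fields.index(n)] for n in cv_names])
    v_bias = data[:, fields.index("metad_bias")] if "metad_bias" in fields \
        else None
    thermo = ThermoState(float(sets.get("temperature", 310.0)))
    stride = float(sets.get("stride", times[1] - times[0] if len(times) > 1
                            else 1.0))
    seed = sets.get("seed")
    seed = None if seed in (None, "None") else int(seed)
    return CVTrajectory(times=times, values=values, thermo=thermo,
                        stride=stride, seed=seed, v_bias=v_bias,
                        labels=tuple(cv_names))


# --------------------------------------------------------------------------
# HILLS

def write_hills(ledger: HillsLedger, path, config_hash: str | None = None):
    labels = ("cv_cq",) if ledger.dimensionality == 1 else ("cv_ring", "cv_tail")
    fields = ["time", *labels, *[f"sigma_{x}" for x in labels],
              "height", "biasf"]
    n = len(ledger)
    cols = [ledger.times[:n]]
    cols += [ledger.centers[:n, j] for j in range(ledger.dimensionality)]
    cols += [ledger.sigmas[:n, j] for j in range(ledger.dimensionality)]
    cols += [ledger.heights[:n], np.full(n, ledger.bias_factor)]
    sets = {"temperature": _FMT % ledger.thermo.temperature,
            "pace": _FMT % ledger.pace, "config_hash": config_hash}
    with open(path, "w") as fh:
        _write_header(fh, fields, sets)
        np.savetxt(fh, np.column_stack(cols), fmt=_FMT)


def read_hills(path) -> HillsLedger:
    fields, sets, _ = _parse_header(path)
    if "time" not in fields or "height" not in fields or "biasf" not in fields:
        raise FormatError(f"{path}: HILLS needs time/height/biasf columns")
    cv_names = [f for f in fields if f.startswith("cv_")]
    sig_names = [f"sigma_{n}" for n in cv_names]
    for s in sig_names:
        if s not in fields:
            raise FormatError(f"{path}: missing column {s!r}")
    data = _read_table(path, fields)
    biasf = data[:, fields.index("biasf")]
    if data.shape[0] and np.any(biasf != biasf[0]):
        raise FormatError(f"{path}: biasf column is not constant")
    if data.shape[0] > 1 and np.any(np.diff(data[:, 0]) <= 0):
        raise FormatError(f"{path}: kernel times must be strictly increasing")
    thermo = ThermoState(float(sets.get("temperature", 310.0)))
    pace = float(sets.get("pace", np.diff(data[:, 0]).min()
                          if data.shape[0] > 1 else 1.0))
    ledger = HillsLedger(len(cv_names), float(biasf[0]) if data.shape[0]
                         else 20.0, thermo, pace)
    centers = np.column_stack([data[:, fields.index(n)] for n in cv_names])
    sigmas = np.column_stack([data[:, fields.index(n)] for n in sig_names])
    for i in range(data.shape[0]):
        ledger.append(GaussianKernel(centers[i], sigmas[i],
                                     float(data[i, fields.index("height")]),
                                     float(data[i, 0])))
    return ledger


# --------------------------------------------------------------------------
# FES / grids

def write_fes(fes: FreeEnergySurface, path, config_hash: str | None = None,
              signed_value: bool = False):
    d = fes.dimensionality
    labels = list(fes.labels)
    fields = [*labels, "free_energy", "error", "mask"]
    sets = {}
    for j, lab in enumerate(labels):
        sets[f"min_{lab}"] = _FMT % fes.axes[j][0]
        sets[f"max_{lab}"] = _FMT % fes.axes[j][-1]
        sets[f"nbins_{lab}"] = str(len(fes.axes[j]))
    sets["reference"] = fes.reference
    sets["temperature"] = _FMT % fes.thermo.temperature
    if fes.bulk_cut is not None:
        sets["bulk_cut"] = _FMT % fes.bulk_cut
    if signed_value:
        sets["signed_value"] = "1"
    sets["config_hash"] = config_hash
    grids = np.meshgrid(*fes.axes, indexing="ij")
    cols = [g.ravel() for g in grids]
    cols += [fes.F.ravel(), fes.error.ravel(),
             fes.mask.astype(float).ravel()]
    with open(path, "w") as fh:
        _write_header(fh, fields, sets)
        np.savetxt(fh, np.column_stack(cols), fmt=_FMT)


def read_fes(path) -> FreeEnergySurface:
    fields, sets, _ = _parse_header(path)
    labels = [f for f in fields if f not in ("free_energy", "error", "mask")]
    if "free_energy" not in fields:
        raise FormatError(f"{path}: missing free_energy column")
    data = _read_table(path, fields)
    nbins = [int(sets[f"nbins_{lab}"]) for lab in labels]
    axes = tuple(np.linspace(float(sets[f"min_{lab}"]),
                             float(sets[f"max_{lab}"]), nb)
                 for lab, nb in zip(labels, nbins))
    shape = tuple(nbins)
    if data.shape[0] != int(np.prod(shape)):
        raise DataError(f"{path}: row count does not match declared grid")
    F = data[:, fields.index("free_energy")].reshape(shape)
    err = (data[:, fields.index("error")].reshape(shape)
           if "error" in fields else np.zeros(shape))
    mask = (data[:, fields.index("mask")].reshape(shape).astype(bool)
            if "mask" in fields else np.isfinite(F))
    thermo = ThermoState(float(sets.get("temperature", 310.0)))
    bulk_cut = float(sets["bulk_cut"]) if "bulk_cut" in sets else None
    return FreeEnergySurface(axes, F, err, mask,
                             sets.get("reference", "none"), thermo,
                             bulk_cut, tuple(labels))


# --------------------------------------------------------------------------
# paths & diffusion profiles

def write_path(path_obj: StringPath, path, labels=("cv_ring", "cv_tail"),
               config_hash: str | None = None):
    fields = ["image", *labels, "arc_length", "free_energy"]
    sets = {"converged": int(path_obj.converged),
            "iterations": path_obj.iterations, "config_hash": config_hash}
    n = len(path_obj.arc_length)
    cols = [np.arange(n)] + [path_obj.images[:, j]
                             for j in range(path_obj.images.shape[1])]
    cols += [path_obj.arc_length, path_obj.F_along]
    with open(path, "w") as fh:
        _write_header(fh, fields, sets)
        np.savetxt(fh, np.column_stack(cols), fmt=_FMT)


def read_path(path) -> StringPath:
    fields, sets, _ = _parse_header(path)
    data = _read_table(path, fields)
    cv_cols = [i for i, f in enumerate(fields)
               if f not in ("image", "arc_length", "free_energy")]
    return StringPath(data[:, cv_cols],
                      data[:, fields.index("arc_length")],
                      data[:, fields.index("free_energy")],
                      bool(int(sets.get("converged", 0))),
                      int(sets.get("iterations", 0)))


def write_d_profile(profile: DiffusionProfile, path,
                    config_hash: str | None = None):
    with open(path, "w") as fh:
        _write_header(fh, ["z", "diff", "error"],
                      {"config_hash": config_hash})
        np.savetxt(fh, np.column_stack([profile.z, profile.D, profile.error]),
                   fmt=_FMT)


def read_d_profile(path) -> DiffusionProfile:
    fields, _, _ = _parse_header(path)
    data = _read_table(path, fields)
    return DiffusionProfile(data[:, 0], data[:, 1], data[:, 2])


# --------------------------------------------------------------------------
# configuration

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration mapping (canonical JSON, sha256)."""
    blob = json.dumps(cfg, sort_keys=True, separators=(",", ":"),
                      default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def verify_artifact(path, cfg_or_hash) -> bool:
    """True when the artifact's embedded config hash matches the config."""
    expected = cfg_or_hash if isinstance(cfg_or_hash, str) \
        else config_hash(cfg_or_hash)
    _, sets, _ = _parse_header(path)
    return sets.get("config_hash") == expected
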