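"""File formats: HDF5 and CSV spectrum dialects, an XYZ-with-box trajectory
dialect, JSON fit-result serialization, and bridges to standard topology +
trajectory readers."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .qens import GlobalFit, PerQFit, QENSSpectrum
from .trajectory import ChainEnsembleTrajectory

__all__ = [
    "write_spectrum_h5", "read_spectrum_h5",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_xyz", "read_xyz",
    "fit_result_to_json", "load_trajectory",
]


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def write_spectrum_h5(path, spectrum: QENSSpectrum, truth_attrs: dict | None = None
                      ) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("q", data=spectrum.q_values)
        f.create_dataset("omega", data=spectrum.omega_values)
        f.create_dataset("intensity", data=spectrum.intensity)
        f.create_dataset("sigma", data=spectrum.sigma)
        f.create_dataset("resolution_fwhm",
                         data=np.atleast_1d(spectrum.resolution_fwhm))
        if truth_attrs:
            for k, v in truth_attrs.items():
                if v is not None and not isinstance(v, (dict, list, np.ndarray)):
                    f.attrs[k] = v


def read_spectrum_h5(path) -> QENSSpectrum:
    with h5py.File(path, "r") as f:
        res = f["resolution_fwhm"][()]
        res = float(res[0]) if np.size(res) == 1 else np.asarray(res)
        return QENSSpectrum(
            q_values=f["q"][()], omega_values=f["omega"][()],
            intensity=f["intensity"][()], sigma=f["sigma"][()],
            resolution_fwhm=res)


def write_spectrum_csv(path, spectrum: QENSSpectrum) -> None:
    """Flat long-format table: one row per (q, ω) point."""
    nq, nw = spectrum.intensity.shape
    df = pd.DataFrame({
        "q": np.repeat(spectrum.q_values, nw),
        "omega": np.tile(spectrum.omega_values, nq),
        "intensity": spectrum.intensity.ravel(),
        "sigma": spectrum.sigma.ravel(),
    })
    with open(path, "w") as fh:
        fh.write(f"# resolution_fwhm={np.mean(np.atleast_1d(spectrum.resolution_fwhm))}\n")
        df.to_csv(fh, index=False)


def read_spectrum_csv(path) -> QENSSpectrum:
    with open(path) as fh:
        header = fh.readline()
        res = 0.9
        if header.startswith("#") and "resolution_fwhm=" in header:
            res = float(header.split("resolution_fwhm=")[1])
        df = pd.read_csv(fh)
    q = np.unique(df["q"].to_numpy())
    omega = np.unique(df["omega"].to_numpy())
    nq, nw = q.size, omega.size
    order = np.lexsort((df["omega"].to_numpy(), df["q"].to_numpy()))
    return QENSSpectrum(
        q_values=q, omega_values=omega,
        intensity=df["intensity"].to_numpy()[order].reshape(nq, nw),
        sigma=df["sigma"].to_numpy()[order].reshape(nq, nw),
        resolution_fwhm=res)


# ---------------------------------------------------------------------------
# XYZ-with-box trajectories
# ---------------------------------------------------------------------------

def write_xyz(path, traj: ChainEnsembleTrajectory) -> None:
    """Extended-XYZ-like plain text: per frame a header with time and box,
    then one line per atom: element chain mass x y z."""
    elements = traj.elements if traj.elements is not None \
        else np.array(["X"] * traj.coords.shape[1])
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            box = traj.box_at(t)
            fh.write(f"{traj.coords.shape[1]}\n")
            fh.write(f"time={traj.times[t]:.9g} "
                     f"box={box[0]:.9g},{box[1]:.9g},{box[2]:.9g}\n")
            for a in range(traj.coords.shape[1]):
                x, y, z = traj.coords[t, a]
                fh.write(f"{elements[a]} {traj.chain_ids[a]} {traj.masses[a]:.9g} "
                         f"{x:.9g} {y:.9g} {z:.9g}\n")


def read_xyz(path) -> ChainEnsembleTrajectory:
    times, frames, boxes = [], [], []
    elements = chain_ids = masses = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        natoms = int(lines[i])
        meta = dict(kv.split("=") for kv in lines[i + 1].split())
        times.append(float(meta["time"]))
        boxes.append([float(v) for v in meta["box"].split(",")])
        frame = np.empty((natoms, 3))
        elems, cids, ms = [], [], []
        for a in range(natoms):
            parts = lines[i + 2 + a].split()
            elems.append(parts[0])
            cids.append(int(parts[1]))
            ms.append(float(parts[2]))
            frame[a] = [float(v) for v in parts[3:6]]
        frames.append(frame)
        if elements is None:
            elements, chain_ids, masses = elems, cids, ms
        i += 2 + natoms
    return ChainEnsembleTrajectory(
        times=np.asarray(times), coords=np.asarray(frames),
        box=np.asarray(boxes), chain_ids=np.asarray(chain_ids),
        masses=np.asarray(masses), elements=np.asarray(elements))


# ---------------------------------------------------------------------------
# Standard topology + trajectory readers
# ---------------------------------------------------------------------------

def load_trajectory(topology, trajectory=None, chain_by: str = "segment"
                    ) -> ChainEnsembleTrajectory:
    """Read PDB/GRO (+XTC/DCD/...) files into a ChainEnsembleTrajectory via
    MDAnalysis.  Chains come from segments ('segment') or connected fragments
    ('fragment'); falls back to a single chain."""
    import MDAnalysis as mda

    u = mda.Universe(str(topology)) if trajectory is None else \
        mda.Universe(str(topology), str(trajectory))
    atoms = u.atoms
    if chain_by == "fragment":
        groups = atoms.fragments
    else:
        groups = [atoms.select_atoms(f"segid {s}") for s in
                  np.unique(atoms.segids)] or [atoms]
    chain_ids = np.empty(atoms.n_atoms, dtype=int)
    for ci, g in enumerate(groups):
        chain_ids[g.indices] = ci
    coords, times, boxes = [], [], []
    for ts in u.trajectory:
        coords.append(atoms.positions.copy())
        times.append(ts.time / 1000.0)  # MDAnalysis ps → ns
        boxes.append(ts.dimensions[:3].copy() if ts.dimensions is not None
                     else np.full(3, np.inf))
    try:
        elements = np.asarray(atoms.elements, dtype=str)
    except Exception:
        elements = np.asarray([n[0] for n in atoms.names], dtype=str)
    masses = atoms.masses
    return ChainEnsembleTrajectory(
        times=np.asarray(times), coords=np.asarray(coords),
        box=np.asarray(boxes), chain_ids=chain_ids,
        masses=np.asarray(masses), elements=elements)


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def fit_result_to_json(result: PerQFit | GlobalFit, path=None) -> str:
    """Serialize a fit result (parameters, uncertainties, metrics) to JSON."""
    payload = _jsonable(asdict(result))
    payload["kind"] = type(result).__name__
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
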