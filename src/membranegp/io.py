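"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: CSV for spectra, seeds, per-cell records,
depth series and trajectory coordinate dumps (comma-separated, UTF-8,
header row, 9 significant digits); multichannel TIFF for images, 32-bit
float TIFF for GP maps, 16-bit TIFF for label maps; GRO + XTC (via
MDAnalysis) for trajectories; JSON for run reports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .gp import EmissionSpectrum, GPMap, TwoChannelImage
from .mdgeom import BilayerTrajectory, DepthSeries
from .segment import CellGPRecord, CellLabelMap, SeedSet

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_two_channel_tiff",
    "write_two_channel_tiff",
    "write_gp_map_tiff",
    "read_gp_map_tiff",
    "write_label_map_tiff",
    "read_label_map_tiff",
    "read_seeds_csv",
    "write_seeds_csv",
    "write_cell_records_csv",
    "read_cell_records_csv",
    "write_depth_series_csv",
    "read_depth_series_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_gro_xtc",
    "read_trajectory_gro_xtc",
    "write_run_report",
    "sha256_of",
]

_FLOAT_FMT = "%.9g"


# --------------------------------------------------------------------------
# spectra


def read_spectrum_csv(path, excitation_wavelength: float | None = None) -> EmissionSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(float),
        df["intensity"].to_numpy(float),
        excitation_wavelength=excitation_wavelength,
    )


def write_spectrum_csv(spectrum: EmissionSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# --------------------------------------------------------------------------
# images


def write_two_channel_tiff(image: TwoChannelImage, path) -> None:
    """Write as a (2, H, W) float32 stack, channel 0 = blue, 1 = red."""
    stack = np.stack([image.blue, image.red]).astype(np.float32)
    tifffile.imwrite(path, stack)


def read_two_channel_tiff(path, channel_order: tuple[int, int] = (0, 1)) -> TwoChannelImage:
    """Read a 2-channel TIFF; ``channel_order`` gives (blue, red) plane indices."""
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError(f"{path}: expected a (C, H, W) stack with C >= 2")
    b, r = channel_order
    return TwoChannelImage(blue=stack[b].astype(float), red=stack[r].astype(float))


def write_gp_map_tiff(gpmap: GPMap, gp_path, valid_path) -> None:
    tifffile.imwrite(gp_path, gpmap.gp.astype(np.float32))
    tifffile.imwrite(valid_path, gpmap.valid.astype(np.uint8))


def read_gp_map_tiff(gp_path, valid_path, intensity_threshold: float = float("nan")) -> GPMap:
    gp = tifffile.imread(gp_path).astype(float)
    valid = tifffile.imread(valid_path).astype(bool)
    return GPMap(gp=gp, valid=valid, intensity_threshold=intensity_threshold)


def write_label_map_tiff(labels: CellLabelMap, path) -> None:
    tifffile.imwrite(path, labels.labels.astype(np.uint16))


def read_label_map_tiff(path) -> CellLabelMap:
    lab = tifffile.imread(path).astype(np.int32)
    return CellLabelMap(labels=lab, n_cells=int(lab.max()))


# --------------------------------------------------------------------------
# seeds and per-cell records


def read_seeds_csv(path) -> SeedSet:
    """Seeds CSV: columns row, col, kind (cell|background)."""
    df = pd.read_csv(path)
    for col in ("row", "col", "kind"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = set(df["kind"]) - {"cell", "background"}
    if bad:
        raise ValueError(f"{path}: unknown seed kind(s) {sorted(bad)}")
    cells = df[df["kind"] == "cell"]
    bg = df[df["kind"] == "background"]
    return SeedSet(
        cell_seeds=tuple(zip(cells["row"].astype(int), cells["col"].astype(int))),
        background_seeds=tuple(zip(bg["row"].astype(int), bg["col"].astype(int))),
    )


def write_seeds_csv(seeds: SeedSet, path) -> None:
    rows = [(r, c, "cell") for r, c in seeds.cell_seeds]
    rows += [(r, c, "background") for r, c in seeds.background_seeds]
    pd.DataFrame(rows, columns=["row", "col", "kind"]).to_csv(path, index=False)


def write_cell_records_csv(records: list[CellGPRecord], path) -> None:
    pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "treatment": [r.treatment if r.treatment is not None else "" for r in records],
            "median_gp": [r.median_gp for r in records],
            "n_membrane_pixels": [r.n_membrane_pixels for r in records],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cell_records_csv(path) -> list[CellGPRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        CellGPRecord(
            cell_id=int(row.cell_id),
            median_gp=float(row.median_gp),
            n_membrane_pixels=int(row.n_membrane_pixels),
            treatment=str(row.treatment) or None,
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# depth series and trajectories


def write_depth_series_csv(series: DepthSeries, path) -> None:
    pd.DataFrame(
        {
            "time_ns": series.time,
            "thickness_A": series.thickness,
            "tilt_deg": series.tilt,
            "rmsd_A": series.rmsd,
            "dist_edge1_A": series.dist_edge1,
            "dist_edge2_A": series.dist_edge2,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_depth_series_csv(path) -> DepthSeries:
    df = pd.read_csv(path)
    return DepthSeries(
        time=df["time_ns"].to_numpy(float),
        thickness=df["thickness_A"].to_numpy(float),
        tilt=df["tilt_deg"].to_numpy(float),
        rmsd=df["rmsd_A"].to_numpy(float),
        dist_edge1=df["dist_edge1_A"].to_numpy(float),
        dist_edge2=df["dist_edge2_A"].to_numpy(float),
    )


def write_trajectory_csv(traj: BilayerTrajectory, path) -> None:
    """Plain-text coordinate dump: one row per atom per frame (portable)."""
    n_frames, n_atoms, _ = traj.coordinates.shape
    frame_idx = np.repeat(np.arange(n_frames), n_atoms)
    atom_idx = np.tile(np.arange(n_atoms), n_frames)
    is_p = np.zeros(n_atoms, dtype=bool)
    is_p[traj.p_atom_indices] = True
    is_dye = np.zeros(n_atoms, dtype=bool)
    is_dye[traj.dye_atom_indices] = True
    flat = traj.coordinates.reshape(-1, 3)
    pd.DataFrame(
        {
            "frame": frame_idx,
            "time_ns": np.repeat(traj.times, n_atoms),
            "atom_index": atom_idx,
            "atom_name": np.tile(np.asarray(traj.atom_names, dtype=object), n_frames),
            "is_phosphate": np.tile(is_p, n_frames).astype(int),
            "is_dye": np.tile(is_dye, n_frames).astype(int),
            "x_A": flat[:, 0],
            "y_A": flat[:, 1],
            "z_A": flat[:, 2],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path) -> BilayerTrajectory:
    df = pd.read_csv(path)
    frames = np.sort(df["frame"].unique())
    first = df[df["frame"] == frames[0]].sort_values("atom_index")
    atom_names = tuple(first["atom_name"].astype(str))
    p_idx = first.loc[first["is_phosphate"] == 1, "atom_index"].to_numpy(int)
    dye_idx = first.loc[first["is_dye"] == 1, "atom_index"].to_numpy(int)
    n_atoms = len(atom_names)
    df = df.sort_values(["frame", "atom_index"])
    coords = df[["x_A", "y_A", "z_A"]].to_numpy(float).reshape(len(frames), n_atoms, 3)
    times = df.groupby("frame")["time_ns"].first().to_numpy(float)
    return BilayerTrajectory(
        times=times,
        coordinates=coords,
        atom_names=atom_names,
        p_atom_indices=p_idx,
        dye_atom_indices=dye_idx,
        dye_heavy_indices=dye_idx,
    )


def write_trajectory_gro_xtc(traj: BilayerTrajectory, gro_path, xtc_path) -> None:
    """Write structure (GRO, first frame) and trajectory (XTC) via MDAnalysis.

    Phosphates become residue LIP (atom P), the dye residue DYE with its
    atom names preserved.  Coordinates are written as stored (Å; MDAnalysis
    converts to nm internally for the files).
    """
    import MDAnalysis as mda

    n_atoms = traj.coordinates.shape[1]
    n_p = traj.p_atom_indices.size
    n_res = n_p + 1  # one residue per lipid P plus one dye residue
    atom_resindex = np.empty(n_atoms, dtype=int)
    atom_resindex[traj.p_atom_indices] = np.arange(n_p)
    atom_resindex[traj.dye_atom_indices] = n_p
    u = mda.Universe.empty(
        n_atoms, n_residues=n_res, atom_resindex=atom_resindex, trajectory=True
    )
    u.add_TopologyAttr("names", list(traj.atom_names))
    u.add_TopologyAttr("resnames", ["LIP"] * n_p + ["DYE"])
    u.add_TopologyAttr("resids", list(range(1, n_res + 1)))
    box = traj.box or (100.0, 100.0, 100.0)
    dims = [box[0], box[1], box[2], 90.0, 90.0, 90.0]
    u.atoms.positions = traj.coordinates[0]
    u.dimensions = dims
    u.atoms.write(str(gro_path))
    with mda.Writer(str(xtc_path), n_atoms) as writer:
        for i in range(traj.coordinates.shape[0]):
            u.atoms.positions = traj.coordinates[i]
            u.trajectory.ts.dimensions = dims
            u.trajectory.ts.time = traj.times[i] * 1000.0  # ns -> ps
            u.trajectory.ts.frame = i
            writer.write(u.atoms)


def read_trajectory_gro_xtc(
    gro_path,
    xtc_path,
    p_name: str = "P",
    dye_resname: str = "DYE",
    heavy_exclude_prefix: str = "H",
) -> BilayerTrajectory:
    """Load a structure + trajectory pair into a :class:`BilayerTrajectory`.

    ``p_name`` selects the lipid phosphorus atoms by atom name and
    ``dye_resname`` the dye residue; dye atoms whose name starts with
    ``heavy_exclude_prefix`` are treated as hydrogens and excluded from the
    heavy-atom set.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(gro_path), str(xtc_path))
    p_sel = u.select_atoms(f"name {p_name}")
    dye_sel = u.select_atoms(f"resname {dye_resname}")
    if p_sel.n_atoms < 4:
        raise ValueError(f"fewer than 4 atoms named {p_name!r} in {gro_path}")
    if dye_sel.n_atoms < 2:
        raise ValueError(f"fewer than 2 dye atoms (resname {dye_resname!r})")
    heavy = dye_sel.select_atoms(f"not name {heavy_exclude_prefix}*")
    times = []
    coords = []
    for ts in u.trajectory:
        times.append(ts.time / 1000.0)  # ps -> ns
        coords.append(u.atoms.positions.copy().astype(float))
    return BilayerTrajectory(
        times=np.asarray(times),
        coordinates=np.asarray(coords),
        atom_names=tuple(u.atoms.names),
        p_atom_indices=p_sel.indices.copy(),
        dye_atom_indices=dye_sel.indices.copy(),
        dye_heavy_indices=heavy.indices.copy(),
    )


# --------------------------------------------------------------------------
# run reports


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
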