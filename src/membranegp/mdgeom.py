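"""Bilayer-trajectory geometry of an embedded membrane dye.

Post-processing of a flat lipid-bilayer trajectory containing a single dye
molecule: per-frame membrane thickness between the phosphate (P) planes,
dye tilt to the membrane normal, heavy-atom RMSD after rigid superposition,
signed distances of the chromophore edge atoms to the proximal phosphate
plane, trailing-window averages, and the convergence time between two
trajectories started from different insertion depths.

Conventions
-----------
* The membrane normal is the laboratory +z axis (the bilayer is built and
  simulated normal to z); no per-frame plane fitting is performed.
* Lengths are Å, times ns, angles degrees.
* Interface distances are signed positive *toward the bilayer center*: an
  atom buried below the proximal phosphate plane has a positive distance.
* The proximal leaflet is fixed per trajectory from the first frame (the
  dye is assumed not to flip between leaflets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BilayerFrame",
    "BilayerTrajectory",
    "DepthSeries",
    "DepthSummary",
    "assign_leaflets",
    "membrane_thickness",
    "tilt_angle",
    "heavy_atom_rmsd",
    "interface_distance",
    "depth_series",
    "window_average",
    "convergence_time",
]


@dataclass(frozen=True)
class BilayerFrame:
    """One trajectory frame: coordinates plus named atom selections.

    ``coordinates`` is an ``(n_atoms, 3)`` array in Å.  ``p_atom_indices``
    selects the lipid phosphorus atoms (both leaflets), ``dye_atom_indices``
    the dye, and ``dye_heavy_indices`` the dye heavy atoms used for RMSD.
    """

    time: float  # ns
    coordinates: np.ndarray
    atom_names: tuple[str, ...]
    p_atom_indices: np.ndarray
    dye_atom_indices: np.ndarray
    dye_heavy_indices: np.ndarray
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        object.__setattr__(self, "coordinates", coords)
        for attr in ("p_atom_indices", "dye_atom_indices", "dye_heavy_indices"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=int))

    def dye_atom_index(self, name: str) -> int:
        """Index (into ``coordinates``) of the dye atom called ``name``."""
        for i in self.dye_atom_indices:
            if self.atom_names[i] == name:
                return int(i)
        raise KeyError(f"dye atom {name!r} not found among dye atoms")


@dataclass
class BilayerTrajectory:
    """A stack of frames sharing topology: times (ns) and coordinates (Å)."""

    times: np.ndarray  # (n_frames,)
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    atom_names: tuple[str, ...]
    p_atom_indices: np.ndarray
    dye_atom_indices: np.ndarray
    dye_heavy_indices: np.ndarray
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if self.times.size != self.coordinates.shape[0]:
            raise ValueError("times and coordinates disagree on frame count")
        self.p_atom_indices = np.asarray(self.p_atom_indices, dtype=int)
        self.dye_atom_indices = np.asarray(self.dye_atom_indices, dtype=int)
        self.dye_heavy_indices = np.asarray(self.dye_heavy_indices, dtype=int)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def frame(self, i: int) -> BilayerFrame:
        return BilayerFrame(
            time=float(self.times[i]),
            coordinates=self.coordinates[i],
            atom_names=self.atom_names,
            p_atom_indices=self.p_atom_indices,
            dye_atom_indices=self.dye_atom_indices,
            dye_heavy_indices=self.dye_heavy_indices,
            box=self.box,
        )


@dataclass
class DepthSeries:
    """Per-frame geometry series (equal lengths, strictly increasing time)."""

    time: np.ndarray  # ns
    thickness: np.ndarray  # Å
    tilt: np.ndarray  # degrees
    rmsd: np.ndarray  # Å, vs the first analyzed frame
    dist_edge1: np.ndarray  # Å, headgroup-side edge atom (N2-like)
    dist_edge2: np.ndarray  # Å, opposite edge atom (C23-like)

    def __post_init__(self) -> None:
        arrays = [self.time, self.thickness, self.tilt, self.rmsd,
                  self.dist_edge1, self.dist_edge2]
        n = {a.size for a in map(np.asarray, arrays)}
        if len(n) != 1:
            raise ValueError("all series must have equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def midpoint(self) -> np.ndarray:
        """Chromophore-midpoint depth: mean of the two edge-atom distances."""
        return 0.5 * (np.asarray(self.dist_edge1) + np.asarray(self.dist_edge2))


@dataclass
class DepthSummary:
    """Trailing-window averages of the edge-atom distances."""

    window: tuple[float, float]  # ns interval actually averaged
    mean_dist_edge1: float
    mean_dist_edge2: float
    mean_midpoint: float
    sd_dist_edge1: float
    sd_dist_edge2: float
    sd_midpoint: float
    n_frames: int


def assign_leaflets(frame: BilayerFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split the P atoms into top and bottom leaflets by their z median.

    Returns ``(top, bottom)`` index arrays into ``frame.coordinates``.  An
    atom exactly at the median z goes to the bottom leaflet (fixed tie rule).
    """
    p_idx = frame.p_atom_indices
    if p_idx.size < 4:
        raise ValueError("need at least 4 phosphate atoms to define two leaflets")
    z = frame.coordinates[p_idx, 2]
    if np.ptp(z) == 0:
        raise ValueError("all phosphate z coordinates equal: no bilayer")
    med = np.median(z)
    top = p_idx[z > med]
    bottom = p_idx[z <= med]
    if top.size < 2 or bottom.size < 2:
        raise ValueError("fewer than 2 phosphate atoms in one leaflet")
    return top, bottom


def membrane_thickness(frame: BilayerFrame) -> float:
    """P-to-P thickness: mean z of the top leaflet minus that of the bottom."""
    top, bottom = assign_leaflets(frame)
    z = frame.coordinates[:, 2]
    return float(z[top].mean() - z[bottom].mean())


def tilt_angle(
    frame: BilayerFrame,
    atom_a: str = "N2",
    atom_b: str = "N3",
    fold: bool = False,
) -> float:
    """Angle (degrees) between the ``atom_a → atom_b`` vector and +z.

    The raw angle lies in [0°, 180°]; with ``fold=True`` it is folded to
    [0°, 90°] (axis angle, ignoring the vector's sense).
    """
    ra = frame.coordinates[frame.dye_atom_index(atom_a)]
    rb = frame.coordinates[frame.dye_atom_index(atom_b)]
    v = rb - ra
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"atoms {atom_a!r} and {atom_b!r} coincide")
    ang = float(np.degrees(np.arccos(np.clip(v[2] / norm, -1.0, 1.0))))
    if fold and ang > 90.0:
        ang = 180.0 - ang
    return ang


def _kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centered ``p`` onto centered ``q``."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def heavy_atom_rmsd(frame: BilayerFrame, reference: BilayerFrame) -> float:
    """RMSD of the dye heavy atoms after optimal rigid superposition.

    The dye is translated and rotated (Kabsch) onto the reference using the
    heavy atoms only, so any global rigid motion of the dye contributes
    nothing; the residual reports internal deformation.
    """
    idx = frame.dye_heavy_indices
    if idx.size < 3:
        raise ValueError("need at least 3 heavy atoms for superposition")
    if not np.array_equal(idx, reference.dye_heavy_indices):
        raise ValueError("frame and reference select different heavy atoms")
    p = frame.coordinates[idx]
    q = reference.coordinates[idx]
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    rot = _kabsch_rotation(pc, qc)
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff**2).sum() / idx.size))


def _proximal_is_top(frame: BilayerFrame, headgroup_atom: str) -> bool:
    top, bottom = assign_leaflets(frame)
    z = frame.coordinates[:, 2]
    z_atom = frame.coordinates[frame.dye_atom_index(headgroup_atom)][2]
    return abs(z[top].mean() - z_atom) <= abs(z[bottom].mean() - z_atom)


def interface_distance(
    frame: BilayerFrame,
    atom: str,
    headgroup_atom: str = "N2",
    proximal_top: bool | None = None,
) -> float:
    """Signed distance (Å) of ``atom`` to the proximal phosphate plane.

    The proximal leaflet is the one whose mean P-plane lies nearest the
    dye's headgroup edge atom (``headgroup_atom``), unless fixed explicitly
    with ``proximal_top``.  Positive values point toward the bilayer center
    (the atom is buried below a top plane, or above a bottom plane).
    """
    if proximal_top is None:
        proximal_top = _proximal_is_top(frame, headgroup_atom)
    top, bottom = assign_leaflets(frame)
    z = frame.coordinates[:, 2]
    z_atom = z[frame.dye_atom_index(atom)]
    if proximal_top:
        return float(z[top].mean() - z_atom)
    return float(z_atom - z[bottom].mean())


def depth_series(
    trajectory: BilayerTrajectory,
    edge_atom_1: str = "N2",
    edge_atom_2: str = "C23",
    tilt_atoms: tuple[str, str] = ("N2", "N3"),
    fold_tilt: bool = False,
) -> DepthSeries:
    """Per-frame thickness, tilt, RMSD and edge-atom interface distances.

    RMSD is computed against the first analyzed frame.  The proximal leaflet
    is decided once, on the first frame, and held fixed.  A failure in any
    frame aborts with the frame index in the error message.
    """
    if trajectory.n_frames < 1:
        raise ValueError("empty trajectory")
    ref = trajectory.frame(0)
    proximal_top = _proximal_is_top(ref, edge_atom_1)
    n = trajectory.n_frames
    thick = np.empty(n)
    tilt = np.empty(n)
    rmsd = np.empty(n)
    d1 = np.empty(n)
    d2 = np.empty(n)
    for i in range(n):
        frame = trajectory.frame(i)
        try:
            thick[i] = membrane_thickness(frame)
            tilt[i] = tilt_angle(frame, *tilt_atoms, fold=fold_tilt)
            rmsd[i] = heavy_atom_rmsd(frame, ref)
            d1[i] = interface_distance(frame, edge_atom_1, proximal_top=proximal_top)
            d2[i] = interface_distance(frame, edge_atom_2, proximal_top=proximal_top)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"frame {i} (t={frame.time} ns): {exc}") from exc
    return DepthSeries(
        time=trajectory.times.copy(),
        thickness=thick,
        tilt=tilt,
        rmsd=rmsd,
        dist_edge1=d1,
        dist_edge2=d2,
    )


def window_average(series: DepthSeries, window_ns: float) -> DepthSummary:
    """Averages over the trailing ``window_ns`` of the series.

    Frames with ``time >= t_end - window_ns`` (inclusive) are used, matching
    the convention of reporting means over the last part of a simulation.
    """
    t = np.asarray(series.time)
    span = t[-1] - t[0]
    if window_ns > span:
        raise ValueError(f"window {window_ns} ns exceeds trajectory span {span} ns")
    t_start = t[-1] - window_ns
    sel = t >= t_start
    if sel.sum() < 2:
        raise ValueError("fewer than 2 frames in the averaging window")
    d1 = np.asarray(series.dist_edge1)[sel]
    d2 = np.asarray(series.dist_edge2)[sel]
    mid = 0.5 * (d1 + d2)
    return DepthSummary(
        window=(float(t[sel][0]), float(t[-1])),
        mean_dist_edge1=float(d1.mean()),
        mean_dist_edge2=float(d2.mean()),
        mean_midpoint=float(mid.mean()),
        sd_dist_edge1=float(d1.std(ddof=1)),
        sd_dist_edge2=float(d2.std(ddof=1)),
        sd_midpoint=float(mid.std(ddof=1)),
        n_frames=int(sel.sum()),
    )


def _trailing_mean(t: np.ndarray, x: np.ndarray, window: float) -> np.ndarray:
    """Mean of ``x`` over the trailing ``window`` at each time (partial at start)."""
    out = np.empty_like(x)
    j = 0
    csum = np.concatenate(([0.0], np.cumsum(x)))
    for i in range(t.size):
        while t[i] - t[j] > window:
            j += 1
        out[i] = (csum[i + 1] - csum[j]) / (i + 1 - j)
    return out


def convergence_time(
    series_a: DepthSeries,
    series_b: DepthSeries,
    tolerance: float,
    hold: float,
    smooth_ns: float = 0.0,
) -> float | None:
    """Earliest time the two midpoint-depth series agree and stay agreeing.

    The chromophore-midpoint distance of each series (optionally smoothed by
    a trailing running mean of width ``smooth_ns``) is compared pointwise on
    the common time grid of ``series_a`` (``series_b`` is linearly resampled
    if its grid differs).  Returns the earliest time ``t`` such that the two
    curves differ by less than ``tolerance`` at every time in
    ``[t, t + hold]``, or ``None`` if no such time exists within the span.
    """
    ta = np.asarray(series_a.time)
    ma = series_a.midpoint
    tb = np.asarray(series_b.time)
    mb = series_b.midpoint
    if not np.array_equal(ta, tb):
        mb = np.interp(ta, tb, mb)
    if smooth_ns > 0:
        ma = _trailing_mean(ta, ma, smooth_ns)
        mb = _trailing_mean(ta, mb, smooth_ns)
    ok = np.abs(ma - mb) < tolerance
    t_end = ta[-1]
    # suffix of consecutively-ok samples ending at each index
    for i in range(ta.size):
        if ta[i] + hold > t_end:
            break
        j = np.searchsorted(ta, ta[i] + hold, side="right")
        if ok[i:j].all():
            return float(ta[i])
    return None
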