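"""Post-hoc molecular-dynamics trajectory summary statistics.

Implements the standard stability/flexibility readouts computed after a
simulation: RMSD against a reference frame (with optional mass-weighted
Kabsch superposition), per-residue RMSF with a mean + 1 SD flexible-residue
flag, mass-weighted radius of gyration, geometric hydrogen-bond counting
(donor–acceptor distance <= 0.35 nm, H–D–A angle <= 30 deg by default), a
cumulant summary of any metric series (mean, SD, SE, standardized skewness,
excess kurtosis), and a tail-band equilibration-time estimate.

Trajectories are plain multi-frame XYZ text plus a sidecar table mapping
atom index to residue index and mass; all coordinates are in nm, times in
ns.  No simulation, PBC handling, or force-field physics lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (nm) with per-atom metadata."""

    times: np.ndarray  # (n_frames,) ns
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    masses: np.ndarray  # (n_atoms,) Da
    residue_index: np.ndarray  # (n_atoms,) 1-based
    elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] != len(self.times):
            raise ValueError("times and coords frame counts differ")
        if self.coords.shape[1] != len(self.masses) or len(self.masses) != len(self.residue_index):
            raise ValueError("per-atom arrays must match the atom count")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if (self.masses <= 0).any():
            raise ValueError("masses must be > 0")
        if len(self.times) > 2:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing must be uniform")
        if not self.elements:
            self.elements = ["C"] * self.coords.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class MetricSeries:
    """A named per-frame series with its summary statistics."""

    name: str
    times: np.ndarray
    values: np.ndarray
    statistics: dict[str, float | None]
    equilibration_time: float | None = None


def series_statistics(values: np.ndarray) -> dict[str, float | None]:
    """Mean, sample SD, SE = SD/sqrt(n), standardized skewness (cum3) and
    excess kurtosis (cum4, Gaussian -> 0).

    Cumulant ratios use population central moments m_k = mean((x - mean)^k):
    cum3 = m3 / m2^1.5, cum4 = m4 / m2^2 - 3; undefined (None) for a
    constant series.  Requires n >= 2.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("series statistics require >= 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    centred = values - mean
    m2 = float(np.mean(centred**2))
    if m2 == 0.0:
        cum3 = cum4 = None
    else:
        cum3 = float(np.mean(centred**3) / m2**1.5)
        cum4 = float(np.mean(centred**4) / m2**2 - 3.0)
    return {"mean": mean, "sd": sd, "se": sd / np.sqrt(n), "cum3": cum3, "cum4": cum4}


def _superpose(mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Kabsch superposition of one frame onto the reference."""
    w = weights / weights.sum()
    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    if len(mobile) < 3 or _is_collinear(ref_c):
        warnings.warn("degenerate superposition: translation-only fallback")
        return mob_c + (w[:, None] * reference).sum(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=weights)
    return rot.apply(mob_c) + (w[:, None] * reference).sum(axis=0)


def _is_collinear(centred: np.ndarray, tol: float = 1e-12) -> bool:
    s = np.linalg.svd(centred, compute_uv=False)
    return bool(np.sum(s > tol * max(1.0, s[0])) < 2)


def _select(traj: Trajectory, selection: np.ndarray | None) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_atoms)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if len(sel) == 0:
        raise ValueError("empty atom selection")
    return sel


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    selection: np.ndarray | None = None,
    superpose: bool = True,
    mass_weighted: bool = True,
) -> MetricSeries:
    """Per-frame RMSD (nm) against a reference frame.

    RMSD = sqrt(sum_i m_i |x_i - x_i^ref|^2 / sum_i m_i) over the selection,
    after optional mass-weighted Kabsch superposition.  ``reference``
    defaults to the first frame.
    """
    sel = _select(traj, selection)
    ref = (traj.coords[0] if reference is None else np.asarray(reference, float))[sel]
    masses = traj.masses[sel] if mass_weighted else np.ones(len(sel))
    values = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.coords[t, sel]
        if superpose:
            frame = _superpose(frame, ref, masses)
        diff2 = np.sum((frame - ref) ** 2, axis=1)
        values[t] = np.sqrt(np.sum(masses * diff2) / masses.sum())
    stats = series_statistics(values) if traj.n_frames >= 2 else {"mean": float(values[0])}
    return MetricSeries("rmsd", traj.times, values, stats)


@dataclass
class RmsfResult:
    """Per-residue RMSF with the mean + 1 SD flexibility flag."""

    residues: np.ndarray  # residue indices (1-based)
    rmsf: np.ndarray  # nm
    threshold: float  # mean + 1 SD over residues
    flexible_residues: np.ndarray
    flexible_runs: list[tuple[int, int]]  # inclusive (start, end) residue runs


def flexibility_threshold(rmsf_values: np.ndarray) -> float:
    """Flexible-residue cutoff: mean(RMSF) + 1 x SD(RMSF) over residues."""
    rmsf_values = np.asarray(rmsf_values, dtype=float)
    return float(rmsf_values.mean() + rmsf_values.std(ddof=1))


def rmsf_per_residue(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    superpose: bool = False,
) -> RmsfResult:
    """Per-residue RMSF (nm): per-atom fluctuation about the time-average
    position, averaged within each residue.

    With ``superpose`` each frame is first fitted onto the mean structure
    (mass-weighted Kabsch, iterated once), removing rigid-body motion.
    Residues above mean + 1 SD are flagged, reported with contiguous runs.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires >= 2 frames")
    sel = _select(traj, selection)
    coords = traj.coords[:, sel]
    masses = traj.masses[sel]
    if superpose:
        ref = coords.mean(axis=0)
        coords = np.stack([_superpose(f, ref, masses) for f in coords])
    mean_pos = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))
    res_ids = traj.residue_index[sel]
    residues = np.unique(res_ids)
    rmsf = np.array([per_atom[res_ids == r].mean() for r in residues])
    threshold = flexibility_threshold(rmsf)
    # strict exceedance with a float-dust guard so a rigid trajectory
    # (all-zero RMSF up to rounding) never flags anything
    exceeds = (rmsf > threshold) & ~np.isclose(rmsf, threshold, rtol=1e-9, atol=1e-12)
    flexible = residues[exceeds]
    runs: list[tuple[int, int]] = []
    for r in flexible:
        if runs and r == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], int(r))
        else:
            runs.append((int(r), int(r)))
    return RmsfResult(residues, rmsf, threshold, flexible, runs)


def radius_of_gyration(traj: Trajectory, selection: np.ndarray | None = None) -> MetricSeries:
    """Per-frame mass-weighted radius of gyration (nm)."""
    sel = _select(traj, selection)
    coords = traj.coords[:, sel]
    m = traj.masses[sel]
    com = (m[None, :, None] * coords).sum(axis=1) / m.sum()
    diff2 = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    values = np.sqrt((m[None, :] * diff2).sum(axis=1) / m.sum())
    stats = series_statistics(values) if traj.n_frames >= 2 else {"mean": float(values[0])}
    return MetricSeries("rg", traj.times, values, stats)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition."""

    distance_cutoff_nm: float = 0.35
    angle_cutoff_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.distance_cutoff_nm <= 0 or self.angle_cutoff_deg <= 0:
            raise ValueError("cutoffs must be > 0")


def hbond_count(
    traj: Trajectory,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[MetricSeries, MetricSeries]:
    """Hydrogen-bond and donor–acceptor pair counts per frame.

    ``donors`` and ``hydrogens`` are parallel arrays (hydrogen i is bonded
    to donor i); ``acceptors`` lists acceptor atoms.  A donor-acceptor pair
    counts toward the *pair* series when the D–A distance is within the
    cutoff; it counts as a *hydrogen bond* when additionally the H–D–A
    angle is within the angle cutoff.  A donor is never paired with itself.
    """
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if len(donors) != len(hydrogens):
        raise ValueError("donors and hydrogens must be parallel arrays")
    if len(donors) == 0 or len(acceptors) == 0:
        warnings.warn("empty donor/acceptor list: zero H-bond series")
        zeros = np.zeros(traj.n_frames)
        stats = series_statistics(zeros) if traj.n_frames >= 2 else {"mean": 0.0}
        return (
            MetricSeries("hbonds", traj.times, zeros, dict(stats)),
            MetricSeries("da_pairs", traj.times, zeros.copy(), dict(stats)),
        )
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff_deg))
    hb = np.zeros(traj.n_frames)
    pairs = np.zeros(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.coords[t]
        d_xyz = frame[donors]  # (nd, 3)
        a_xyz = frame[acceptors]  # (na, 3)
        h_xyz = frame[hydrogens]
        da = a_xyz[None, :, :] - d_xyz[:, None, :]  # (nd, na, 3)
        dist = np.linalg.norm(da, axis=2)
        not_self = donors[:, None] != acceptors[None, :]
        within = (dist <= criteria.distance_cutoff_nm) & not_self
        pairs[t] = int(within.sum())
        dh = h_xyz - d_xyz  # (nd, 3)
        dh_norm = np.linalg.norm(dh, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ikj->ik", dh, da) / (dh_norm[:, None] * dist)
        hb[t] = int((within & (cosang >= cos_cut)).sum())
    hb_stats = series_statistics(hb) if traj.n_frames >= 2 else {"mean": float(hb[0])}
    pair_stats = series_statistics(pairs) if traj.n_frames >= 2 else {"mean": float(pairs[0])}
    return (
        MetricSeries("hbonds", traj.times, hb, hb_stats),
        MetricSeries("da_pairs", traj.times, pairs, pair_stats),
    )


def equilibration_time(
    series: MetricSeries, tolerance: float = 1.0, min_plateau_ns: float = 5.0
) -> float | None:
    """Earliest time from which the series stays inside the tail band.

    The band is mean +/- tolerance x SD of the last 50% of frames.  Returns
    the earliest t* such that every value from t* to the end lies inside the
    band and the remaining span is at least ``min_plateau_ns``; None when no
    such time exists (e.g. a monotone ramp that exits the band at the end).
    """
    values = np.asarray(series.values, dtype=float)
    times = np.asarray(series.times, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("equilibration detection requires >= 2 frames")
    tail = values[n // 2 :]
    centre, spread = tail.mean(), tail.std(ddof=0)
    inside = np.abs(values - centre) <= tolerance * spread
    outside_idx = np.flatnonzero(~inside)
    start = 0 if len(outside_idx) == 0 else int(outside_idx[-1]) + 1
    if start >= n:
        return None
    t_star = float(times[start])
    if times[-1] - t_star < min_plateau_ns - 1e-12:
        return None
    return t_star
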