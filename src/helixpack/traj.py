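"""Geometry and energy post-processing of trajectory snapshots.

Operations here consume :class:`~helixpack.structio.TrajectoryFrames`
(coordinates in Å) together with atom-index selections, and report
membrane-scale quantities in nm: centre-of-mass separations, smoothed
steering-force traces, work integrals, lipid number-density profiles
along the inter-monomer axis, lipid-shell tracking, leaflet-to-leaflet
thickness maps and truncated non-bonded group–group energies.

All geometric quantities are invariant under rigid translation of every
frame, and a density profile summed over bins recovers the atom count
inside the analysed slab exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import TrajectoryFrames
from .units import ang_to_nm, kbt_pn_nm

__all__ = [
    "ForceTrace",
    "DensityProfile",
    "WorkCurve",
    "com_distance",
    "window_average",
    "integrate_work",
    "lipid_density_profile",
    "track_shell",
    "membrane_thickness_profile",
    "group_interaction_energy",
]

#: Coulomb prefactor 1/(4πε0) in kJ·nm/(mol·e²).
COULOMB_KJ_NM_PER_MOL_E2 = 138.935458


@dataclass
class ForceTrace:
    """A constant-velocity pulling record: time (ps), guide position along
    the pulling direction (nm) and spring force on the pulled group (pN)."""

    time_ps: np.ndarray
    guide_nm: np.ndarray
    force_pn: np.ndarray

    def __post_init__(self) -> None:
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.guide_nm = np.asarray(self.guide_nm, dtype=float)
        self.force_pn = np.asarray(self.force_pn, dtype=float)
        if not (len(self.time_ps) == len(self.guide_nm) == len(self.force_pn)):
            raise ValueError("trace columns have different lengths")
        if len(self.time_ps) > 1 and not np.all(np.diff(self.time_ps) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class DensityProfile:
    """Atoms per nm³ binned along the inter-monomer axis, snapshot-averaged."""

    bin_centers_nm: np.ndarray
    density: np.ndarray            # atoms/nm³, mean over snapshots
    n_snapshots: int
    bin_width_nm: float
    transverse_halfwidth_nm: float
    z_interval_nm: tuple[float, float]

    @property
    def bin_volume_nm3(self) -> float:
        z0, z1 = self.z_interval_nm
        return self.bin_width_nm * 2.0 * self.transverse_halfwidth_nm * (z1 - z0)


@dataclass
class WorkCurve:
    """Accumulated external work along the guide coordinate."""

    guide_nm: np.ndarray
    work_pn_nm: np.ndarray

    def work_kbt(self, temperature_k: float) -> np.ndarray:
        return self.work_pn_nm / kbt_pn_nm(temperature_k)


def _check_selection(sel, label: str) -> np.ndarray:
    sel = np.asarray(sel, dtype=int)
    if sel.size == 0:
        raise ValueError(f"empty selection: {label}")
    return sel


def _com_nm(frames: TrajectoryFrames, sel: np.ndarray,
            masses: np.ndarray | None) -> np.ndarray:
    """Per-frame mass-weighted centre of mass in nm, shape (F, 3)."""
    xyz = ang_to_nm(frames.coords[:, sel, :])
    if masses is None:
        return xyz.mean(axis=1)
    w = np.asarray(masses, dtype=float)[sel]
    return (xyz * w[None, :, None]).sum(axis=1) / w.sum()


def com_distance(frames: TrajectoryFrames, sel_a, sel_b,
                 masses: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Distance between the two selections' centres of mass per frame.

    Returns (times in ps, distances in nm).  ``masses`` is a per-atom
    array over the whole roster; unit masses are assumed when omitted.
    """
    sel_a = _check_selection(sel_a, "selection A")
    sel_b = _check_selection(sel_b, "selection B")
    d = np.linalg.norm(_com_nm(frames, sel_a, masses)
                       - _com_nm(frames, sel_b, masses), axis=1)
    return frames.times.copy(), d


def window_average(x: np.ndarray, y: np.ndarray, window: float = 0.5,
                   ) -> np.ndarray:
    """Boxcar mean of ``y`` over all samples within ±window/2 of each x.

    Edges use the truncated window (the mean runs over however many
    samples actually fall inside).  The default 0.5 nm window matches the
    smoothing used for steering-force traces plotted against separation.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # ±window/2 inclusive; the epsilon keeps grid-aligned boundary samples
    # from dropping in or out through floating-point rounding
    half = window / 2.0 + 1e-9 * window
    lo = np.searchsorted(xs, x - half, side="left")
    hi = np.searchsorted(xs, x + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(ys)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def integrate_work(trace: ForceTrace) -> WorkCurve:
    """Trapezoidal work integral of force over the guide coordinate.

    The stiff-spring convention is used: work accumulates along the guide
    (dummy-point) coordinate, which advances at the prescribed pulling
    speed, not along the instantaneous molecular coordinate.
    """
    if len(trace.time_ps) < 2:
        raise ValueError("need at least 2 samples to integrate")
    dz = np.diff(trace.guide_nm)
    if np.any(dz < 0):
        raise ValueError("guide position must be non-decreasing (forward pull)")
    inc = 0.5 * (trace.force_pn[1:] + trace.force_pn[:-1]) * dz
    work = np.concatenate([[0.0], np.cumsum(inc)])
    return WorkCurve(guide_nm=trace.guide_nm.copy(), work_pn_nm=work)


def _axis_frame(point_a_nm, point_b_nm):
    a = np.asarray(point_a_nm, dtype=float)
    b = np.asarray(point_b_nm, dtype=float)
    ab = b - a
    length = np.linalg.norm(ab)
    if length == 0:
        raise ValueError("axis endpoints coincide")
    u = ab / length
    # transverse in-plane direction (perpendicular to axis, horizontal)
    t = np.cross([0.0, 0.0, 1.0], u)
    tn = np.linalg.norm(t)
    if tn < 1e-12:  # axis along z: any horizontal direction serves
        t = np.array([1.0, 0.0, 0.0])
    else:
        t = t / tn
    return a, u, t, length


def lipid_density_profile(frames: TrajectoryFrames, lipid_sel,
                          axis: tuple, bin_width_nm: float = 0.5,
                          transverse_halfwidth_nm: float = 1.0,
                          z_interval_nm: tuple[float, float] = (-2.0, 0.0),
                          ) -> DensityProfile:
    """Lipid number density binned along the line joining two monomers.

    ``axis`` is (pointA, pointB) in nm.  Per snapshot, atoms whose
    projection onto the axis falls in a bin, whose transverse offset is
    within ±``transverse_halfwidth_nm`` and whose z lies inside
    ``z_interval_nm`` (the leaflet of interest, default the cytoplasmic
    lower half of a 4 nm slab) are counted; density is count over bin
    volume, averaged over snapshots.
    """
    lipid_sel = _check_selection(lipid_sel, "lipid selection")
    z0, z1 = z_interval_nm
    if bin_width_nm <= 0 or transverse_halfwidth_nm <= 0 or z1 <= z0:
        raise ValueError("slab has zero or negative volume")
    a, u, t, length = _axis_frame(*axis)
    n_bins = max(1, int(np.ceil(length / bin_width_nm)))
    edges = np.arange(n_bins + 1) * bin_width_nm
    counts = np.zeros(n_bins)
    for f in range(frames.n_frames):
        xyz = ang_to_nm(frames.coords[f, lipid_sel, :]) - a
        s = xyz @ u
        trans = xyz @ t
        z = xyz[:, 2] + a[2]          # z kept absolute
        keep = ((np.abs(trans) <= transverse_halfwidth_nm)
                & (z >= z0) & (z <= z1) & (s >= 0) & (s <= edges[-1]))
        counts += np.histogram(s[keep], bins=edges)[0]
    vol = bin_width_nm * 2.0 * transverse_halfwidth_nm * (z1 - z0)
    return DensityProfile(
        bin_centers_nm=0.5 * (edges[:-1] + edges[1:]),
        density=counts / (frames.n_frames * vol),
        n_snapshots=frames.n_frames,
        bin_width_nm=bin_width_nm,
        transverse_halfwidth_nm=transverse_halfwidth_nm,
        z_interval_nm=(z0, z1))


def track_shell(frames: TrajectoryFrames, monomer_sel, chain_sels: list,
                masses: np.ndarray | None = None,
                ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Distance of tagged lipid chains from a monomer's centre of mass.

    Returns (times in ps, one distance series in nm per tagged chain).
    Chains that travel with the monomer keep a constant distance; chains
    outside the co-moving shell fall behind as the monomer is steered.
    """
    monomer_sel = _check_selection(monomer_sel, "monomer selection")
    com_m = _com_nm(frames, monomer_sel, masses)
    series = []
    for ci, chain in enumerate(chain_sels):
        chain = _check_selection(chain, f"chain selection {ci}")
        com_c = _com_nm(frames, chain, masses)
        series.append(np.linalg.norm(com_c - com_m, axis=1))
    return frames.times.copy(), series


def membrane_thickness_profile(frames: TrajectoryFrames, head_sel_upper,
                               head_sel_lower, axis: tuple,
                               bin_width_nm: float = 0.5,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Leaflet-to-leaflet thickness binned along the inter-monomer axis.

    Per bin: mean z of upper-leaflet head atoms minus mean z of
    lower-leaflet head atoms, averaged over frames; bins with no atoms in
    either leaflet report NaN rather than zero.  Returns
    (bin centres in nm, thickness in nm).
    """
    up = _check_selection(head_sel_upper, "upper head selection")
    lo = _check_selection(head_sel_lower, "lower head selection")
    a, u, _, length = _axis_frame(*axis)
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(1, int(np.ceil(length / bin_width_nm)))
    edges = np.arange(n_bins + 1) * bin_width_nm

    def _accumulate(sel):
        zsum = np.zeros(n_bins)
        cnt = np.zeros(n_bins)
        for f in range(frames.n_frames):
            xyz = ang_to_nm(frames.coords[f, sel, :])
            s = (xyz - a) @ u
            z = xyz[:, 2]
            keep = (s >= 0) & (s <= edges[-1])
            which = np.clip(np.searchsorted(edges, s[keep], side="right") - 1,
                            0, n_bins - 1)
            np.add.at(zsum, which, z[keep])
            np.add.at(cnt, which, 1.0)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, zsum / np.maximum(cnt, 1), np.nan)

    gap = _accumulate(up) - _accumulate(lo)
    return 0.5 * (edges[:-1] + edges[1:]), gap


def group_interaction_energy(frames: TrajectoryFrames, sel_a, sel_b,
                             params: dict[int, tuple[float, float, float]],
                             cutoff_nm: float = 1.2,
                             dielectric: float = 1.0,
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncated pairwise non-bonded energy between two atom groups.

    ``params`` maps atom index → (ε in kJ/mol, σ in nm, q in e).
    Lennard-Jones 12-6 with Lorentz–Berthelot combining and plain
    truncation at ``cutoff_nm``; Coulomb with a fixed relative
    dielectric, same truncation.  Energies are comparative (generic
    parameters), not force-field-faithful.  Returns
    (times in ps, LJ kJ/mol, Coulomb kJ/mol).
    """
    sel_a = _check_selection(sel_a, "selection A")
    sel_b = _check_selection(sel_b, "selection B")
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("selections overlap; groups must be disjoint")
    for sel in (sel_a, sel_b):
        for i in sel:
            if int(i) not in params:
                raise ValueError(f"missing (epsilon, sigma, q) for atom {int(i)}")
    eps_a = np.array([params[int(i)][0] for i in sel_a])
    sig_a = np.array([params[int(i)][1] for i in sel_a])
    q_a = np.array([params[int(i)][2] for i in sel_a])
    eps_b = np.array([params[int(i)][0] for i in sel_b])
    sig_b = np.array([params[int(i)][1] for i in sel_b])
    q_b = np.array([params[int(i)][2] for i in sel_b])

    eps_ij = np.sqrt(np.outer(eps_a, eps_b))
    sig_ij = 0.5 * (sig_a[:, None] + sig_b[None, :])
    qq = np.outer(q_a, q_b)

    lj_t = np.empty(frames.n_frames)
    coul_t = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        ra = ang_to_nm(frames.coords[f, sel_a, :])
        rb = ang_to_nm(frames.coords[f, sel_b, :])
        r = np.linalg.norm(ra[:, None, :] - rb[None, :, :], axis=-1)
        inside = r <= cutoff_nm
        rr = np.where(inside, r, np.inf)
        sr6 = (sig_ij / rr) ** 6
        lj_t[f] = float(np.sum(4.0 * eps_ij * (sr6 ** 2 - sr6)))
        coul_t[f] = float(np.sum(
            np.where(inside, COULOMB_KJ_NM_PER_MOL_E2 * qq / (dielectric * rr), 0.0)))
    return frames.times.copy(), lj_t, coul_t
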