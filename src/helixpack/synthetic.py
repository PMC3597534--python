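"""Synthetic fixtures with known ground truth.

Three generators emulate the data the analysis modules were built for:

* :func:`make_dumbbell` — a two-rigid-domain Cα structure joined by a
  sparse flexible linker, the canonical hinge-detection case;
* :func:`make_membrane_patch` — a point-atom membrane slab with a
  controllable high-density region around two embedded helices and an
  optional thinned channel between them;
* :func:`simulate_pull` — overdamped Langevin pulling of a particle on a
  prescribed 1-D free-energy profile with a constant-velocity harmonic
  guide, producing stochastic work traces for the Jarzynski estimators;
* :func:`gaussian_work_set` — i.i.d. Gaussian endpoint works, the
  closed-form oracle for the exponential-average identity.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import MolecularStructure, TrajectoryFrames
from .traj import ForceTrace
from .free_energy import WorkTraceSet
from .units import DEFAULT_TEMPERATURE_K, kbt_pn_nm, nm_to_ang

__all__ = [
    "PMFSpec",
    "GeneratorConfig",
    "MembranePatch",
    "make_dumbbell",
    "make_helix",
    "make_membrane_patch",
    "simulate_pull",
    "gaussian_work_set",
]


# ---------------------------------------------------------------------------
# Prescribed free-energy profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PMFSpec:
    """Analytic 1-D free-energy profile F(x) in kBT over x in nm.

    F(x) = slope·x + Σ_k h_k·exp(−(x−c_k)²/(2 w_k²)) − well_depth·g(x),
    i.e. a gentle downhill ramp, Gaussian bumps (the lipid-packing
    barriers), and a deep Gaussian contact well — the qualitative shape
    of a membrane-mediated association profile: the free energy decreases
    gradually on approach, passes local peaks where the lipid pack is
    disturbed, then drops sharply on dimer contact.

    The default keeps a 4 kBT principal barrier, a desk-scale stand-in
    for the hundreds-of-kBT barriers of the real membrane system that a
    stochastic sampler could never cross.
    """

    x_range_nm: tuple[float, float] = (0.0, 4.0)
    slope_kbt_per_nm: float = -0.5
    bumps: tuple[tuple[float, float, float], ...] = ((4.0, 2.0, 0.4),)
    #: (depth kBT, centre nm, width nm) of the contact well; depth 0 disables.
    well: tuple[float, float, float] = (8.0, 3.8, 0.3)

    def value(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f = self.slope_kbt_per_nm * x
        for h, c, w in self.bumps:
            f = f + h * np.exp(-((x - c) ** 2) / (2 * w ** 2))
        d, c, w = self.well
        f = f - d * np.exp(-((x - c) ** 2) / (2 * w ** 2))
        return f

    def grad(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.full_like(x, self.slope_kbt_per_nm)
        for h, c, w in self.bumps:
            g = g - h * (x - c) / w ** 2 * np.exp(-((x - c) ** 2) / (2 * w ** 2))
        d, c, w = self.well
        g = g + d * (x - c) / w ** 2 * np.exp(-((x - c) ** 2) / (2 * w ** 2))
        return g

    def true_barrier_kbt(self, n_grid: int = 4001) -> float:
        """Peak minus deepest preceding valley on a fine grid, in kBT."""
        x = np.linspace(*self.x_range_nm, n_grid)
        f = self.value(x) - self.value(self.x_range_nm[0])
        ipeak = int(np.argmax(f))
        if ipeak == 0:
            return 0.0
        return float(f[ipeak] - np.min(f[:ipeak]))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the stochastic pulling generator.

    Friction and temperature set the particle's diffusivity
    D = kBT/γ ≈ 4.3 nm²/ns at the defaults, fast enough that the
    quasi-static regime is reached at desk-scale pulling speeds; the
    guide spring is stiff (300 pN/nm) so the guide coordinate resolves
    the profile to ~0.12 nm.
    """

    seed: int = 0
    pull_speed_nm_ns: float = 1.0
    spring_pn_nm: float = 300.0
    friction_pn_ns_nm: float = 1.0
    temperature_k: float = DEFAULT_TEMPERATURE_K
    dt_ns: float = 1e-3
    record_every: int = 10
    equilibration_ns: float = 0.1

    def __post_init__(self) -> None:
        if min(self.pull_speed_nm_ns, self.spring_pn_nm,
               self.friction_pn_ns_nm, self.dt_ns) <= 0:
            raise ValueError("speed, spring, friction and dt must be positive")
        if self.temperature_k < 0:
            raise ValueError("temperature must be non-negative")


# ---------------------------------------------------------------------------
# Hinged dumbbell structure
# ---------------------------------------------------------------------------

def _lattice_block(n: int, spacing: float) -> np.ndarray:
    """n cubic-lattice points (Å) filling x-slices from x = 0 upward.

    The first slice (x = 0) is always complete and laterally centred, so
    a linker approaching from −x finds several non-collinear anchor atoms
    within the 8 Å cutoff; within a slice, points fill centre-outward.
    """
    m = max(2, int(np.ceil(n ** (1.0 / 3.0))))
    g = (np.arange(m) - (m - 1) / 2.0) * spacing
    lat = np.array([(y, z) for y in g for z in g])
    lat = lat[np.argsort(np.linalg.norm(lat, axis=1), kind="stable")]
    pts = []
    sx = 0
    while len(pts) < n:
        for y, z in lat:
            pts.append((sx * spacing, y, z))
            if len(pts) == n:
                break
        sx += 1
    return np.array(pts)


def make_dumbbell(n1: int = 30, n2: int = 30, linker: int = 10,
                  seed: int = 0, spacing: float = 5.0,
                  ) -> tuple[MolecularStructure, list[str]]:
    """Two compact Cα clusters joined by a sparse helical linker.

    Clusters are dense cubic-lattice blocks (spacing 5 Å: axial and
    face-diagonal contacts under an 8 Å cutoff brace every face, hence
    internally rigid); the linker is a shallow helical coil whose nodes
    touch only a few nearby sequence neighbours — three-dimensionally
    rigid (the composite keeps exactly six zero modes) yet axially
    compliant like a coil spring, so the lowest internal mode is an
    anti-phase displacement of the two domains with its amplitude node
    inside the linker, exactly the pattern the hinge detector targets.  Returns the structure and per-residue ground-truth labels in
    {"domain1", "linker", "domain2"}.
    """
    if n1 < 10 or n2 < 10:
        raise ValueError("clusters need at least 10 residues each")
    if linker < 2:
        raise ValueError("linker needs at least 2 residues")
    rng = np.random.default_rng(seed)

    # cluster 1 mirrored so its complete lattice face points toward +x
    blob1 = _lattice_block(n1, spacing) * np.array([-1.0, 1.0, 1.0])
    attach1 = blob1[0]                   # lateral centre of the +x face

    # shallow helical coil: 1.0 Å axial rise, 3.2 Å radius, 36° per node;
    # neighbour distances d1≈2.2, d2≈4.3, d3≈6.0, d4≈7.6, d5≈8.1 Å, so
    # springs reach the fourth sequence neighbour: the coil is
    # three-dimensionally rigid (no fold or twist mechanisms) yet axially
    # compliant, like a coil spring, and far softer than the braced blocks
    rise, radius, turn = 1.0, 3.2, np.deg2rad(36.0)
    lk = np.empty((linker, 3))
    for i in range(linker):
        ang = (i + 1) * turn
        lk[i] = attach1 + np.array([
            (i + 1) * rise, radius * np.cos(ang), radius * np.sin(ang)])

    # cluster 2: complete face toward −x, its anchor atom continuing the
    # helical phase one position past the linker end (an anchor off the
    # line of the last two strand nodes transmits torsion; a purely
    # axial continuation would leave a free twist mechanism)
    ang = (linker + 1) * turn
    entry = attach1 + np.array([(linker + 1) * rise,
                                radius * np.cos(ang), radius * np.sin(ang)])
    blob2 = _lattice_block(n2, spacing)
    blob2 = blob2 + (entry - blob2[0])

    coords = np.vstack([blob1, lk, blob2])
    coords = coords + rng.normal(0.0, 0.15, size=coords.shape)
    n = len(coords)
    labels = (["domain1"] * n1) + (["linker"] * linker) + (["domain2"] * n2)
    s = MolecularStructure(
        names=["CA"] * n, resnames=["ALA"] * n,
        resids=np.arange(1, n + 1), chains=["A"] * n, coords=coords)

    from .enm import _component_count  # local import: avoid cycle at load
    if _component_count(s, cutoff=8.0) != 1:
        raise ValueError("generated elastic network is disconnected; "
                         "adjust spacing/linker parameters")
    return s, labels


def make_helix(n_residues: int = 10, seed: int = 0,
               resname: str = "ALA") -> MolecularStructure:
    """An ideal α-helical Cα trace (2.3 Å radius, 1.5 Å rise, 100°/residue)."""
    i = np.arange(n_residues)
    ang = np.deg2rad(100.0) * i
    coords = np.stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i], axis=1)
    rng = np.random.default_rng(seed)
    coords = coords + rng.normal(0.0, 0.05, size=coords.shape)
    return MolecularStructure(
        names=["CA"] * n_residues, resnames=[resname] * n_residues,
        resids=np.arange(1, n_residues + 1), chains=["A"] * n_residues,
        coords=coords)


# ---------------------------------------------------------------------------
# Membrane patch
# ---------------------------------------------------------------------------

@dataclass
class MembranePatch:
    """A generated membrane fixture plus its ground truth.

    ``structure``/``frames`` carry the snapshot stack; the selection
    arrays index the roster; ground-truth fields record exactly what was
    injected so recovery tests need no re-derivation.
    """

    structure: MolecularStructure
    frames: TrajectoryFrames
    lipid_sel: np.ndarray
    head_upper_sel: np.ndarray
    head_lower_sel: np.ndarray
    monomer_sels: list[np.ndarray] = field(default_factory=list)
    baseline_density: float = 100.0          # atoms/nm³
    contrast_factor: float = 0.0
    contrast_x_nm: tuple[float, float] | None = None
    thickness_nm: float = 4.0
    channel_thickness_nm: float | None = None
    channel_x_nm: tuple[float, float] | None = None
    monomer_x_nm: tuple[float, float] = (0.0, 0.0)


def make_membrane_patch(box_nm: tuple[float, float, float] = (10.0, 6.0, 4.0),
                        baseline_density: float = 100.0,
                        contrast_factor: float = 0.0,
                        contrast_x_nm: tuple[float, float] | None = None,
                        monomer_x_nm: tuple[float, float] = (2.5, 7.5),
                        channel_thickness_nm: float | None = None,
                        channel_x_nm: tuple[float, float] | None = None,
                        n_frames: int = 9,
                        frame_spacing_ps: float = 100.0,
                        jitter_nm: float = 0.03,
                        seed: int = 0) -> MembranePatch:
    """Poisson point-atom membrane slab with injected ground truth.

    The slab spans x ∈ [0, lx], y ∈ [−ly/2, ly/2], z ∈ [−lz/2, lz/2]
    (midplane at z = 0).  Lipid tail atoms are sampled at
    ``baseline_density``; inside ``contrast_x_nm`` (defaulting to the
    inter-monomer stretch) the density is (1 + contrast_factor)× higher,
    emulating the ~20% lipid-packing contrast seen between approaching
    helices.  ``channel_thickness_nm`` thins the slab (and its head-group
    surfaces) to that value inside ``channel_x_nm``.  Two vertical
    helices (chains A and B) are embedded at ``monomer_x_nm``.  Snapshots
    are the base configuration under per-frame positional jitter, at
    100 ps spacing (nine microstates by default, matching the averaging
    protocol the profiles are meant for).
    """
    if baseline_density <= 0:
        raise ValueError("baseline density must be positive")
    if contrast_factor < 0:
        raise ValueError("contrast factor must be non-negative")
    lx, ly, lz = box_nm
    if min(lx, ly, lz) <= 0:
        raise ValueError("box dimensions must be positive")
    if channel_thickness_nm is not None and channel_thickness_nm >= lz:
        raise ValueError("channel must be thinner than the slab")
    rng = np.random.default_rng(seed)

    if contrast_x_nm is None and contrast_factor > 0:
        contrast_x_nm = monomer_x_nm
    if channel_x_nm is None and channel_thickness_nm is not None:
        channel_x_nm = monomer_x_nm

    def _local_halfz(x):
        hz = np.full_like(x, lz / 2.0)
        if channel_thickness_nm is not None:
            inside = (x >= channel_x_nm[0]) & (x <= channel_x_nm[1])
            hz[inside] = channel_thickness_nm / 2.0
        return hz

    def _sample_slab(density: float, x_range: tuple[float, float]) -> np.ndarray:
        x0, x1 = x_range
        vol = (x1 - x0) * ly * lz     # nominal volume; channel culls later
        n = rng.poisson(density * vol)
        pts = np.empty((n, 3))
        pts[:, 0] = rng.uniform(x0, x1, n)
        pts[:, 1] = rng.uniform(-ly / 2, ly / 2, n)
        pts[:, 2] = rng.uniform(-lz / 2, lz / 2, n)
        keep = np.abs(pts[:, 2]) <= _local_halfz(pts[:, 0])
        return pts[keep]

    tails = _sample_slab(baseline_density, (0.0, lx))
    if contrast_factor > 0:
        tails = np.vstack([
            tails, _sample_slab(baseline_density * contrast_factor,
                                contrast_x_nm)])

    # head groups on the two local surfaces, ~2 per nm² in-plane
    n_head = rng.poisson(2.0 * lx * ly)
    hx = rng.uniform(0.0, lx, n_head)
    hy = rng.uniform(-ly / 2, ly / 2, n_head)
    hz = _local_halfz(hx)
    heads_up = np.stack([hx, hy, hz], axis=1)
    heads_lo = np.stack([hx, hy, -hz], axis=1)

    def _helix(xc: float) -> np.ndarray:
        nres = max(4, int(round(lz / 0.15)))
        i = np.arange(nres)
        ang = np.deg2rad(100.0) * i
        return np.stack([xc + 0.23 * np.cos(ang), 0.23 * np.sin(ang),
                         -lz / 2 + 0.15 * i], axis=1)

    mono_a, mono_b = _helix(monomer_x_nm[0]), _helix(monomer_x_nm[1])

    # PDB residue numbers are 4 digits; big tail clouds span several chains
    blocks = []
    tail_chain_ids = "TSRQPONMLKJI"
    for ci, start in enumerate(range(0, max(len(tails), 1), 9000)):
        blocks.append((tail_chain_ids[ci], "LIP", "C",
                       tails[start:start + 9000]))
    blocks += [("U", "HEA", "P", heads_up),
               ("W", "HEA", "P", heads_lo), ("A", "ALA", "CA", mono_a),
               ("B", "ALA", "CA", mono_b)]
    names, resnames, resids, chains, coords = [], [], [], [], []
    sels: dict[str, np.ndarray] = {}
    at = 0
    for ch, rn, an, pts in blocks:
        k = len(pts)
        sels[ch] = np.arange(at, at + k)
        names += [an] * k
        resnames += [rn] * k
        resids += list(range(1, k + 1))
        chains += [ch] * k
        coords.append(pts)
        at += k
    base = nm_to_ang(np.vstack(coords))
    structure = MolecularStructure(
        names=names, resnames=resnames, resids=np.array(resids),
        chains=chains, coords=base)

    fr = np.stack([
        base + rng.normal(0.0, nm_to_ang(jitter_nm), size=base.shape)
        for _ in range(n_frames)])
    frames = TrajectoryFrames(coords=fr,
                              times=np.arange(n_frames) * frame_spacing_ps)
    lipid_sel = np.concatenate([sels[ch] for ch, rn, _, _ in blocks
                                if rn == "LIP"])
    return MembranePatch(
        structure=structure, frames=frames,
        lipid_sel=lipid_sel, head_upper_sel=sels["U"],
        head_lower_sel=sels["W"], monomer_sels=[sels["A"], sels["B"]],
        baseline_density=baseline_density, contrast_factor=contrast_factor,
        contrast_x_nm=contrast_x_nm, thickness_nm=lz,
        channel_thickness_nm=channel_thickness_nm, channel_x_nm=channel_x_nm,
        monomer_x_nm=monomer_x_nm)


# ---------------------------------------------------------------------------
# Stochastic pulling
# ---------------------------------------------------------------------------

def simulate_pull(pmf: PMFSpec, cfg: GeneratorConfig, m_repeats: int = 10,
                  ) -> list[ForceTrace]:
    """Overdamped Langevin pulls of one particle across a prescribed PMF.

    A harmonic guide of stiffness k advances from the profile's start to
    its end at constant speed; the particle follows Euler–Maruyama
    dynamics dx = −U'(x)/γ·dt + sqrt(2kBT·dt/γ)·dW with
    U(x) = F_pmf(x) + k/2·(x − z(t))².  Each repeat is equilibrated with
    the guide parked at the origin, then pulled; the recorded force is
    the spring force k·(z − x) in pN.  Repeats use independent child
    seeds of ``cfg.seed`` and are bit-reproducible.
    """
    stab = cfg.dt_ns * cfg.spring_pn_nm / cfg.friction_pn_ns_nm
    if stab > 0.5:
        raise ValueError(
            f"time step too large for the guide spring: dt·k/γ = {stab:.3g} "
            f"exceeds the stability bound 0.5; use dt < "
            f"{0.5 * cfg.friction_pn_ns_nm / cfg.spring_pn_nm:.3g} ns")
    x0, x1 = pmf.x_range_nm
    kbt = kbt_pn_nm(cfg.temperature_k) if cfg.temperature_k > 0 else 0.0
    k, gam, dt = cfg.spring_pn_nm, cfg.friction_pn_ns_nm, cfg.dt_ns
    noise_amp = np.sqrt(2.0 * kbt * dt / gam) if kbt > 0 else 0.0
    kbt_force = kbt_pn_nm(cfg.temperature_k) if cfg.temperature_k > 0 \
        else kbt_pn_nm(DEFAULT_TEMPERATURE_K)
    # PMF forces are defined in kBT/nm at the *thermal* scale even for the
    # deterministic (T=0) drag solution, where the profile force is zero
    # only if the profile is flat.
    n_steps = int(np.ceil((x1 - x0) / (cfg.pull_speed_nm_ns * dt)))
    n_equil = int(np.ceil(cfg.equilibration_ns / dt))
    seeds = np.random.SeedSequence(cfg.seed).spawn(m_repeats)
    if noise_amp:
        # one independent stream per repeat, drawn up front
        xi_all = np.stack([np.random.default_rng(s).standard_normal(
            n_equil + n_steps) for s in seeds], axis=1)
    else:
        xi_all = np.zeros((n_equil + n_steps, m_repeats))

    x = np.full(m_repeats, x0, dtype=float)
    # equilibrate with the guide parked at x0
    for step in range(n_equil):
        fx = -pmf.grad(x) * kbt_force + k * (x0 - x)
        x = x + dt * fx / gam + noise_amp * xi_all[step]

    rec_t, rec_z, rec_f = [], [], []
    t = 0.0
    z = x0
    for step in range(n_steps + 1):
        if step % cfg.record_every == 0 or step == n_steps:
            rec_t.append(t)
            rec_z.append(z)
            rec_f.append(k * (z - x))
        if step == n_steps:
            break
        fx = -pmf.grad(x) * kbt_force + k * (z - x)
        x = x + dt * fx / gam + noise_amp * xi_all[n_equil + step]
        t += dt
        z = min(x0 + cfg.pull_speed_nm_ns * t, x1)

    times = np.array(rec_t) * 1e3          # ns → ps
    guides = np.array(rec_z)
    forces = np.array(rec_f)               # (n_rec, M)
    return [ForceTrace(time_ps=times, guide_nm=guides, force_pn=forces[:, i])
            for i in range(m_repeats)]


# ---------------------------------------------------------------------------
# Gaussian work oracle
# ---------------------------------------------------------------------------

def gaussian_work_set(mu_kbt: float, sigma2_kbt2: float, m_repeats: int,
                      grid_nm: np.ndarray | None = None, seed: int = 0,
                      temperature_k: float = DEFAULT_TEMPERATURE_K,
                      ) -> WorkTraceSet:
    """i.i.d. Gaussian endpoint works on a trivial two-point grid.

    Each repeat ramps linearly from zero to W_i ~ N(mu, sigma²) (kBT).
    For this ensemble the exponential average has the closed form
    ΔF = μ − β σ²/2, making the set the independent oracle for both
    Jarzynski estimators.
    """
    if sigma2_kbt2 < 0:
        raise ValueError("variance must be non-negative")
    if m_repeats < 1:
        raise ValueError("need at least one repeat")
    if grid_nm is None:
        grid_nm = np.array([0.0, 1.0])
    grid_nm = np.asarray(grid_nm, dtype=float)
    rng = np.random.default_rng(seed)
    end = rng.normal(mu_kbt, np.sqrt(sigma2_kbt2), size=m_repeats)
    frac = (grid_nm - grid_nm[0]) / (grid_nm[-1] - grid_nm[0])
    works = end[:, None] * frac[None, :]
    return WorkTraceSet(coordinate_nm=grid_nm, works_kbt=works,
                        temperature_k=temperature_k)
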