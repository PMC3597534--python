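"""Cα elastic-network normal-mode analysis.

The protein is reduced to its Cα atoms, connected by uniform Hookean
springs whenever two nodes lie within a distance cutoff (default 8 Å).
Normal modes are the eigenvectors of the resulting 3N×3N Hessian; a
connected 3-D structure has exactly six zero-frequency rigid-body modes,
and "mode 7" — the first internal mode — carries the softest collective
deformation.  For a molecule made of two rigid domains joined by a
flexible segment, that mode is an anti-phase domain motion about a hinge,
which :func:`detect_hinge` localizes.

Covalent links recorded on the structure (e.g. the junction between a
crystal-structure ectodomain and an NMR transmembrane fragment) always
receive a spring, regardless of the cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .structio import MolecularStructure, select_atoms

__all__ = [
    "ModeSet",
    "HingeReport",
    "HingeConfig",
    "build_hessian",
    "compute_modes",
    "deformation_energy",
    "detect_hinge",
    "find_hinge_mode",
]

#: Relative threshold below which an eigenvalue counts as a rigid-body zero.
ZERO_MODE_RTOL = 1e-8


class DegenerateGeometryError(ValueError):
    """Two network nodes coincide; spring direction undefined."""


@dataclass
class ModeSet:
    """Eigendecomposition of the Cα elastic-network Hessian.

    ``eigenvalues`` ascend (units of the spring constant); ``eigenvectors``
    holds one orthonormal 3N-vector per column.  Mode indices are 1-based
    and include the six rigid-body modes, so mode 7 is the first internal
    mode, matching the conventional numbering of NMA web services.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray          # (3N, 3N), columns are modes
    cutoff: float                     # Å
    spring_constant: float
    node_roster: list[tuple[str, int]]  # (chain, resid) per node

    @property
    def n_nodes(self) -> int:
        return len(self.node_roster)

    @property
    def n_zero_modes(self) -> int:
        lmax = self.eigenvalues[-1] if len(self.eigenvalues) else 0.0
        return int(np.sum(self.eigenvalues <= ZERO_MODE_RTOL * max(lmax, 1e-300)))

    def eigenvalue(self, mode_index: int) -> float:
        """Eigenvalue of a 1-based mode index."""
        self._check_index(mode_index)
        return float(self.eigenvalues[mode_index - 1])

    def mode_vector(self, mode_index: int) -> np.ndarray:
        """Per-node displacement 3-vectors of a 1-based mode, shape (N, 3)."""
        self._check_index(mode_index)
        return self.eigenvectors[:, mode_index - 1].reshape(-1, 3)

    def _check_index(self, mode_index: int) -> None:
        if not 1 <= mode_index <= len(self.eigenvalues):
            raise IndexError(
                f"mode index {mode_index} out of range 1..{len(self.eigenvalues)}")


@dataclass
class HingeReport:
    """Domain decomposition of one mode.

    ``labels`` maps every residue (by roster position) to ``"domain1"``,
    ``"domain2"`` or ``"hinge"``; ``anticorrelation`` is the cosine between
    the two domains' mean displacement vectors (−1 for perfectly anti-phase
    motion).  ``found`` is False when the mode moves the molecule as a
    single block and no hinge exists.
    """

    found: bool
    mode_index: int
    labels: list[str] = field(default_factory=list)
    hinge_residues: list[tuple[str, int]] = field(default_factory=list)
    anticorrelation: float = float("nan")


@dataclass
class HingeConfig:
    """Tunable thresholds of the hinge detector.

    Residues with modal amplitude above ``amplitude_percentile`` form the
    two moving groups; hinge candidates lie below ``hinge_percentile``.
    A hinge is reported only when both groups hold at least
    ``min_group_fraction`` of the residues and their mean displacements
    are anti-correlated below ``max_anticorrelation``.
    """

    amplitude_percentile: float = 50.0
    hinge_percentile: float = 25.0
    min_group_fraction: float = 0.10
    max_anticorrelation: float = -0.25
    #: percent of each group's sequence extent trimmed before testing
    #: separation (rigid-domain rotation contaminates a few member signs)
    group_trim_percent: float = 10.0


def _ca_nodes(s: MolecularStructure) -> np.ndarray:
    idx = select_atoms(s, name="CA")
    if len(idx) == 0:
        idx = np.arange(s.n_atoms)  # point-node structures (no CA naming)
    return idx


def build_hessian(s: MolecularStructure, cutoff: float = 8.0, k: float = 1.0,
                  extra_links: list[tuple[tuple[str, int], tuple[str, int]]] | None = None,
                  ) -> np.ndarray:
    """Elastic-network Hessian over the Cα nodes.

    Each connected pair (i, j) contributes the 3×3 super-element
    k·u uᵀ (u the unit inter-node vector) added to the diagonal blocks and
    subtracted from the off-diagonal blocks.  Pairs beyond ``cutoff``
    contribute nothing; recorded covalent links always contribute.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    nodes = _ca_nodes(s)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 network nodes")
    xyz = s.coords[nodes]
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    pair = dist <= cutoff
    np.fill_diagonal(pair, False)

    links = list(s.links) + list(extra_links or [])
    if links:
        keys = [(s.chains[i], int(s.resids[i])) for i in nodes]
        pos = {key: i for i, key in enumerate(keys)}
        for ka, kb in links:
            if ka in pos and kb in pos:
                pair[pos[ka], pos[kb]] = pair[pos[kb], pos[ka]] = True

    ii, jj = np.nonzero(np.triu(pair, 1))
    if np.any(dist[ii, jj] < 1e-9):
        raise DegenerateGeometryError("coincident nodes in the elastic network")

    hess = np.zeros((3 * n, 3 * n))
    for i, j in zip(ii, jj):
        u = diff[i, j] / dist[i, j]
        blk = k * np.outer(u, u)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hess[si, si] += blk
        hess[sj, sj] += blk
        hess[si, sj] -= blk
        hess[sj, si] -= blk
    return hess


def _component_count(s: MolecularStructure, cutoff: float) -> int:
    nodes = _ca_nodes(s)
    xyz = s.coords[nodes]
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    adj = (dist <= cutoff).astype(int)
    if s.links:
        keys = [(s.chains[i], int(s.resids[i])) for i in nodes]
        pos = {key: i for i, key in enumerate(keys)}
        for ka, kb in s.links:
            if ka in pos and kb in pos:
                adj[pos[ka], pos[kb]] = adj[pos[kb], pos[ka]] = 1
    ncomp, _ = connected_components(csr_matrix(adj), directed=False)
    return int(ncomp)


def compute_modes(s: MolecularStructure, cutoff: float = 8.0, k: float = 1.0,
                  ) -> ModeSet:
    """Full symmetric eigendecomposition of the elastic-network Hessian.

    Eigenvalues with |λ| < 1e-8·λ_max are clamped to exactly zero.  A
    disconnected network is analysed anyway but triggers a warning naming
    the component count, since each extra component adds six zero modes.
    """
    hess = build_hessian(s, cutoff=cutoff, k=k)
    vals, vecs = eigh(hess)
    lmax = max(float(vals[-1]), 1e-300)
    vals = np.where(np.abs(vals) < ZERO_MODE_RTOL * lmax, 0.0, vals)
    nodes = _ca_nodes(s)
    roster = [(s.chains[i], int(s.resids[i])) for i in nodes]
    ncomp = _component_count(s, cutoff)
    if ncomp > 1:
        warnings.warn(
            f"elastic network has {ncomp} disconnected components; "
            f"expect {6 * ncomp} zero modes", stacklevel=2)
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, cutoff=cutoff,
                   spring_constant=k, node_roster=roster)


def deformation_energy(m: ModeSet, mode_index: int) -> float:
    """Deformation energy ½·λ at unit modal amplitude (1-based index)."""
    return 0.5 * m.eigenvalue(mode_index)


def detect_hinge(m: ModeSet, s: MolecularStructure, mode_index: int = 7,
                 config: HingeConfig | None = None) -> HingeReport:
    """Locate the hinge between two anti-phase rigid domains in one mode.

    Algorithm: (1) per-residue displacement 3-vectors come straight from
    the eigenvector; (2) residues with amplitude above the median split
    into two direction groups by the sign of their projection onto the
    first principal axis of the displacement set; (3) the hinge is the set
    of residues below the 25th amplitude percentile lying sequence-wise
    between the two groups; (4) anticorrelation is the cosine between the
    group mean displacements.  When the mode moves the molecule as one
    block (one group empty/tiny, or groups not anti-correlated) a
    ``found=False`` report is returned rather than an exception.
    """
    cfg = config or HingeConfig()
    if m.eigenvalue(mode_index) == 0.0:
        raise ValueError(f"mode {mode_index} is a rigid-body mode")
    disp = m.mode_vector(mode_index)              # (N, 3)
    amp = np.linalg.norm(disp, axis=1)
    n = len(amp)

    # principal axis of the displacement vectors
    _, _, vt = np.linalg.svd(disp - disp.mean(axis=0), full_matrices=False)
    axis = vt[0]
    proj = disp @ axis

    moving = amp > np.percentile(amp, cfg.amplitude_percentile)
    g1 = np.nonzero(moving & (proj > 0))[0]
    g2 = np.nonzero(moving & (proj <= 0))[0]

    no_hinge = HingeReport(found=False, mode_index=mode_index)
    if min(len(g1), len(g2)) < max(1, int(cfg.min_group_fraction * n)):
        return no_hinge

    mean1, mean2 = disp[g1].mean(axis=0), disp[g2].mean(axis=0)
    denom = np.linalg.norm(mean1) * np.linalg.norm(mean2)
    anticorr = float(mean1 @ mean2 / denom) if denom > 0 else 0.0
    if anticorr > cfg.max_anticorrelation:
        return no_hinge

    # order groups along the sequence; hinge candidates sit between them.
    # Extents are percentile-trimmed: a rigid domain rotating about the
    # hinge flips the projection sign of a few of its own residues, and
    # those strays must not abolish an otherwise clean separation.
    if np.median(g1) > np.median(g2):
        g1, g2 = g2, g1
    lo = int(np.percentile(g1, 100.0 - cfg.group_trim_percent))
    hi = int(np.ceil(np.percentile(g2, cfg.group_trim_percent)))
    if hi <= lo:  # interleaved groups: no clean sequence separation
        return no_hinge
    quiet = amp < np.percentile(amp, cfg.hinge_percentile)
    candidates = [i for i in range(lo + 1, hi) if quiet[i]]
    if not candidates:
        return no_hinge
    # keep the longest contiguous run: the hinge is one sequence segment
    runs, run = [], [candidates[0]]
    for i in candidates[1:]:
        if i == run[-1] + 1:
            run.append(i)
        else:
            runs.append(run)
            run = [i]
    runs.append(run)
    hinge_idx = max(runs, key=len)

    labels = []
    first_h, last_h = min(hinge_idx), max(hinge_idx)
    for i in range(n):
        if i in hinge_idx:
            labels.append("hinge")
        elif i <= first_h:
            labels.append("domain1")
        elif i >= last_h:
            labels.append("domain2")
        else:  # non-quiet residue inside the hinge window
            labels.append("domain1" if proj[i] * proj[g1].mean() > 0 else "domain2")
    return HingeReport(
        found=True, mode_index=mode_index, labels=labels,
        hinge_residues=[m.node_roster[i] for i in hinge_idx],
        anticorrelation=anticorr)


def find_hinge_mode(m: ModeSet, s: MolecularStructure, max_mode: int = 12,
                    config: HingeConfig | None = None) -> HingeReport:
    """Hinge report of the lowest internal mode showing two-domain motion.

    The handful of softest internal modes of a hinged molecule are
    near-degenerate (bending about two axes, twist, stretch), and which
    one lands at mode 7 can swap under small coordinate perturbations.
    This scans modes 7..``max_mode`` and returns the first mode for which
    :func:`detect_hinge` finds a hinge, or the (not-found) report of the
    first internal mode.
    """
    first = max(7, m.n_zero_modes + 1)
    report = None
    for mode in range(first, min(max_mode, len(m.eigenvalues)) + 1):
        rep = detect_hinge(m, s, mode_index=mode, config=config)
        if report is None:
            report = rep
        if rep.found:
            return rep
    if report is None:
        raise ValueError("no internal modes available")
    return report
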