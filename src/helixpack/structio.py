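"""Structure and trajectory I/O.

Molecular structures are lightweight coordinate containers (one entry per
atom: name, residue name, residue index, chain id, position in Å) read from
and written to PDB via Biopython's strict parser; trajectory snapshots are
carried as stacked coordinate frames sharing one atom roster, read either
from multi-model PDB or from XYZ.

Composite structures (e.g. an ectodomain crystal structure joined to an
NMR transmembrane-cytoplasmic fragment) are assembled with
:func:`join_chains`, which records each covalent link so the elastic
network can bridge the junction regardless of its spatial distance.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .units import ang_to_nm, nm_to_ang  # noqa: F401  (re-exported converters)

__all__ = [
    "MolecularStructure",
    "TrajectoryFrames",
    "StructureError",
    "ParseError",
    "read_structure",
    "read_frames",
    "write_structure",
    "write_frames",
    "read_xyz_frames",
    "write_xyz_frames",
    "select_atoms",
    "join_chains",
]

# Rough atomic masses (Da) keyed by element symbol, for mass-weighted COMs
# when no explicit masses are supplied.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06,
}


class StructureError(ValueError):
    """Raised for invalid structures or failed lookups."""


class ParseError(StructureError):
    """Raised when an input file cannot be parsed; message names the line."""


@dataclass
class MolecularStructure:
    """Atoms with chain/residue identity and 3-D coordinates in Å.

    Invariants: coordinates finite, (chain, residue index, atom name)
    unique, residue indices non-decreasing within each chain.  ``links``
    holds covalent junctions recorded by :func:`join_chains` as pairs of
    (chain_id, residue_index).
    """

    names: list[str]
    resnames: list[str]
    resids: np.ndarray
    chains: list[str]
    coords: np.ndarray
    masses: np.ndarray | None = None
    links: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def validate(self) -> None:
        n = self.n_atoms
        if not (len(self.names) == len(self.resnames) == len(self.resids)
                == len(self.chains) == n):
            raise StructureError("atom attribute lists have mismatched lengths")
        if n and not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        keys = list(zip(self.chains, self.resids.tolist(), self.names))
        if len(set(keys)) != n:
            raise StructureError("duplicate (chain, residue, atom) identity")
        last: dict[str, int] = {}
        for ch, ri in zip(self.chains, self.resids.tolist()):
            if ch in last and ri < last[ch]:
                raise StructureError(
                    f"residue indices decrease within chain {ch!r} at residue {ri}")
            last[ch] = ri

    def atom_masses(self) -> np.ndarray:
        """Explicit masses if set, else element masses guessed from names."""
        if self.masses is not None:
            return self.masses
        out = np.empty(self.n_atoms)
        for i, nm in enumerate(self.names):
            el = nm.strip()[:1].upper()
            out[i] = _ELEMENT_MASSES.get(el, 12.011)
        return out

    def subset(self, indices: np.ndarray) -> "MolecularStructure":
        idx = np.asarray(indices, dtype=int)
        return MolecularStructure(
            names=[self.names[i] for i in idx],
            resnames=[self.resnames[i] for i in idx],
            resids=self.resids[idx],
            chains=[self.chains[i] for i in idx],
            coords=self.coords[idx],
            masses=None if self.masses is None else self.masses[idx],
        )

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue index) pairs."""
        seen: list[tuple[str, int]] = []
        prev = None
        for ch, ri in zip(self.chains, self.resids.tolist()):
            key = (ch, ri)
            if key != prev:
                if key not in seen:
                    seen.append(key)
                prev = key
        return seen


@dataclass
class TrajectoryFrames:
    """Stacked coordinate frames (Å) over one atom roster, with times in ps."""

    coords: np.ndarray          # (n_frames, n_atoms, 3)
    times: np.ndarray           # ps, strictly increasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("frame array must have shape (F, N, 3)")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.coords.shape[0]:
            raise StructureError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# PDB reading/writing (Biopython strict parser underneath)
# ---------------------------------------------------------------------------

def _as_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if source.strip() and "\n" not in source and Path(source).is_file():
        return Path(source).read_text()
    return source


def _parse_models(text: str):
    if not text.strip():
        raise ParseError("empty input: no ATOM records found")
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        bio = parser.get_structure("s", io.StringIO(text))
    except PDBConstructionException as exc:
        raise ParseError(str(exc)) from exc
    models = []
    for model in bio:
        names, resnames, resids, chains, xyz = [], [], [], [], []
        for chain in model:
            for res in chain:
                het, ri, icode = res.id
                if icode != " ":
                    raise ParseError(
                        f"insertion code {icode!r} at residue {ri} not supported")
                for atom in res:
                    if atom.is_disordered():
                        # keep the first altloc by identifier
                        alt = sorted(atom.disordered_get_id_list())[0]
                        atom = atom.disordered_get(alt)
                    names.append(atom.get_name())
                    resnames.append(res.get_resname())
                    resids.append(ri)
                    chains.append(chain.id)
                    xyz.append(atom.get_coord())
        if not names:
            continue
        models.append(MolecularStructure(
            names=names, resnames=resnames, resids=np.array(resids),
            chains=chains, coords=np.array(xyz, dtype=float)))
    if not models:
        raise ParseError("empty input: no ATOM records found")
    return models


def read_structure(source: str | Path) -> MolecularStructure:
    """Read a PDB (text or path); multi-model files yield the first model."""
    return _parse_models(_as_text(source))[0]


def read_frames(source: str | Path, dt_ps: float = 1.0,
                ) -> tuple[MolecularStructure, TrajectoryFrames]:
    """Read a multi-model PDB as a trajectory.

    PDB carries no time axis, so frame times default to ``index * dt_ps``
    (snapshots in this workflow are written every 1 or 10 ps).
    """
    models = _parse_models(_as_text(source))
    n0 = models[0].n_atoms
    if any(m.n_atoms != n0 for m in models):
        raise ParseError("models have differing atom counts")
    coords = np.stack([m.coords for m in models])
    times = np.arange(len(models)) * dt_ps
    return models[0], TrajectoryFrames(coords=coords, times=times)


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resid: int, pos: np.ndarray) -> str:
    nm = name if len(name) >= 4 else f" {name:<3s}"
    el = name.strip()[:1].upper()
    return (f"ATOM  {serial % 100000:5d} {nm:<4s}{resname:>4s} {chain:1s}"
            f"{resid:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"  1.00  0.00          {el:>2s}")


def _structure_lines(s: MolecularStructure) -> list[str]:
    if s.n_atoms and (s.resids.max() > 9999 or s.resids.min() < -999):
        raise StructureError("residue index outside the PDB 4-digit field")
    lines = []
    for i in range(s.n_atoms):
        lines.append(_pdb_atom_line(i + 1, s.names[i], s.resnames[i],
                                    s.chains[i], int(s.resids[i]), s.coords[i]))
    return lines


def write_structure(s: MolecularStructure, path: str | Path | None = None) -> str:
    """Serialize to PDB text (ATOM records, 3-decimal coordinates)."""
    text = "\n".join(_structure_lines(s) + ["END", ""])
    if path is not None:
        Path(path).write_text(text)
    return text


def write_frames(s: MolecularStructure, frames: TrajectoryFrames,
                 path: str | Path | None = None) -> str:
    """Serialize a trajectory as a multi-model PDB."""
    if frames.n_atoms != s.n_atoms:
        raise StructureError("frame atom count does not match roster")
    lines: list[str] = []
    for f in range(frames.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        tmp = MolecularStructure(
            names=s.names, resnames=s.resnames, resids=s.resids,
            chains=s.chains, coords=frames.coords[f])
        lines.extend(_structure_lines(tmp))
        lines.append("ENDMDL")
    lines += ["END", ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# XYZ trajectory dialect (atom count / comment-with-time / name x y z, in Å)
# ---------------------------------------------------------------------------

def write_xyz_frames(s: MolecularStructure, frames: TrajectoryFrames,
                     path: str | Path | None = None) -> str:
    lines: list[str] = []
    for f in range(frames.n_frames):
        lines.append(str(s.n_atoms))
        lines.append(f"t= {frames.times[f]:.6f} ps")
        for i in range(s.n_atoms):
            x, y, z = frames.coords[f, i]
            lines.append(f"{s.names[i]} {x:.6f} {y:.6f} {z:.6f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_xyz_frames(source: str | Path, dt_ps: float = 1.0,
                    ) -> tuple[list[str], TrajectoryFrames]:
    """Read an XYZ trajectory; returns (atom names, frames).

    Frame times come from a ``t= <value> ps`` comment when present, else
    ``index * dt_ps``.
    """
    text = _as_text(source)
    raw = text.splitlines()
    frames, times, names = [], [], None
    i, fidx = 0, 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n = int(raw[i].strip())
        except ValueError as exc:
            raise ParseError(f"expected atom count at line {i + 1}") from exc
        comment = raw[i + 1] if i + 1 < len(raw) else ""
        t = fidx * dt_ps
        toks = comment.split()
        if len(toks) >= 2 and toks[0] == "t=":
            t = float(toks[1])
        block = raw[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"truncated frame starting at line {i + 1}")
        fnames, xyz = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"malformed XYZ record at line {i + 3 + j}")
            fnames.append(parts[0])
            try:
                xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise ParseError(
                    f"malformed coordinate at line {i + 3 + j}") from exc
        if names is None:
            names = fnames
        elif fnames != names:
            raise ParseError("atom roster changes between XYZ frames")
        frames.append(np.array(xyz))
        times.append(t)
        i += 2 + n
        fidx += 1
    if not frames:
        raise ParseError("empty input: no XYZ frames found")
    return names, TrajectoryFrames(coords=np.stack(frames), times=np.array(times))


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def _parse_resid_range(tok: str) -> tuple[int, int]:
    for sep in (":", "-"):
        if sep in tok and not tok.lstrip("-").isdigit():
            a, b = tok.split(sep, 1)
            return int(a), int(b)
    v = int(tok)
    return v, v


def select_atoms(s: MolecularStructure, expr: str | None = None, *,
                 name: str | None = None, chain: str | None = None,
                 resid: tuple[int, int] | int | None = None,
                 resname: str | None = None) -> np.ndarray:
    """Indices of atoms matching a filter, in stable (input) order.

    Either pass keyword filters, or an expression in the mini-language
    ``"<clause> and <clause> ..."`` with clauses ``name X``, ``chain X``,
    ``resname X``, ``resid N`` and ``resid A:B`` (inclusive range).
    Empty selections are allowed.
    """
    if expr is not None:
        for clause in expr.split(" and "):
            toks = clause.split()
            if len(toks) != 2:
                raise ValueError(f"cannot parse selection clause {clause!r}")
            key, val = toks
            if key == "name":
                name = val
            elif key == "chain":
                chain = val
            elif key == "resname":
                resname = val
            elif key == "resid":
                resid = _parse_resid_range(val)
            else:
                raise ValueError(f"unknown selection keyword {key!r}")
    mask = np.ones(s.n_atoms, dtype=bool)
    if name is not None:
        mask &= np.array([n == name for n in s.names])
    if chain is not None:
        mask &= np.array([c == chain for c in s.chains])
    if resname is not None:
        mask &= np.array([r == resname for r in s.resnames])
    if resid is not None:
        lo, hi = (resid, resid) if isinstance(resid, int) else resid
        mask &= (s.resids >= lo) & (s.resids <= hi)
    return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# Chain joining
# ---------------------------------------------------------------------------

def join_chains(a: MolecularStructure, b: MolecularStructure,
                links: list[tuple[str, int, str, int]] | None = None,
                rename_b: dict[str, str] | None = None) -> MolecularStructure:
    """Merge two structures, recording covalent links across the junction.

    ``links`` lists (chain_in_a, resid_in_a, chain_in_b, resid_in_b); each
    named residue must exist.  The recorded link metadata makes the elastic
    network bridge the junction with a spring even when the linked residues
    sit beyond the distance cutoff.  ``rename_b`` remaps chain ids of ``b``
    before merging to keep chain ids disjoint.
    """
    links = links or []
    b_chains = [rename_b.get(c, c) if rename_b else c for c in b.chains]

    def _check(st: MolecularStructure, chs: list[str], ch: str, ri: int, label: str):
        for c, r in zip(chs, st.resids.tolist()):
            if c == ch and r == ri:
                return
        raise StructureError(f"link residue ({ch!r}, {ri}) not found in {label}")

    merged = MolecularStructure(
        names=a.names + b.names,
        resnames=a.resnames + b.resnames,
        resids=np.concatenate([a.resids, b.resids]) if a.n_atoms or b.n_atoms
        else np.array([], dtype=int),
        chains=a.chains + b_chains,
        coords=np.vstack([a.coords, b.coords]) if a.n_atoms or b.n_atoms
        else np.zeros((0, 3)),
        masses=None if (a.masses is None or b.masses is None)
        else np.concatenate([a.masses, b.masses]),
    )
    merged.links = list(a.links) + list(b.links)
    for ca, ra, cb, rb in links:
        cb = rename_b.get(cb, cb) if rename_b else cb
        _check(a, a.chains, ca, ra, "first structure")
        _check(b, b_chains, cb, rb, "second structure")
        merged.links.append(((ca, ra), (cb, rb)))
    return merged
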