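"""Coarse-grained bead structures: PDB/GRO I/O and structural diagnostics.

All coordinates are stored in nanometres. PDB files (Angstrom) are converted
on read and write; GRO files are native nm. Bead and residue indices are
1-based at every interface, matching topology-file convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import EmptyInputError, EnmixError, ParameterError, ParseError, ValidationError

DEFAULT_BACKBONE_NAMES = frozenset({"BB"})

_PDB_SCALE = 0.1  # Angstrom -> nm


@dataclass(frozen=True)
class Bead:
    """One coarse-grained interaction site."""

    index: int
    name: str
    residue_index: int
    residue_name: str
    position: tuple[float, float, float]

    def __post_init__(self):
        if self.index < 1:
            raise ValidationError(f"bead index must be >= 1, got {self.index}")
        if not all(np.isfinite(self.position)):
            raise ValidationError(f"bead {self.index} has non-finite position")


@dataclass
class BeadStructure:
    """Ordered collection of beads for one conformational state."""

    beads: list[Bead]
    title: str = ""
    #: original-index map populated by :func:`select_backbone`
    index_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.beads:
            raise EmptyInputError("structure contains no beads")
        idx = [b.index for b in self.beads]
        if any(j <= i for i, j in zip(idx, idx[1:])):
            raise ValidationError("bead indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in nm, in bead order."""
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.beads]

    @property
    def residue_indices(self) -> list[int]:
        return [b.residue_index for b in self.beads]

    def bead_by_index(self, index: int) -> Bead:
        for b in self.beads:
            if b.index == index:
                return b
        raise IndexError(f"no bead with index {index}")

    def with_positions(self, positions: np.ndarray) -> "BeadStructure":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.beads), 3):
            raise ParameterError(
                f"positions shape {positions.shape} does not match bead count {len(self.beads)}"
            )
        beads = [
            Bead(b.index, b.name, b.residue_index, b.residue_name, tuple(p))
            for b, p in zip(self.beads, positions)
        ]
        return BeadStructure(beads, title=self.title)


@dataclass
class Trajectory:
    """Sequence of frames over a fixed bead set; times in ps, coordinates nm."""

    frames: list[tuple[float, np.ndarray]]
    reference: BeadStructure

    def __post_init__(self):
        n = len(self.reference)
        times = []
        for i, (t, pos) in enumerate(self.frames):
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (n, 3):
                raise ValidationError(f"frame {i} has {pos.shape[0]} beads, expected {n}")
            self.frames[i] = (float(t), pos)
            times.append(t)
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("frame times must be nondecreasing")

    def __len__(self) -> int:
        return len(self.frames)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "gro"):
            raise ParameterError(f"unsupported structure format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "gro"):
        return suffix
    raise ParameterError(f"cannot infer format from {path!r}; pass format='pdb' or 'gro'")


def read_structure(path, format: str | None = None) -> BeadStructure:
    """Read a coarse-grained structure from a PDB or GRO file.

    PDB coordinates are converted from Angstrom to nm. Only ATOM records of
    the first model are read; HETATM records (waters, ligands) are skipped.
    """
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path)
    return _read_gro(path)


def _read_pdb(path) -> BeadStructure:
    beads: list[Bead] = []
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "TITLE" and not title:
                title = line[10:].strip()
            elif rec == "ENDMDL":
                break  # first model only
            elif rec == "ATOM":
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    resseq = int(line[22:26])
                    x = float(line[30:38]) * _PDB_SCALE
                    y = float(line[38:46]) * _PDB_SCALE
                    z = float(line[46:54]) * _PDB_SCALE
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"malformed ATOM record: {exc}", path, lineno) from None
                beads.append(Bead(serial, name, resseq, resname, (x, y, z)))
    if not beads:
        raise EmptyInputError(f"{path}: no ATOM records found")
    return BeadStructure(beads, title=title)


def _read_gro(path) -> BeadStructure:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 2:
        raise ParseError("GRO file must have a title and atom-count line", path, 1)
    title = lines[0].strip()
    try:
        n_atoms = int(lines[1])
    except ValueError:
        raise ParseError("second line must be the atom count", path, 2) from None
    if n_atoms == 0:
        raise EmptyInputError(f"{path}: zero atoms declared")
    if len(lines) < 2 + n_atoms:
        raise ParseError(f"expected {n_atoms} atom lines, file truncated", path, len(lines))
    beads: list[Bead] = []
    for i in range(n_atoms):
        lineno = 3 + i
        line = lines[2 + i]
        try:
            resseq = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed GRO atom line: {exc}", path, lineno) from None
        beads.append(Bead(serial, name, resseq, resname, (x, y, z)))
    return BeadStructure(beads, title=title)


def write_structure(s: BeadStructure, path, format: str | None = None) -> None:
    """Write a structure as PDB (nm -> Angstrom) or GRO (nm)."""
    fmt = _infer_format(path, format)
    with open(path, "w") as fh:
        if fmt == "pdb":
            if s.title:
                fh.write(f"TITLE     {s.title}\n")
            for b in s.beads:
                x, y, z = (c / _PDB_SCALE for c in b.position)
                fh.write(
                    f"ATOM  {b.index:5d} {b.name:<4s}{b.residue_name:<4s} "
                    f"{b.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}\n"
                )
            fh.write("END\n")
        else:
            fh.write(f"{s.title or 'enmix structure'}\n")
            fh.write(f"{len(s):5d}\n")
            for b in s.beads:
                x, y, z = b.position
                fh.write(
                    f"{b.residue_index:5d}{b.residue_name:<5s}{b.name:>5s}"
                    f"{b.index:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{10.0:10.5f}{10.0:10.5f}{10.0:10.5f}\n")


def select_backbone(
    s: BeadStructure, backbone_names: Iterable[str] = DEFAULT_BACKBONE_NAMES
) -> BeadStructure:
    """Keep only beads whose name is in ``backbone_names``.

    Original bead indices are retained on the beads themselves and recorded
    in ``index_map`` (original index -> 1-based rank in the selection).
    An empty selection is not an error: a ``UserWarning`` is emitted and
    ``None`` is returned, since a zero-bead structure is not constructible.
    """
    names = set(backbone_names)
    kept = [b for b in s.beads if b.name in names]
    if not kept:
        import warnings

        warnings.warn("backbone selection is empty", UserWarning, stacklevel=2)
        return None
    out = BeadStructure(list(kept), title=s.title)
    out.index_map = {b.index: rank for rank, b in enumerate(kept, start=1)}
    return out


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = True) -> float:
    """Root-mean-square deviation between two coordinate sets, nm.

    With ``fit=True`` the optimal proper rigid-body superposition
    (translation + rotation, reflections excluded) of ``b`` onto ``a`` is
    applied first.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ParameterError(f"coordinate shapes differ or are not (N,3): {a.shape} vs {b.shape}")
    if fit:
        if a.shape[0] < 3:
            raise ParameterError("fit=True requires at least 3 beads")
        a_c = a - a.mean(axis=0)
        b_c = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(a_c, b_c)  # proper rotation (det +1)
        b_c = rot.apply(b_c)
        diff = a_c - b_c
    else:
        diff = a - b
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def end_to_end(t: Trajectory, first_bead: int, last_bead: int) -> np.ndarray:
    """Per-frame distance (nm) between two beads given by their 1-based indices."""
    index_of = {b.index: row for row, b in enumerate(t.reference.beads)}
    try:
        i = index_of[first_bead]
        j = index_of[last_bead]
    except KeyError as exc:
        raise IndexError(f"no bead with index {exc.args[0]}") from None
    return np.array([float(np.linalg.norm(pos[i] - pos[j])) for _, pos in t.frames])


def read_trajectory(path, reference: BeadStructure, format: str | None = None) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a plain TSV.

    TSV layout: one frame per line, ``time_ps`` followed by ``x y z`` for
    each bead in reference order.
    """
    suffix = (format or Path(path).suffix.lstrip(".")).lower()
    if suffix == "pdb":
        return _read_pdb_trajectory(path, reference)
    return _read_tsv_trajectory(path, reference)


def _read_pdb_trajectory(path, reference: BeadStructure) -> Trajectory:
    frames: list[tuple[float, np.ndarray]] = []
    current: list[list[float]] = []
    time = 0.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ATOM":
                try:
                    current.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except ValueError as exc:
                    raise ParseError(f"malformed ATOM record: {exc}", path, lineno) from None
            elif rec == "ENDMDL":
                frames.append((time, np.asarray(current) * _PDB_SCALE))
                current = []
                time += 1.0
    if current:
        frames.append((time, np.asarray(current) * _PDB_SCALE))
    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    return Trajectory(frames, reference)


def _read_tsv_trajectory(path, reference: BeadStructure) -> Trajectory:
    frames: list[tuple[float, np.ndarray]] = []
    n = len(reference)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                continue
            fields = line.split()
            if len(fields) != 1 + 3 * n:
                raise ParseError(
                    f"expected {1 + 3 * n} columns, found {len(fields)}", path, lineno
                )
            vals = [float(v) for v in fields]
            frames.append((vals[0], np.asarray(vals[1:], dtype=float).reshape(n, 3)))
    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    return Trajectory(frames, reference)
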