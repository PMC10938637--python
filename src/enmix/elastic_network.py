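"""State-specific elastic networks of harmonic distance restraints.

A network is built from backbone bead coordinates: every bead pair closer
than the cutoff (default 0.9 nm) and at least ``min_seq_sep`` residues apart
receives a harmonic restraint whose minimum is the measured distance and
whose force constant is uniform (default 500 kJ/mol/nm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .cg_structures import BeadStructure
from .constants import DEFAULT_CUTOFF, DEFAULT_FORCE_CONSTANT
from .errors import ParameterError, ValidationError


@dataclass(frozen=True)
class HarmonicTerm:
    """One harmonic distance restraint between beads ``i`` and ``j`` (1-based)."""

    i: int
    j: int
    b0: float  # nm
    k: float  # kJ/mol/nm^2

    def __post_init__(self):
        if self.i >= self.j:
            raise ValidationError(f"term indices must satisfy i < j, got ({self.i}, {self.j})")
        if self.b0 <= 0:
            raise ValidationError(f"b0 must be positive, got {self.b0}")
        if self.k < 0:
            raise ValidationError(f"force constant must be >= 0, got {self.k}")


@dataclass
class ElasticNetwork:
    """The set of restraints defining one conformational state."""

    terms: list[HarmonicTerm]
    cutoff: float
    default_k: float
    source_label: str = ""
    #: bead index -> residue index, retained for residue-based stripping
    residue_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        pairs = [(t.i, t.j) for t in self.terms]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (i, j) pair in elastic network")
        for t in self.terms:
            if t.b0 > self.cutoff:
                raise ValidationError(
                    f"term ({t.i},{t.j}) has b0={t.b0} beyond cutoff {self.cutoff}"
                )

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return {(t.i, t.j) for t in self.terms}


def build_network(
    s: BeadStructure,
    cutoff: float = DEFAULT_CUTOFF,
    k: float = DEFAULT_FORCE_CONSTANT,
    min_seq_sep: int = 2,
    exclude_pairs: Iterable[tuple[int, int]] = (),
    source_label: str = "",
) -> ElasticNetwork:
    """Construct the elastic network for a structure.

    Includes exactly the bead pairs with Euclidean distance <= ``cutoff``
    (ties included), residue separation >= ``min_seq_sep``, and not listed
    in ``exclude_pairs`` (order-insensitive). b0 is the measured distance.
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if k < 0:
        raise ParameterError(f"force constant must be >= 0, got {k}")
    excluded = {tuple(sorted(p)) for p in exclude_pairs}
    pos = s.positions
    indices = [b.index for b in s.beads]
    residues = [b.residue_index for b in s.beads]

    tree = cKDTree(pos)
    terms: list[HarmonicTerm] = []
    for a, b in sorted(tree.query_pairs(r=cutoff)):
        i, j = indices[a], indices[b]
        if i > j:
            i, j = j, i
        if abs(residues[a] - residues[b]) < min_seq_sep:
            continue
        if (i, j) in excluded:
            continue
        d = float(np.linalg.norm(pos[a] - pos[b]))
        terms.append(HarmonicTerm(i, j, d, k))
    terms.sort(key=lambda t: (t.i, t.j))
    return ElasticNetwork(
        terms,
        cutoff=cutoff,
        default_k=k,
        source_label=source_label,
        residue_of=dict(zip(indices, residues)),
    )


def strip_network(net: ElasticNetwork, residues: Iterable[int]) -> ElasticNetwork:
    """Remove every restraint touching any of the given residues.

    ``residues`` covering all residues empties the network, which is how an
    unfolded reference state is modelled. An empty set is the identity.
    """
    doomed = set(residues)
    if not doomed:
        kept = list(net.terms)
    else:
        if not net.residue_of:
            raise ParameterError(
                "network lacks a bead-to-residue map; rebuild it with build_network"
            )
        kept = [
            t
            for t in net.terms
            if net.residue_of[t.i] not in doomed and net.residue_of[t.j] not in doomed
        ]
    return ElasticNetwork(
        kept,
        cutoff=net.cutoff,
        default_k=net.default_k,
        source_label=net.source_label,
        residue_of=dict(net.residue_of),
    )


def rubber_band_lines(net: ElasticNetwork, funct: int = 6) -> list[str]:
    """Render the network as GROMACS-dialect rubber-band [bonds] lines."""
    lines = ["; Rubber band"]
    for t in net.terms:
        lines.append(f"{t.i:5d} {t.j:5d} {funct:4d} {t.b0:10.5f} {t.k:10.1f}")
    return lines
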