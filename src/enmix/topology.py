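"""GROMACS-dialect topology subset: parse, validate, transform, write.

Only the directives the mixing method touches are modelled —
``[moleculetype]``, ``[atoms]``, ``[bonds]`` (including the rubber-band
block), ``[angles]`` and ``[constraints]``. Everything else is preserved
verbatim for round-trip writing.

Supported bonded function types: bonds 1 and 6 (harmonic), angles 2
(cosine-harmonic) and 10 (restricted bending), constraints 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .errors import ParseError, UnsupportedFunctError, ValidationError

#: comment substring that marks the start of the rubber-band block in [bonds]
RUBBER_BAND_MARKER = "Rubber band"

_RECOGNIZED = {"moleculetype", "atoms", "bonds", "angles", "constraints"}
_ALLOWED_FUNCTS = {"bonds": {1, 6}, "rubber_band": {1, 6}, "angles": {2, 10}, "constraints": {1}}
_PARAM_COUNTS = {"bonds": (2, 4), "rubber_band": (2, 4), "angles": (2, 4), "constraints": (1, 2)}
_N_INDICES = {"bonds": 2, "rubber_band": 2, "angles": 3, "constraints": 2}


@dataclass(frozen=True)
class AtomRecord:
    index: int
    type: str
    residue_index: int
    residue_name: str
    bead_name: str
    charge: float


@dataclass(frozen=True)
class BondedTerm:
    """A bond, rubber band, angle or constraint line.

    ``params`` holds (b0/theta0, k) for an endpoint-A-only term or
    (b0_A, k_A, b0_B, k_B) for a dual-endpoint term; constraints carry a
    single distance.
    """

    atom_indices: tuple[int, ...]
    funct: int
    params: tuple[float, ...]
    section_tag: str

    def __post_init__(self):
        n = _N_INDICES.get(self.section_tag)
        if n is None:
            raise ValidationError(f"unknown section tag {self.section_tag!r}")
        if len(self.atom_indices) != n:
            raise ValidationError(
                f"{self.section_tag} term needs {n} atom indices, got {len(self.atom_indices)}"
            )
        if self.funct not in _ALLOWED_FUNCTS[self.section_tag]:
            raise UnsupportedFunctError(
                f"funct {self.funct} not supported in [{self.section_tag}]"
            )
        if len(self.params) not in _PARAM_COUNTS[self.section_tag]:
            raise ValidationError(
                f"{self.section_tag} term has {len(self.params)} parameters"
            )


@dataclass
class Topology:
    """One molecule's topology: atoms, recognized bonded terms, passthrough."""

    molecule_name: str = ""
    nrexcl: int = 1
    atoms: list[AtomRecord] = field(default_factory=list)
    bonded: list[BondedTerm] = field(default_factory=list)
    raw_passthrough: list[str] = field(default_factory=list)

    def terms(self, section_tag: str) -> list[BondedTerm]:
        return [t for t in self.bonded if t.section_tag == section_tag]

    def validate(self, path=None) -> None:
        n = len(self.atoms)
        for rank, a in enumerate(self.atoms, start=1):
            if a.index != rank:
                raise ValidationError(
                    f"atom indices must be contiguous from 1; atom {rank} has index {a.index}"
                )
        for t in self.bonded:
            for idx in t.atom_indices:
                if not 1 <= idx <= n:
                    raise ValidationError(
                        f"[{t.section_tag}] term {t.atom_indices} references atom {idx} "
                        f"but topology has {n} atoms"
                    )


def _strip_comment(line: str) -> str:
    return line.split(";", 1)[0]


_DIRECTIVE_RE = re.compile(r"^\s*\[\s*(\S+)\s*\]\s*$")


def parse_topology(path) -> Topology:
    """Parse a .itp/.top file into a :class:`Topology`.

    Rubber-band lines inside ``[bonds]`` are recognized by a comment line
    containing :data:`RUBBER_BAND_MARKER` and tagged ``rubber_band``.
    Unrecognized directives are captured verbatim into ``raw_passthrough``.
    """
    top = Topology()
    section = None
    in_rubber = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            m = _DIRECTIVE_RE.match(_strip_comment(line))
            if m:
                name = m.group(1).lower()
                if name in _RECOGNIZED:
                    section = name
                    in_rubber = False
                else:
                    section = "__passthrough__"
                    top.raw_passthrough.append(line)
                continue
            if section == "__passthrough__":
                if line.strip():
                    top.raw_passthrough.append(line)
                continue
            stripped = line.strip()
            if stripped.startswith(";"):
                if section == "bonds" and RUBBER_BAND_MARKER.lower() in stripped.lower():
                    in_rubber = True
                continue
            content = _strip_comment(line).strip()
            if not content:
                continue
            if section is None:
                # top-level free lines (#include etc.) pass through verbatim
                top.raw_passthrough.append(line)
                continue
            fields = content.split()
            try:
                if section == "moleculetype":
                    top.molecule_name = fields[0]
                    top.nrexcl = int(fields[1]) if len(fields) > 1 else 1
                elif section == "atoms":
                    top.atoms.append(
                        AtomRecord(
                            index=int(fields[0]),
                            type=fields[1],
                            residue_index=int(fields[2]),
                            residue_name=fields[3],
                            bead_name=fields[4],
                            charge=float(fields[6]) if len(fields) > 6 else 0.0,
                        )
                    )
                else:
                    tag = "rubber_band" if (section == "bonds" and in_rubber) else section
                    n_idx = _N_INDICES[tag]
                    indices = tuple(int(f) for f in fields[:n_idx])
                    funct = int(fields[n_idx])
                    params = tuple(float(f) for f in fields[n_idx + 1 :])
                    top.bonded.append(BondedTerm(indices, funct, params, tag))
            except UnsupportedFunctError as exc:
                raise UnsupportedFunctError(f"{path}:{lineno}: {exc}") from None
            except (ValueError, IndexError, ValidationError) as exc:
                raise ParseError(f"malformed [{section}] line: {exc}", path, lineno) from None
    # normalize to writer section order (stable within a section) so that
    # parse(write(T)) == T holds regardless of input section order
    rank = {"bonds": 0, "rubber_band": 1, "angles": 2, "constraints": 3}
    top.bonded.sort(key=lambda term: rank[term.section_tag])
    try:
        top.validate(path)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None
    return top


def convert_restricted_angles(t: Topology) -> Topology:
    """Rewrite every funct-10 (restricted bending) angle as funct 2.

    Parameters (theta0, k) are kept unchanged; idempotent.
    """
    bonded = [
        replace(term, funct=2)
        if term.section_tag == "angles" and term.funct == 10
        else term
        for term in t.bonded
    ]
    return Topology(
        molecule_name=t.molecule_name,
        nrexcl=t.nrexcl,
        atoms=list(t.atoms),
        bonded=bonded,
        raw_passthrough=list(t.raw_passthrough),
    )


def format_bonded_line(term: BondedTerm) -> str:
    idx = "".join(f"{i:6d}" for i in term.atom_indices)
    cols = []
    for pos, p in enumerate(term.params):
        # alternating distance/angle then force-constant columns
        cols.append(f"{p:12.5f}" if pos % 2 == 0 else f"{p:12.1f}")
    return f"{idx}{term.funct:4d}" + "".join(cols)


def write_topology(t: Topology, path) -> None:
    """Emit a topology file that re-parses to an equal :class:`Topology`."""
    t.validate()
    with open(path, "w") as fh:
        fh.write(render_topology(t))


def render_topology(t: Topology) -> str:
    out: list[str] = []
    if t.molecule_name:
        out += ["[ moleculetype ]", f"{t.molecule_name}  {t.nrexcl}", ""]
    out.append("[ atoms ]")
    for a in t.atoms:
        out.append(
            f"{a.index:6d} {a.type:>5s} {a.residue_index:5d} {a.residue_name:>5s} "
            f"{a.bead_name:>5s} {a.index:5d} {a.charge:9.4f}"
        )
    out.append("")
    plain_bonds = t.terms("bonds")
    rubber = t.terms("rubber_band")
    if plain_bonds or rubber:
        out.append("[ bonds ]")
        out += [format_bonded_line(b) for b in plain_bonds]
        if rubber:
            out.append(f"; {RUBBER_BAND_MARKER}")
            out += [format_bonded_line(b) for b in rubber]
        out.append("")
    angles = t.terms("angles")
    if angles:
        out.append("[ angles ]")
        out += [format_bonded_line(b) for b in angles]
        out.append("")
    constraints = t.terms("constraints")
    if constraints:
        out.append("[ constraints ]")
        out += [format_bonded_line(b) for b in constraints]
        out.append("")
    out += t.raw_passthrough
    return "\n".join(out) + "\n"
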