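"""Topology and trajectory model plus PDB reading/writing.

Parses single-model PDB topologies and multi-model (MODEL/ENDMDL) PDB
trajectories into lightweight containers, assigns ligand/protein roles, and
annotates chemical groups: arginine guanidinium (NE/NH1/NH2 represented by
CZ), carboxylates (two oxygens represented by the carboxyl carbon), and
aromatic rings (standard side-chain templates plus configured ligand rings).

Coordinates are Cartesian angstrom throughout; no periodic-boundary handling
(inputs are assumed binding-site-centred, as post-processed trajectories
are).  Residue numbers from the file are preserved verbatim so that
crystal-structure labels like "ARG929" round-trip.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import biotite.structure.io.pdb as _pdb

__all__ = [
    "AtomRecord",
    "GroupAnnotation",
    "RingAnnotation",
    "Topology",
    "Trajectory",
    "StructureError",
    "read_topology",
    "read_trajectory",
    "write_topology",
    "write_trajectory",
    "annotate_groups",
]

#: Residue names treated as solvent/ions and never as the ligand.
SOLVENT_RESNAMES = frozenset({"HOH", "WAT", "SOL", "NA", "CL", "K", "MG", "ZN", "CA"})

#: Aromatic side-chain ring atom names per standard residue.
RESIDUE_RING_TEMPLATES = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
}

#: Side-chain carboxylates of standard residues: (oxygen names, carbon name).
RESIDUE_CARBOXYLATE_TEMPLATES = {
    "ASP": (("OD1", "OD2"), "CG"),
    "GLU": (("OE1", "OE2"), "CD"),
}


class StructureError(ValueError):
    """Raised for unparseable or inconsistent structure input."""


@dataclass(frozen=True)
class AtomRecord:
    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    is_ligand: bool

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def residue_label(self) -> str:
        """Crystal-structure style label, e.g. ``ARG929``."""
        return f"{self.residue_name}{self.residue_number}"


@dataclass(frozen=True)
class GroupAnnotation:
    """An equivalent-atom group with a single representative atom."""

    kind: str  # "carboxylate" | "guanidinium"
    member_indices: frozenset[int]
    representative_index: int
    residue_label: str
    is_ligand: bool


@dataclass(frozen=True)
class RingAnnotation:
    """An aromatic ring, quantified downstream by its centroid."""

    atom_indices: frozenset[int]
    residue_label: str
    is_ligand: bool


@dataclass
class Topology:
    atoms: list[AtomRecord]
    groups: list[GroupAnnotation] = field(default_factory=list)
    rings: list[RingAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_lig = sum(a.is_ligand for a in self.atoms)
        if n_lig == 0:
            raise StructureError("topology contains no ligand atoms")
        if n_lig == len(self.atoms):
            raise StructureError("topology contains no protein atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_indices(self, ligand: bool) -> np.ndarray:
        return np.array(
            [a.atom_index for a in self.atoms if a.is_ligand == ligand and a.is_heavy],
            dtype=int,
        )

    def group_of_atom(self, atom_index: int, kind: str) -> Optional[GroupAnnotation]:
        for g in self.groups:
            if g.kind == kind and atom_index in g.member_indices:
                return g
        return None


@dataclass
class Trajectory:
    """Per-frame coordinates (frames x atoms x 3, angstrom) of one replicate."""

    coordinates: np.ndarray
    replicate_id: str = ""
    frame_times_ns: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructureError(
                f"coordinates must be frames x atoms x 3, got shape {self.coordinates.shape}"
            )
        if self.n_frames < 1:
            raise StructureError("trajectory must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


def _element_from_name(atom_name: str) -> str:
    """PDB atom-name heuristic: two-letter element if both chars alphabetic
    at columns 13-14 and known (Cl, Br, ...), else first alphabetic char."""
    name = atom_name.strip()
    if not name:
        raise StructureError("empty atom name, cannot infer element")
    two = name[:2].capitalize()
    if two in ("Cl", "Br", "Na", "Mg", "Zn", "Fe", "Se"):
        return two
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise StructureError(f"cannot infer element from atom name {atom_name!r}")


def _model_atom_counts(pdb_text: str) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in pdb_text.splitlines():
        rec = line[:6]
        if rec.startswith("ENDMDL"):
            if in_model:
                counts.append(current)
            in_model = False
        elif rec.startswith("MODEL"):
            in_model, saw_model, current = True, True, 0
        elif rec.startswith("ATOM") or rec.startswith("HETATM"):
            if not saw_model:  # file without MODEL records: implicit model 1
                in_model, saw_model, current = True, True, 0
            current += 1
    if in_model:
        counts.append(current)
    return counts


def _parse_pdb(pdb_text: str):
    try:
        pdb_file = _pdb.PDBFile.read(io.StringIO(pdb_text))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise StructureError(f"PDB parse failure: {exc}") from exc
    return stack


def read_topology(
    pdb_text: str,
    ligand_resname: Optional[str] = None,
) -> Topology:
    """Parse a PDB topology from text.

    The ligand is identified by ``ligand_resname`` when given, else by
    HETATM records whose residue name is not a solvent/ion.  The element is
    taken from the element column when present, falling back to an
    atom-name heuristic.
    """
    counts = _model_atom_counts(pdb_text)
    if not counts or counts[0] == 0:
        raise StructureError("no ATOM/HETATM records found")
    stack = _parse_pdb(pdb_text)
    arr = stack[0]
    atoms: list[AtomRecord] = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        element = str(arr.element[i]).strip().capitalize()
        if not element:
            element = _element_from_name(name)
        resname = str(arr.res_name[i])
        if ligand_resname is not None:
            is_lig = resname == ligand_resname
        else:
            is_lig = bool(arr.hetero[i]) and resname not in SOLVENT_RESNAMES
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=name,
                element=element,
                residue_name=resname,
                residue_number=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                is_ligand=is_lig,
            )
        )
    return Topology(atoms=atoms)


def read_trajectory(
    pdb_text: str,
    topo: Topology,
    replicate_id: str = "",
) -> Trajectory:
    """Parse a multi-model PDB trajectory against a known topology.

    Every MODEL block must contain exactly the topology's atoms in order.
    """
    counts = _model_atom_counts(pdb_text)
    if not counts:
        raise StructureError("no ATOM/HETATM records found")
    for model_no, count in enumerate(counts, start=1):
        if count != topo.n_atoms:
            raise StructureError(
                f"model {model_no}: expected {topo.n_atoms} atoms, got {count}"
            )
    stack = _parse_pdb(pdb_text)
    return Trajectory(coordinates=np.asarray(stack.coord, dtype=float), replicate_id=replicate_id)


def _format_atom_line(atom: AtomRecord, xyz: Sequence[float], serial: int) -> str:
    record = "HETATM" if atom.is_ligand else "ATOM  "
    name = atom.atom_name
    # PDB convention: single-letter elements start at column 14
    name_field = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
    return (
        f"{record}{serial:>5d} {name_field} {atom.residue_name:<3s} "
        f"{atom.chain_id:1s}{atom.residue_number:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_topology(topo: Topology, coordinates: np.ndarray) -> str:
    """Write a single-model PDB (fixed columns, 3-decimal coordinates)."""
    lines = [
        _format_atom_line(a, coordinates[i], i + 1) for i, a in enumerate(topo.atoms)
    ]
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory(topo: Topology, traj: Trajectory) -> str:
    """Write a multi-model PDB trajectory."""
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        frame = traj.coordinates[f]
        lines.extend(
            _format_atom_line(a, frame[i], i + 1) for i, a in enumerate(topo.atoms)
        )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _residue_groups(topo: Topology):
    """Yield (residue key, {atom_name: index}) per residue in file order."""
    seen: dict[tuple, dict[str, int]] = {}
    order: list[tuple] = []
    for a in topo.atoms:
        key = (a.chain_id, a.residue_number, a.residue_name, a.is_ligand)
        if key not in seen:
            seen[key] = {}
            order.append(key)
        seen[key][a.atom_name] = a.atom_index
    for key in order:
        yield key, seen[key]


def annotate_groups(
    topo: Topology,
    ligand_carboxylates: Sequence[dict] = (),
    ligand_rings: Sequence[Sequence[str]] = (),
) -> Topology:
    """Attach guanidinium, carboxylate and aromatic-ring annotations.

    Protein residues follow standard templates: every ARG gains a
    guanidinium group {NE, NH1, NH2} represented by CZ (missing CZ ->
    warning, group skipped); ASP/GLU side chains and C-terminal O/OXT pairs
    gain carboxylate groups represented by the carboxyl carbon; PHE, TYR,
    HIS and TRP gain their side-chain rings.  Ligand carboxylates and rings
    are configured by atom-name sets, e.g.
    ``ligand_carboxylates=[{"oxygens": ["O1", "O2"], "carbon": "C1"}]`` and
    ``ligand_rings=[["C2", "C3", "C4", "C5", "C6", "C7"]]``; a configured
    ligand ring name absent from the topology is an error.

    Returns a new Topology sharing the same atoms.
    """
    groups: list[GroupAnnotation] = []
    rings: list[RingAnnotation] = []
    for (chain, resnum, resname, is_lig), by_name in _residue_groups(topo):
        label = f"{resname}{resnum}"
        if is_lig:
            continue
        if resname == "ARG":
            members = [by_name.get(n) for n in ("NE", "NH1", "NH2")]
            if "CZ" not in by_name or any(m is None for m in members):
                warnings.warn(
                    f"arginine {label} missing guanidinium atoms; group skipped",
                    stacklevel=2,
                )
            else:
                groups.append(
                    GroupAnnotation(
                        "guanidinium",
                        frozenset(members),  # type: ignore[arg-type]
                        by_name["CZ"],
                        label,
                        is_ligand=False,
                    )
                )
        if resname in RESIDUE_CARBOXYLATE_TEMPLATES:
            oxy_names, carbon = RESIDUE_CARBOXYLATE_TEMPLATES[resname]
            if all(n in by_name for n in oxy_names) and carbon in by_name:
                groups.append(
                    GroupAnnotation(
                        "carboxylate",
                        frozenset(by_name[n] for n in oxy_names),
                        by_name[carbon],
                        label,
                        is_ligand=False,
                    )
                )
        if all(n in by_name for n in ("O", "OXT", "C")):  # C-terminus
            groups.append(
                GroupAnnotation(
                    "carboxylate",
                    frozenset((by_name["O"], by_name["OXT"])),
                    by_name["C"],
                    label,
                    is_ligand=False,
                )
            )
        for template in RESIDUE_RING_TEMPLATES.get(resname, ()):
            if all(n in by_name for n in template):
                rings.append(
                    RingAnnotation(
                        frozenset(by_name[n] for n in template), label, is_ligand=False
                    )
                )

    lig_by_name = {a.atom_name: a.atom_index for a in topo.atoms if a.is_ligand}
    lig_label = next(a.residue_label for a in topo.atoms if a.is_ligand)
    for spec in ligand_carboxylates:
        oxygens, carbon = spec["oxygens"], spec["carbon"]
        missing = [n for n in (*oxygens, carbon) if n not in lig_by_name]
        if missing:
            raise StructureError(
                f"configured ligand carboxylate atoms {missing} not found in ligand"
            )
        groups.append(
            GroupAnnotation(
                "carboxylate",
                frozenset(lig_by_name[n] for n in oxygens),
                lig_by_name[carbon],
                lig_label,
                is_ligand=True,
            )
        )
    for ring_names in ligand_rings:
        missing = [n for n in ring_names if n not in lig_by_name]
        if missing:
            raise StructureError(f"configured ligand ring atoms {missing} not found in ligand")
        rings.append(
            RingAnnotation(
                frozenset(lig_by_name[n] for n in ring_names), lig_label, is_ligand=True
            )
        )
    return Topology(atoms=topo.atoms, groups=groups, rings=rings)
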