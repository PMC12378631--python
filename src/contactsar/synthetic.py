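"""Synthetic protein-ligand complexes with known ground truth.

Generates a schematic binding pocket (one arginine per salt-bridge
program, a tyrosine ring for pi-stacking, a static glutamate control), a
ligand carrying a carboxylate, an amide-nitrogen surrogate and a six-carbon
aromatic ring, and trajectories in which each programmed contact follows a
two-state (bound/unbound) Markov chain with a prescribed stationary
occupancy.  Potencies follow a linear occupancy -> pIC50 model with
Gaussian noise, so every downstream stage — enumeration, filtering,
collapsing, occupancy, PLS — can be validated against planted truth.

Geometry is schematic (groups on fixed axes), not physical: only
inter-group distances matter to the analysis.  In the bound state the
governing distance sits at ``d_on`` (plus clipped axial noise), in the
unbound state at ``d_off``; both are separated from the contact-type
cutoff by a validated margin so occupancy is exactly the fraction of bound
frames.  All randomness derives from the spec seed; identical specs give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chem import ic50_from_pic50
from .contacts import DEFAULT_OCCUPANCY_CUTOFFS
from .structure import (
    AtomRecord,
    Topology,
    Trajectory,
    annotate_groups,
    write_topology,
    write_trajectory,
)

__all__ = [
    "ContactProgram",
    "SyntheticSpec",
    "SarDataset",
    "default_spec",
    "paper_preset",
    "total_sampling_us_per_ligand",
    "build_topology",
    "simulate_trajectory",
    "markov_state_series",
    "generate_sar_dataset",
    "write_sar_dataset",
]

#: Axial placement noise: sd and hard clip, angstrom.
_AXIAL_SD, _AXIAL_CLIP = 0.1, 0.3
#: Hard clip on per-atom jitter, in units of jitter_sd.
_JITTER_CLIP_SIGMA = 4.0

_CUTOFF_BY_KIND = {
    "salt_bridge": DEFAULT_OCCUPANCY_CUTOFFS["salt_bridge"],
    "hbond": DEFAULT_OCCUPANCY_CUTOFFS["hbond"],
    "pi_stack": DEFAULT_OCCUPANCY_CUTOFFS["pi_stack"],
}


@dataclass(frozen=True)
class ContactProgram:
    """One programmed ligand-residue contact with per-ligand occupancy."""

    kind: str  # salt_bridge | hbond | pi_stack
    residue_label: str  # e.g. "ARG929" -> residue name + number
    target_occupancy: tuple  # one stationary P(bound) per ligand, in [0, 1]
    d_on: float  # bound-state governing distance, angstrom
    d_off: float  # unbound-state governing distance, angstrom
    beta_true: float = 0.0  # planted pIC50 change per unit occupancy

    @property
    def cutoff(self) -> float:
        return _CUTOFF_BY_KIND[self.kind]

    @property
    def residue_name(self) -> str:
        return self.residue_label[:3]

    @property
    def residue_number(self) -> int:
        return int(self.residue_label[3:])


@dataclass(frozen=True)
class SyntheticSpec:
    n_ligands: int = 8
    replicates_per_ligand: int = 3
    frames_per_replicate: int = 2000
    programs: tuple = ()
    intercept: float = 7.0  # pIC50 at zero occupancy everywhere
    noise_sd: float = 0.2  # pIC50 units
    switching_rate: float = 0.5  # total on+off rate per frame
    jitter_sd: float = 0.02  # per-atom positional jitter, angstrom
    replicate_length_ns: float = 500.0  # nominal simulated time metadata
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_ligand < 1:
            raise ValueError("need at least one replicate per ligand")
        # worst case: axial placement noise plus full 3-D jitter of both
        # endpoints of the governing distance
        margin = _AXIAL_CLIP + 2 * np.sqrt(3.0) * _JITTER_CLIP_SIGMA * self.jitter_sd
        for prog in self.programs:
            if prog.kind not in _CUTOFF_BY_KIND:
                raise ValueError(f"unknown contact program kind {prog.kind!r}")
            if len(prog.target_occupancy) != self.n_ligands:
                raise ValueError(
                    f"program {prog.residue_label}: {len(prog.target_occupancy)} "
                    f"target occupancies for {self.n_ligands} ligands"
                )
            if any(not 0.0 <= t <= 1.0 for t in prog.target_occupancy):
                raise ValueError(f"program {prog.residue_label}: occupancy outside [0, 1]")
            if not prog.d_on + margin < prog.cutoff:
                raise ValueError(
                    f"program {prog.residue_label}: d_on={prog.d_on} too close to "
                    f"cutoff {prog.cutoff} for jitter margin {margin:.2f}"
                )
            if not prog.d_off - margin > prog.cutoff:
                raise ValueError(
                    f"program {prog.residue_label}: d_off={prog.d_off} too close to "
                    f"cutoff {prog.cutoff} for jitter margin {margin:.2f}"
                )

    @property
    def ligand_ids(self) -> list[str]:
        return [f"lig{i + 1}" for i in range(self.n_ligands)]

    @property
    def annotation_rules(self) -> dict:
        """Group/ring detection config matching the generated ligand."""
        return {
            "ligand_carboxylates": [{"oxygens": ["O1", "O2"], "carbon": "C1"}],
            "ligand_rings": [["C2", "C3", "C4", "C5", "C6", "C7"]],
        }


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default planted SAR dataset: 8 ligands x 3 replicates x 2000 frames.

    Occupancies of the two salt-bridge programs form a crossed two-level
    design so their columns are nearly orthogonal; the planted coefficients
    mirror the potency-lowering ARG929-like contact (beta = -1.5) and the
    potency-enhancing ARG439-like contact (beta = +1.5).  A pi-stacking
    program with zero planted effect and a constant-occupancy glutamate
    hydrogen bond act as nuisance columns.
    """
    programs = (
        ContactProgram(
            "salt_bridge",
            "ARG929",
            (0.9, 0.9, 0.1, 0.1, 0.8, 0.8, 0.2, 0.2),
            d_on=4.0,
            d_off=8.0,
            beta_true=-1.5,
        ),
        ContactProgram(
            "salt_bridge",
            "ARG439",
            (0.1, 0.9, 0.1, 0.9, 0.2, 0.8, 0.2, 0.8),
            d_on=4.0,
            d_off=8.0,
            beta_true=1.5,
        ),
        ContactProgram(
            "pi_stack",
            "TYR961",
            (0.5, 0.3, 0.7, 0.6, 0.4, 0.5, 0.6, 0.4),
            d_on=4.0,
            d_off=9.0,
            beta_true=0.0,
        ),
    )
    kwargs = dict(n_ligands=8, programs=programs, seed=seed)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def paper_preset(seed: int = 0) -> SyntheticSpec:
    """Four-ligand preset mirroring the triplicate 500 ns study layout.

    Small enough to trip the downstream small-sample warning, as the real
    four-ligand study does.
    """
    programs = (
        ContactProgram(
            "salt_bridge", "ARG929", (0.1, 0.2, 0.8, 0.9), 4.0, 8.0, beta_true=-1.5
        ),
        ContactProgram(
            "salt_bridge", "ARG439", (0.9, 0.8, 0.2, 0.1), 4.0, 8.0, beta_true=1.5
        ),
        ContactProgram(
            "pi_stack", "TYR961", (0.3, 0.8, 0.7, 0.6), 4.0, 9.0, beta_true=0.0
        ),
    )
    return SyntheticSpec(n_ligands=4, programs=programs, seed=seed)


def total_sampling_us_per_ligand(spec: SyntheticSpec) -> float:
    """Total nominal sampling per ligand in microseconds (replicates x length)."""
    return spec.replicates_per_ligand * spec.replicate_length_ns / 1000.0


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_HEX = [
    (np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a))) for a in range(0, 360, 60)
]
_RING_RADIUS = 1.39

#: Guanidinium atom offsets relative to CZ, pointing along -x (toward the
#: ligand when the residue sits on the +x axis).
_GUANIDINIUM_OFFSETS = {
    "NH1": (-1.1, 0.7, 0.0),
    "NH2": (-1.1, -0.7, 0.0),
    "NE": (1.2, 0.4, 0.0),
    "CZ": (0.0, 0.0, 0.0),
}

_LIGAND_RING_CENTER = np.array([0.0, 4.5, 0.0])
# Off the carboxylate/arginine x-axis and the ring z-axis so the amide
# nitrogen never strays near a programmed group's cutoff shell.
_AMIDE_N = np.array([0.0, 0.0, -3.5])


def _ligand_atoms_and_coords():
    atoms = [
        ("C1", "C", (0.0, 0.0, 0.0)),
        ("O1", "O", (0.55, 1.05, 0.0)),
        ("O2", "O", (0.55, -1.05, 0.0)),
        ("N1", "N", tuple(_AMIDE_N)),
        ("C8", "C", (0.0, 2.5, 0.0)),
    ]
    for k, (cx, cy) in enumerate(_HEX):
        atoms.append(
            (
                f"C{k + 2}",
                "C",
                (
                    _LIGAND_RING_CENTER[0] + _RING_RADIUS * cx,
                    _LIGAND_RING_CENTER[1] + _RING_RADIUS * cy,
                    _LIGAND_RING_CENTER[2],
                ),
            )
        )
    return atoms


def _program_layout(spec: SyntheticSpec):
    """Per program: atom entries, anchor point, direction, offsets from the
    governing point.  Directions are allocated per kind so programs never
    collide: salt bridges along +/-x, pi stacks along +/-z from the ligand
    ring, switching hbonds along diagonals below the amide nitrogen."""
    salt_dirs = [np.array(v) for v in ((1.0, 0, 0), (-1.0, 0, 0))]
    pi_dirs = [np.array(v) for v in ((0.0, 0, 1.0), (0.0, 0, -1.0))]
    hb_dirs = [
        np.array(v) for v in ((0.0, -0.7071, -0.7071), (0.0, 0.7071, -0.7071))
    ]
    used = {"salt_bridge": 0, "pi_stack": 0, "hbond": 0}
    layouts = []
    for prog in spec.programs:
        if used.get(prog.kind, 99) >= {"salt_bridge": 2, "pi_stack": 2, "hbond": 2}.get(prog.kind, 0):
            raise ValueError(f"too many {prog.kind} programs for the schematic pocket")
        if prog.kind == "salt_bridge":
            direction = salt_dirs[used["salt_bridge"]]
            anchor = np.zeros(3)  # ligand C_COOH
            sign = -1.0 if direction[0] < 0 else 1.0
            offsets = {
                name: np.array(off) * np.array([sign, 1.0, 1.0])
                for name, off in _GUANIDINIUM_OFFSETS.items()
            }
            atom_entries = [(n, "N" if n.startswith("N") else "C") for n in
                            ("NE", "NH1", "NH2", "CZ")]
        elif prog.kind == "pi_stack":
            direction = pi_dirs[used["pi_stack"]]
            anchor = _LIGAND_RING_CENTER.copy()
            offsets = {}
            names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
            for name, (cx, cy) in zip(names, _HEX):
                offsets[name] = np.array([_RING_RADIUS * cx, _RING_RADIUS * cy, 0.0])
            offsets["OH"] = np.array([0.0, 2.1, 0.0])
            atom_entries = [(n, "O" if n == "OH" else "C") for n in names + ["OH"]]
        elif prog.kind == "hbond":
            direction = hb_dirs[used["hbond"]]
            anchor = _AMIDE_N.copy()
            offsets = {"OG": np.zeros(3), "CB": np.array([0.0, -1.2, 0.6])}
            atom_entries = [("OG", "O"), ("CB", "C")]
        else:  # pragma: no cover - guarded at spec validation
            raise ValueError(prog.kind)
        used[prog.kind] += 1
        layouts.append(
            {
                "program": prog,
                "anchor": anchor,
                "direction": direction,
                "offsets": offsets,
                "atom_entries": atom_entries,
            }
        )
    return layouts


def build_topology(spec: SyntheticSpec) -> tuple[Topology, np.ndarray]:
    """Build the schematic pocket topology and its base coordinates.

    Returns the annotated topology (guanidinium, carboxylate and ring
    groups attached) and the base coordinate array, with each programmed
    group placed at its unbound-state distance.
    """
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []

    def add(name, element, resname, resnum, chain, is_lig, xyz):
        atoms.append(
            AtomRecord(
                atom_index=len(atoms),
                atom_name=name,
                element=element,
                residue_name=resname,
                residue_number=resnum,
                chain_id=chain,
                is_ligand=is_lig,
            )
        )
        coords.append(tuple(float(v) for v in xyz))

    for name, element, xyz in _ligand_atoms_and_coords():
        add(name, element, "LIG", 1, "L", True, xyz)

    for layout in _program_layout(spec):
        prog = layout["program"]
        base = layout["anchor"] + layout["direction"] * prog.d_off
        for name, element in layout["atom_entries"]:
            add(
                name,
                element,
                prog.residue_name,
                prog.residue_number,
                "A",
                False,
                base + layout["offsets"][name],
            )

    # Static control residues: a glutamate hydrogen bond pinned in contact,
    # an arginine whose guanidinium faces the amide nitrogen (exercising the
    # guanidinium-only collapse), and a serine hydroxyl facing both
    # carboxylate oxygens (exercising the carboxylate-only collapse).
    glu_base = _AMIDE_N + np.array([0.0, 0.0, -2.9])
    add("OE1", "O", "GLU", 465, "A", False, glu_base)
    add("OE2", "O", "GLU", 465, "A", False, glu_base + np.array([1.0, 0.8, -0.6]))
    add("CD", "C", "GLU", 465, "A", False, glu_base + np.array([0.55, 0.5, -0.45]))
    arg_cz = _AMIDE_N + np.array([0.0, -4.3, 0.0])
    add("NE", "N", "ARG", 100, "A", False, arg_cz + np.array([0.0, -1.2, 0.4]))
    add("NH1", "N", "ARG", 100, "A", False, arg_cz + np.array([0.0, 1.1, 0.7]))
    add("NH2", "N", "ARG", 100, "A", False, arg_cz + np.array([0.0, 1.1, -0.7]))
    add("CZ", "C", "ARG", 100, "A", False, arg_cz)
    add("OG", "O", "SER", 200, "A", False, (0.55, 1.05, 3.0))
    add("CB", "C", "SER", 200, "A", False, (0.55, 1.05, 4.45))

    topo = Topology(atoms=atoms)
    rules = spec.annotation_rules
    topo = annotate_groups(
        topo,
        ligand_carboxylates=rules["ligand_carboxylates"],
        ligand_rings=rules["ligand_rings"],
    )
    return topo, np.array(coords)


def markov_state_series(
    rng: np.random.Generator,
    n_frames: int,
    target_occupancy: float,
    switching_rate: float,
) -> np.ndarray:
    """Two-state (0 = unbound, 1 = bound) Markov chain realisation.

    Transition probabilities per frame are ``p(0->1) = rate x pi`` and
    ``p(1->0) = rate x (1 - pi)``, giving stationary P(bound) = pi; the
    initial state is drawn from the stationary distribution, so the
    expected occupancy equals the target at every length.
    """
    pi = float(target_occupancy)
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"target occupancy {pi} outside [0, 1]")
    if pi == 0.0 or pi == 1.0:
        rng.random()  # keep the draw count aligned across targets
        return np.full(n_frames, int(pi), dtype=np.int8)
    p_on = switching_rate * pi
    p_off = switching_rate * (1.0 - pi)
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=np.int8)
    state = 1 if u[0] < pi else 0
    states[0] = state
    for k in range(1, n_frames):
        if state == 1:
            state = 0 if u[k] < p_off else 1
        else:
            state = 1 if u[k] < p_on else 0
        states[k] = state
    return states


def _rng_for(spec: SyntheticSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, *stream])


def simulate_trajectory(
    topo: Topology,
    base_coords: np.ndarray,
    spec: SyntheticSpec,
    ligand_index: int,
    replicate_index: int,
) -> Trajectory:
    """Simulate one replicate for one ligand.

    Each programmed group rigid-translates along its axis between the
    bound (``d_on``) and unbound (``d_off``) distance following its Markov
    chain; every atom additionally receives clipped Gaussian jitter.
    Deterministic for fixed (spec seed, ligand, replicate).
    """
    if not 0 <= ligand_index < spec.n_ligands:
        raise ValueError(f"ligand index {ligand_index} outside 0..{spec.n_ligands - 1}")
    rng = _rng_for(spec, 1, ligand_index, replicate_index)
    n = spec.frames_per_replicate
    coords = np.repeat(base_coords[None, :, :], n, axis=0)

    by_residue: dict[tuple[str, int], list[int]] = {}
    for a in topo.atoms:
        by_residue.setdefault((a.residue_name, a.residue_number), []).append(a.atom_index)

    for layout in _program_layout(spec):
        prog = layout["program"]
        states = markov_state_series(
            rng, n, prog.target_occupancy[ligand_index], spec.switching_rate
        )
        axial = np.clip(rng.normal(0.0, _AXIAL_SD, size=n), -_AXIAL_CLIP, _AXIAL_CLIP)
        dist = np.where(states == 1, prog.d_on, prog.d_off) + axial
        centers = layout["anchor"][None, :] + dist[:, None] * layout["direction"][None, :]
        idx = by_residue[(prog.residue_name, prog.residue_number)]
        names = {topo.atoms[i].atom_name: i for i in idx}
        for name, i in names.items():
            coords[:, i, :] = centers + layout["offsets"][name][None, :]

    jitter = rng.normal(0.0, spec.jitter_sd, size=coords.shape)
    clip = _JITTER_CLIP_SIGMA * spec.jitter_sd
    coords += np.clip(jitter, -clip, clip)
    return Trajectory(
        coordinates=coords,
        replicate_id=f"lig{ligand_index + 1}_rep{replicate_index + 1}",
    )


# ---------------------------------------------------------------------------
# Full SAR dataset
# ---------------------------------------------------------------------------


@dataclass
class SarDataset:
    spec: SyntheticSpec
    topology: Topology
    base_coords: np.ndarray
    trajectories: dict  # (ligand_id, replicate_id) -> Trajectory
    pic50: np.ndarray  # per ligand
    ic50_nM: np.ndarray
    ground_truth: dict


def generate_sar_dataset(spec: SyntheticSpec) -> SarDataset:
    """Generate the full in-memory dataset with ground-truth sidecar.

    pIC50_i = intercept + sum_j beta_j x target_occupancy_ij + noise, with
    occupancy on the 0..1 fraction scale; IC50 is back-computed in nM.
    """
    topo, base = build_topology(spec)
    trajectories = {}
    for li, lig_id in enumerate(spec.ligand_ids):
        for ri in range(spec.replicates_per_ligand):
            trajectories[(lig_id, f"rep{ri + 1}")] = simulate_trajectory(
                topo, base, spec, li, ri
            )
    rng = _rng_for(spec, 2)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_ligands) if spec.noise_sd > 0 else np.zeros(spec.n_ligands)
    targets = np.array([prog.target_occupancy for prog in spec.programs])  # programs x ligands
    betas = np.array([prog.beta_true for prog in spec.programs])
    pic50 = spec.intercept + (betas @ targets if len(spec.programs) else 0.0) + noise
    ic50 = np.array([ic50_from_pic50(p) for p in pic50])
    ground_truth = {
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "ligand_ids": spec.ligand_ids,
        "programs": [
            {
                "kind": prog.kind,
                "residue_label": prog.residue_label,
                "beta_true": prog.beta_true,
                "target_occupancy": list(prog.target_occupancy),
            }
            for prog in spec.programs
        ],
        "pic50": pic50.tolist(),
        "ic50_nM": ic50.tolist(),
    }
    return SarDataset(
        spec=spec,
        topology=topo,
        base_coords=base,
        trajectories=trajectories,
        pic50=pic50,
        ic50_nM=ic50,
        ground_truth=ground_truth,
    )


def write_sar_dataset(dataset: SarDataset, outdir: Path) -> dict:
    """Write topology.pdb, traj_<ligand>_<rep>.pdb, ligands.csv and
    ground_truth.json; returns a manifest of ligand/replicate -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "topology.pdb").write_text(
        write_topology(dataset.topology, dataset.base_coords)
    )
    manifest = {"topology": "topology.pdb", "trajectories": []}
    for (lig_id, rep_id), traj in sorted(dataset.trajectories.items()):
        name = f"traj_{lig_id}_{rep_id}.pdb"
        (outdir / name).write_text(write_trajectory(dataset.topology, traj))
        manifest["trajectories"].append(
            {"ligand": lig_id, "replicate": rep_id, "path": name}
        )
    lines = ["ligand_id,formula,ic50_nM"]
    for lig_id, ic50 in zip(dataset.spec.ligand_ids, dataset.ic50_nM):
        lines.append(f"{lig_id},,{ic50:.6g}")
    (outdir / "ligands.csv").write_text("\n".join(lines) + "\n")
    (outdir / "ground_truth.json").write_text(
        json.dumps(dataset.ground_truth, indent=2, sort_keys=True)
    )
    manifest["ligand_table"] = "ligands.csv"
    manifest["annotation_rules"] = dataset.spec.annotation_rules
    return manifest
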