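"""Contact enumeration, hbond/pi-stack filtering, equivalent-atom collapsing.

The fingerprint pipeline runs in three stages:

1. *Enumeration*: every ligand-heavy x protein-heavy atom pair that comes
   within a candidate cutoff (default 4 A) in at least one sampled frame.
2. *Filtering*: keep only hydrogen-bond-capable pairs (both atoms N/O/S by
   default) and add ring-ring pi-stacking candidates whose centroids
   approach within a candidate ring cutoff.
3. *Collapsing*: distances to the two oxygens of a ligand carboxylate are
   replaced by one distance to the carboxyl carbon (C_COOH); distances to
   the three guanidinium nitrogens of an arginine are replaced by one
   distance to its CZ carbon.  A pair hit by both rules becomes a single
   salt-bridge contact C_COOH<->CZ.

Each resulting :class:`ContactDefinition` carries the per-type occupancy
cutoff used downstream.  A distance exactly equal to a cutoff counts as
in-contact (<=).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .structure import RingAnnotation, Topology, Trajectory

__all__ = [
    "DEFAULT_OCCUPANCY_CUTOFFS",
    "DEFAULT_HBOND_ELEMENTS",
    "ContactDefinition",
    "ContactSet",
    "ContactError",
    "enumerate_candidates",
    "filter_contacts",
    "collapse_equivalents",
    "ring_centroid_distance",
    "contact_set_to_frame",
    "contact_set_from_frame",
]

#: Per-contact-type occupancy cutoffs in angstrom.  These are conventional
#: geometric criteria, configurable in every entry point.
DEFAULT_OCCUPANCY_CUTOFFS: Mapping[str, float] = {
    "hbond": 3.5,
    "collapsed_carboxylate": 5.0,
    "collapsed_guanidinium": 5.0,
    "salt_bridge": 5.0,
    "pi_stack": 5.5,
}

#: Heavy-atom elements considered hydrogen-bond capable.
DEFAULT_HBOND_ELEMENTS = frozenset({"N", "O", "S"})

#: Candidate cutoff on ring centroids at enumeration time (permissive
#: superset; the pi_stack occupancy cutoff governs the final statistic).
DEFAULT_RING_CANDIDATE_CUTOFF = 6.0

Selector = Union[int, tuple]


class ContactError(ValueError):
    """Raised for invalid contact input (missing annotation, bad selector)."""


@dataclass(frozen=True)
class ContactDefinition:
    """One collapsed ligand-group <-> residue-group distance definition.

    Selectors are atom indices (plain atoms or group representatives) or
    sorted index tuples (aromatic rings, measured centroid-to-centroid).
    """

    contact_id: str
    contact_type: str
    ligand_selector: Selector
    residue_selector: Selector
    cutoff: float
    residue_number: int = 0
    ligand_order: int = 0

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ContactError(f"cutoff must be positive, got {self.cutoff}")


@dataclass
class ContactSet:
    contacts: list[ContactDefinition]
    provenance: dict = field(default_factory=dict)
    #: original filtered atom pair -> contact_id (surjective audit map)
    audit: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.contacts)

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def contact_ids(self) -> list[str]:
        return [c.contact_id for c in self.contacts]


def _sampled(traj: Trajectory, stride: int) -> np.ndarray:
    if stride < 1:
        raise ContactError(f"stride must be >= 1, got {stride}")
    if traj.n_frames < 1:
        raise ContactError("empty trajectory")
    return traj.coordinates[::stride]


def enumerate_candidates(
    traj: Trajectory,
    topo: Topology,
    candidate_cutoff: float = 4.0,
    stride: int = 1,
) -> list[tuple[int, int]]:
    """Ligand-heavy x protein-heavy atom pairs within the candidate cutoff.

    A pair qualifies if its distance is <= ``candidate_cutoff`` in at least
    one sampled frame (every ``stride``-th frame).  Hydrogens never appear.
    The result is sorted by (residue atom index, ligand atom index) and is
    deterministic for fixed input.
    """
    if not candidate_cutoff > 0:
        raise ContactError(f"candidate cutoff must be positive, got {candidate_cutoff}")
    frames = _sampled(traj, stride)
    lig = topo.heavy_indices(ligand=True)
    prot = topo.heavy_indices(ligand=False)
    hit = np.zeros((lig.size, prot.size), dtype=bool)
    chunk = max(1, int(2e6 // max(1, lig.size * prot.size)))
    for start in range(0, frames.shape[0], chunk):
        block = frames[start : start + chunk]
        diff = block[:, lig, None, :] - block[:, None, prot, :]
        d2 = np.einsum("flpc,flpc->flp", diff, diff)
        hit |= (d2 <= candidate_cutoff**2).any(axis=0)
    li, pi = np.nonzero(hit)
    pairs = sorted(zip(lig[li].tolist(), prot[pi].tolist()), key=lambda p: (p[1], p[0]))
    return pairs


def ring_centroid_distance(
    frame_coords: np.ndarray, ring_a: Iterable[int], ring_b: Iterable[int]
) -> float:
    """Euclidean distance between the arithmetic-mean centroids of two rings."""
    ia, ib = list(ring_a), list(ring_b)
    if not ia or not ib:
        raise ContactError("ring atom set must be non-empty")
    ca = np.asarray(frame_coords)[ia].mean(axis=0)
    cb = np.asarray(frame_coords)[ib].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def _ring_candidates(
    traj: Trajectory,
    topo: Topology,
    ring_cutoff: float,
    stride: int,
) -> list[tuple[RingAnnotation, RingAnnotation]]:
    frames = _sampled(traj, stride)
    lig_rings = [r for r in topo.rings if r.is_ligand]
    res_rings = [r for r in topo.rings if not r.is_ligand]
    out = []
    for lr in lig_rings:
        la = sorted(lr.atom_indices)
        lc = frames[:, la].mean(axis=1)
        for rr in res_rings:
            ra = sorted(rr.atom_indices)
            rc = frames[:, ra].mean(axis=1)
            dmin = np.linalg.norm(lc - rc, axis=1).min()
            if dmin <= ring_cutoff:
                out.append((lr, rr))
    return out


def filter_contacts(
    pairs: Sequence[tuple[int, int]],
    topo: Topology,
    traj: Optional[Trajectory] = None,
    hbond_elements: Iterable[str] = DEFAULT_HBOND_ELEMENTS,
    ring_candidate_cutoff: float = DEFAULT_RING_CANDIDATE_CUTOFF,
    stride: int = 1,
) -> tuple[list[tuple[int, int]], list[tuple[RingAnnotation, RingAnnotation]]]:
    """Restrict pairs to putative hydrogen bonds; add pi-stack candidates.

    An atom pair survives iff both atoms are hydrogen-bond capable
    (elements in ``hbond_elements``).  If a trajectory is given, every
    annotated ligand ring x residue ring whose centroid distance dips to
    ``ring_candidate_cutoff`` or below in a sampled frame is emitted as a
    pi-stack candidate.
    """
    capable = set(hbond_elements)
    kept = [
        (li, ri)
        for li, ri in pairs
        if topo.atoms[li].element in capable and topo.atoms[ri].element in capable
    ]
    rings = (
        _ring_candidates(traj, topo, ring_candidate_cutoff, stride)
        if traj is not None
        else []
    )
    return kept, rings


def _ligand_ring_label(topo: Topology, ring: RingAnnotation) -> str:
    lig_rings = [r for r in topo.rings if r.is_ligand]
    if len(lig_rings) == 1:
        return "ring"
    return f"ring{lig_rings.index(ring) + 1}"


def collapse_equivalents(
    pairs: Sequence[tuple[int, int]],
    topo: Topology,
    ring_pairs: Sequence[tuple[RingAnnotation, RingAnnotation]] = (),
    cutoffs: Optional[Mapping[str, float]] = None,
    provenance: Optional[dict] = None,
) -> ContactSet:
    """Merge chemically equivalent distances into single contact definitions.

    Ligand-side carboxylate oxygens collapse onto the carboxyl carbon
    (C_COOH); residue-side arginine guanidinium nitrogens (NE/NH1/NH2)
    collapse onto CZ.  A pair hit by both rules becomes one salt-bridge
    contact C_COOH<->CZ; untouched pairs become atom-to-atom hbond
    contacts.  Ring candidate pairs become centroid-distance pi-stack
    contacts.  An arginine nitrogen whose residue lacks a guanidinium
    annotation (e.g. skipped for a missing CZ) is an error.
    """
    cut = dict(DEFAULT_OCCUPANCY_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)
    merged: dict[tuple, ContactDefinition] = {}
    audit: dict[tuple[int, int], str] = {}

    for li, ri in pairs:
        lig_atom, res_atom = topo.atoms[li], topo.atoms[ri]
        lig_group = topo.group_of_atom(li, "carboxylate")
        if lig_group is not None and not lig_group.is_ligand:
            lig_group = None
        res_group = topo.group_of_atom(ri, "guanidinium")
        if res_atom.residue_name == "ARG" and res_atom.atom_name in ("NE", "NH1", "NH2"):
            if res_group is None:
                raise ContactError(
                    f"guanidinium annotation missing for atom {res_atom.atom_name} "
                    f"of {res_atom.residue_label}"
                )
        lig_sel = lig_group.representative_index if lig_group else li
        res_sel = res_group.representative_index if res_group else ri
        if lig_group and res_group:
            ctype = "salt_bridge"
        elif lig_group:
            ctype = "collapsed_carboxylate"
        elif res_group:
            ctype = "collapsed_guanidinium"
        else:
            ctype = "hbond"
        lig_label = "C_COOH" if lig_group else lig_atom.atom_name
        res_part = "CZ" if res_group else res_atom.atom_name
        contact_id = f"{lig_label}-{res_atom.residue_label}:{res_part}"
        key = (lig_sel, res_sel)
        if key not in merged:
            merged[key] = ContactDefinition(
                contact_id=contact_id,
                contact_type=ctype,
                ligand_selector=lig_sel,
                residue_selector=res_sel,
                cutoff=cut[ctype],
                residue_number=res_atom.residue_number,
                ligand_order=lig_sel,
            )
        audit[(li, ri)] = merged[key].contact_id

    for lr, rr in ring_pairs:
        lig_sel = tuple(sorted(lr.atom_indices))
        res_sel = tuple(sorted(rr.atom_indices))
        key = (lig_sel, res_sel)
        if key in merged:
            continue
        first_res_atom = topo.atoms[res_sel[0]]
        merged[key] = ContactDefinition(
            contact_id=f"{_ligand_ring_label(topo, lr)}-{rr.residue_label}:ring",
            contact_type="pi_stack",
            ligand_selector=lig_sel,
            residue_selector=res_sel,
            cutoff=cut["pi_stack"],
            residue_number=first_res_atom.residue_number,
            ligand_order=min(lig_sel),
        )

    contacts = sorted(
        merged.values(), key=lambda c: (c.residue_number, c.ligand_order, c.contact_id)
    )
    ids = [c.contact_id for c in contacts]
    if len(set(ids)) != len(ids):
        raise ContactError(f"non-unique contact ids: {sorted(ids)}")
    return ContactSet(contacts=contacts, provenance=dict(provenance or {}), audit=audit)


def _sel_to_str(sel: Selector) -> str:
    if isinstance(sel, tuple):
        return "+".join(str(i) for i in sel)
    return str(sel)


def _sel_from_str(text: str) -> Selector:
    if "+" in text:
        return tuple(int(t) for t in text.split("+"))
    return int(text)


def contact_set_to_frame(cs: ContactSet) -> pd.DataFrame:
    """Serialize to the canonical CSV layout (deterministic byte output)."""
    return pd.DataFrame(
        {
            "contact_id": [c.contact_id for c in cs],
            "contact_type": [c.contact_type for c in cs],
            "ligand_selector": [_sel_to_str(c.ligand_selector) for c in cs],
            "residue_selector": [_sel_to_str(c.residue_selector) for c in cs],
            "cutoff": [c.cutoff for c in cs],
        }
    )


def contact_set_from_frame(df: pd.DataFrame, topo: Topology) -> ContactSet:
    """Rebuild a ContactSet from its CSV serialization."""
    contacts = []
    for row in df.itertuples(index=False):
        res_sel = _sel_from_str(str(row.residue_selector))
        res_idx = res_sel[0] if isinstance(res_sel, tuple) else res_sel
        lig_sel = _sel_from_str(str(row.ligand_selector))
        contacts.append(
            ContactDefinition(
                contact_id=str(row.contact_id),
                contact_type=str(row.contact_type),
                ligand_selector=lig_sel,
                residue_selector=res_sel,
                cutoff=float(row.cutoff),
                residue_number=topo.atoms[res_idx].residue_number,
                ligand_order=min(lig_sel) if isinstance(lig_sel, tuple) else lig_sel,
            )
        )
    return ContactSet(contacts=contacts)


def contact_set_to_json(cs: ContactSet) -> str:
    payload = {
        "provenance": cs.provenance,
        "contacts": contact_set_to_frame(cs).to_dict(orient="records"),
    }
    return json.dumps(payload, indent=2, sort_keys=True)
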