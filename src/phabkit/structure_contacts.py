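"""Antibody-antigen interface geometry.

Implements the contact criteria used for the structure-function analysis of
phosphohistidine binders, taken literally as defaults and fully
configurable:

* H-bond: donor-acceptor distance <= 2.5 A, donor angle (D-H...A) and
  acceptor angle (H...A-X) both within 120-180 deg.
* Water bridge: the same angular windows with a 2.8 A distance window on
  each leg, water-mediated between the two molecules.
* pi-cation: cationic group within 4.5 A of an aromatic ring centroid.
* pi-pi: two aromatic rings with centroid distance within 3.5-5.0 A;
  classified parallel (interplanar angle < 30 deg), T-shaped (> 60 deg) or
  intermediate.

The 2.5 A heavy-atom donor-acceptor cutoff is unusually short compared with
the conventional ~3.5 A; it is kept as the literal default and a
conventional profile is available via :func:`ContactCriteria.conventional`.

Also provided: Kabsch superposition and Calpha RMSD, paratope shells,
GXGX "nest"-motif detection on numbered CDR segments, and Shrake-Rupley
SASA / buried-surface areas with a 1.7 A probe default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .formats_io import Atom, StructureModel
from .numbering import NumberedChain, NumberedPosition

# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference coordinates."""

    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # 3-vector, y = R x + t
    rmsd: float               # A
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition (proper rotation) of paired coordinate sets."""
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays are required")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("at least 3 atom pairs are required")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    a, b = ref - ref_c, mob - mob_c
    sv = np.linalg.svd(b, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) coordinates: rotation is not unique")
    rot, rssd = Rotation.align_vectors(a, b)
    rmsd = rssd / math.sqrt(n)
    rmat = rot.as_matrix()
    translation = ref_c - rmat @ mob_c
    return SuperpositionResult(rotation=rmat, translation=translation,
                               rmsd=float(rmsd), n_atoms=n)


def ca_coordinates(model: StructureModel, chain_id: str) -> np.ndarray:
    """Calpha coordinates of one chain, in residue order."""
    coords = [a.xyz for a in model.chain(chain_id) if a.name == "CA"]
    if not coords:
        raise ValueError(f"chain {chain_id!r} has no CA atoms")
    return np.array(coords, dtype=float)


# ---------------------------------------------------------------------------
# Criteria and contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactCriteria:
    """Geometric contact criteria (defaults follow the literal published set)."""

    hbond_da_max: float = 2.5
    bridge_da_max: float = 2.8
    donor_angle: tuple[float, float] = (120.0, 180.0)
    acceptor_angle: tuple[float, float] = (120.0, 180.0)
    pi_cation_max: float = 4.5
    pi_pi_range: tuple[float, float] = (3.5, 5.0)
    parallel_max_angle: float = 30.0
    t_shaped_min_angle: float = 60.0

    def __post_init__(self):
        if min(self.hbond_da_max, self.bridge_da_max, self.pi_cation_max) <= 0:
            raise ValueError("distance maxima must be positive")
        if not (self.pi_pi_range[0] < self.pi_pi_range[1]):
            raise ValueError("pi_pi_range must be ordered")

    @classmethod
    def conventional(cls) -> "ContactCriteria":
        """A conventional heavy-atom H-bond profile (D-A <= 3.5 A)."""
        return cls(hbond_da_max=3.5, bridge_da_max=3.5)


@dataclass(frozen=True)
class Contact:
    """One typed interface interaction with its geometry."""

    kind: str                         # hbond | water_bridge | pi_pi | pi_cation | hydrophobic
    partner_a: str                    # atom/ring descriptor on the receptor side
    partner_b: str                    # atom/ring descriptor on the ligand side
    distance: float                   # A (leg distances for bridges: max of the two)
    donor_angle: float | None = None
    acceptor_angle: float | None = None
    interplanar_angle: float | None = None
    offset: float | None = None
    classification: str | None = None  # pi_pi: T-shaped / parallel / intermediate
    via: str | None = None             # water descriptor for bridges

    def satisfies(self, criteria: ContactCriteria) -> bool:
        lo_a, hi_a = criteria.donor_angle
        if self.kind == "hbond":
            ok = self.distance <= criteria.hbond_da_max
            if self.donor_angle is not None:
                ok &= lo_a <= self.donor_angle <= hi_a
            if self.acceptor_angle is not None:
                ok &= criteria.acceptor_angle[0] <= self.acceptor_angle <= criteria.acceptor_angle[1]
            return ok
        if self.kind == "water_bridge":
            return self.distance <= criteria.bridge_da_max
        if self.kind == "pi_cation":
            return self.distance <= criteria.pi_cation_max
        if self.kind == "pi_pi":
            return criteria.pi_pi_range[0] <= self.distance <= criteria.pi_pi_range[1]
        return True


def _describe(atom: Atom) -> str:
    ic = atom.insertion_code or ""
    return f"{atom.chain_id}/{atom.residue_name}{atom.residue_seq}{ic}/{atom.name}"


# ---------------------------------------------------------------------------
# Molecule partition
# ---------------------------------------------------------------------------

def partition_atoms(
    model: StructureModel,
    ligand_chains: Iterable[str] | None = None,
) -> tuple[list[Atom], list[Atom]]:
    """Split non-water atoms into (receptor, ligand).

    With ``ligand_chains`` given, chains split the molecule; otherwise the
    non-water HETATM records form the ligand.
    """
    non_water = [a for a in model.atoms if not a.is_water]
    if ligand_chains is not None:
        lig_set = set(ligand_chains)
        receptor = [a for a in non_water if a.chain_id not in lig_set]
        ligand = [a for a in non_water if a.chain_id in lig_set]
    else:
        receptor = [a for a in non_water if not a.is_hetatm]
        ligand = [a for a in non_water if a.is_hetatm]
    return receptor, ligand


def _angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at p2 in degrees."""
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


_POLAR_ELEMENTS = frozenset({"N", "O", "S"})


def _hydrogens_of(atoms: Sequence[Atom], heavy: Atom, max_bond: float = 1.3) -> list[Atom]:
    hx = []
    hpos = np.array(heavy.xyz)
    for a in atoms:
        if a.element == "H" and a.residue_key == heavy.residue_key:
            if np.linalg.norm(np.array(a.xyz) - hpos) <= max_bond:
                hx.append(a)
    return hx


def _heavy_neighbors(atoms: Sequence[Atom], center: Atom, max_bond: float = 1.8) -> list[Atom]:
    out = []
    cpos = np.array(center.xyz)
    for a in atoms:
        if a is center or a.element == "H":
            continue
        if a.residue_key == center.residue_key:
            if np.linalg.norm(np.array(a.xyz) - cpos) <= max_bond:
                out.append(a)
    return out


def _hbond_geometry(
    donor: Atom,
    acceptor: Atom,
    donor_side_atoms: Sequence[Atom],
    acceptor_side_atoms: Sequence[Atom],
    criteria: ContactCriteria,
    da_max: float,
    allow_heavy_fallback: bool = False,
) -> tuple[bool, float, float | None, float | None]:
    """Evaluate one candidate D...A pair; returns (ok, dist, donor_ang, acc_ang)."""
    dpos, apos = np.array(donor.xyz), np.array(acceptor.xyz)
    dist = float(np.linalg.norm(dpos - apos))
    if dist > da_max or dist < 0.5:
        return False, dist, None, None
    lo_d, hi_d = criteria.donor_angle
    lo_a, hi_a = criteria.acceptor_angle

    hydrogens = _hydrogens_of(donor_side_atoms, donor)
    donor_ang: float | None = None
    best_h = None
    if hydrogens:
        for h in hydrogens:
            ang = _angle(dpos, np.array(h.xyz), apos)
            if donor_ang is None or ang > donor_ang:
                donor_ang, best_h = ang, h
        if not (lo_d <= donor_ang <= hi_d):
            return False, dist, donor_ang, None
    elif allow_heavy_fallback:
        # fallback for hydrogen-free models: the heavy-atom antecedent angle
        # X-D...A stands in for D-H...A
        antecedents = _heavy_neighbors(donor_side_atoms, donor)
        if antecedents:
            donor_ang = max(_angle(np.array(x.xyz), dpos, apos) for x in antecedents)
            if not (lo_d <= donor_ang <= hi_d):
                return False, dist, donor_ang, None
        else:
            warnings.warn(
                f"no hydrogen or antecedent for donor {_describe(donor)}; "
                "donor-angle test skipped", stacklevel=2,
            )
    else:
        # the model carries explicit hydrogens: an atom without one is not a donor
        return False, dist, None, None

    acc_ang: float | None = None
    neighbors = _heavy_neighbors(acceptor_side_atoms, acceptor)
    if neighbors:
        ref = np.array(best_h.xyz) if best_h is not None else dpos
        acc_ang = max(_angle(ref, apos, np.array(x.xyz)) for x in neighbors)
        if not (lo_a <= acc_ang <= hi_a):
            return False, dist, donor_ang, acc_ang
    return True, dist, donor_ang, acc_ang


def _polar_atoms(atoms: Sequence[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element in _POLAR_ELEMENTS]


def detect_hbonds(
    model: StructureModel,
    criteria: ContactCriteria | None = None,
    ligand_chains: Iterable[str] | None = None,
) -> list[Contact]:
    """Inter-molecular hydrogen bonds under the distance/angle criteria.

    Donors are N/O/S heavy atoms (with their hydrogens when present;
    otherwise the heavy-atom antecedent angle is used as a documented
    fallback); acceptors are N/O/S.  Both directions are tried for every
    polar pair across the interface.
    """
    criteria = criteria or ContactCriteria()
    receptor, ligand = partition_atoms(model, ligand_chains)
    has_h = any(a.element == "H" for a in receptor + ligand)
    if not has_h:
        warnings.warn(
            "model has no explicit hydrogens; donor angles fall back to "
            "heavy-atom antecedent geometry", stacklevel=2,
        )
    contacts: list[Contact] = []
    seen: set[tuple] = set()
    for side_d, side_a in ((receptor, ligand), (ligand, receptor)):
        for donor in _polar_atoms(side_d):
            for acceptor in _polar_atoms(side_a):
                ok, dist, dang, aang = _hbond_geometry(
                    donor, acceptor, side_d, side_a, criteria, criteria.hbond_da_max,
                    allow_heavy_fallback=not has_h,
                )
                if not ok:
                    continue
                key = frozenset((_describe(donor), _describe(acceptor)))
                if key in seen:
                    continue
                seen.add(key)
                rec_is_donor = side_d is receptor
                contacts.append(
                    Contact(
                        kind="hbond",
                        partner_a=_describe(donor) if rec_is_donor else _describe(acceptor),
                        partner_b=_describe(acceptor) if rec_is_donor else _describe(donor),
                        distance=dist,
                        donor_angle=dang,
                        acceptor_angle=aang,
                    )
                )
    return contacts


def detect_water_bridges(
    model: StructureModel,
    criteria: ContactCriteria | None = None,
    ligand_chains: Iterable[str] | None = None,
) -> list[Contact]:
    """Water-mediated hydrogen-bond bridges between the two molecules.

    A water bridges receptor atom X and ligand atom Y when it forms a
    criteria-satisfying bond (2.8 A window) to each; either partner may be
    the donor of its leg.
    """
    criteria = criteria or ContactCriteria()
    receptor, ligand = partition_atoms(model, ligand_chains)
    water_atoms = model.waters
    water_o = [a for a in water_atoms if a.element == "O"]
    water_has_h = any(a.element == "H" for a in water_atoms)
    contacts: list[Contact] = []
    for w in water_o:
        def leg_partners(side: list[Atom]) -> list[tuple[Atom, float]]:
            side_has_h = any(a.element == "H" for a in side)
            found = []
            for x in _polar_atoms(side):
                ok1, d1, _, _ = _hbond_geometry(
                    w, x, water_atoms, side, criteria, criteria.bridge_da_max,
                    allow_heavy_fallback=not water_has_h,
                )
                ok2, d2, _, _ = _hbond_geometry(
                    x, w, side, water_atoms, criteria, criteria.bridge_da_max,
                    allow_heavy_fallback=not side_has_h,
                )
                if ok1 or ok2:
                    found.append((x, min(d for ok, d in ((ok1, d1), (ok2, d2)) if ok)))
            return found

        rec_partners = leg_partners(receptor)
        lig_partners = leg_partners(ligand)
        for x, dx in rec_partners:
            for y, dy in lig_partners:
                contacts.append(
                    Contact(
                        kind="water_bridge",
                        partner_a=_describe(x),
                        partner_b=_describe(y),
                        distance=max(dx, dy),
                        via=_describe(w),
                    )
                )
    return contacts


# ---------------------------------------------------------------------------
# Aromatic rings, pi-pi and pi-cation
# ---------------------------------------------------------------------------

#: Ring atom names per residue template.  Trp contributes two rings.
RING_TEMPLATES: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    # phospho-triazolylalanine / phosphohistidine ligand ring names mirror HIS
    "NEP": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}


@dataclass(frozen=True)
class AromaticRing:
    """A planar aromatic ring: centroid plus unit normal."""

    residue: str                 # descriptor chain/RESn
    atom_names: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray

    @staticmethod
    def from_atoms(atoms: Sequence[Atom], max_deviation: float = 0.2) -> "AromaticRing":
        if len(atoms) < 3:
            raise ValueError("a ring needs at least 3 atoms")
        coords = np.array([a.xyz for a in atoms], dtype=float)
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        _, sv, vt = np.linalg.svd(centered)
        if sv[1] < 1e-9:
            raise ValueError("degenerate ring: atoms are collinear")
        normal = vt[2]
        deviation = float(np.max(np.abs(centered @ normal)))
        if deviation > max_deviation:
            raise ValueError(f"ring atoms deviate {deviation:.2f} A from planarity")
        a0 = atoms[0]
        res = f"{a0.chain_id}/{a0.residue_name}{a0.residue_seq}{a0.insertion_code or ''}"
        return AromaticRing(
            residue=res,
            atom_names=tuple(a.name for a in atoms),
            centroid=centroid,
            normal=normal / np.linalg.norm(normal),
        )


def extract_rings(atoms: Sequence[Atom]) -> list[AromaticRing]:
    """All template aromatic rings among His/Phe/Tyr/Trp (and ring-bearing ligands)."""
    rings: list[AromaticRing] = []
    by_res: dict[tuple, list[Atom]] = {}
    for a in atoms:
        by_res.setdefault(a.residue_key, []).append(a)
    for key, res_atoms in by_res.items():
        resname = key[3]
        for names in RING_TEMPLATES.get(resname, []):
            sel = [a for a in res_atoms if a.name in names]
            if len(sel) == len(names):
                rings.append(AromaticRing.from_atoms(sel))
    return rings


def ring_geometry(ring_a: AromaticRing, ring_b: AromaticRing) -> tuple[float, float, float]:
    """(centroid distance A, interplanar angle deg in [0, 90], offset A).

    The offset is the lateral displacement of ring B's centroid projected
    onto ring A's plane (PLIP-style definition).
    """
    d = ring_b.centroid - ring_a.centroid
    distance = float(np.linalg.norm(d))
    cosang = abs(float(np.dot(ring_a.normal, ring_b.normal)))
    angle = math.degrees(math.acos(min(1.0, cosang)))
    in_plane = d - np.dot(d, ring_a.normal) * ring_a.normal
    offset = float(np.linalg.norm(in_plane))
    return distance, angle, offset


def classify_pi_pi(angle: float, criteria: ContactCriteria | None = None) -> str:
    criteria = criteria or ContactCriteria()
    if angle < criteria.parallel_max_angle:
        return "parallel"
    if angle > criteria.t_shaped_min_angle:
        return "T-shaped"
    return "intermediate"


def detect_pi_pi(
    model: StructureModel,
    criteria: ContactCriteria | None = None,
    ligand_chains: Iterable[str] | None = None,
) -> list[Contact]:
    """Inter-molecular pi-pi stacking contacts (face-to-face or face-to-edge)."""
    criteria = criteria or ContactCriteria()
    receptor, ligand = partition_atoms(model, ligand_chains)
    lo, hi = criteria.pi_pi_range
    contacts = []
    for ra in extract_rings(receptor):
        for rb in extract_rings(ligand):
            dist, angle, offset = ring_geometry(ra, rb)
            if lo <= dist <= hi:
                contacts.append(
                    Contact(
                        kind="pi_pi",
                        partner_a=ra.residue,
                        partner_b=rb.residue,
                        distance=dist,
                        interplanar_angle=angle,
                        offset=offset,
                        classification=classify_pi_pi(angle, criteria),
                    )
                )
    return contacts


#: Cationic group templates: atom names whose centroid carries the charge.
CATION_TEMPLATES: dict[str, list[list[str]]] = {
    "LYS": [["NZ"]],
    "ARG": [["CZ", "NH1", "NH2", "NE"]],
}


def _cation_sites(atoms: Sequence[Atom]) -> list[tuple[str, np.ndarray]]:
    sites = []
    by_res: dict[tuple, list[Atom]] = {}
    for a in atoms:
        by_res.setdefault(a.residue_key, []).append(a)
    for key, res_atoms in by_res.items():
        resname = key[3]
        for names in CATION_TEMPLATES.get(resname, []):
            sel = [a for a in res_atoms if a.name in names]
            if len(sel) == len(names):
                pos = np.mean([a.xyz for a in sel], axis=0)
                a0 = sel[0]
                desc = f"{a0.chain_id}/{a0.residue_name}{a0.residue_seq}{a0.insertion_code or ''}/{'+'.join(names)}"
                sites.append((desc, pos))
    return sites


def detect_pi_cation(
    model: StructureModel,
    criteria: ContactCriteria | None = None,
    ligand_chains: Iterable[str] | None = None,
) -> list[Contact]:
    """Cation-to-ring-centroid contacts within the pi-cation distance cutoff."""
    criteria = criteria or ContactCriteria()
    receptor, ligand = partition_atoms(model, ligand_chains)
    contacts = []
    for side_rings, side_cations, flip in (
        (receptor, ligand, True),    # ligand cation onto receptor ring
        (ligand, receptor, False),   # receptor cation onto ligand ring
    ):
        for ring in extract_rings(side_rings):
            for desc, pos in _cation_sites(side_cations):
                dist = float(np.linalg.norm(pos - ring.centroid))
                if dist <= criteria.pi_cation_max:
                    pa, pb = (ring.residue, desc) if flip else (desc, ring.residue)
                    contacts.append(
                        Contact(kind="pi_cation", partner_a=pa, partner_b=pb, distance=dist)
                    )
    return contacts


def detect_all_contacts(
    model: StructureModel,
    criteria: ContactCriteria | None = None,
    ligand_chains: Iterable[str] | None = None,
) -> list[Contact]:
    criteria = criteria or ContactCriteria()
    out: list[Contact] = []
    for fn in (detect_hbonds, detect_water_bridges, detect_pi_pi, detect_pi_cation):
        out.extend(fn(model, criteria, ligand_chains))
    return out


# ---------------------------------------------------------------------------
# Paratope shell and GXGX motif
# ---------------------------------------------------------------------------

_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


def paratope_shell(
    model: StructureModel,
    ligand_chains: Iterable[str],
    radius: float = 10.0,
    contact_mode: bool = False,
    criteria: ContactCriteria | None = None,
) -> list[tuple[str, int, str, str]]:
    """Receptor residues near the antigen.

    Radius mode (default): residues with any side-chain atom within
    ``radius`` of any antigen atom.  Contact mode: residues appearing in any
    detected contact.
    """
    receptor, ligand = partition_atoms(model, ligand_chains)
    if not ligand:
        raise ValueError("empty antigen selection")
    if contact_mode:
        contacts = detect_all_contacts(model, criteria, ligand_chains)
        keys: dict[tuple, None] = {}
        rec_keys = {a.residue_key for a in receptor}
        for c in contacts:
            for desc in (c.partner_a, c.partner_b):
                key = _residue_key_from_descriptor(desc, model)
                if key is not None and key in rec_keys:
                    keys.setdefault(key, None)
        return sorted(keys)
    lig_coords = np.array([a.xyz for a in ligand])
    tree = cKDTree(lig_coords)
    found: dict[tuple, None] = {}
    for a in receptor:
        if a.name in _BACKBONE or a.element == "H":
            continue
        if tree.query_ball_point(a.xyz, r=radius):
            found.setdefault(a.residue_key, None)
    return sorted(found)


def _residue_key_from_descriptor(desc: str, model: StructureModel):
    parts = desc.split("/")
    if len(parts) < 2:
        return None
    chain, res = parts[0], parts[1]
    i = 3
    while i < len(res) and res[:i].isalpha():
        i += 1
    resname = res[:3]
    rest = res[3:]
    icode = ""
    if rest and rest[-1].isalpha():
        icode = rest[-1]
        rest = rest[:-1]
    try:
        seq = int(rest)
    except ValueError:
        return None
    return (chain, seq, icode, resname)


def find_gxgx(segment: NumberedChain | Sequence[tuple[NumberedPosition, str]]):
    """All G-x-G-x motif occurrences on a numbered CDR segment.

    The glycine-rich "nest" motif cradles a phosphoryl group with its
    backbone amides.  Returns one (first-glycine-position,
    second-glycine-position) pair per match.
    """
    pairs = segment.positions if isinstance(segment, NumberedChain) else tuple(segment)
    matches = []
    for i in range(len(pairs) - 3):
        aas = [pairs[i + k][1] for k in range(4)]
        if aas[0] == "G" and aas[2] == "G":
            matches.append((pairs[i][0], pairs[i + 2][0]))
    return matches


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

#: van der Waals radii (A) per element for SASA.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    atoms: StructureModel | Sequence[Atom],
    probe: float = 1.7,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (A^2).

    Each atom is covered with ``n_points`` quasi-uniform test points on its
    solvent-expanded sphere (radius vdW + probe); points falling inside any
    neighbour's expanded sphere are occluded.  Hydrogens, when present,
    occlude like any other atom.
    """
    if isinstance(atoms, StructureModel):
        atoms = atoms.atoms
    atoms = list(atoms)
    if not atoms:
        raise ValueError("no atoms")
    table = radii or VDW_RADII
    coords = np.array([a.xyz for a in atoms], dtype=float)
    rr = np.array([table.get(a.element.upper(), _DEFAULT_RADIUS) + probe for a in atoms])
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = rr.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + rr[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], r=rr[i] + max_r):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > rr[j] ** 2
        areas[i] = 4.0 * math.pi * rr[i] ** 2 * accessible.mean()
    return areas


def buried_surface(
    part_a: Sequence[Atom],
    part_b: Sequence[Atom],
    probe: float = 1.7,
    n_points: int = 960,
    per_side: bool = False,
) -> float:
    """Buried surface area of a complex: SASA(A) + SASA(B) - SASA(AB).

    The total is reported by default; ``per_side=True`` halves it (average
    area buried per partner).
    """
    a_area = sasa(part_a, probe, n_points).sum()
    b_area = sasa(part_b, probe, n_points).sum()
    ab_area = sasa(list(part_a) + list(part_b), probe, n_points).sum()
    buried = a_area + b_area - ab_area
    return float(buried / 2.0) if per_side else float(buried)
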