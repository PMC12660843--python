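"""Deterministic synthetic-fixture generators.

Every module of the toolkit is testable offline against fixtures built
here: V-domain sequences with known ground-truth numbering, soft-randomized
clone pools, noiseless or noisy sensorgrams, and 3D interface models whose
contact geometry (distances, angles, offsets) is prescribed exactly by
construction.  Identical parameters and seed give byte-identical fixtures.

All structures are synthetic constructions, not downloads or copies of any
deposited model.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats_io import Atom, SequenceRecord, StructureModel, write_fasta, write_pdb
from .kinetics import sensorgrams_to_frame, simulate_sensorgram
from .library_design import sample_library, soft_design
from .numbering import get_reference

AROMATIC_CC = 1.39   # benzene C-C bond -> ring radius
NH_BOND = 1.01
CO_BOND = 1.23


# ---------------------------------------------------------------------------
# Sequence fixtures
# ---------------------------------------------------------------------------

def make_chain(
    chain_kind: str = "H",
    cdr_edits: Mapping[int, str] | None = None,
    insertions: Sequence[tuple[int, str]] = (),
    n_random_cdr_edits: int = 0,
    seed: int = 0,
    record_id: str | None = None,
) -> tuple[SequenceRecord, list[tuple[tuple[int, str], str]]]:
    """A V-domain built from the shipped Kabat reference with known numbering.

    ``cdr_edits`` maps Kabat numbers to replacement residues; ``insertions``
    is a list of (anchor Kabat number, residues) inserted right after the
    anchor with codes a, b, ...  Returns the sequence record and the
    ground-truth numbering as ((number, insertion_code), aa) pairs.
    """
    ref = get_reference(chain_kind, "kabat")
    rng = np.random.default_rng(seed)
    truth: list[tuple[tuple[int, str], str]] = [
        ((i + 1, ""), aa) for i, aa in enumerate(ref.sequence)
    ]
    edits = dict(cdr_edits or {})
    if n_random_cdr_edits:
        cdr_numbers = [
            n for name, (lo, hi) in ref.regions.items() if name.startswith("CDR")
            for n in range(lo, hi + 1)
        ]
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for n in rng.choice(cdr_numbers, size=n_random_cdr_edits, replace=False):
            edits[int(n)] = aas[rng.integers(len(aas))]
    for number, aa in edits.items():
        if not (1 <= number <= len(ref.sequence)):
            raise ValueError(f"edit position {number} outside the domain")
        idx = next(i for i, ((n, ic), _) in enumerate(truth) if n == number and not ic)
        truth[idx] = ((number, ""), aa)
    for anchor, residues in insertions:
        idx = next(
            (i for i, ((n, ic), _) in enumerate(truth) if n == anchor and not ic), None
        )
        if idx is None:
            raise ValueError(f"insertion anchor {anchor} outside the domain")
        letters = "abcdefghijklmnopqrstuvwxyz"
        ins = [((anchor, letters[k]), aa) for k, aa in enumerate(residues)]
        truth[idx + 1: idx + 1] = ins
    sequence = "".join(aa for _, aa in truth)
    rec = SequenceRecord(
        id=record_id or f"synthetic-{chain_kind}-{seed}",
        residues=sequence,
        description="synthetic V-domain fixture",
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Interface fixtures
# ---------------------------------------------------------------------------

class _AtomBuilder:
    def __init__(self):
        self.atoms: list[Atom] = []
        self._serial = 0

    def add(self, name, element, resname, resseq, chain, xyz, het=False):
        self._serial += 1
        self.atoms.append(
            Atom(
                serial=self._serial, name=name, element=element,
                residue_name=resname, residue_seq=resseq, insertion_code="",
                chain_id=chain, xyz=tuple(float(v) for v in xyz), is_hetatm=het,
            )
        )

    def model(self, name="fixture") -> StructureModel:
        return StructureModel(atoms=self.atoms, name=name)


def _hexagon(centroid: np.ndarray, normal: np.ndarray, radius: float = AROMATIC_CC,
             phase: float = 0.0) -> np.ndarray:
    normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = phase + np.arange(6) * math.pi / 3.0
    return np.array([centroid + radius * (math.cos(a) * u + math.sin(a) * v) for a in angles])


_RING_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]  # hexagon walk order


def make_interface(kind: str, **params) -> StructureModel:
    """A two-chain structure realizing a prescribed interface geometry.

    Kinds and their parameters (all distances A, angles deg):

    * ``pi_pi``: ``distance``, ``angle`` (interplanar), ``offset`` —
      two Phe rings, receptor chain A and ligand chain B.
    * ``hbond``: ``da_distance``, ``donor_angle``, ``acceptor_angle`` —
      ligand N-H donor (chain B) to receptor C=O acceptor (chain A).
    * ``water_bridge``: ``d_receptor``, ``d_ligand`` — receptor carbonyl O
      and ligand amine N bridged by an explicit water (with hydrogens).
    * ``pi_cation``: ``distance`` — Lys NZ (chain B) above a Phe ring
      centroid (chain A).

    The requested geometry holds within 1e-6 before PDB quantization.
    """
    b = _AtomBuilder()
    if kind == "pi_pi":
        d = float(params.get("distance", 5.0))
        ang = math.radians(float(params.get("angle", 75.0)))
        offset = float(params.get("offset", 0.0))
        if d <= 0 or offset < 0 or offset > d:
            raise ValueError("unrealizable ring geometry")
        ca = np.zeros(3)
        na = np.array([0.0, 0.0, 1.0])
        h = math.sqrt(d * d - offset * offset)
        cb = np.array([offset, 0.0, h])
        nb = np.array([math.sin(ang), 0.0, math.cos(ang)])
        for name, xyz in zip(_RING_NAMES, _hexagon(ca, na)):
            b.add(name, "C", "PHE", 1, "A", xyz)
        for name, xyz in zip(_RING_NAMES, _hexagon(cb, nb)):
            b.add(name, "C", "PHE", 1, "B", xyz)
    elif kind == "hbond":
        d = float(params.get("da_distance", 2.4))
        alpha = math.radians(float(params.get("donor_angle", 160.0)))
        beta = float(params.get("acceptor_angle", 150.0))
        if d <= 1.0:
            raise ValueError("unrealizable donor-acceptor distance")
        acc = np.zeros(3)                     # acceptor O
        don = np.array([d, 0.0, 0.0])        # donor N
        # H with |H-D| = NH_BOND and angle(D-H-A) = alpha
        ha = math.cos(alpha) * NH_BOND + math.sqrt(
            max(0.0, NH_BOND**2 * math.cos(alpha) ** 2 - NH_BOND**2 + d * d)
        )
        hx = (ha * ha - NH_BOND**2 + d * d) / (2.0 * d)
        hy = math.sqrt(max(0.0, ha * ha - hx * hx))
        h_pos = np.array([hx, hy, 0.0])
        # antecedent carbon so that angle(H-A-X) = beta
        u = h_pos / np.linalg.norm(h_pos)
        rot = math.radians(beta)
        x_dir = np.array(
            [math.cos(rot) * u[0] - math.sin(rot) * u[1],
             math.sin(rot) * u[0] + math.cos(rot) * u[1], 0.0]
        )
        b.add("OD1", "O", "ASN", 1, "A", acc)          # side-chain carbonyl acceptor
        b.add("CG", "C", "ASN", 1, "A", CO_BOND * x_dir)
        b.add("NE2", "N", "GLN", 1, "B", don)          # side-chain amide donor
        b.add("HE21", "H", "GLN", 1, "B", h_pos)
    elif kind == "water_bridge":
        d1 = float(params.get("d_receptor", 2.7))
        d2 = float(params.get("d_ligand", 2.7))
        if min(d1, d2) <= 1.0:
            raise ValueError("unrealizable bridge distances")
        w = np.zeros(3)
        o_rec = np.array([-d1, 0.0, 0.0])
        phi = math.radians(70.0)
        n_lig = d2 * np.array([math.cos(phi), math.sin(phi), 0.0])
        # water donates to the receptor O: H on the W->O segment
        h_w = w + NH_BOND * (o_rec - w) / np.linalg.norm(o_rec - w)
        # ligand N donates to water: H on the N->W segment
        h_n = n_lig + NH_BOND * (w - n_lig) / np.linalg.norm(w - n_lig)
        b.add("OD1", "O", "ASN", 1, "A", o_rec)
        b.add("CG", "C", "ASN", 1, "A", o_rec + np.array([-CO_BOND, 0.0, 0.0]))
        b.add("NE2", "N", "GLN", 1, "B", n_lig)
        b.add("HE21", "H", "GLN", 1, "B", h_n)
        b.add("O", "O", "HOH", 100, "W", w, het=True)
        b.add("H1", "H", "HOH", 100, "W", h_w, het=True)
    elif kind == "pi_cation":
        d = float(params.get("distance", 4.2))
        if d <= 0:
            raise ValueError("unrealizable distance")
        for name, xyz in zip(_RING_NAMES, _hexagon(np.zeros(3), np.array([0.0, 0.0, 1.0]))):
            b.add(name, "C", "PHE", 1, "A", xyz)
        b.add("NZ", "N", "LYS", 1, "B", np.array([0.0, 0.0, d]))
    else:
        raise ValueError(f"unknown interface kind {kind!r}")
    return b.model(name=f"{kind}-fixture")


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

def make_benchmark_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a directory of fixtures plus a JSON manifest of ground truth.

    The manifest records, for every fixture, the parameters it was built
    with — the values the test-suite assertions check against.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    # V-domain fixtures
    for chain_kind in ("H", "L"):
        rec, truth = make_chain(chain_kind=chain_kind, seed=seed, record_id=f"ref-{chain_kind}")
        write_fasta([rec], out / f"chain_{chain_kind}.fasta")
        manifest[f"chain_{chain_kind}"] = {
            "file": f"chain_{chain_kind}.fasta",
            "numbering": [[n, ic, aa] for (n, ic), aa in truth],
        }
    anchor = 100
    rec, truth = make_chain(
        chain_kind="H", insertions=[(anchor, "DV")], seed=seed, record_id="H-ins-100ab"
    )
    write_fasta([rec], out / "chain_H_insertions.fasta")
    manifest["chain_H_insertions"] = {
        "file": "chain_H_insertions.fasta",
        "anchor": anchor,
        "n_insertions": 2,
        "numbering": [[n, ic, aa] for (n, ic), aa in truth],
    }

    # interface fixtures
    geometries = {
        "pi_pi": {"distance": 5.0, "angle": 75.0, "offset": 1.5},
        "hbond": {"da_distance": 2.4, "donor_angle": 160.0, "acceptor_angle": 150.0},
        "water_bridge": {"d_receptor": 2.7, "d_ligand": 2.7},
        "pi_cation": {"distance": 4.2},
    }
    for kind, params in geometries.items():
        model = make_interface(kind, **params)
        write_pdb(model, out / f"{kind}.pdb")
        manifest[kind] = {"file": f"{kind}.pdb", **params}

    # sensorgram fixtures at the engineered-variant rate scale
    ka, kd, rmax = 2.4e5, 4.2e-3, 1.0
    concs = [2e-8, 6e-8, 2e-7]
    traces = [
        simulate_sensorgram(ka, kd, c, rmax, noise_sd=0.01 * rmax, seed=seed + i)
        for i, c in enumerate(concs)
    ]
    sensorgrams_to_frame(traces).to_csv(out / "sensorgrams.csv", index=False)
    manifest["sensorgrams"] = {
        "file": "sensorgrams.csv", "ka": ka, "kd": kd, "rmax": rmax,
        "concentrations": concs, "noise_sd": 0.01,
    }

    # soft-randomized library fixture: one diversified CDR-like window
    template = (
        "GAAGTTCAGCTGGTTGAATCTGGTGGTGGTCTGGTTCAGCCTGGTGGTTCTCTG"
        "CGTCTGAGCTGTGCTGCTTCTGGTTTCACCTTCTCT"
    )
    design = soft_design(template, diversified_codons=[10, 11, 12, 13], wt_fraction=0.7)
    dna, proteins = sample_library(design, n_clones=200, seed=seed)
    write_fasta(
        [SequenceRecord(id=f"clone{i}", residues=s) for i, s in enumerate(dna)],
        out / "library_clones.fasta",
    )
    manifest["library"] = {
        "file": "library_clones.fasta",
        "template": template,
        "diversified_codons": [10, 11, 12, 13],
        "wt_fraction": 0.7,
        "n_clones": 200,
    }

    # selection-pool fixture: protein clones enriched for one substitution
    from .selection_analysis import EnrichmentModel, load_pool, simulate_selection

    rng = np.random.default_rng(seed + 17)
    template_aa = "DIQMTQSPSS"
    clones = []
    for _ in range(400):
        c = list(template_aa)
        if rng.random() < 0.10:
            c[4] = "Y"
        clones.append("".join(c))
    pool0 = load_pool("a", template_aa, clones)
    rounds = simulate_selection(
        pool0, EnrichmentModel(factors={(4, "Y"): 3.0}, rounds=3, seed=seed + 18)
    )
    write_fasta(
        [SequenceRecord(id=f"r3c{i}", residues=s) for i, s in enumerate(rounds[-1].clones)],
        out / "selection_pool.fasta",
    )
    manifest["selection_pool"] = {
        "file": "selection_pool.fasta",
        "template": template_aa,
        "substitution": [4, "Y"],
        "enrichment_factor": 3.0,
        "initial_frequency": 0.10,
        "rounds": 3,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
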