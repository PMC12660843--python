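"""Readers/writers for the standard formats the toolkit touches.

Sequences travel as FASTA (via Biopython), structures as fixed-column PDB
(via gemmi), tables as CSV with a header row, fit reports as JSON, and run
configuration as a YAML key-value file.  All floats written to tables are
serialized with 6 significant digits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("phabkit")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (amino acids or nucleotides, upper case)."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def _validate_alphabet(rec: SequenceRecord, alphabet: str) -> None:
    allowed = AA_ALPHABET if alphabet == "aa" else DNA_ALPHABET
    for i, ch in enumerate(rec.residues):
        if ch not in allowed:
            raise ValueError(
                f"record {rec.id!r}: character {ch!r} at position {i + 1} "
                f"is not in the {alphabet.upper()} alphabet"
            )


def read_fasta(path: str | Path, alphabet: str = "aa") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Parameters
    ----------
    path:
        FASTA file path.
    alphabet:
        ``"aa"`` (20 canonical residues + X) or ``"dna"`` (ACGTN).
        Off-alphabet characters raise :class:`ValueError` naming the
        offending character and its position.
    """
    if alphabet not in ("aa", "dna"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id {rec.id!r}", stacklevel=2)
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        sr = SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc)
        if not sr.residues:
            raise ValueError(f"record {sr.id!r} is empty")
        _validate_alphabet(sr, alphabet)
        records.append(sr)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    seqio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqio_records)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom of a :class:`StructureModel` (PDB-style fields)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str  # "" when absent
    chain_id: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetatm: bool = False

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code, self.residue_name)


@dataclass
class StructureModel:
    """A flat atom list parsed from / writable to fixed-column PDB."""

    atoms: list[Atom] = field(default_factory=list)
    name: str = "model"

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a model")
        for a in self.atoms:
            if not all(abs(c) < 1e6 and c == c for c in a.xyz):
                raise ValueError(f"non-finite coordinate in atom serial {a.serial}")

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    @property
    def waters(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_water]

    def residues(self) -> dict[tuple[str, int, str, str], list[Atom]]:
        """Group atoms by (chain, seq, icode, resname), preserving order."""
        out: dict[tuple[str, int, str, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out


def read_pdb(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM records of a PDB file into a :class:`StructureModel`.

    Waters (HOH/WAT) are retained and flagged via :attr:`Atom.is_water`.
    Elements missing from the element column are inferred from the atom name
    with a warning.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"no models found in {path}")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                elem = "H" if at.element.is_hydrogen else at.element.name.upper()
                if elem in ("", "X"):
                    elem = "".join(c for c in at.name if c.isalpha())[:1].upper()
                    warnings.warn(
                        f"element missing for atom {at.name!r}; inferred {elem!r}",
                        stacklevel=2,
                    )
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=elem,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        insertion_code=(res.seqid.icode or " ").strip(),
                        chain_id=chain.name,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                        is_hetatm=het,
                    )
                )
    return StructureModel(atoms=atoms, name=Path(path).stem)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as fixed-column PDB (3-decimal coords)."""
    # gemmi containers copy on add_*, so build bottom-up: atoms -> residue
    # -> chain -> model -> structure, each fully populated before insertion
    by_chain: dict[str, dict[tuple, list[Atom]]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain_id, {}).setdefault(a.residue_key, []).append(a)
    st = gemmi.Structure()
    st.name = model.name
    md = gemmi.Model("1")
    for chain_id, residues in by_chain.items():
        chain = gemmi.Chain(chain_id)
        for key, atoms in residues.items():
            res = gemmi.Residue()
            res.name = atoms[0].residue_name
            res.seqid = gemmi.SeqId(atoms[0].residue_seq, atoms[0].insertion_code or " ")
            res.het_flag = "H" if atoms[0].is_hetatm else "A"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.serial = a.serial
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.xyz)
                at.occ = a.occupancy
                at.b_iso = a.b_factor
                res.add_atom(at)
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Documented defaults per pipeline stage.  Unknown stages or keys are errors.
DEFAULT_CONFIG: dict[str, dict[str, object]] = {
    "global": {"seed": 0},
    "numbering": {"scheme": "kabat", "cdr_definition": "kabat", "min_score_fraction": 0.4},
    "library": {"wt_fraction": 0.7, "flank_length": 15},
    "kinetics": {"noise_sd": 0.0, "restarts": 3},
    "contacts": {
        "hbond_da_max": 2.5,
        "bridge_da_max": 2.8,
        "pi_cation_max": 4.5,
        "pi_pi_min": 3.5,
        "pi_pi_max": 5.0,
        "angle_min": 120.0,
        "angle_max": 180.0,
    },
    "sasa": {"probe_radius": 1.7, "n_points": 960},
}


@dataclass(frozen=True)
class RunConfig:
    """Stage -> parameter mapping with a global RNG seed.

    Resolution order: CLI flags override config-file values, which override
    the documented defaults in :data:`DEFAULT_CONFIG`.
    """

    stages: dict[str, dict[str, object]] = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return int(self.stages["global"]["seed"])  # type: ignore[arg-type]

    def get(self, stage: str, key: str):
        return self.stages[stage][key]

    def override(self, stage: str, **kwargs) -> "RunConfig":
        if stage not in self.stages:
            raise KeyError(f"unknown config stage {stage!r}")
        merged = {k: dict(v) for k, v in self.stages.items()}
        for key, val in kwargs.items():
            if key not in merged[stage]:
                raise KeyError(f"unknown parameter {key!r} for stage {stage!r}")
            merged[stage][key] = val
        return RunConfig(stages=merged)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config, validating every stage/key against the defaults."""
    stages = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config must be a mapping of stage -> {key: value}")
        for stage, params in user.items():
            if stage not in stages:
                raise KeyError(f"unknown config stage {stage!r}")
            if not isinstance(params, dict):
                raise ValueError(f"stage {stage!r} must map keys to values")
            for key, val in params.items():
                if key not in stages[stage]:
                    raise KeyError(f"unknown parameter {key!r} for stage {stage!r}")
                stages[stage][key] = val
    return RunConfig(stages=stages)


def log_stage(stage: str, config: RunConfig, **extra) -> None:
    """Log a stage's effective parameters and seed (called at stage start)."""
    params = dict(config.stages.get(stage, {}))
    params.update(extra)
    logger.info("stage=%s seed=%d params=%s", stage, config.seed, params)


def fmt_float(x: float) -> str:
    """Serialize a float with 6 significant digits (table convention)."""
    return f"{x:.6g}"
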