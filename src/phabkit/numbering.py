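"""Kabat and IMGT numbering of antibody variable domains.

The numbering algorithm aligns a query V-domain globally to a shipped
reference consensus (one per scheme and chain kind, packaged under
``phabkit/data``), transfers scheme positions across aligned columns, and
assigns insertion codes left-to-right at the scheme's canonical insertion
anchors (Kabat H 100a.., 52a.., 35a..; L 27a.., 95a..).  CDR segments whose
length differs from the reference are renumbered by the scheme's
length-based fill rule rather than by raw alignment columns, which is how
both Kabat and IMGT define loop numbering.

A query that cannot be aligned to the profile (score below 40% of the
reference self-score) is rejected as "not a V-domain".
"""

from __future__ import annotations

import functools
import math
import string
from dataclasses import dataclass, field
from importlib import resources

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import SequenceRecord

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
CDR_REGIONS = frozenset({"CDR1", "CDR2", "CDR3"})

#: Kabat CDR intervals (inclusive position numbers) per chain kind.
KABAT_CDR_INTERVALS = {
    "H": {"CDR1": (31, 35), "CDR2": (50, 65), "CDR3": (95, 102)},
    "L": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
}

#: IMGT unique-numbering region slots (identical for H and L).
IMGT_SLOTS = {
    "FR1": list(range(1, 27)),
    "CDR1": list(range(27, 39)),
    "FR2": list(range(39, 56)),
    "CDR2": list(range(56, 66)),
    "FR3": list(range(66, 105)),
    "CDR3": list(range(105, 118)),
    "FR4": list(range(118, 129)),
}

# Order in which IMGT framework slots are left empty when the framework is
# shorter than its slot capacity (FR gaps sit at the IMGT-standard places:
# position 10 in FR1, 73/81-84 in FR3, the tail of FR4).
IMGT_FR_DROP_ORDER = {
    "FR1": [10, 9, 8, 7, 6, 5],
    "FR2": [55, 54, 53, 52],
    "FR3": [81, 82, 83, 84, 73, 72, 71, 70],
    "FR4": [128, 127, 126, 125],
}

_MIN_SCORE_FRACTION = 0.4


class NotAVDomainError(ValueError):
    """Raised when a sequence cannot be numbered as a V-domain."""


@dataclass(frozen=True, order=False)
class NumberedPosition:
    """A scheme position such as Kabat H100a.

    Total order: number ascending, then no-insertion before 'a' < 'b' < ...
    """

    scheme: str
    number: int
    insertion: str = ""
    chain_kind: str = "H"

    def __post_init__(self):
        if self.scheme not in ("kabat", "imgt"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.chain_kind not in ("H", "L"):
            raise ValueError(f"chain_kind must be 'H' or 'L', got {self.chain_kind!r}")
        if self.number < 1:
            raise ValueError("position number must be positive")
        if self.insertion and (len(self.insertion) != 1 or self.insertion not in string.ascii_lowercase):
            raise ValueError(f"insertion code must be a single letter a-z, got {self.insertion!r}")

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.number, self.insertion)

    def __lt__(self, other: "NumberedPosition") -> bool:
        self._check_comparable(other)
        return self.sort_key < other.sort_key

    def __le__(self, other: "NumberedPosition") -> bool:
        self._check_comparable(other)
        return self.sort_key <= other.sort_key

    def _check_comparable(self, other: "NumberedPosition") -> None:
        if self.scheme != other.scheme or self.chain_kind != other.chain_kind:
            raise ValueError("cannot compare positions from different schemes/chains")

    def render(self, with_chain: bool = False) -> str:
        s = f"{self.number}{self.insertion}"
        return f"{s}^{self.chain_kind}" if with_chain else s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class NumberedChain:
    """An antibody V-domain with one scheme position per residue."""

    chain_kind: str
    scheme: str
    positions: tuple[tuple[NumberedPosition, str], ...]
    id: str = ""

    def __post_init__(self):
        keys = [p.sort_key for p, _ in self.positions]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("positions must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    def aa_at(self, pos: NumberedPosition) -> str | None:
        for p, aa in self.positions:
            if p.sort_key == pos.sort_key:
                return aa
        return None

    def position_map(self) -> dict[tuple[int, str], str]:
        return {p.sort_key: aa for p, aa in self.positions}


@dataclass(frozen=True)
class RegionMap:
    """FR1..FR4 / CDR1..CDR3 intervals partitioning a numbered chain."""

    chain_kind: str
    cdr_definition: str
    intervals: tuple[tuple[str, tuple[int, str], tuple[int, str]], ...]  # (name, lo_key, hi_key)

    def region_of(self, pos: NumberedPosition) -> str:
        key = pos.sort_key
        for name, lo, hi in self.intervals:
            if lo <= key <= hi:
                return name
        raise KeyError(f"position {pos} outside every region interval")

    def interval(self, name: str) -> tuple[tuple[int, str], tuple[int, str]]:
        for n, lo, hi in self.intervals:
            if n == name:
                return lo, hi
        raise KeyError(name)


@dataclass(frozen=True)
class _Reference:
    chain_kind: str
    scheme: str
    sequence: str
    #: 1-based inclusive residue-index span per region
    regions: dict[str, tuple[int, int]]
    #: Kabat: canonical insertion anchor (position number) per region
    anchors: dict[str, int] = field(default_factory=dict)

    def region_of_index(self, idx: int) -> str:
        for name, (lo, hi) in self.regions.items():
            if lo <= idx <= hi:
                return name
        raise KeyError(idx)

    def labels(self) -> list[int]:
        """Scheme position number for each reference residue (no insertions)."""
        out = [0] * len(self.sequence)
        for name, (lo, hi) in self.regions.items():
            n = hi - lo + 1
            if self.scheme == "kabat":
                nums = list(range(lo, hi + 1))  # Kabat number == residue index
            else:
                slots = IMGT_SLOTS[name]
                if name in CDR_REGIONS:
                    nums = _imgt_cdr_fill(slots, n)
                else:
                    nums = _imgt_fr_fill(slots, IMGT_FR_DROP_ORDER[name], n)
            for i, num in zip(range(lo, hi + 1), nums):
                out[i - 1] = num
        return out


def _imgt_cdr_fill(slots: list[int], n: int) -> list[int]:
    """Symmetric IMGT loop fill: gaps open in the middle of the loop."""
    if n > len(slots):
        raise ValueError("loop longer than slot capacity")
    front = math.ceil(n / 2)
    back = n - front
    return slots[:front] + (slots[len(slots) - back:] if back else [])


def _imgt_fr_fill(slots: list[int], drop_order: list[int], n: int) -> list[int]:
    if n > len(slots):
        raise ValueError("framework longer than slot capacity")
    drop = set(drop_order[: len(slots) - n])
    kept = [s for s in slots if s not in drop]
    if len(kept) != n:  # drop order exhausted; drop from the tail
        extra = len(kept) - n
        kept = kept[: len(kept) - extra]
    return kept


@functools.lru_cache(maxsize=None)
def _load_reference_data() -> dict:
    with resources.files("phabkit.data").joinpath("vdomain_references.yaml").open() as fh:
        return yaml.safe_load(fh)


@functools.lru_cache(maxsize=None)
def get_reference(chain_kind: str, scheme: str) -> _Reference:
    raw = _load_reference_data()["heavy" if chain_kind == "H" else "light"]
    spec = raw[scheme]
    return _Reference(
        chain_kind=chain_kind,
        scheme=scheme,
        sequence=raw["sequence"].replace(" ", ""),
        regions={k: tuple(v) for k, v in spec["regions"].items()},
        anchors=dict(spec.get("anchors", {})),
    )


@functools.lru_cache(maxsize=None)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    return al


def _letters(k: int) -> list[str]:
    if k > 26:
        raise ValueError("more than 26 insertions at one anchor")
    return list(string.ascii_lowercase[:k])


def _kabat_fill(slots: list[int], anchor: int, n: int) -> list[tuple[int, str]]:
    """Number ``n`` residues into Kabat ``slots`` with insertions at ``anchor``.

    Shorter-than-reference segments keep the slots nearest both segment ends
    (deletions open just after the anchor); longer segments overflow into
    insertion codes anchor+a, anchor+b, ... left to right.
    """
    ia = slots.index(anchor)
    if n <= len(slots):
        front = min(n, ia + 1)
        back = n - front
        nums = slots[:front] + (slots[len(slots) - back:] if back else [])
        return [(x, "") for x in nums]
    k = n - len(slots)
    out = [(x, "") for x in slots[: ia + 1]]
    out += [(anchor, c) for c in _letters(k)]
    out += [(x, "") for x in slots[ia + 1:]]
    return out


def _imgt_fill(region: str, n: int) -> list[tuple[int, str]]:
    slots = IMGT_SLOTS[region]
    if region in CDR_REGIONS:
        if n <= len(slots):
            return [(x, "") for x in _imgt_cdr_fill(slots, n)]
        front = math.ceil(len(slots) / 2)
        anchor = slots[front - 1]  # 111 for CDR3, 32 for CDR1, 60 for CDR2
        k = n - len(slots)
        out = [(x, "") for x in slots[:front]]
        out += [(anchor, c) for c in _letters(k)]
        out += [(x, "") for x in slots[front:]]
        return out
    if n <= len(slots):
        return [(x, "") for x in _imgt_fr_fill(slots, IMGT_FR_DROP_ORDER[region], n)]
    k = n - len(slots)
    out = [(x, "") for x in slots]
    out[-1:] = [(slots[-1], "")] + [(slots[-1], c) for c in _letters(k)]
    return out


def _query_to_ref_map(ref_seq: str, query: str) -> list[int | None]:
    """For each query residue, the aligned reference index (1-based) or None."""
    aln = _aligner().align(ref_seq, query)[0]
    mapping: list[int | None] = [None] * len(query)
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        for off in range(q1 - q0):
            mapping[q0 + off] = r0 + off + 1
    return mapping


def number_chain(
    seq: SequenceRecord | str,
    chain_kind: str,
    scheme: str = "kabat",
    min_score_fraction: float = _MIN_SCORE_FRACTION,
) -> NumberedChain:
    """Assign scheme positions to every residue of a V-domain sequence.

    Parameters
    ----------
    seq:
        The V-domain amino-acid sequence (60-150 residues).
    chain_kind:
        ``"H"`` or ``"L"``.
    scheme:
        ``"kabat"`` or ``"imgt"``.

    Raises
    ------
    NotAVDomainError
        If the alignment score against the reference profile falls below
        ``min_score_fraction`` of the reference self-score.
    """
    if isinstance(seq, SequenceRecord):
        rec_id, qseq = seq.id, seq.residues
    else:
        rec_id, qseq = "", str(seq)
    qseq = qseq.upper()
    if not (60 <= len(qseq) <= 150):
        raise NotAVDomainError(f"sequence length {len(qseq)} outside the V-domain range 60-150")
    ref = get_reference(chain_kind, scheme)
    al = _aligner()
    self_score = al.score(ref.sequence, ref.sequence)
    score = al.score(ref.sequence, qseq)
    if score < min_score_fraction * self_score:
        raise NotAVDomainError(
            f"not a V-domain: profile score {score:.0f} below "
            f"{min_score_fraction:.0%} of reference self-score {self_score:.0f}"
        )
    q2r = _query_to_ref_map(ref.sequence, qseq)
    if q2r[0] is None:
        raise NotAVDomainError("cannot number an N-terminal overhang before scheme position 1")

    # assign each query residue to a region; insertion runs attach to the
    # adjacent CDR when they sit on an FR/CDR boundary
    regions_of_query: list[str] = []
    last_ref = 0
    for i, r in enumerate(q2r):
        if r is not None:
            regions_of_query.append(ref.region_of_index(r))
            last_ref = r
        else:
            prev_region = ref.region_of_index(last_ref) if last_ref else "FR1"
            nxt = next((q2r[j] for j in range(i + 1, len(q2r)) if q2r[j] is not None), None)
            next_region = ref.region_of_index(nxt) if nxt is not None else prev_region
            if prev_region != next_region and next_region in CDR_REGIONS:
                regions_of_query.append(next_region)
            else:
                regions_of_query.append(prev_region)

    ref_labels = ref.labels()
    positions: list[tuple[NumberedPosition, str]] = []
    i = 0
    n_q = len(qseq)
    while i < n_q:
        region = regions_of_query[i]
        j = i
        has_insertion = False
        while j < n_q and regions_of_query[j] == region:
            if q2r[j] is None:
                has_insertion = True
            j += 1
        members = list(range(i, j))
        renumber = has_insertion or (scheme == "imgt" and region in CDR_REGIONS)
        if renumber:
            lo, hi = ref.regions[region]
            if scheme == "kabat":
                slots = list(range(lo, hi + 1))
                anchor = ref.anchors.get(region, slots[-1])
                labels = _kabat_fill(slots, anchor, len(members))
            else:
                labels = _imgt_fill(region, len(members))
        else:
            labels = [(ref_labels[q2r[m] - 1], "") for m in members]
        for m, (num, ins) in zip(members, labels):
            positions.append(
                (NumberedPosition(scheme=scheme, number=num, insertion=ins, chain_kind=chain_kind), qseq[m])
            )
        i = j

    nc = NumberedChain(chain_kind=chain_kind, scheme=scheme, positions=tuple(positions), id=rec_id)
    assert nc.sequence == qseq  # round-trip invariant
    return nc


def extract_regions(nc: NumberedChain, cdr_definition: str | None = None) -> RegionMap:
    """Partition a numbered chain into FR1..FR4 / CDR1..CDR3 intervals.

    ``cdr_definition`` defaults to the chain's numbering scheme and must be
    compatible with it (Kabat intervals are defined on Kabat numbers, IMGT
    intervals on IMGT numbers).
    """
    cdr_definition = cdr_definition or nc.scheme
    if cdr_definition not in ("kabat", "imgt"):
        raise ValueError(f"unknown CDR definition {cdr_definition!r}")
    if cdr_definition != nc.scheme:
        raise ValueError(
            f"chain numbered under {nc.scheme!r} is incompatible with "
            f"{cdr_definition!r} CDR boundaries; renumber first"
        )
    if cdr_definition == "kabat":
        cdrs = KABAT_CDR_INTERVALS[nc.chain_kind]
    else:
        cdrs = {k: (IMGT_SLOTS[k][0], IMGT_SLOTS[k][-1]) for k in CDR_REGIONS}
    c1, c2, c3 = cdrs["CDR1"], cdrs["CDR2"], cdrs["CDR3"]
    hi_key = lambda n: (n, "\x7f")  # any insertion code on n sorts below this
    lo_key = lambda n: (n, "")
    last = max((p.number for p, _ in nc.positions), default=200) + 1
    intervals = (
        ("FR1", (1, ""), hi_key(c1[0] - 1)),
        ("CDR1", lo_key(c1[0]), hi_key(c1[1])),
        ("FR2", lo_key(c1[1] + 1), hi_key(c2[0] - 1)),
        ("CDR2", lo_key(c2[0]), hi_key(c2[1])),
        ("FR3", lo_key(c2[1] + 1), hi_key(c3[0] - 1)),
        ("CDR3", lo_key(c3[0]), hi_key(c3[1])),
        ("FR4", lo_key(c3[1] + 1), hi_key(last)),
    )
    for _, lo, hi in intervals:
        if hi < lo:
            raise ValueError("region intervals collapsed; position table missing a boundary")
    return RegionMap(chain_kind=nc.chain_kind, cdr_definition=cdr_definition, intervals=intervals)


def chain_table(nc: NumberedChain, region_map: RegionMap | None = None) -> list[dict]:
    """Rows of (chain, scheme, position, insertion, aa, region) for CSV output."""
    rm = region_map or extract_regions(nc)
    rows = []
    for pos, aa in nc.positions:
        rows.append(
            {
                "chain_id": nc.id or nc.chain_kind,
                "scheme": nc.scheme,
                "position": pos.number,
                "insertion": pos.insertion,
                "aa": aa,
                "region": rm.region_of(pos),
            }
        )
    return rows
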