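"""CDR grafting and Vernier-zone back-mutation planning.

Humanization of a non-human antibody proceeds by grafting its six CDRs onto
a human acceptor framework (here, any acceptor numbered under the same
scheme), then selectively back-mutating framework "Vernier zone" residues
to the donor when the straight graft loses antigen binding.  All
coordinates are scheme positions (Kabat by default), and mutations render
in the conventional ``X##Y^chain`` notation, e.g. ``L46R^L``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .numbering import (
    CDR_REGIONS,
    NumberedChain,
    NumberedPosition,
    extract_regions,
)


@dataclass(frozen=True)
class VernierSet:
    """A set of framework Kabat positions eligible for back-mutation."""

    chain_kind: str
    positions: frozenset[NumberedPosition]

    def __contains__(self, item) -> bool:
        if isinstance(item, NumberedPosition):
            return any(p.sort_key == item.sort_key for p in self.positions)
        return any(p.number == item and not p.insertion for p in self.positions)

    def __iter__(self):
        return iter(sorted(self.positions, key=lambda p: p.sort_key))

    def __len__(self) -> int:
        return len(self.positions)


def load_vernier_set(chain_kind: str, path: str | Path | None = None) -> VernierSet:
    """Load a Vernier set from YAML (``heavy:``/``light:`` lists of Kabat numbers).

    With no path, the shipped Foote-Winter-derived table is used.
    """
    if path is None:
        with resources.files("phabkit.data").joinpath("vernier_kabat.yaml").open() as fh:
            data = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    numbers = data["heavy" if chain_kind == "H" else "light"]
    positions = frozenset(
        NumberedPosition(scheme="kabat", number=int(n), chain_kind=chain_kind) for n in numbers
    )
    return VernierSet(chain_kind=chain_kind, positions=positions)


def default_vernier_set(chain_kind: str) -> VernierSet:
    """The shipped curated Kabat Vernier positions for one chain kind."""
    return load_vernier_set(chain_kind)


@dataclass(frozen=True)
class Mutation:
    position: NumberedPosition
    from_aa: str
    to_aa: str

    def render(self) -> str:
        return f"{self.from_aa}{self.position.render()}{self.to_aa}^{self.position.chain_kind}"

    def __str__(self) -> str:  # pragma: no cover
        return self.render()


@dataclass(frozen=True)
class GraftPlan:
    """A CDR graft of a donor onto an acceptor framework, plus back-mutations."""

    donor_id: str
    acceptor_id: str
    chain_kind: str
    cdr_definition: str
    grafted_chain: NumberedChain
    back_mutations: tuple[Mutation, ...] = ()

    @property
    def grafted_sequence(self) -> str:
        return self.grafted_chain.sequence

    def render_mutations(self) -> list[str]:
        return [m.render() for m in self.back_mutations]


def _check_same_frame(a: NumberedChain, b: NumberedChain) -> None:
    if a.chain_kind != b.chain_kind:
        raise ValueError(f"chain_kind mismatch: {a.chain_kind!r} vs {b.chain_kind!r}")
    if a.scheme != b.scheme:
        raise ValueError(f"numbering scheme mismatch: {a.scheme!r} vs {b.scheme!r}")


def graft_cdrs(
    donor: NumberedChain,
    acceptor: NumberedChain,
    cdr_definition: str | None = None,
) -> GraftPlan:
    """Build the loop-grafted chain: donor CDRs on the acceptor framework.

    Donor CDR insertion codes are carried over, so a donor CDR longer than
    the acceptor's produces a length-changing graft.
    """
    _check_same_frame(donor, acceptor)
    cdr_definition = cdr_definition or donor.scheme
    regions = extract_regions(donor, cdr_definition)  # same intervals for both chains

    merged: list[tuple[NumberedPosition, str]] = []
    for pos, aa in acceptor.positions:
        if regions.region_of(pos) not in CDR_REGIONS:
            merged.append((pos, aa))
    for pos, aa in donor.positions:
        if regions.region_of(pos) in CDR_REGIONS:
            merged.append((pos, aa))
    merged.sort(key=lambda item: item[0].sort_key)

    grafted = NumberedChain(
        chain_kind=donor.chain_kind,
        scheme=donor.scheme,
        positions=tuple(merged),
        id=f"{donor.id or 'donor'}-CDRs-on-{acceptor.id or 'acceptor'}",
    )
    return GraftPlan(
        donor_id=donor.id or "donor",
        acceptor_id=acceptor.id or "acceptor",
        chain_kind=donor.chain_kind,
        cdr_definition=cdr_definition,
        grafted_chain=grafted,
    )


def apply_back_mutations(
    plan: GraftPlan,
    positions: Iterable[NumberedPosition | int],
    donor: NumberedChain,
) -> GraftPlan:
    """Back-mutate framework positions of the graft to the donor residue.

    Positions where donor and graft already agree are silently skipped.
    Requesting a CDR position is an error: Vernier back-mutation is a
    framework operation by definition.
    """
    regions = extract_regions(plan.grafted_chain, plan.cdr_definition)
    donor_map = donor.position_map()

    wanted: list[NumberedPosition] = []
    for p in positions:
        if isinstance(p, int):
            p = NumberedPosition(
                scheme=plan.grafted_chain.scheme, number=p, chain_kind=plan.chain_kind
            )
        wanted.append(p)

    new_positions = list(plan.grafted_chain.positions)
    mutations = list(plan.back_mutations)
    for p in wanted:
        if regions.region_of(p) in CDR_REGIONS:
            raise ValueError(f"{p.render()} is not a framework position")
        if p.sort_key not in donor_map:
            raise KeyError(f"position {p.render()} absent from donor chain")
        donor_aa = donor_map[p.sort_key]
        for i, (pos, aa) in enumerate(new_positions):
            if pos.sort_key == p.sort_key:
                if aa != donor_aa:
                    mutations.append(Mutation(position=pos, from_aa=aa, to_aa=donor_aa))
                    new_positions[i] = (pos, donor_aa)
                break
        else:
            raise KeyError(f"position {p.render()} absent from grafted chain")

    grafted = replace(plan.grafted_chain, positions=tuple(new_positions))
    return replace(plan, grafted_chain=grafted, back_mutations=tuple(mutations))


GAP = "-"


def diff_chains(
    a: NumberedChain, b: NumberedChain
) -> list[tuple[NumberedPosition, str, str]]:
    """Position-wise differences between two chains of the same frame.

    Returns (position, aa_in_a, aa_in_b) sorted by position order; positions
    present in only one chain are reported with ``"-"`` for the other.
    """
    _check_same_frame(a, b)
    map_a = {p.sort_key: (p, aa) for p, aa in a.positions}
    map_b = {p.sort_key: (p, aa) for p, aa in b.positions}
    out: list[tuple[NumberedPosition, str, str]] = []
    for key in sorted(set(map_a) | set(map_b)):
        pa = map_a.get(key)
        pb = map_b.get(key)
        aa_a = pa[1] if pa else GAP
        aa_b = pb[1] if pb else GAP
        if aa_a != aa_b:
            out.append(((pa or pb)[0], aa_a, aa_b))
    return out
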