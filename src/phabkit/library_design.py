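"""Soft-randomization phage-library mathematics and emitters.

A soft-randomized library dopes each wild-type nucleotide of the
diversified codons with the three alternatives: the synthesis resin mixes
70% of the wild-type base with 10% of each other base, which retains the
wild-type amino acid roughly half of the time while sampling diversity at
every targeted position.  This module computes the exact per-codon
amino-acid distributions by 64-codon enumeration, stop probabilities,
diversity statistics, the stop-template and mutagenic-oligo sequences used
for Kunkel-style construction, and a seeded desk-scale clone sampler.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

BASES = ("A", "C", "G", "T")
STOP = "*"
STOP_CODONS = ("TAA", "TAG", "TGA")


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class NucleotideMixture:
    """Per-base probabilities at one template position (sum to 1)."""

    probabilities: dict[str, float]
    wt_base: str

    def __post_init__(self):
        if self.wt_base not in BASES:
            raise ValueError(f"invalid base {self.wt_base!r}")
        if set(self.probabilities) != set(BASES):
            raise ValueError("mixture must assign a probability to each of A, C, G, T")
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("probabilities must be non-negative")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def p(self, base: str) -> float:
        return self.probabilities[base]

    @property
    def support(self) -> list[str]:
        return [b for b in BASES if self.probabilities[b] > 0]

    def serialize(self) -> str:
        """Percent notation, e.g. ``A70/C10/G10/T10`` (soft mixes have no IUPAC code)."""
        return "/".join(f"{b}{self.probabilities[b] * 100:g}" for b in BASES)


def fixed_mixture(base: str) -> NucleotideMixture:
    return NucleotideMixture(
        probabilities={b: (1.0 if b == base else 0.0) for b in BASES}, wt_base=base
    )


def soft_mixture(wt_base: str, wt_fraction: float = 0.7) -> NucleotideMixture:
    """The soft-randomization mixture: ``wt_fraction`` wild type, the rest split evenly."""
    if not (0.0 < wt_fraction <= 1.0):
        raise ValueError("wt_fraction must be in (0, 1]")
    other = (1.0 - wt_fraction) / 3.0
    return NucleotideMixture(
        probabilities={b: (wt_fraction if b == wt_base else other) for b in BASES},
        wt_base=wt_base,
    )


@dataclass(frozen=True)
class AADistribution:
    """Probability over the 20 amino acids plus STOP (``*``)."""

    probabilities: dict[str, float]

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"amino-acid probabilities sum to {total}, not 1")

    def p(self, aa: str) -> float:
        return self.probabilities.get(aa, 0.0)

    @property
    def stop_probability(self) -> float:
        return self.probabilities.get(STOP, 0.0)

    @property
    def support(self) -> list[str]:
        return sorted(aa for aa, p in self.probabilities.items() if p > 0)


def codon_distribution(m1, m2, m3) -> dict[str, float]:
    """P(codon) for all 64 codons under three independent base mixtures."""
    out = {}
    for b1, b2, b3 in itertools.product(BASES, repeat=3):
        p = m1.p(b1) * m2.p(b2) * m3.p(b3)
        if p > 0:
            out[b1 + b2 + b3] = p
    return out


def codon_aa_distribution(
    m1: NucleotideMixture, m2: NucleotideMixture, m3: NucleotideMixture
) -> AADistribution:
    """Exact amino-acid distribution of one diversified codon (64-codon enumeration)."""
    probs: dict[str, float] = {}
    for codon, p in codon_distribution(m1, m2, m3).items():
        aa = translate_codon(codon)
        probs[aa] = probs.get(aa, 0.0) + p
    return AADistribution(probabilities=probs)


def soft_codon_aa_distribution(wt_codon: str, wt_fraction: float = 0.7) -> AADistribution:
    return codon_aa_distribution(*(soft_mixture(b, wt_fraction) for b in wt_codon))


def stop_probability(m1, m2, m3) -> float:
    """P(TAA) + P(TAG) + P(TGA) under the three mixtures."""
    dist = codon_distribution(m1, m2, m3)
    return sum(dist.get(c, 0.0) for c in STOP_CODONS)


def sense_codons() -> list[str]:
    return [
        "".join(c)
        for c in itertools.product(BASES, repeat=3)
        if translate_codon("".join(c)) != STOP
    ]


def wt_retention_stats(wt_fraction: float = 0.7) -> dict:
    """Per-sense-codon P(wild-type amino acid retained) under soft randomization.

    Returns the per-codon table plus its mean and median, the figures usually
    quoted when a soft-randomized library is described as retaining the
    parental residue "roughly half the time".
    """
    table: dict[str, float] = {}
    for codon in sense_codons():
        wt_aa = translate_codon(codon)
        table[codon] = soft_codon_aa_distribution(codon, wt_fraction).p(wt_aa)
    values = np.array(sorted(table.values()))
    return {
        "per_codon": table,
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "wt_codon_probability": wt_fraction**3,
    }


# ---------------------------------------------------------------------------
# Library design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryDesign:
    """An in-frame template CDS with per-codon nucleotide mixtures."""

    template_cds: str
    diversified_codons: dict[int, tuple[NucleotideMixture, NucleotideMixture, NucleotideMixture]]
    flank_length: int = 15

    def __post_init__(self):
        cds = self.template_cds.upper()
        object.__setattr__(self, "template_cds", cds)
        if len(cds) % 3 != 0:
            raise ValueError("template CDS length must be divisible by 3")
        if any(b not in BASES for b in cds):
            raise ValueError("template CDS must be unambiguous DNA")
        n_codons = len(cds) // 3
        for idx in self.diversified_codons:
            if not (0 <= idx < n_codons):
                raise ValueError(f"diversified codon index {idx} out of range")
        protein = str(Seq(cds).translate())
        if STOP in protein[:-1]:
            raise ValueError("template CDS contains an internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.template_cds) // 3

    def codon(self, idx: int) -> str:
        return self.template_cds[3 * idx: 3 * idx + 3]

    def mixtures_at(self, idx: int):
        if idx in self.diversified_codons:
            return self.diversified_codons[idx]
        return tuple(fixed_mixture(b) for b in self.codon(idx))


def soft_design(
    template_cds: str,
    diversified_codons: Sequence[int],
    wt_fraction: float = 0.7,
    flank_length: int = 15,
) -> LibraryDesign:
    """Convenience constructor: soft-randomize the listed codons of a CDS."""
    cds = template_cds.upper()
    mixtures = {
        int(i): tuple(soft_mixture(b, wt_fraction) for b in cds[3 * i: 3 * i + 3])
        for i in diversified_codons
    }
    if len(mixtures) != len(diversified_codons):
        raise ValueError("diversified codon indices must be unique")
    return LibraryDesign(template_cds=cds, diversified_codons=mixtures, flank_length=flank_length)


def build_stop_template(template_cds: str, regions: Sequence[tuple[int, int]]) -> str:
    """Replace the first codon of each mutagenized region with TAA.

    The stop template guarantees that only clones repaired by a mutagenic
    oligo express full-length protein, removing wild-type background from
    the library.  Regions are (start, end) codon-index ranges, inclusive,
    and must not overlap.
    """
    cds = template_cds.upper()
    n_codons = len(cds) // 3
    occupied: set[int] = set()
    starts = []
    for start, end in regions:
        if not (0 <= start <= end < n_codons):
            raise ValueError(f"region ({start}, {end}) outside CDS")
        span = set(range(start, end + 1))
        if span & occupied:
            raise ValueError("mutagenized regions overlap")
        occupied |= span
        starts.append(start)
    out = list(cds)
    for start in starts:
        out[3 * start: 3 * start + 3] = "TAA"
    return "".join(out)


@dataclass(frozen=True)
class OligoSpec:
    """A mutagenic oligo: exact flanks plus explicit per-position mixtures."""

    region: tuple[int, int]
    flank5: str
    flank3: str
    positions: tuple[tuple[int, NucleotideMixture], ...]  # (nt index in CDS, mixture)
    reverse_complement: bool = False

    def serialize_positions(self) -> list[str]:
        return [m.serialize() for _, m in self.positions]

    @property
    def template_strand_sequence(self) -> str:
        """Most-probable-base rendering (flanks exact, mixtures collapsed to wt)."""
        core = "".join(m.wt_base for _, m in self.positions)
        return self.flank5 + core + self.flank3


def design_oligo(
    design: LibraryDesign,
    region: tuple[int, int],
    reverse_complement: bool = False,
) -> OligoSpec:
    """Emit the mutagenic oligo covering one codon-index region.

    The flanks are exact template substrings of length ``design.flank_length``
    (they anneal to the stop template and repair its stop codon); diversified
    positions are emitted as explicit percent mixtures, since soft
    randomization is not expressible in IUPAC degeneracy codes.
    """
    start, end = region
    if not (0 <= start <= end < design.n_codons):
        raise ValueError(f"region ({start}, {end}) outside CDS")
    nt_start, nt_end = 3 * start, 3 * (end + 1)
    if nt_start - design.flank_length < 0 or nt_end + design.flank_length > len(design.template_cds):
        raise ValueError("flank extends past the CDS")
    flank5 = design.template_cds[nt_start - design.flank_length: nt_start]
    flank3 = design.template_cds[nt_end: nt_end + design.flank_length]
    positions = []
    for codon_idx in range(start, end + 1):
        for k, mix in enumerate(design.mixtures_at(codon_idx)):
            positions.append((3 * codon_idx + k, mix))
    return OligoSpec(
        region=(start, end),
        flank5=flank5,
        flank3=flank3,
        positions=tuple(positions),
        reverse_complement=reverse_complement,
    )


def apply_oligo(stop_template: str, oligo: OligoSpec, core: str | None = None) -> str:
    """Substitute an oligo's covered region into a stop template (wt core by default)."""
    start = oligo.positions[0][0]
    end = oligo.positions[-1][0] + 1
    core = core or "".join(m.wt_base for _, m in oligo.positions)
    if len(core) != end - start:
        raise ValueError("core length mismatch")
    return stop_template[:start] + core + stop_template[end:]


# ---------------------------------------------------------------------------
# Sampling and diversity
# ---------------------------------------------------------------------------

def sample_library(
    design: LibraryDesign, n_clones: int, seed: int | np.random.Generator = 0
) -> tuple[list[str], list[str]]:
    """Draw clones from the library distribution (desk-scale emulation).

    Each diversified base is drawn independently from its mixture; fixed
    positions are copied from the template.  Deterministic for a fixed seed.
    Returns (DNA clones, translated proteins).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = np.array(list(design.template_cds))
    clones = np.tile(template, (n_clones, 1))
    base_arr = np.array(BASES)
    for idx in sorted(design.diversified_codons):
        for k, mix in enumerate(design.diversified_codons[idx]):
            col = 3 * idx + k
            probs = np.array([mix.p(b) for b in BASES])
            clones[:, col] = base_arr[rng.choice(4, size=n_clones, p=probs)]
    dna = ["".join(row) for row in clones]
    proteins = [str(Seq(s).translate()) for s in dna]
    return dna, proteins


def diversity_report(design: LibraryDesign, sample_size: int | None = None,
                     enumeration_cap: int = 200_000, seed: int = 0,
                     mc_draws: int = 20_000) -> dict:
    """Combinatorial and expected-sampled diversity of a design.

    ``theoretical_aa_diversity`` counts amino-acid sequences with non-zero
    probability (product of per-position support sizes).  When
    ``sample_size`` is given, the expected number of distinct protein
    sequences in a sample of that size is computed by Poissonization,
    E[#distinct] = sum_s (1 - exp(-n p_s)): exactly when the support is
    below ``enumeration_cap``, otherwise by importance sampling from the
    library distribution (a documented approximation).
    """
    dists = [
        codon_aa_distribution(*design.diversified_codons[i])
        for i in sorted(design.diversified_codons)
    ]
    support_sizes = [len(d.support) for d in dists]
    theoretical = math.prod(support_sizes)
    report = {
        "n_diversified_codons": len(dists),
        "per_codon_support": support_sizes,
        "theoretical_aa_diversity": theoretical,
        "stop_probability_any": 1.0 - float(np.prod([1.0 - d.stop_probability for d in dists])),
    }
    if sample_size is not None:
        n = sample_size
        supports = [[(aa, d.p(aa)) for aa in d.support] for d in dists]
        if theoretical <= enumeration_cap:
            expected = 0.0
            for combo in itertools.product(*supports) if supports else [()]:
                p = math.prod(pr for _, pr in combo) if combo else 1.0
                expected += 1.0 - math.exp(-n * p)
            report["expected_distinct_sampled"] = expected
            report["expected_distinct_method"] = "exact-poissonization"
        else:
            rng = np.random.default_rng(seed)
            logps = np.zeros(mc_draws)
            for d in dists:
                aas = d.support
                probs = np.array([d.p(a) for a in aas])
                draws = rng.choice(len(aas), size=mc_draws, p=probs)
                logps += np.log(probs[draws])
            p_s = np.exp(logps)
            report["expected_distinct_sampled"] = float(
                np.mean((1.0 - np.exp(-n * p_s)) / p_s)
            )
            report["expected_distinct_method"] = "importance-sampling"
    return report
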