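"""Analysis of clone pools from phage affinity selections.

After several rounds of selection, surviving clones are sequenced and
compared position-by-position with the parental template: the substitution
matrix (counts of each non-template residue per scheme position per pool)
summarizes what the selection enriched, the template fraction measures how
completely the selection moved away from the parent, and per-substitution
2x2 association tests make the usual "this substitution correlates with
binding" claim computable.  A seeded multi-round selection simulator
provides ground truth for end-to-end testing of the analyzers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .numbering import NumberedChain


@dataclass(frozen=True)
class ClonePool:
    """Equal-length protein clones aligned to a template (substitution-only)."""

    pool_id: str
    template: str
    clones: tuple[str, ...]
    n_rejected_indels: int = 0

    def __len__(self) -> int:
        return len(self.clones)


def load_pool(pool_id: str, template: str, clones: Iterable[str]) -> ClonePool:
    """Build a pool, rejecting (and counting) clones whose length differs.

    Selections built by soft randomization are substitution-only, so
    length-changed clones are sequencing artifacts; they are excluded with a
    count rather than aligned.
    """
    kept, rejected = [], 0
    for c in clones:
        if len(c) == len(template):
            kept.append(c.upper())
        else:
            rejected += 1
    if not kept:
        raise ValueError(f"pool {pool_id!r} has no clones matching the template length")
    return ClonePool(
        pool_id=pool_id, template=template.upper(), clones=tuple(kept),
        n_rejected_indels=rejected,
    )


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Counts of each amino acid per position for one pool.

    Rows are keyed by scheme position labels (e.g. Kabat ``"100a"``) when a
    numbering is supplied, else by 1-based sequence index.
    """

    pool_id: str
    position_labels: tuple[str, ...]
    template_aa: tuple[str, ...]
    counts: tuple[Mapping[str, int], ...]
    n_clones: int

    def substitution_count(self, label: str, aa: str) -> int:
        i = self.position_labels.index(label)
        return self.counts[i].get(aa, 0)

    def substitution_frequency(self, label: str, aa: str) -> float:
        return self.substitution_count(label, aa) / self.n_clones

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, wt, cnt in zip(self.position_labels, self.template_aa, self.counts):
            for aa, n in sorted(cnt.items()):
                if aa != wt and n > 0:
                    rows.append(
                        {"position": label, "template_aa": wt, "aa": aa,
                         "count": n, "frequency": n / self.n_clones}
                    )
        return pd.DataFrame(rows, columns=["position", "template_aa", "aa", "count", "frequency"])


def build_substitution_matrix(
    pool: ClonePool, numbering: NumberedChain | None = None
) -> SubstitutionMatrix:
    """Count every amino acid per position across a pool's clones."""
    if numbering is not None:
        if len(numbering) != len(pool.template):
            raise ValueError(
                f"template length {len(pool.template)} does not match "
                f"numbering length {len(numbering)}"
            )
        labels = tuple(p.render() for p, _ in numbering.positions)
    else:
        labels = tuple(str(i + 1) for i in range(len(pool.template)))
    counts: list[dict[str, int]] = [dict() for _ in pool.template]
    for clone in pool.clones:
        for i, aa in enumerate(clone):
            counts[i][aa] = counts[i].get(aa, 0) + 1
    return SubstitutionMatrix(
        pool_id=pool.pool_id,
        position_labels=labels,
        template_aa=tuple(pool.template),
        counts=tuple(counts),
        n_clones=len(pool),
    )


def template_fraction(pool: ClonePool) -> float:
    """Fraction of clones identical to the template (0 after a hard selection)."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    return sum(1 for c in pool.clones if c == pool.template) / len(pool)


def fold_change(absorbance_variant, absorbance_reference):
    """Fold change in absorbance over a reference clone (vectorized)."""
    ref = np.asarray(absorbance_reference, dtype=float)
    var = np.asarray(absorbance_variant, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference absorbance must be positive")
    out = var / ref
    return float(out) if out.ndim == 0 else out


def _bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def substitution_binding_association(
    matrix_pool: ClonePool,
    binder_labels: Sequence[bool],
    numbering: NumberedChain | None = None,
    min_count: int = 1,
) -> pd.DataFrame:
    """Per-substitution 2x2 association with an external binder/non-binder label.

    For every substitution observed at least ``min_count`` times the 2x2
    table [with/without substitution x binder/non-binder] is scored with a
    Haldane-corrected odds ratio and a two-sided Fisher exact p; q-values
    are Benjamini-Hochberg across all tested substitutions.
    """
    labels = np.asarray(binder_labels, dtype=bool)
    if len(labels) != len(matrix_pool):
        raise ValueError("one binder label per clone is required")
    if labels.all() or (~labels).all():
        raise ValueError("no contrast: all clones share the same binder label")
    if numbering is not None:
        pos_labels = [p.render() for p, _ in numbering.positions]
    else:
        pos_labels = [str(i + 1) for i in range(len(matrix_pool.template))]

    clones = np.array([list(c) for c in matrix_pool.clones])
    template = np.array(list(matrix_pool.template))
    rows = []
    for i in range(clones.shape[1]):
        col = clones[:, i]
        for aa in sorted(set(col) - {template[i]}):
            has = col == aa
            if has.sum() < min_count:
                continue
            a = int(np.sum(has & labels))       # substitution & binder
            b = int(np.sum(has & ~labels))      # substitution & non-binder
            c = int(np.sum(~has & labels))
            d = int(np.sum(~has & ~labels))
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"position": pos_labels[i], "template_aa": template[i], "aa": aa,
                 "n_with": a + b, "binder_with": a, "binder_without": c,
                 "odds_ratio": odds, "p_value": float(p)}
            )
    df = pd.DataFrame(
        rows,
        columns=["position", "template_aa", "aa", "n_with", "binder_with",
                 "binder_without", "odds_ratio", "p_value"],
    )
    if len(df):
        df["q_value"] = _bh_adjust(df["p_value"].to_numpy())
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# Selection simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentModel:
    """Multiplicative per-substitution fitness for the selection simulator.

    ``factors`` maps (0-based position, amino acid) to a strictly positive
    enrichment factor per round; a clone's weight is the product over the
    substitutions it carries.  Factor 1 is neutral, >1 enriched, <1 depleted.
    """

    factors: Mapping[tuple[int, str], float]
    rounds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("enrichment factors must be strictly positive")

    def clone_weight(self, clone: str, template: str) -> float:
        w = 1.0
        for (i, aa), f in self.factors.items():
            if clone[i] == aa and template[i] != aa:
                w *= f
        return w


def simulate_selection(
    initial: ClonePool, model: EnrichmentModel
) -> list[ClonePool]:
    """Resample a pool for ``model.rounds`` rounds with fitness-proportional weights.

    Each round draws ``len(pool)`` clones with replacement, with probability
    proportional to the product of enrichment factors of the substitutions a
    clone carries (a Wright-Fisher-style selection round).  Seeded and
    deterministic.  Returns the pool after each round.
    """
    rng = np.random.default_rng(model.seed)
    pools = []
    current = list(initial.clones)
    for rnd in range(1, model.rounds + 1):
        weights = np.array([model.clone_weight(c, initial.template) for c in current])
        probs = weights / weights.sum()
        idx = rng.choice(len(current), size=len(current), p=probs)
        current = [current[i] for i in idx]
        pools.append(
            ClonePool(
                pool_id=f"{initial.pool_id}-r{rnd}",
                template=initial.template,
                clones=tuple(current),
            )
        )
    return pools


def expected_frequency_trajectory(f0: float, factor: float, rounds: int) -> list[float]:
    """Deterministic expectation for one substitution under selection.

    One round maps frequency f to f' = s f / (s f + (1 - f)) where s is the
    enrichment factor: the mean-field recursion the stochastic simulator
    fluctuates around (e.g. s=3: f' = 3f / (1 + 2f)).
    """
    out = [f0]
    f = f0
    for _ in range(rounds):
        f = factor * f / (factor * f + (1.0 - f))
        out.append(f)
    return out


def estimate_enrichment_factor(frequencies: Sequence[float]) -> float:
    """Recover the per-round enrichment factor from a frequency trajectory.

    Inverts the mean-field recursion round by round on the odds scale
    (odds' = s * odds) and returns the geometric mean of the per-round
    ratios, ignoring rounds where the frequency is pinned at 0 or 1.
    """
    ratios = []
    for f_prev, f_next in zip(frequencies, frequencies[1:]):
        if 0.0 < f_prev < 1.0 and 0.0 < f_next < 1.0:
            odds_prev = f_prev / (1.0 - f_prev)
            odds_next = f_next / (1.0 - f_next)
            ratios.append(odds_next / odds_prev)
    if not ratios:
        raise ValueError("trajectory has no informative rounds")
    return float(np.exp(np.mean(np.log(ratios))))
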