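"""Set algebra over per-condition DE gene sets.

Conditions are (timepoint, dose) pairs; each carries a set of DE genes with
their fold-change sign.  The operations here mirror the descriptive
questions asked of such collections: pairwise overlap (Venn partitions),
all-by-all overlap matrices, the non-redundant union with dose categories,
genes DE at every timepoint, and the temporal-shift pattern in which a
high-dose response reappears later at the low dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import DEFAULT_TIMEPOINTS, DEProfile, condition_name, parse_condition

__all__ = [
    "Condition",
    "DESetCollection",
    "VennPartition",
    "TemporalShiftResult",
    "venn_partition",
    "overlap_matrix",
    "union_categories",
    "always_de",
    "temporal_shift_fraction",
]

Condition = tuple[str, int]  # (timepoint label, dose in nM)


@dataclass(frozen=True)
class VennPartition:
    """Two-set partition counts with the overlap percentage.

    ``overlap_pct`` is 100 * |A n B| / |A u B|; an empty union is flagged
    and reported as 0.
    """

    only_a: int
    shared: int
    only_b: int

    @property
    def union_size(self) -> int:
        return self.only_a + self.shared + self.only_b

    @property
    def empty_union(self) -> bool:
        return self.union_size == 0

    @property
    def overlap_pct(self) -> float:
        if self.empty_union:
            return 0.0
        return 100.0 * self.shared / self.union_size


def venn_partition(a: Iterable[str], b: Iterable[str]) -> VennPartition:
    """Partition two gene sets into exclusive and shared counts."""
    a, b = set(a), set(b)
    shared = len(a & b)
    return VennPartition(only_a=len(a) - shared, shared=shared, only_b=len(b) - shared)


@dataclass(frozen=True)
class DESetCollection:
    """Per-condition signed DE gene sets over an ordered timepoint vocabulary."""

    sets: Mapping[Condition, Mapping[str, int]]  # condition -> {gene: sign in {+1,-1}}
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        for cond, genes in self.sets.items():
            tp, _ = cond
            if tp not in self.timepoints:
                raise ValueError(f"condition {cond} uses timepoint outside vocabulary")
            bad = {g: s for g, s in genes.items() if s not in (1, -1)}
            if bad:
                raise ValueError(f"condition {cond}: signs must be +1/-1, got {bad}")

    @property
    def conditions(self) -> list[Condition]:
        return sorted(self.sets, key=lambda c: (self.timepoints.index(c[0]), c[1]))

    def doses(self) -> list[int]:
        return sorted({d for _, d in self.sets})

    def genes(self, cond: Condition) -> set[str]:
        return set(self.sets.get(cond, {}))

    def signed(self, cond: Condition) -> dict[str, int]:
        return dict(self.sets.get(cond, {}))

    @classmethod
    def from_profile(
        cls, profile: DEProfile, timepoints: Sequence[str] = DEFAULT_TIMEPOINTS
    ) -> "DESetCollection":
        """Build from a DE profile whose columns are ``D{t}_{dose}nM`` labels."""
        sign = profile.sign
        sets: dict[Condition, dict[str, int]] = {}
        for col in sign.columns:
            cond = parse_condition(col)
            s = sign[col]
            sets[cond] = {g: int(v) for g, v in s[s != 0].items()}
        return cls(sets, tuple(timepoints))

    def write(self, path: str | Path) -> None:
        rows = [
            (condition_name(*cond), g, s)
            for cond in self.conditions
            for g, s in sorted(self.sets[cond].items())
        ]
        pd.DataFrame(rows, columns=["condition", "gene", "sign"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, timepoints: Sequence[str] = DEFAULT_TIMEPOINTS) -> "DESetCollection":
        df = pd.read_csv(path, sep="\t")
        sets: dict[Condition, dict[str, int]] = {}
        for _, row in df.iterrows():
            cond = parse_condition(row["condition"])
            sets.setdefault(cond, {})[str(row["gene"])] = int(row.get("sign", 1))
        return cls(sets, tuple(timepoints))


def overlap_matrix(coll: DESetCollection) -> pd.DataFrame:
    """All-by-all overlap percentages between condition DE sets."""
    conds = coll.conditions
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions for an overlap matrix")
    labels = [condition_name(*c) for c in conds]
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, ci in enumerate(conds):
        for j, cj in enumerate(conds):
            if j < i:
                continue
            pct = venn_partition(coll.genes(ci), coll.genes(cj)).overlap_pct
            out.iat[i, j] = out.iat[j, i] = pct
    return out


def union_categories(
    coll: DESetCollection, dose_low: int = 10, dose_high: int = 100
) -> tuple[set[str], dict[str, str]]:
    """Non-redundant DE union with per-gene dose categories.

    A gene is ``both_doses`` if DE at some timepoint at the low dose and at
    some (possibly different) timepoint at the high dose; otherwise
    ``only_low`` / ``only_high``.  The categories partition the union.
    """
    doses_present = set(coll.doses())
    missing = {dose_low, dose_high} - doses_present
    if missing:
        raise ValueError(f"dose(s) {sorted(missing)} absent from collection {sorted(doses_present)}")
    at_low: set[str] = set()
    at_high: set[str] = set()
    for (tp, dose), genes in coll.sets.items():
        if dose == dose_low:
            at_low |= set(genes)
        elif dose == dose_high:
            at_high |= set(genes)
    union = at_low | at_high
    cats = {}
    for g in union:
        if g in at_low and g in at_high:
            cats[g] = "both_doses"
        elif g in at_low:
            cats[g] = "only_low"
        else:
            cats[g] = "only_high"
    return union, cats


def always_de(coll: DESetCollection, dose: int, sign_aware: bool = False) -> set[str]:
    """Genes DE at *every* timepoint present for the given dose.

    With ``sign_aware`` the fold-change sign must also be constant.
    """
    conds = [c for c in coll.conditions if c[1] == dose]
    if not conds:
        return set()
    result = coll.genes(conds[0])
    for c in conds[1:]:
        result &= coll.genes(c)
    if sign_aware:
        result = {g for g in result if len({coll.sets[c][g] for c in conds}) == 1}
    return result


@dataclass(frozen=True)
class TemporalShiftResult:
    """Outcome of the temporal-shift scan, with the rule that produced it."""

    shifted_genes: frozenset[str]
    denominator_genes: frozenset[str]
    definition: str

    @property
    def n_shifted(self) -> int:
        return len(self.shifted_genes)

    @property
    def denominator(self) -> int:
        return len(self.denominator_genes)

    @property
    def fraction(self) -> float:
        return self.n_shifted / self.denominator if self.denominator else 0.0


def temporal_shift_fraction(
    coll: DESetCollection,
    dose_high: int = 100,
    dose_low: int = 10,
    sign_matched: bool = True,
    require_absent_at_i: bool = True,
) -> TemporalShiftResult:
    """Fraction of high-dose DE genes whose response reappears later at low dose.

    Default rule: a gene is *shifted* iff for some non-final timepoint index
    i it is DE at the high dose at i, DE (same sign if ``sign_matched``) at
    the low dose at some strictly later index j, and (if
    ``require_absent_at_i``) not DE at the low dose at i itself.  The
    denominator is every gene DE at the high dose at any non-final
    timepoint.  The rule applied is recorded in the result metadata.
    """
    tps = [t for t in coll.timepoints if any(c[0] == t for c in coll.conditions)]
    if len(tps) < 2:
        raise ValueError("temporal-shift scan needs at least 2 timepoints with conditions")
    high = {t: coll.signed((t, dose_high)) for t in tps}
    low = {t: coll.signed((t, dose_low)) for t in tps}

    denominator: set[str] = set()
    shifted: set[str] = set()
    for i, tp_i in enumerate(tps[:-1]):
        for gene, sgn in high[tp_i].items():
            denominator.add(gene)
            if require_absent_at_i and gene in low[tp_i]:
                continue
            for tp_j in tps[i + 1 :]:
                s_low = low[tp_j].get(gene)
                if s_low is not None and (not sign_matched or s_low == sgn):
                    shifted.add(gene)
                    break
    definition = (
        f"DE at dose {dose_high} at non-final timepoint i, "
        f"DE{' with same sign' if sign_matched else ''} at dose {dose_low} at some j>i"
        + (f", not DE at dose {dose_low} at i" if require_absent_at_i else "")
        + f"; denominator = genes DE at dose {dose_high} at any non-final timepoint"
    )
    return TemporalShiftResult(frozenset(shifted), frozenset(denominator), definition)
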