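"""Two-unranked-list gene-set enrichment.

For a target list of n genes drawn from a background of N, and a term
annotating B background genes of which b are in the target, the enrichment
fold is E = (b/n)/(B/N) and the p-value is the exact hypergeometric upper
tail P(X >= b).  Benjamini-Hochberg q-values are computed over the emitted
records of each run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TermAnnotation", "read_gmt", "write_gmt", "enrichment_fold", "enrich", "recurrent_terms"]


@dataclass(frozen=True)
class TermAnnotation:
    """Flat gene-set annotation: term id -> (name, gene set)."""

    terms: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        empty = [t for t, (_, genes) in self.terms.items() if not genes]
        if empty:
            raise ValueError(f"term(s) with empty gene sets: {sorted(empty)}")

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


def read_gmt(path: str | Path) -> TermAnnotation:
    """Parse a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a term are collapsed; a duplicate term id is an
    error, as is a line with fewer than 3 fields.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3")
            term_id, desc = fields[0], fields[1]
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            genes = frozenset(g for g in fields[2:] if g)
            terms[term_id] = (desc, genes)
    return TermAnnotation(terms)


def write_gmt(terms: TermAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(terms.terms):
            name, genes = terms.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def enrichment_fold(b: int, n: int, B: int, N: int) -> float:
    """E = (b/n)/(B/N): target-list term frequency over background frequency."""
    if n <= 0 or B <= 0 or N <= 0:
        raise ValueError("n, B and N must be positive")
    return (b / n) / (B / N)


def enrich(
    target: Iterable[str],
    background: Iterable[str],
    terms: TermAnnotation,
    min_b: int = 3,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every term in the target list.

    The target must be a subset of the background; term gene sets are
    intersected with the background before counting.  Records with b >=
    min_b are emitted, BH-corrected, and sorted by ascending p (ties by
    term id).  Columns: term, name, b, n, B, N, E, p, q.
    """
    target, background = set(target), set(background)
    stray = target - background
    if stray:
        raise ValueError(f"target gene(s) missing from background: {sorted(stray)[:5]}")
    if not background:
        raise ValueError("background is empty")
    N, n = len(background), len(target)
    rows = []
    for term_id in sorted(terms.terms):
        name, genes = terms.terms[term_id]
        in_bg = genes & background
        B = len(in_bg)
        b = len(in_bg & target)
        if b < min_b or B == 0:
            continue
        p = float(stats.hypergeom.sf(b - 1, N, B, n))
        rows.append({"term": term_id, "name": name, "b": b, "n": n, "B": B, "N": N,
                     "E": enrichment_fold(b, n, B, N), "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "name", "b", "n", "B", "N", "E", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def recurrent_terms(
    tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    q_max: float = 0.05,
    min_conditions: int = 1,
) -> pd.Series:
    """Terms significant (q <= q_max) in >= min_conditions enrichment tables."""
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    if len(tables) == 0:
        raise ValueError("need at least one enrichment table")
    counts: dict[str, int] = {}
    for df in tables:
        if len(df) == 0:
            continue
        for term in df.loc[df["q"] <= q_max, "term"]:
            counts[term] = counts.get(term, 0) + 1
    s = pd.Series(counts, name="n_conditions", dtype=int).sort_index()
    return s[s >= min_conditions].sort_values(ascending=False, kind="stable")
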