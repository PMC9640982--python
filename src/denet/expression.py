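"""Count-table IO, normalization, sample summaries and fold-change DE calls.

One library per condition (no biological replicates) rules out
variance-based differential-expression tests: there is no within-group
variance to estimate.  Differential expression is therefore called on the
magnitude of the log2 fold change between a treated sample and its matched
control, computed on median-of-ratios normalized counts with a pseudocount.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "StudyDesign",
    "DEProfile",
    "Contrast",
    "DEFAULT_TIMEPOINTS",
    "read_counts",
    "size_factors",
    "normalize_log",
    "sample_distance_matrix",
    "pca",
    "default_contrasts",
    "log2_fold_changes",
    "call_de",
    "marker_panel_matrix",
    "condition_name",
    "parse_condition",
]

#: Ordered timepoint vocabulary of the differentiation time course.
DEFAULT_TIMEPOINTS: tuple[str, ...] = ("D0", "D4", "D9", "D12", "D18", "D28")

#: Doses in nM used in the study design.
DEFAULT_DOSES: tuple[int, ...] = (0, 10, 100)

_CONDITION_RE = re.compile(r"^(?P<tp>[A-Za-z]\w*?)_(?P<dose>\d+)nM$")


def condition_name(timepoint: str, dose_nM: int) -> str:
    """Canonical condition label, e.g. ``D4_10nM``."""
    return f"{timepoint}_{dose_nM}nM"


def parse_condition(name: str) -> tuple[str, int]:
    """Invert :func:`condition_name`; raises ``ValueError`` on other labels."""
    m = _CONDITION_RE.match(name)
    if m is None:
        raise ValueError(f"not a condition label of the form 'D4_10nM': {name!r}")
    return m.group("tp"), int(m.group("dose"))


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Gene and sample identifiers are ordered and unique; the count block has
    matching dimensions.  Invariants are enforced at construction.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {label} id(s): {', '.join(sorted(dupes))}")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count block shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts % 1 != 0):
                i, j = _first_bad(counts, lambda x: ~np.isfinite(x) | (x % 1 != 0))
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {counts[i, j]}"
                )
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = _first_bad(counts, lambda x: x < 0)
            raise ValueError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {counts[i, j]}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.gene_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _first_bad(a: np.ndarray, pred) -> tuple[int, int]:
    idx = np.argwhere(pred(a))
    return tuple(idx[0])


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count table (first column gene ids, header sample ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.apply(pd.to_numeric).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in count table {path}: {exc}") from exc
    return CountMatrix(tuple(map(str, df.index)), tuple(map(str, df.columns)), values)


@dataclass(frozen=True)
class StudyDesign:
    """Sample sheet: one row per sample with its timepoint label and dose (nM).

    Timepoint labels come from an ordered vocabulary so "later timepoint"
    is well defined; replicate samples per (timepoint, dose) are allowed
    even though the motivating design has exactly one.
    """

    table: pd.DataFrame  # columns: sample_id, timepoint, dose_nM
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        required = {"sample_id", "timepoint", "dose_nM"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing column(s): {sorted(missing)}")
        dupes = _duplicates(self.table["sample_id"])
        if dupes:
            raise ValueError(f"duplicate sample id(s) in design: {sorted(dupes)}")
        unknown = set(self.table["timepoint"]) - set(self.timepoints)
        if unknown:
            raise ValueError(
                f"timepoint label(s) {sorted(unknown)} not in vocabulary {list(self.timepoints)}"
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table["sample_id"])

    def samples_for(self, timepoint: str, dose_nM: int) -> list[str]:
        t = self.table
        sel = t[(t["timepoint"] == timepoint) & (t["dose_nM"] == dose_nM)]
        return list(sel["sample_id"])

    def doses(self) -> list[int]:
        return sorted(set(self.table["dose_nM"]))

    def validate_against(self, cm: CountMatrix) -> None:
        """Every count-matrix sample must appear exactly once in the design."""
        missing = set(cm.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"sample(s) in count matrix but not in design: {sorted(missing)}")

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, timepoints: Sequence[str] = DEFAULT_TIMEPOINTS) -> "StudyDesign":
        df = pd.read_csv(path, sep="\t")
        df["dose_nM"] = df["dose_nM"].astype(int)
        return cls(df, tuple(timepoints))


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    Reference genes are the rows with strictly positive counts in every
    sample; each sample's factor is the median across reference genes of
    count / (row geometric mean).
    """
    counts = cm.counts
    ref = np.all(counts > 0, axis=1)
    if not ref.any():
        raise ValueError("no all-positive gene row; size factors are undefined")
    sub = counts[ref].astype(float)
    geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    return np.median(sub / geo, axis=0)


def normalize_log(cm: CountMatrix, s: np.ndarray, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), genes x samples."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    s = np.asarray(s, dtype=float)
    if s.shape != (len(cm.sample_ids),) or np.any(s <= 0):
        raise ValueError("size factors must be positive, one per sample")
    m = np.log2(cm.counts / s + pseudocount)
    return pd.DataFrame(m, index=list(cm.gene_ids), columns=list(cm.sample_ids))


def sample_distance_matrix(m: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """1 - correlation distance between sample columns.

    Identical samples sit at distance 0, perfectly anticorrelated ones at 2.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    sd = m.std(axis=0, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance sample column(s): {flat}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = m.corr(method=method)
    dist = 1.0 - corr
    # enforce the contract exactly against float round-off
    vals = (dist.to_numpy() + dist.to_numpy().T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return pd.DataFrame(vals, index=dist.index, columns=dist.columns)


def pca(m: pd.DataFrame, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples from the gene-centered matrix.

    Returns per-sample scores for the first ``n_components`` components and
    the variance fraction of *every* component (non-increasing, sums to 1).
    """
    n_genes, n_samples = m.shape
    rank_bound = min(n_genes, n_samples)
    if not 1 <= n_components <= rank_bound:
        raise ValueError(f"n_components must be in [1, {rank_bound}], got {n_components}")
    x = m.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)  # center each gene across samples
    # samples are observations: SVD of the samples x genes matrix
    u, sv, _ = np.linalg.svd(x.T, full_matrices=False)
    scores = u[:, :n_components] * sv[:n_components]
    var = sv**2
    frac = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=m.columns, columns=cols), frac


@dataclass(frozen=True)
class Contrast:
    """A named treated-vs-control sample grouping."""

    name: str
    treated: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.treated or not self.control:
            raise ValueError(f"contrast {self.name!r}: treated and control must be non-empty")
        if set(self.treated) & set(self.control):
            raise ValueError(f"contrast {self.name!r}: treated and control overlap")


def default_contrasts(design: StudyDesign, mode: str = "dose_vs_control") -> list[Contrast]:
    """Build the study's standard contrasts.

    ``dose_vs_control``: (timepoint t, dose d) vs (t, dose 0) for each
    treated dose; ``spontaneous``: (t, dose 0) vs (first timepoint, dose 0),
    tracking differentiation itself rather than the treatment.
    """
    contrasts: list[Contrast] = []
    if mode == "dose_vs_control":
        for tp in design.timepoints:
            ctrl = design.samples_for(tp, 0)
            if not ctrl:
                continue
            for dose in design.doses():
                if dose == 0:
                    continue
                treated = design.samples_for(tp, dose)
                if treated:
                    contrasts.append(Contrast(condition_name(tp, dose), tuple(treated), tuple(ctrl)))
    elif mode == "spontaneous":
        base_tp = design.timepoints[0]
        base = design.samples_for(base_tp, 0)
        if not base:
            raise ValueError(f"no baseline samples at ({base_tp}, 0 nM)")
        for tp in design.timepoints:
            if tp == base_tp:
                continue
            treated = design.samples_for(tp, 0)
            if treated:
                contrasts.append(Contrast(condition_name(tp, 0), tuple(treated), tuple(base)))
    else:
        raise ValueError(f"unknown contrast mode {mode!r}")
    if not contrasts:
        raise ValueError("design yields no contrasts")
    return contrasts


def log2_fold_changes(
    cm: CountMatrix,
    contrasts: Sequence[Contrast],
    pseudocount: float = 1.0,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change for each contrast.

    lfc = mean over treated samples of log2(count/s + pc) minus the same
    mean over control samples, on median-of-ratios normalized counts.
    """
    if factors is None:
        factors = size_factors(cm)
    norm = normalize_log(cm, factors, pseudocount)
    known = set(cm.sample_ids)
    out = {}
    for c in contrasts:
        unknown = (set(c.treated) | set(c.control)) - known
        if unknown:
            raise ValueError(f"contrast {c.name!r} references unknown sample(s): {sorted(unknown)}")
        out[c.name] = norm[list(c.treated)].mean(axis=1) - norm[list(c.control)].mean(axis=1)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class DEProfile:
    """Per-gene, per-condition log2 fold changes with threshold DE calls.

    ``is_de`` is the inclusive rule |lfc| >= threshold; ``sign`` is the
    fold-change sign for DE entries and 0 otherwise.
    """

    lfc: pd.DataFrame  # genes x condition columns
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"DE threshold must be > 0, got {self.threshold}")

    @property
    def is_de(self) -> pd.DataFrame:
        return self.lfc.abs() >= self.threshold

    @property
    def sign(self) -> pd.DataFrame:
        return np.sign(self.lfc).astype(int) * self.is_de.astype(int)

    def de_genes(self, condition: str) -> set[str]:
        col = self.is_de[condition]
        return set(col.index[col])

    def write(self, path: str | Path) -> None:
        """TSV with an (lfc, is_de) column pair per condition."""
        blocks = []
        for cond in self.lfc.columns:
            blocks.append(self.lfc[cond].rename(f"{cond}.lfc"))
            blocks.append(self.is_de[cond].astype(int).rename(f"{cond}.is_de"))
        df = pd.concat(blocks, axis=1)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, threshold: float = 1.0) -> "DEProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lfc_cols = [c for c in df.columns if c.endswith(".lfc")]
        lfc = df[lfc_cols].rename(columns=lambda c: c[: -len(".lfc")])
        return cls(lfc, threshold)


def call_de(lfc: pd.DataFrame, threshold: float = 1.0) -> DEProfile:
    """Flag genes with |log2 fold change| >= threshold (inclusive)."""
    return DEProfile(lfc, threshold)


def marker_panel_matrix(
    lfc: pd.DataFrame, panel: Sequence[str] | Sequence[tuple[str, str]]
) -> tuple[pd.DataFrame, list[str]]:
    """Extract a marker panel's fold-change rows in panel order.

    Panel entries may be gene ids or (gene, group-label) pairs; group labels
    become a ``group`` index level.  Genes absent from the table are
    reported in the returned list, never silently dropped.
    """
    if len(panel) == 0:
        raise ValueError("marker panel is empty")
    if lfc.shape[1] == 0:
        raise ValueError("fold-change table has no condition columns")
    entries = [(p, None) if isinstance(p, str) else (p[0], p[1]) for p in panel]
    present = [(g, grp) for g, grp in entries if g in lfc.index]
    missing = [g for g, _ in entries if g not in lfc.index]
    mat = lfc.loc[[g for g, _ in present]].copy()
    if any(grp is not None for _, grp in present):
        mat.index = pd.MultiIndex.from_tuples(present, names=["gene", "group"])
    return mat, missing
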