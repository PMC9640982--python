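"""Synthetic-data generators with ground truth, for recovery and calibration.

Everything the pipeline consumes can be generated here: a scale-free
(preferential-attachment) network presented as overlapping pathway files,
degree-biased DE node sets, a replicate-free count matrix with planted
per-condition log2 fold changes (including a temporal-shift gene class),
and flat term annotations with one planted enriched term.  Each generator
is fully deterministic under a fixed seed and returns the planted truth so
tests can measure recovery rather than eyeball plausibility.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .de_sets import DESetCollection
from .enrichment import TermAnnotation, write_gmt
from .expression import (
    DEFAULT_TIMEPOINTS,
    CountMatrix,
    StudyDesign,
    condition_name,
    parse_condition,
)
from .pathways import BioNetwork, Pathway, PathwayCollection

__all__ = [
    "DESpec",
    "SimulationTruth",
    "gen_scale_free",
    "gen_pathway_cover",
    "plant_de_set",
    "gen_design",
    "gen_counts",
    "gen_terms",
    "write_dataset",
]


def gen_scale_free(n: int, m_attach: int, seed: int | None = None) -> BioNetwork:
    """Barabási–Albert preferential-attachment network.

    Connected, simple, with exactly m_attach * (n - m_attach) edges;
    node names are gene-symbol-like labels G00000..
    """
    if not (n > m_attach >= 1):
        raise ValueError(f"need n > m_attach >= 1, got n={n}, m_attach={m_attach}")
    g = nx.barabasi_albert_graph(n, m_attach, seed=seed)
    mapping = {i: f"G{i:05d}" for i in g.nodes}
    return BioNetwork(nx.relabel_nodes(g, mapping))


def gen_pathway_cover(
    net: BioNetwork,
    n_pathways: int = 20,
    size_mean: int | None = None,
    seed: int | None = None,
) -> PathwayCollection:
    """Present a network as overlapping pathway files covering every edge.

    Pathways are connected edge subsets grown from random seed edges;
    every network edge belongs to at least one pathway, so merging the
    collection reproduces the input graph exactly.  ``n_pathways`` is a
    target: growth stops a pathway early when no uncovered edge touches
    it, so the emitted count can exceed the target; extra overlapping
    pathways are added if coverage finishes early.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    edges = sorted(tuple(sorted(e)) for e in net.graph.edges)
    if not edges:
        raise ValueError("network has no edges to cover")
    rng = np.random.default_rng(seed)
    target = size_mean or max(1, math.ceil(len(edges) / n_pathways))

    incident: dict[str, list[int]] = {}
    for i, (a, b) in enumerate(edges):
        incident.setdefault(a, []).append(i)
        incident.setdefault(b, []).append(i)

    uncovered = set(range(len(edges)))
    groups: list[list[int]] = []
    while uncovered:
        start = int(rng.choice(sorted(uncovered)))
        group = [start]
        uncovered.discard(start)
        node_set = set(edges[start])
        frontier = {i for v in node_set for i in incident[v] if i in uncovered}
        while len(group) < target and frontier:
            e = int(rng.choice(sorted(frontier)))
            frontier.discard(e)
            if e not in uncovered:
                continue
            group.append(e)
            uncovered.discard(e)
            for v in edges[e]:
                if v not in node_set:
                    node_set.add(v)
                    frontier.update(i for i in incident[v] if i in uncovered)
            frontier &= uncovered
        groups.append(group)

    # top up with overlapping pathways re-sampling already-covered regions
    while len(groups) < n_pathways:
        start = int(rng.integers(len(edges)))
        group = [start]
        node_set = set(edges[start])
        frontier = {i for v in node_set for i in incident[v] if i != start}
        while len(group) < target and frontier:
            e = int(rng.choice(sorted(frontier)))
            frontier.discard(e)
            group.append(e)
            for v in edges[e]:
                if v not in node_set:
                    node_set.add(v)
                    frontier.update(i for i in incident[v] if i not in group)
        groups.append(group)

    pathways = []
    for gi, group in enumerate(groups):
        es = frozenset(frozenset(edges[i]) for i in group)
        ns = frozenset(v for e in es for v in e)
        pid = f"PW{gi:04d}"
        pathways.append(Pathway(pid, f"synthetic pathway {gi}", ns, es))
    return PathwayCollection(tuple(pathways))


def plant_de_set(
    net: BioNetwork, n_de: int, beta: float = 0.0, seed: int | None = None
) -> set[str]:
    """Sample a DE node set with selection probability proportional to degree^beta.

    beta = 0 is uniform; beta < 0 biases toward low-connectivity nodes
    (the bias observed for DE genes in real pathway networks).  Sampling
    is without replacement and always returns exactly n_de nodes.
    """
    nodes = sorted(net.graph.nodes)
    if not 0 < n_de < len(nodes):
        raise ValueError(f"n_de must be in (0, {len(nodes)}), got {n_de}")
    deg = np.array([net.graph.degree[v] for v in nodes], dtype=float)
    if beta == 0:
        w = np.ones_like(deg)
    else:
        w = np.where(deg > 0, deg, np.nan) ** beta
        w = np.where(np.isnan(w), 0.0, w)
    if (w > 0).sum() < n_de:
        raise ValueError(f"only {(w > 0).sum()} nodes have positive sampling weight; need {n_de}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(nodes), size=n_de, replace=False, p=w / w.sum())
    return {nodes[i] for i in idx}


def gen_design(
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    doses: Sequence[int] = (0, 10, 100),
    baseline_timepoint: str | None = "D0",
) -> StudyDesign:
    """One-sample-per-condition design: timepoints x doses, baseline at dose 0 only."""
    rows = []
    for tp in timepoints:
        for dose in sorted(doses):
            if tp == baseline_timepoint and dose != 0:
                continue
            rows.append({"sample_id": condition_name(tp, dose), "timepoint": tp, "dose_nM": dose})
    return StudyDesign(pd.DataFrame(rows), tuple(timepoints))


@dataclass(frozen=True)
class DESpec:
    """What to plant: per-condition DE fraction, effect size, shift class.

    Per treated timepoint, ``frac_de`` of all genes carry a |log2 fold
    change| of ``lfc_abs`` at both doses (regular genes; disjoint across
    timepoints).  On top of these, a temporal-shift class is planted —
    effect at the high dose at a non-final timepoint, reproduced at the
    low dose only at a strictly later timepoint — sized so that the
    planted shift fraction (shifted / genes DE at the high dose at any
    non-final timepoint) equals ``shift_frac`` up to rounding.
    """

    frac_de: float = 0.1
    lfc_abs: float = 2.0
    shift_frac: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.frac_de <= 1:
            raise ValueError(f"frac_de must be in [0,1], got {self.frac_de}")
        if not 0 <= self.shift_frac <= 1:
            raise ValueError(f"shift_frac must be in [0,1], got {self.shift_frac}")
        if self.lfc_abs < 0:
            raise ValueError("lfc_abs must be >= 0")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth returned by :func:`gen_counts` / :func:`gen_terms`."""

    de_lfc: Mapping[str, Mapping[str, float]]  # condition label -> {gene: signed lfc}
    shifted_genes: frozenset[str]
    high_dose_nonfinal_genes: frozenset[str]  # temporal-shift denominator
    seed: int | None
    planted_term: str | None = None
    planted_term_fold: float | None = None
    de_bias_beta: float | None = None

    def de_genes(self, condition: str) -> set[str]:
        return set(self.de_lfc.get(condition, {}))

    def all_de_genes(self) -> set[str]:
        return {g for genes in self.de_lfc.values() for g in genes}

    def to_set_collection(self, timepoints: Sequence[str] = DEFAULT_TIMEPOINTS) -> DESetCollection:
        """Noise-free DE flags straight from the planted truth."""
        sets = {
            parse_condition(label): {g: int(np.sign(l)) for g, l in genes.items()}
            for label, genes in self.de_lfc.items()
        }
        return DESetCollection(sets, tuple(timepoints))

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_lfc": {c: dict(sorted(g.items())) for c, g in sorted(self.de_lfc.items())},
                "shifted_genes": sorted(self.shifted_genes),
                "high_dose_nonfinal_genes": sorted(self.high_dose_nonfinal_genes),
                "seed": self.seed,
                "planted_term": self.planted_term,
                "planted_term_fold": self.planted_term_fold,
                "de_bias_beta": self.de_bias_beta,
            },
            indent=2,
            sort_keys=True,
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gen_counts(
    design: StudyDesign,
    n_genes: int = 10_000,
    de_spec: DESpec = DESpec(),
    dispersion: float = 0.05,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
    mean_log_median: float = 200.0,
    mean_log_sigma: float = 1.2,
    min_mean: float = 1.0,
    gene_ids: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Replicate-free negative-binomial counts with planted fold changes.

    Baseline gene means are log-normal (median ``mean_log_median``,
    log-sd ``mean_log_sigma``, floored at ``min_mean``); per-sample size
    factors are log-uniform in ``size_factor_range``; counts are NB with
    variance mu + dispersion*mu^2.  Planted genes multiply their treated
    means by 2^(+/- lfc_abs) in their assigned conditions.  Regular planted
    genes respond at both doses at one timepoint; shifted genes respond at
    the high dose at a non-final timepoint i and at the low dose at a
    later timepoint only.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if gene_ids is not None:
        genes = list(gene_ids)
        if len(genes) != n_genes:
            raise ValueError(f"gene_ids has {len(genes)} entries but n_genes={n_genes}")
    else:
        genes = [f"gene{i:05d}" for i in range(n_genes)]
    base = np.exp(rng.normal(math.log(mean_log_median), mean_log_sigma, size=n_genes))
    base = np.maximum(base, min_mean)

    doses = [d for d in design.doses() if d > 0]
    treated_tps = [
        tp for tp in design.timepoints if any(design.samples_for(tp, d) for d in doses)
    ]
    de_lfc: dict[str, dict[str, float]] = {
        condition_name(tp, d): {} for tp in treated_tps for d in doses
        if design.samples_for(tp, d)
    }

    # frac_de is the planted DE fraction per condition: n_per_tp regular genes
    # respond at both doses at one timepoint; shifted genes are extra, sized so
    # the planted temporal-shift fraction equals shift_frac after rounding.
    n_tp = len(treated_tps)
    n_per_tp = round(de_spec.frac_de * n_genes)
    n_regular = n_per_tp * n_tp
    n_nonfinal = n_per_tp * max(n_tp - 1, 0)
    if de_spec.shift_frac >= 1:
        raise ValueError("shift_frac must be < 1")
    n_shift = round(de_spec.shift_frac / (1 - de_spec.shift_frac) * n_nonfinal)
    n_de = n_regular + n_shift
    shifted_genes: set[str] = set()
    denominator: set[str] = set()
    if n_de > n_genes:
        raise ValueError(f"planting needs {n_de} genes but only {n_genes} exist")
    if n_shift > 0 and len(doses) < 2:
        raise ValueError("temporal-shift planting needs two treated doses")
    if n_shift > 0 and n_tp < 2:
        raise ValueError("temporal-shift planting needs >= 2 treated timepoints")

    planted_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    if n_de:
        dose_high = max(doses)
        dose_low = min(doses)
        for k, (gi, sgn) in enumerate(zip(planted_idx, signs)):
            gene = genes[gi]
            lfc = sgn * de_spec.lfc_abs
            if k < n_shift:
                i = int(rng.integers(0, n_tp - 1))
                j = int(rng.integers(i + 1, n_tp))
                de_lfc[condition_name(treated_tps[i], dose_high)][gene] = lfc
                de_lfc[condition_name(treated_tps[j], dose_low)][gene] = lfc
                shifted_genes.add(gene)
                denominator.add(gene)
            else:
                i = (k - n_shift) % n_tp  # spread regular genes evenly
                for d in doses:
                    de_lfc[condition_name(treated_tps[i], d)][gene] = lfc
                if i < n_tp - 1:
                    denominator.add(gene)

    sfactors = np.exp(
        rng.uniform(math.log(size_factor_range[0]), math.log(size_factor_range[1]),
                    size=len(design.sample_ids))
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    counts = np.empty((n_genes, len(design.sample_ids)), dtype=np.int64)
    for j, sid in enumerate(design.sample_ids):
        row = design.table[design.table["sample_id"] == sid].iloc[0]
        label = condition_name(row["timepoint"], int(row["dose_nM"]))
        mu = base.copy()
        for gene, lfc in de_lfc.get(label, {}).items():
            mu[gene_pos[gene]] *= 2.0**lfc
        counts[:, j] = _nb_draw(rng, mu * sfactors[j], dispersion)

    cm = CountMatrix(tuple(genes), tuple(design.sample_ids), counts)
    truth = SimulationTruth(
        de_lfc={c: dict(g) for c, g in de_lfc.items()},
        shifted_genes=frozenset(shifted_genes),
        high_dose_nonfinal_genes=frozenset(denominator),
        seed=seed,
    )
    return cm, truth


def gen_terms(
    universe: Iterable[str],
    n_terms: int = 50,
    planted: tuple[Iterable[str], float, float] | None = None,
    term_size_range: tuple[int, int] = (10, 100),
    seed: int | None = None,
) -> tuple[TermAnnotation, dict]:
    """Random flat gene sets plus one planted differentially covered term.

    ``planted`` is (target genes, coverage in target, coverage in
    background): the planted term contains that fraction of the target
    list and of the rest of the universe, giving a true coverage fold of
    cov_target / cov_background.
    """
    universe = sorted(set(universe))
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = term_size_range
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(universe))
        members = rng.choice(len(universe), size=size, replace=False)
        terms[f"T{t:04d}"] = (f"random term {t}", frozenset(universe[i] for i in members))

    truth: dict = {"planted_term": None, "true_fold": None}
    if planted is not None:
        target, cov_t, cov_b = planted
        target = sorted(set(target))
        if not (0 < cov_t < 1 and 0 < cov_b < 1):
            raise ValueError("planted coverage fractions must be in (0, 1)")
        bg = sorted(set(universe) - set(target))
        n_t = max(1, round(cov_t * len(target)))
        n_b = max(1, round(cov_b * len(bg)))
        pick_t = rng.choice(len(target), size=n_t, replace=False)
        pick_b = rng.choice(len(bg), size=n_b, replace=False)
        genes = frozenset(target[i] for i in pick_t) | frozenset(bg[i] for i in pick_b)
        term_id = "T_PLANTED"
        terms[term_id] = ("planted enriched term", genes)
        truth = {"planted_term": term_id, "true_fold": cov_t / cov_b,
                 "n_in_target": int(n_t), "n_in_background": int(n_b)}
    return TermAnnotation(terms), truth


def write_dataset(
    directory: str | Path,
    design: StudyDesign,
    counts: CountMatrix,
    truth: SimulationTruth,
    pathways: PathwayCollection | None = None,
    terms: TermAnnotation | None = None,
) -> dict[str, Path]:
    """Write a full synthetic dataset in the pipeline's input formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["counts"] = directory / "counts.tsv"
    counts.write(paths["counts"])
    paths["design"] = directory / "design.tsv"
    design.write(paths["design"])
    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    if pathways is not None:
        paths["pathway_manifest"] = pathways.write(directory / "pathways")
    if terms is not None:
        paths["gmt"] = directory / "terms.gmt"
        write_gmt(terms, paths["gmt"])
    return paths
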