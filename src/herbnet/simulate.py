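"""Seeded generators for every input the pipeline consumes.

The upstream sources of a herb-formula network study are database
exports (ingredient tables, compound-target pairs, interaction networks,
disease gene lists, annotation snapshots) that carry no ground truth.
These generators produce structurally similar inputs *with* ground
truth planted by construction — which compounds survive the ADME screen,
which genes are shared between drug targets and disease genes, which
network nodes are hubs, which annotation terms are enriched — so every
stage's statistical behavior is testable offline.

Default scales mirror the six-herb decoction study the pipeline was
built around: 981 candidate compounds of which 70 pass the OB/DL screen,
247 drug targets, 262 disease genes, 50 planted overlap genes.

All randomness flows through one :class:`numpy.random.Generator`; the
same seed reproduces byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
import math
import statistics
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io import (
    CompoundRecord,
    GeneSetCollection,
    write_compound_table,
    write_edge_list,
    write_gene_list,
    write_gmt,
)

logger = logging.getLogger("herbnet")

_HERB_CODES = ("EH", "CR", "MO", "AS", "AR", "PC")  # six source herbs


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class AnnotationConfig:
    """Synthetic annotation snapshot: ``n_terms`` decoy terms with sizes
    in ``term_size_range`` over an ``n_background``-gene universe, plus
    ``n_planted`` terms whose members are drawn from the planted overlap
    genes with probability ``hit_prob`` (the planted enrichment signal)."""

    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)
    n_planted: int = 3
    planted_term_size: int = 40
    hit_prob: float = 0.8
    n_background: int = 2000


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a full synthetic study.

    Compound OB values are log-normal (percent scale), DL values Beta;
    for the planted pass fraction both are truncated above the screening
    thresholds so the intended number of compounds survives exactly.
    Compound-target degrees follow a truncated discrete power law
    (exponent ``ct_degree_exponent``, lower cut ``ct_degree_min``, cap
    ``ct_degree_cap``) reproducing the heavy-tailed skew of real
    compound tables (max degree >> median).  PPI graphs grow by
    preferential attachment with ``ppi_attachment`` edges per new node;
    ``n_planted_hubs`` nodes are boosted to at least four times the
    median degree.  Exactly ``planted_overlap`` genes are shared between
    the drug-target and disease-gene namespaces by explicit shared
    draws.
    """

    seed: int = 7
    n_compounds: int = 981
    ob_lognormal: tuple[float, float] = (3.8, 0.45)  # (mu, sigma) of ln OB
    dl_beta: tuple[float, float] = (1.6, 3.0)
    ob_min: float = 30.0
    dl_min: float = 0.18
    pass_fraction_target: float = 70 / 981
    ct_degree_exponent: float = 1.8
    ct_degree_min: int = 4
    ct_degree_cap: int = 160
    n_targets: int = 247
    ppi_attachment: int = 15
    n_planted_hubs: int = 5
    n_disease_genes: int = 262
    planted_overlap: int = 50
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def __post_init__(self) -> None:
        if self.planted_overlap > min(self.n_targets, self.n_disease_genes):
            raise ValidationError(
                "planted_overlap cannot exceed either gene-set size"
            )
        for name in ("n_compounds", "n_targets", "n_disease_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.pass_fraction_target <= 1.0:
            raise ValidationError("pass_fraction_target must be in [0,1]")


@dataclass
class ScenarioBundle:
    """Everything a pipeline run consumes, plus the planted truth."""

    config: ScenarioConfig
    compounds: list[CompoundRecord]
    ct_pairs: list[tuple[str, str]]
    targets: list[str]
    ppi_edges: list[tuple[str, str]]
    disease_genes: set[str]
    disease_ppi_edges: list[tuple[str, str]]
    gene_sets: GeneSetCollection
    truth: dict


# ---------------------------------------------------------------------------
# samplers


def _truncated_power_law(rng: np.random.Generator, alpha: float, xmin: int, cap: int) -> int:
    """One draw from a discrete power law on [xmin, cap] (inverse-CDF of
    the continuous truncated Pareto, floored)."""
    u = rng.random()
    one_minus = 1.0 - alpha
    lo, hi = float(xmin), float(cap) + 1.0
    x = (lo**one_minus + u * (hi**one_minus - lo**one_minus)) ** (1.0 / one_minus)
    return min(cap, max(xmin, int(x)))


def _sample_ob_dl(
    rng: np.random.Generator, cfg: ScenarioConfig, must_pass: bool
) -> tuple[float, float]:
    mu, sigma = cfg.ob_lognormal
    a, b = cfg.dl_beta
    if must_pass:
        ob = float(rng.lognormal(mu, sigma))
        while ob < cfg.ob_min:
            ob = float(rng.lognormal(mu, sigma))
        dl = float(rng.beta(a, b))
        while dl < cfg.dl_min:
            dl = float(rng.beta(a, b))
        return round(ob, 2), round(dl, 2)
    ob = round(float(rng.lognormal(mu, sigma)), 2)
    dl = round(float(rng.beta(a, b)), 2)
    if ob >= cfg.ob_min and dl >= cfg.dl_min:
        mode = rng.choice(["low_ob", "low_dl", "both"])
        # upper factors keep the forced values below threshold after rounding
        if mode in ("low_ob", "both"):
            ob = round(cfg.ob_min * float(rng.uniform(0.2, 0.97)), 2)
        if mode in ("low_dl", "both"):
            dl = round(cfg.dl_min * float(rng.uniform(0.05, 0.9)), 2)
    return ob, dl


# ---------------------------------------------------------------------------
# compound-target pairing


def degree_matched_ct_pairs(
    degree_table: Mapping[str, int],
    n_targets: int,
    seed,
    targets: Sequence[str] | None = None,
) -> list[tuple[str, str]]:
    """Build a compound-target pair list in which every compound gets
    exactly its stated number of distinct targets.

    When the degree total is at least ``n_targets``, every target is used
    at least once (a first pass hands each target to a compound with
    spare capacity); remaining slots are filled by seeded weighted
    sampling with power-law target popularity, giving the heavy-tailed
    target-degree profile of real compound-target networks.  A degree
    total below ``n_targets`` leaves some targets unused, with a warning;
    a single degree above ``n_targets`` is infeasible.
    """
    rng = _rng(seed)
    if targets is None:
        targets = [f"G{i + 1:04d}" for i in range(n_targets)]
    elif len(targets) != n_targets:
        raise ValidationError("targets list length must equal n_targets")
    bad = {c: d for c, d in degree_table.items() if d > n_targets}
    if bad:
        raise ValidationError(
            f"infeasible degrees (exceed {n_targets} available targets): {bad}"
        )
    if any(d < 0 for d in degree_table.values()):
        raise ValidationError("degrees must be non-negative")
    total = sum(degree_table.values())
    if total < n_targets:
        logger.warning(
            "degree total %d < %d targets; some targets will be unused", total, n_targets
        )
    assigned: dict[str, set[str]] = {c: set() for c in degree_table}
    order = sorted(degree_table, key=lambda c: (-degree_table[c], c))
    shuffled = list(targets)
    rng.shuffle(shuffled)
    # coverage pass: hand each target to some compound with spare capacity
    i = 0
    for t in shuffled:
        placed = False
        for _ in range(len(order)):
            c = order[i % len(order)]
            i += 1
            if len(assigned[c]) < degree_table[c] and t not in assigned[c]:
                assigned[c].add(t)
                placed = True
                break
        if not placed:  # capacity exhausted (total < n_targets)
            break
    # popularity weights: Zipf over a fixed shuffled rank order
    ranks = np.arange(1, n_targets + 1, dtype=float)
    weights = ranks**-0.8
    weights /= weights.sum()
    target_arr = np.array(shuffled, dtype=object)
    for c in order:
        need = degree_table[c] - len(assigned[c])
        if need <= 0:
            continue
        mask = np.array([t not in assigned[c] for t in target_arr])
        pool = target_arr[mask]
        w = weights[mask]
        picks = rng.choice(pool, size=need, replace=False, p=w / w.sum())
        assigned[c].update(picks.tolist())
    pairs = [(c, t) for c in sorted(assigned) for t in sorted(assigned[c])]
    return pairs


# ---------------------------------------------------------------------------
# PPI with planted hubs


def simulate_ppi_with_hubs(
    seed,
    n_nodes: int = 100,
    attachment: int = 3,
    n_hubs: int = 5,
    boost: float = 4.0,
    names: Sequence[str] | None = None,
) -> tuple[nx.Graph, list[str]]:
    """Preferential-attachment PPI graph with ``n_hubs`` planted hubs.

    Hubs are boosted with extra random edges until their degree is at
    least ``boost`` times the median degree of the final graph (the loop
    re-checks the median after boosting, so the guarantee holds at
    return).  With the default boost of 4 every planted hub strictly
    exceeds the twice-the-median selection threshold by construction.
    """
    rng = _rng(seed)
    if n_hubs >= n_nodes:
        raise ValidationError("n_hubs must be smaller than n_nodes")
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(rng.integers(2**31)))
    if names is None:
        names = [f"P{i + 1:04d}" for i in range(n_nodes)]
    elif len(names) != n_nodes:
        raise ValidationError("names length must equal n_nodes")
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    g.name = "ppi"
    hubs = [str(x) for x in rng.choice(np.array(names, dtype=object), n_hubs, replace=False)]
    for _ in range(50):
        med = statistics.median(d for _, d in g.degree())
        # a hub cannot exceed n-1 neighbors; dense small graphs saturate there
        goal = min(n_nodes - 1, math.ceil(boost * med))
        ok = True
        for h in hubs:
            need = goal - g.degree(h)
            if need <= 0:
                continue
            ok = False
            non_nbrs = np.array(
                [x for x in names if x != h and not g.has_edge(h, x)], dtype=object
            )
            picks = rng.choice(non_nbrs, size=need, replace=False)
            g.add_edges_from((h, str(p)) for p in picks)
        if ok:
            break
    return g, hubs


# ---------------------------------------------------------------------------
# enrichment scenario


def simulate_enrichment(
    seed,
    n_background: int = 2000,
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 60),
    planted_term_size: int = 40,
    query_size: int = 50,
    hit_prob: float = 0.8,
) -> tuple[set[str], GeneSetCollection, str]:
    """One planted-enrichment replicate.

    A collection of ``n_terms`` terms over an ``n_background`` universe
    contains one planted term of size ``planted_term_size``; the query of
    ``query_size`` genes draws each member from the planted term with
    probability ``hit_prob`` (distinct draws, falling back to the rest of
    the background once the term is exhausted).  Returns
    (query, collection, planted_term_id).
    """
    rng = _rng(seed)
    bg = [f"B{i + 1:04d}" for i in range(n_background)]
    bg_arr = np.array(bg, dtype=object)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_id = "T_PLANTED"
    planted = set(rng.choice(bg_arr, planted_term_size, replace=False).tolist())
    terms[planted_id] = ("planted signal term", frozenset(planted))
    lo, hi = term_size_range
    for i in range(n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(bg_arr, size, replace=False).tolist()
        terms[f"T{i + 1:03d}"] = (f"decoy term {i + 1}", frozenset(members))
    query: set[str] = set()
    planted_pool = sorted(planted)
    rng.shuffle(planted_pool)
    rest_pool = sorted(set(bg) - planted)
    rng.shuffle(rest_pool)
    while len(query) < query_size:
        if rng.random() < hit_prob and planted_pool:
            query.add(planted_pool.pop())
        elif rest_pool:
            query.add(rest_pool.pop())
    collection = GeneSetCollection(background=frozenset(bg), terms=terms)
    return query, collection, planted_id


# ---------------------------------------------------------------------------
# full scenario


def simulate_scenario(cfg: ScenarioConfig) -> ScenarioBundle:
    """Generate a full synthetic study bundle under one seed.

    The truth record stores the ids of compounds planted to pass the
    OB/DL screen, the planted overlap genes, the planted PPI hubs and the
    planted enriched terms, so downstream recovery can be scored exactly.
    """
    rng = _rng(cfg.seed)
    n = cfg.n_compounds
    width = len(str(n))
    ids = [f"C{i + 1:0{width}d}" for i in range(n)]
    n_pass = round(cfg.pass_fraction_target * n)
    pass_idx = set(rng.choice(n, n_pass, replace=False).tolist())

    compounds: list[CompoundRecord] = []
    for i, cid in enumerate(ids):
        ob, dl = _sample_ob_dl(rng, cfg, must_pass=i in pass_idx)
        n_herbs = 1 + int(rng.random() < 0.15)
        herbs = tuple(
            f"{h}{int(rng.integers(1, 26)):02d}"
            for h in rng.choice(np.array(_HERB_CODES, dtype=object), n_herbs, replace=False)
        )
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                chemical_name=f"synthetic-compound-{i + 1}",
                ob=ob,
                dl=dl,
                herb_codes=herbs,
            )
        )
    pass_ids = [ids[i] for i in sorted(pass_idx)]

    # compound-target degrees for the screened compounds: heavy-tailed
    targets = [f"G{i + 1:04d}" for i in range(cfg.n_targets)]
    degree_table = {
        cid: min(
            cfg.n_targets,
            _truncated_power_law(rng, cfg.ct_degree_exponent, cfg.ct_degree_min, cfg.ct_degree_cap),
        )
        for cid in pass_ids
    }
    ct_pairs = degree_matched_ct_pairs(degree_table, cfg.n_targets, rng, targets=targets)

    # drug-target PPI with planted hubs
    ppi, planted_hubs = simulate_ppi_with_hubs(
        rng,
        n_nodes=cfg.n_targets,
        attachment=min(cfg.ppi_attachment, cfg.n_targets - 1),
        n_hubs=cfg.n_planted_hubs,
        names=targets,
    )
    ppi_edges = [tuple(sorted(e)) for e in ppi.edges()]
    ppi_edges.sort()

    # disease genes: exact planted overlap by explicit shared draws
    overlap_genes = set(
        rng.choice(np.array(targets, dtype=object), cfg.planted_overlap, replace=False).tolist()
    )
    n_extra = cfg.n_disease_genes - cfg.planted_overlap
    disease_only = [f"D{i + 1:04d}" for i in range(n_extra)]
    disease_genes = overlap_genes | set(disease_only)
    dis_names = sorted(disease_genes)
    dis_graph, _ = simulate_ppi_with_hubs(
        rng,
        n_nodes=cfg.n_disease_genes,
        attachment=min(cfg.ppi_attachment, cfg.n_disease_genes - 1),
        n_hubs=1,
        names=dis_names,
    )
    disease_ppi_edges = sorted(tuple(sorted(e)) for e in dis_graph.edges())

    # annotation snapshot with planted enrichment of the overlap genes
    ann = cfg.annotation
    filler_needed = max(0, ann.n_background - len(set(targets) | disease_genes))
    background = sorted(set(targets) | disease_genes | {f"BG{i + 1:04d}" for i in range(filler_needed)})
    bg_arr = np.array(background, dtype=object)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_terms: list[str] = []
    overlap_sorted = sorted(overlap_genes)
    for j in range(ann.n_planted):
        members: set[str] = set()
        pool = list(overlap_sorted)
        rng.shuffle(pool)
        rest = sorted(set(background) - overlap_genes)
        rng.shuffle(rest)
        while len(members) < ann.planted_term_size:
            if rng.random() < ann.hit_prob and pool:
                members.add(pool.pop())
            elif rest:
                members.add(rest.pop())
        tid = f"T_PLANTED_{j + 1}"
        terms[tid] = (f"planted enriched term {j + 1}", frozenset(members))
        planted_terms.append(tid)
    lo, hi = ann.term_size_range
    for j in range(ann.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(bg_arr, size, replace=False).tolist())
        terms[f"T{j + 1:03d}"] = (f"decoy term {j + 1}", frozenset(members))
    gene_sets = GeneSetCollection(background=frozenset(background), terms=terms)

    truth = {
        "planted_pass_ids": pass_ids,
        "planted_overlap_genes": sorted(overlap_genes),
        "planted_hubs": sorted(planted_hubs),
        "planted_terms": planted_terms,
        "n_pass": n_pass,
        "ct_degree_table": degree_table,
    }
    return ScenarioBundle(
        config=cfg,
        compounds=compounds,
        ct_pairs=ct_pairs,
        targets=targets,
        ppi_edges=ppi_edges,
        disease_genes=disease_genes,
        disease_ppi_edges=disease_ppi_edges,
        gene_sets=gene_sets,
        truth=truth,
    )


def write_bundle(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle to disk in the pipeline's native text formats.

    Returns the path of every artifact.  Outputs round-trip through the
    package's readers without loss.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": outdir / "compounds.tsv",
        "ct_pairs": outdir / "ct_pairs.tsv",
        "targets": outdir / "targets.txt",
        "ppi_edges": outdir / "ppi_edges.tsv",
        "disease_genes": outdir / "disease_genes.txt",
        "disease_ppi_edges": outdir / "disease_ppi_edges.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "background": outdir / "background.txt",
        "truth": outdir / "truth.json",
    }
    write_compound_table(bundle.compounds, paths["compounds"])
    with open(paths["ct_pairs"], "w") as fh:
        for c, t in bundle.ct_pairs:
            fh.write(f"{c}\t{t}\n")
    write_gene_list(bundle.targets, paths["targets"])
    g = nx.Graph(bundle.ppi_edges)
    write_edge_list(g, paths["ppi_edges"])
    write_gene_list(bundle.disease_genes, paths["disease_genes"])
    write_edge_list(nx.Graph(bundle.disease_ppi_edges), paths["disease_ppi_edges"])
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    write_gene_list(bundle.gene_sets.background, paths["background"])
    truth = dict(bundle.truth)
    truth["config"] = asdict(bundle.config)
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
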