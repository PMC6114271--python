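"""Gene-set over-representation analysis with BH FDR control and
kappa-score grouping of redundant terms.

The test statistic is the upper-tail hypergeometric probability: with a
background universe of N genes of which K belong to a term, drawing the
n query genes without replacement, the p-value is P(X >= k) for the
observed overlap k.  Benjamini-Hochberg step-up adjusts across tested
terms.  Significant terms are then clustered into groups by Cohen's
kappa on their gene-membership contingency tables (the grouping
convention popularized by the ClueGO tool), using single-linkage
connected components at a kappa threshold (default 0.4).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneSetCollection

logger = logging.getLogger("herbnet")


def hypergeometric_pvalue(k: int, K: int, n: int, N: int, two_sided: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Parameters: k observed overlap, K term size, n query size, N
    background size.  Computed via the survival function of
    ``scipy.stats.hypergeom`` (log-gamma based, numerically stable).
    ``two_sided=True`` doubles the smaller tail (capped at 1).
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValidationError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    upper = float(hypergeom.sf(k - 1, N, K, n))
    if not two_sided:
        return min(upper, 1.0)
    lower = float(hypergeom.cdf(k, N, K, n))
    return min(1.0, 2.0 * min(upper, lower))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values (same order as input)."""
    if len(p_values) == 0:
        return []
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested term: contingency counts, p-value and BH q-value."""

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float
    gene_hits: frozenset[str]
    group_id: str | None = None

    def as_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "term_name": self.term_name,
            "k": self.k,
            "K": self.K,
            "n": self.n,
            "N": self.N,
            "p": self.p_value,
            "q": self.q_value,
            "group_id": self.group_id,
            "gene_hits": ",".join(sorted(self.gene_hits)),
        }


def enrich_gene_sets(
    query: Iterable[str],
    collection: GeneSetCollection,
    min_term_size: int = 3,
    max_term_size: int = 500,
    two_sided: bool = False,
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` genes in each term of the
    collection.

    Query symbols outside the background are dropped with a warning (an
    empty query after that intersection is an error).  The term-size
    window is applied before testing; q-values are adjusted across the
    surviving terms only.  Rows come back sorted by p-value (term_id
    breaks ties deterministically).
    """
    query = {g.upper() for g in query}
    in_bg = query & collection.background
    dropped = query - in_bg
    if dropped:
        logger.warning(
            "%d query gene(s) outside the background dropped: %s%s",
            len(dropped),
            sorted(dropped)[:5],
            "..." if len(dropped) > 5 else "",
        )
    if not in_bg:
        raise ValidationError("query is empty after background intersection")
    N = len(collection.background)
    n = len(in_bg)
    tested: list[tuple[str, str, frozenset[str]]] = [
        (tid, name, genes)
        for tid, (name, genes) in collection.terms.items()
        if min_term_size <= len(genes) <= max_term_size
    ]
    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for tid, name, genes in tested:
        hits = in_bg & genes
        p = hypergeometric_pvalue(len(hits), len(genes), n, N, two_sided=two_sided)
        pvals.append(p)
        rows.append(
            EnrichmentRow(
                term_id=tid,
                term_name=name,
                k=len(hits),
                K=len(genes),
                n=n,
                N=N,
                p_value=p,
                q_value=1.0,
                gene_hits=frozenset(hits),
            )
        )
    qvals = bh_adjust(pvals)
    rows = [
        EnrichmentRow(
            term_id=r.term_id,
            term_name=r.term_name,
            k=r.k,
            K=r.K,
            n=r.n,
            N=r.N,
            p_value=r.p_value,
            q_value=q,
            gene_hits=r.gene_hits,
        )
        for r, q in zip(rows, qvals)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def significant_rows(rows: Sequence[EnrichmentRow], fdr: float = 0.05) -> list[EnrichmentRow]:
    """Rows with q-value <= fdr."""
    return [r for r in rows if r.q_value <= fdr]


def kappa_score(term_a: Iterable[str], term_b: Iterable[str], background: Iterable[str]) -> float:
    """Cohen's kappa of two terms' gene memberships over a background.

    Builds the 2x2 joint-membership table over the N background genes and
    returns (Po - Pe) / (1 - Pe).  Identical non-trivial terms score 1;
    a degenerate table with Pe = 1 (both terms empty or both covering the
    whole background) returns 0 with a warning.
    """
    bg = {g.upper() for g in background}
    a = {g.upper() for g in term_a}
    b = {g.upper() for g in term_b}
    if not a <= bg or not b <= bg:
        raise ValidationError("terms must be subsets of the background")
    N = len(bg)
    if N == 0:
        raise ValidationError("empty background")
    both = len(a & b)
    neither = N - len(a | b)
    po = (both + neither) / N
    pa, pb = len(a) / N, len(b) / N
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        warnings.warn("degenerate membership table (Pe = 1); kappa defined as 0")
        return 0.0
    return (po - pe) / (1 - pe)


@dataclass
class TermGroup:
    """A single-linkage cluster of enriched terms, labeled by its
    smallest-p member."""

    group_id: str
    representative: str
    members: list[str]


def group_terms_by_kappa(
    rows: Sequence[EnrichmentRow],
    collection: GeneSetCollection,
    threshold: float = 0.4,
) -> list[TermGroup]:
    """Cluster enriched terms whose pairwise kappa reaches ``threshold``.

    Builds the graph on the given rows with edges where
    kappa >= threshold and takes connected components (single linkage).
    Each group is labeled by its lowest-p member; groups are returned in
    order of that representative's p-value.
    """
    import networkx as nx

    ids = [r.term_id for r in rows]
    by_id = {r.term_id: r for r in rows}
    g = nx.Graph()
    g.add_nodes_from(ids)
    for ta, tb in combinations(ids, 2):
        ka = kappa_score(
            collection.terms[ta][1], collection.terms[tb][1], collection.background
        )
        if ka >= threshold:
            g.add_edge(ta, tb)
    groups: list[TermGroup] = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda t: (by_id[t].p_value, t))
        rep = members[0]
        groups.append(TermGroup(group_id=f"G{rep}", representative=rep, members=members))
    groups.sort(key=lambda gr: (by_id[gr.representative].p_value, gr.representative))
    for i, gr in enumerate(groups, start=1):
        gr.group_id = f"group{i:02d}"
    return groups


def annotate_groups(rows: Sequence[EnrichmentRow], groups: Sequence[TermGroup]) -> list[EnrichmentRow]:
    """Return rows with ``group_id`` filled in from a grouping."""
    gid = {m: gr.group_id for gr in groups for m in gr.members}
    return [
        EnrichmentRow(
            term_id=r.term_id,
            term_name=r.term_name,
            k=r.k,
            K=r.K,
            n=r.n,
            N=r.N,
            p_value=r.p_value,
            q_value=r.q_value,
            gene_hits=r.gene_hits,
            group_id=gid.get(r.term_id),
        )
        for r in rows
    ]
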