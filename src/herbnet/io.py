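"""Readers and writers for the external formats the pipeline touches.

Native formats are plain text: TSV compound tables, two-column TSV (or
three-column SIF) edge lists, GMT gene-set files, and newline-delimited
gene lists.  A 70-compound screened-ingredient table for the six-herb
Erxian decoction ships with the package (:func:`load_table1`).

Gene symbols are canonicalized to upper case throughout; compound
identifiers are case-sensitive (the ``C##`` convention keeps the two
namespaces disjoint).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("herbnet")

_REQUIRED_COMPOUND_COLUMNS = ("compound_id", "chemical_name", "ob", "dl")


@dataclass(frozen=True)
class CompoundRecord:
    """One screened compound from an ingredient table.

    Attributes
    ----------
    compound_id : str
        Short code, e.g. ``"C28"``.  Unique within a table.
    chemical_name : str
        Free-text chemical name.
    ob : float
        Predicted oral bioavailability, in percent (non-negative).
    dl : float
        Drug-likeness index in [0, 1] (Tanimoto similarity to a
        drug-reference descriptor profile).
    herb_codes : tuple of str
        Source-herb membership labels, e.g. ``("EH22", "PC19")``.
    degree : int or None
        Number of targets in a compound-target network; ``None`` until a
        network has been built or the table carries a degree column.
    """

    compound_id: str
    chemical_name: str
    ob: float
    dl: float
    herb_codes: tuple[str, ...] = ()
    degree: int | None = None

    def __post_init__(self) -> None:
        if self.ob < 0:
            raise ValidationError(f"{self.compound_id}: ob must be >= 0, got {self.ob}")
        if not 0.0 <= self.dl <= 1.0:
            raise ValidationError(f"{self.compound_id}: dl must be in [0,1], got {self.dl}")
        if self.degree is not None and self.degree < 0:
            raise ValidationError(f"{self.compound_id}: degree must be >= 0")


@dataclass(frozen=True)
class SourceCatalog:
    """Compound names exported from one upstream database.

    Names are canonicalized case-insensitively (casefolded) so that the
    same molecule listed with different capitalization in different
    databases still intersects.
    """

    source_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"catalog {self.source_name!r} is empty")
        canon = frozenset(m.casefold() for m in self.members)
        object.__setattr__(self, "members", canon)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO/KEGG-like terms) over a declared background.

    ``terms`` maps term_id -> (term_name, member gene set); every member
    belongs to ``background`` and no term is empty.
    """

    background: frozenset[str]
    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.background = frozenset(g.upper() for g in self.background)
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for term_id, (name, genes) in self.terms.items():
            genes = frozenset(g.upper() for g in genes)
            if not genes:
                raise ValidationError(f"term {term_id!r} is empty")
            stray = genes - self.background
            if stray:
                raise ValidationError(
                    f"term {term_id!r} has members outside the background: {sorted(stray)[:5]}"
                )
            clean[term_id] = (name, genes)
        self.terms = clean

    def term_sizes(self) -> dict[str, int]:
        return {tid: len(genes) for tid, (_, genes) in self.terms.items()}


# ---------------------------------------------------------------------------
# compound tables


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a TSV compound table into a list of :class:`CompoundRecord`.

    Required columns: ``compound_id``, ``chemical_name``, ``ob``, ``dl``;
    optional: ``herb_codes`` (comma-joined), ``degree``.  Row order is
    preserved.  Malformed numeric fields raise :class:`FormatError` with
    the offending line number rather than being coerced.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED_COMPOUND_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        cid = row["compound_id"].strip()
        if cid in seen:
            raise FormatError(f"{path}:{line_no}: duplicate compound_id {cid!r}")
        seen.add(cid)
        try:
            ob = float(row["ob"])
            dl = float(row["dl"])
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: non-numeric ob/dl field ({exc})") from None
        degree: int | None = None
        if "degree" in df.columns and row["degree"].strip() != "":
            try:
                degree = int(row["degree"])
            except ValueError:
                raise FormatError(
                    f"{path}:{line_no}: non-integer degree {row['degree']!r}"
                ) from None
        herbs: tuple[str, ...] = ()
        if "herb_codes" in df.columns and row["herb_codes"].strip():
            herbs = tuple(h.strip() for h in row["herb_codes"].split(",") if h.strip())
        records.append(
            CompoundRecord(
                compound_id=cid,
                chemical_name=row["chemical_name"].strip(),
                ob=ob,
                dl=dl,
                herb_codes=herbs,
                degree=degree,
            )
        )
    return records


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write compound records back to TSV (inverse of :func:`read_compound_table`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "herb_codes": ",".join(r.herb_codes),
                "chemical_name": r.chemical_name,
                "ob": r.ob,
                "dl": r.dl,
                "degree": "" if r.degree is None else r.degree,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_table1() -> list[CompoundRecord]:
    """The packaged 70-compound Erxian-decoction table (post OB/DL screen),
    with per-compound target counts from the published compound-target
    network."""
    ref = resources.files("herbnet.data").joinpath("table1_compounds.tsv")
    with resources.as_file(ref) as p:
        return read_compound_table(p)


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path: str | Path, kind: str = "ppi") -> nx.Graph:
    """Read a two-column TSV (or three-column SIF) edge list.

    Parameters
    ----------
    path : path
        TSV with two columns, or SIF with a middle interaction label.
    kind : {"ct", "ppi"}
        For ``"ct"`` column 1 is a compound id and column 2 a target
        symbol; nodes are labeled with a ``partition`` attribute and a
        node appearing on both sides raises :class:`ValidationError`.

    Duplicate edges are collapsed; self-loops are dropped with a logged
    count.  Target/gene symbols are upper-cased; compound ids are not.
    """
    if kind not in {"ct", "ppi"}:
        raise ValueError(f"kind must be 'ct' or 'ppi', got {kind!r}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:  # SIF: source <interaction> target
                a, _, b = fields
            else:
                raise FormatError(
                    f"{path}:{line_no}: expected 2 (TSV) or 3 (SIF) columns, got {len(fields)}"
                )
            a, b = a.strip(), b.strip()
            if not a or not b:
                raise FormatError(f"{path}:{line_no}: empty node name")
            pairs.append((a, b))
    if kind == "ct":
        from .network import build_ct_network  # local import avoids a cycle

        return build_ct_network(pairs)
    g = nx.Graph(name=str(path))
    n_loops = 0
    for a, b in pairs:
        a, b = a.upper(), b.upper()
        if a == b:
            n_loops += 1
            continue
        g.add_edge(a, b)
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_loops)
    return g


def write_edge_list(g: nx.Graph, path: str | Path, sif: bool = False) -> None:
    """Write a graph as a two-column TSV, or SIF with a generic label."""
    with open(path, "w") as fh:
        for a, b in sorted(map(sorted, g.edges())):
            if sif:
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# gene sets and gene lists


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (term_id TAB description TAB gene ...).

    If ``background`` is not given, the union of all term members is used
    as the background universe.  Terms with zero genes are skipped with a
    warning; a duplicate term_id is an error.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{line_no}: GMT line needs id and description")
            term_id, desc, *genes = fields
            genes = [g.strip().upper() for g in genes if g.strip()]
            if term_id in terms:
                raise FormatError(f"{path}:{line_no}: duplicate term_id {term_id!r}")
            if not genes:
                logger.warning("%s:%d: term %r has no genes; skipped", path, line_no, term_id)
                continue
            terms[term_id] = (desc, frozenset(genes))
    if background is None:
        bg = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    else:
        bg = frozenset(g.upper() for g in background)
    return GeneSetCollection(background=bg, terms=terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, genes) in collection.terms.items():
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a newline-delimited gene list; ``#`` comments allowed.
    Symbols are upper-cased."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line.upper())
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# results envelope


def write_results(
    rows: Sequence[Mapping], path: str | Path, parameters: Mapping | None = None
) -> None:
    """Write result rows as TSV (``.tsv``) or as a JSON envelope
    ``{parameters, rows, log}`` (any other suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)
    else:
        payload = {"parameters": dict(parameters or {}), "rows": [dict(r) for r in rows], "log": []}
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
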