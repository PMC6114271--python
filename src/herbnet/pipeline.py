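"""End-to-end orchestration: screen compounds, build networks, select
hubs, intersect with the disease gene set, and run enrichment — from a
single YAML/dict config, with a machine-readable run report.

Stage order is fixed: filter -> ct-net -> ppi (topology + hubs) ->
overlap -> enrich.  A stage runs only when its inputs are configured;
a configured-but-missing input file aborts before any stage runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import adme, enrichment, io, network, topology
from .errors import ValidationError

logger = logging.getLogger("herbnet")

STAGE_ORDER = ("filter", "ct_net", "ppi", "overlap", "enrich")

_INPUT_KEYS = (
    "compounds",
    "ct_pairs",
    "ppi_edges",
    "ppi_nodes",
    "disease_genes",
    "disease_ppi_edges",
    "gene_sets",
    "background",
)


@dataclass
class RunReport:
    """Per-stage counts, the parameter echo, and the stage ordering of
    one pipeline run.  Counts are internally consistent (kept <= in;
    overlap <= min of the two gene sets) and recomputable from the
    artifacts written alongside."""

    seed: int | None
    parameters: dict
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, **counts: Any) -> None:
        self.stages.append({"stage": name, **counts})

    def as_dict(self) -> dict:
        return {"seed": self.seed, "parameters": self.parameters, "stages": self.stages}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, default=str) + "\n")


def _load_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _preflight(cfg: dict) -> dict[str, Path]:
    inputs = cfg.get("inputs", {})
    unknown = set(inputs) - set(_INPUT_KEYS)
    if unknown:
        raise ValidationError(f"unknown input key(s): {sorted(unknown)}")
    paths: dict[str, Path] = {}
    missing = []
    for key, value in inputs.items():
        p = Path(value)
        if not p.exists():
            missing.append(f"{key}: {p}")
        paths[key] = p
    if missing:
        raise ValidationError("missing input file(s): " + "; ".join(missing))
    if "disease_genes" in paths:
        if not io.read_gene_list(paths["disease_genes"]):
            raise ValidationError(f"disease gene list {paths['disease_genes']} is empty")
    return paths


def run_pipeline(config: Mapping | str | Path, outdir: str | Path) -> RunReport:
    """Execute the configured stages, writing one artifact per stage plus
    ``report.json`` and ``run.log`` under ``outdir``.

    Raises :class:`ValidationError` for pre-flight problems (before any
    stage runs) and lets stage-level errors propagate with the stage
    name attached.
    """
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    try:
        return _run(cfg, outdir)
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _run(cfg: dict, outdir: Path) -> RunReport:
    paths = _preflight(cfg)
    params = {
        "filter": {"ob_min": 30.0, "dl_min": 0.18, **cfg.get("filter", {})},
        "hubs": {"scope": "per_partition", **cfg.get("hubs", {})},
        "enrichment": {
            "fdr": 0.05,
            "kappa_threshold": 0.4,
            "min_term_size": 3,
            "max_term_size": 500,
            **cfg.get("enrichment", {}),
        },
    }
    report = RunReport(seed=cfg.get("seed"), parameters=params)
    t0 = time.time()

    kept_ids: set[str] | None = None
    current_stage = "preflight"
    try:
        # ----- filter ---------------------------------------------------
        if "compounds" in paths:
            current_stage = "filter"
            records = io.read_compound_table(paths["compounds"])
            crit = adme.FilterCriteria(**params["filter"])
            kept, rejected = adme.filter_compounds(records, crit)
            kept_ids = {r.compound_id for r in kept}
            io.write_compound_table(kept, outdir / "kept.tsv")
            io.write_results(
                [{"compound_id": r.record.compound_id, "reason": r.reason} for r in rejected],
                outdir / "rejected.tsv",
            )
            report.add_stage("filter", n_in=len(records), n_kept=len(kept), n_rejected=len(rejected))
            logger.info("filter: %d in, %d kept", len(records), len(kept))

        # ----- compound-target network ---------------------------------
        ct_graph = None
        if "ct_pairs" in paths:
            current_stage = "ct_net"
            raw_pairs = []
            with open(paths["ct_pairs"]) as fh:
                for line in fh:
                    if line.strip() and not line.startswith("#"):
                        a, b = line.rstrip("\n").split("\t")[:2]
                        raw_pairs.append((a, b))
            if kept_ids is not None:
                raw_pairs = [(c, t) for c, t in raw_pairs if c in kept_ids]
            ct_graph = network.build_ct_network(raw_pairs)
            degrees = network.ct_degree_table(ct_graph)
            io.write_results(
                [{"compound_id": c, "degree": d} for c, d in sorted(degrees.items())],
                outdir / "ct_degrees.tsv",
            )
            hub_sel = topology.select_hubs(ct_graph, scope=params["hubs"]["scope"])
            hub_compounds = hub_sel.hubs_in_partition(ct_graph, "compound")
            hub_targets = hub_sel.hubs_in_partition(ct_graph, "target")
            io.write_results(
                [
                    {"node": h, "degree": hub_sel.degrees[h],
                     "partition": ct_graph.nodes[h].get("partition")}
                    for h in hub_sel.hubs
                ],
                outdir / "ct_hubs.tsv",
            )
            report.add_stage(
                "ct_net",
                n_compounds=len(degrees),
                n_targets=len(network.ct_targets(ct_graph)),
                n_edges=ct_graph.number_of_edges(),
                n_hub_compounds=len(hub_compounds),
                n_hub_targets=len(hub_targets),
            )
            logger.info(
                "ct_net: %d compounds, %d targets, %d hub compounds",
                len(degrees),
                len(network.ct_targets(ct_graph)),
                len(hub_compounds),
            )

        # ----- drug-target PPI: topology + hubs ------------------------
        drug_net = None
        if "ppi_edges" in paths:
            current_stage = "ppi"
            nodes = io.read_gene_list(paths["ppi_nodes"]) if "ppi_nodes" in paths else None
            drug_net = io.read_edge_list(paths["ppi_edges"], kind="ppi")
            if nodes:
                drug_net.add_nodes_from(nodes)
            summary = topology.path_statistics(drug_net)
            (outdir / "topology.json").write_text(json.dumps(summary.as_dict(), indent=2) + "\n")
            ppi_hubs = topology.select_hubs(drug_net, scope="all_nodes")
            io.write_results(
                [{"node": h, "degree": ppi_hubs.degrees[h]} for h in ppi_hubs.hubs],
                outdir / "ppi_hubs.tsv",
            )
            report.add_stage(
                "ppi",
                n_nodes=drug_net.number_of_nodes(),
                n_edges=drug_net.number_of_edges(),
                radius=summary.radius,
                diameter=summary.diameter,
                characteristic_path_length=summary.characteristic_path_length,
                n_hubs=len(ppi_hubs.hubs),
            )
            logger.info("ppi: %d nodes, %d edges", drug_net.number_of_nodes(), drug_net.number_of_edges())

        # ----- drug / disease overlap ----------------------------------
        overlap = None
        if "disease_genes" in paths and drug_net is not None:
            current_stage = "overlap"
            disease_nodes = io.read_gene_list(paths["disease_genes"])
            if "disease_ppi_edges" in paths:
                disease_net = io.read_edge_list(paths["disease_ppi_edges"], kind="ppi")
                disease_net.add_nodes_from(disease_nodes)
            else:
                disease_net = network.build_disease_network([], nodes=disease_nodes)
            overlap = network.map_overlap(drug_net, disease_net)
            (outdir / "overlap.json").write_text(
                json.dumps(
                    {
                        "n_drug_targets": len(overlap.drug_targets),
                        "n_disease_genes": len(overlap.disease_genes),
                        "n_shared": len(overlap.shared),
                        "shared": sorted(overlap.shared),
                    },
                    indent=2,
                )
                + "\n"
            )
            io.write_gene_list(overlap.shared, outdir / "overlap_genes.txt")
            report.add_stage(
                "overlap",
                n_drug_targets=len(overlap.drug_targets),
                n_disease_genes=len(overlap.disease_genes),
                n_shared=len(overlap.shared),
            )
            logger.info("overlap: %d shared genes", len(overlap.shared))

        # ----- enrichment ----------------------------------------------
        if "gene_sets" in paths and overlap is not None and overlap.shared:
            current_stage = "enrich"
            background = (
                io.read_gene_list(paths["background"]) if "background" in paths else None
            )
            collection = io.read_gmt(paths["gene_sets"], background=background)
            ep = params["enrichment"]
            rows = enrichment.enrich_gene_sets(
                overlap.shared,
                collection,
                min_term_size=ep["min_term_size"],
                max_term_size=ep["max_term_size"],
            )
            sig = enrichment.significant_rows(rows, fdr=ep["fdr"])
            groups = enrichment.group_terms_by_kappa(
                sig, collection, threshold=ep["kappa_threshold"]
            )
            rows = enrichment.annotate_groups(rows, groups)
            io.write_results([r.as_dict() for r in rows], outdir / "enrichment.tsv")
            enriched_genes = set().union(*(r.gene_hits for r in sig)) if sig else set()
            report.add_stage(
                "enrich",
                n_terms_tested=len(rows),
                n_significant=len(sig),
                n_groups=len(groups),
                n_enriched_genes=len(enriched_genes),
            )
            logger.info("enrich: %d significant terms in %d groups", len(sig), len(groups))
    except ValidationError as exc:
        raise ValidationError(f"stage {current_stage!r}: {exc}") from exc

    logger.info("pipeline finished in %.3f s", time.time() - t0)
    report.write(outdir / "report.json")
    return report
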