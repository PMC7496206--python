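"""End-to-end pipeline orchestration with a provenance manifest.

Stages (mirroring the analysis workflow): differential-expression
calling for genes and miRNAs -> profile classification -> evidence
merging and level resolution -> inverse-expression pairing per
condition -> four sub-networks + TF layer -> Ago2 Level-4 promotion ->
keyword sub-networks and enrichment.  All outputs are written under one
directory; the manifest records a hash of the configuration, the seed,
and row counts in/out per stage.  Reruns with the same inputs and
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from glunet import io_formats as io
from glunet.ago2 import IPFilter, ip_supported_entities, promote_level4
from glunet.diffexpr import (
    GENE_THRESHOLDS,
    MIRNA_THRESHOLDS,
    Thresholds,
    call_differential,
)
from glunet.enrichment import enrich, keyword_networks, read_gmt
from glunet.mti import ConsensusParams, evidence_to_frame, load_experimental, load_predictions, merge_evidence
from glunet.network import (
    build_tf_layer,
    edges_to_frame,
    export_network,
    hub_mirnas,
    network_summary,
    pair_inverse,
    split_networks,
)
from glunet.profiles import classify_entities, type_counts

log = logging.getLogger("glunet")


@dataclass
class PipelineConfig:
    """Paths and constants for one pipeline run.

    Defaults are the analysis constants: gene DE 1.5 / 0.67, miRNA DE
    1.4 / 0.71, abundance floors 10 / 10, IP floors 8 / 100, consensus
    >= 3 tools with miRanda >= 140 and MFE <= -10, hub degree > 10,
    top-20 enrichment.
    """

    gene_expression: Path
    mirna_expression: Path
    experimental_mti: Optional[Path] = None
    predictions: dict[str, Path] = field(default_factory=dict)
    gene_ip: Optional[Path] = None
    mirna_ip: Optional[Path] = None
    tf_table: Optional[Path] = None
    annotations: Optional[Path] = None
    term_sets_gmt: Optional[Path] = None
    outdir: Path = Path("glunet_out")
    gene_thresholds: Thresholds = GENE_THRESHOLDS
    mirna_thresholds: Thresholds = MIRNA_THRESHOLDS
    consensus: ConsensusParams = ConsensusParams()
    ip_filter: IPFilter = IPFilter()
    hub_min_targets: int = 10
    enrichment_top: int = 20
    enrichment_correction: str = "bh"
    strict: bool = True
    seed: int = 0

    def validate(self) -> None:
        required = {"gene_expression": self.gene_expression, "mirna_expression": self.mirna_expression}
        optional = {
            "experimental_mti": self.experimental_mti,
            "gene_ip": self.gene_ip,
            "mirna_ip": self.mirna_ip,
            "tf_table": self.tf_table,
            "annotations": self.annotations,
            "term_sets_gmt": self.term_sets_gmt,
            **{f"predictions[{t}]": p for t, p in self.predictions.items()},
        }
        missing = [k for k, p in required.items() if not Path(p).is_file()]
        missing += [k for k, p in optional.items() if p is not None and not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    def config_hash(self) -> str:
        def ser(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: ser(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, Path):
                return str(x)
            if isinstance(x, dict):
                return {k: ser(v) for k, v in sorted(x.items())}
            return x

        fields = ser(self)
        fields.pop("outdir", None)  # where outputs land is not analysis config
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "notes": {
            "condition_semantics": "profile types spanning both comparisons (I/D/M/V) "
            "contribute to both conditions' networks"
        },
    }

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        log.info("stage %-12s %s", name, counts)

    t0 = time.perf_counter()

    # differential expression
    gene_expr = io.read_expression(config.gene_expression, "gene")
    mirna_expr = io.read_expression(config.mirna_expression, "mirna")
    gene_low = call_differential(gene_expr, config.gene_thresholds, "low_vs_mod")
    gene_high = call_differential(gene_expr, config.gene_thresholds, "high_vs_mod")
    mirna_low = call_differential(mirna_expr, config.mirna_thresholds, "low_vs_mod")
    mirna_high = call_differential(mirna_expr, config.mirna_thresholds, "high_vs_mod")
    io.write_calls([*gene_low, *gene_high], outdir / "gene_calls.tsv")
    io.write_calls([*mirna_low, *mirna_high], outdir / "mirna_calls.tsv")
    stage("diffexpr", n_genes=len(gene_expr), n_mirnas=len(mirna_expr))

    # profiles
    gene_profiles = classify_entities(gene_low, gene_high)
    mirna_profiles = classify_entities(mirna_low, mirna_high)
    io.write_profiles(gene_profiles, outdir / "gene_profiles.tsv")
    io.write_profiles(mirna_profiles, outdir / "mirna_profiles.tsv")
    gc, mc = type_counts(gene_profiles), type_counts(mirna_profiles)
    pd.DataFrame(
        [{"profile": str(t), "genes": gc[t], "mirnas": mc[t]} for t in gc]
    ).to_csv(outdir / "profile_counts.tsv", sep="\t", index=False)
    stage(
        "profiles",
        n_gene_classified=len(gene_profiles),
        n_mirna_classified=len(mirna_profiles),
    )

    # evidence
    fragments = []
    if config.experimental_mti:
        fragments += load_experimental(config.experimental_mti, strict=config.strict)
    if config.predictions:
        fragments += load_predictions(config.predictions, strict=config.strict)
    evidence = merge_evidence(fragments)
    ev_frame = evidence_to_frame(evidence, config.consensus)
    ev_frame.to_csv(outdir / "evidence.tsv", sep="\t", index=False, float_format="%.6g")
    stage(
        "mti",
        n_fragments=len(fragments),
        n_candidates=len(evidence),
        n_leveled=int((ev_frame["level"] != "none").sum()),
    )

    # inverse-expression pairing + sub-networks
    edges = []
    for condition in ("low", "high"):
        edges += pair_inverse(
            mirna_profiles, gene_profiles, evidence, condition, config.consensus
        )
    subnets = split_networks(edges)
    summaries = {name: network_summary(es) for name, es in subnets.items()}
    export_network(edges, outdir / "edges.tsv", "edge-tsv")
    export_network(edges, outdir / "network.sif", "sif")
    export_network(edges, outdir / "network.graphml", "graphml")
    for name, es in subnets.items():
        export_network(es, outdir / f"network_{name}.tsv", "edge-tsv")
    hubs = hub_mirnas(edges, config.hub_min_targets)
    pd.DataFrame(hubs, columns=["mirna", "n_targets"]).to_csv(
        outdir / "hub_mirnas.tsv", sep="\t", index=False
    )
    stage("network", n_edges=len(edges), **{f"{k}_edges": v["n_edges"] for k, v in summaries.items()})

    # TF layer
    tf_edges = []
    if config.tf_table:
        tf_edges = build_tf_layer(io.read_tf_table(config.tf_table), mirna_profiles, gene_profiles)
        export_network(tf_edges, outdir / "tf_layer.tsv", "edge-tsv")
    stage("tf_layer", n_tf_edges=len(tf_edges))

    # Ago2 level-4 promotion
    level4_edges, ratio = [], None
    if config.gene_ip and config.mirna_ip:
        gene_set, mirna_set = ip_supported_entities(
            io.read_ip_table(config.gene_ip), io.read_ip_table(config.mirna_ip), config.ip_filter
        )
        level4_edges, ratio = promote_level4(edges, gene_set, mirna_set)
        export_network(level4_edges, outdir / "edges_level4.tsv", "edge-tsv")
        per_subnet = {
            name: (promote_level4(es, gene_set, mirna_set)[1] if es else 1.0)
            for name, es in subnets.items()
        }
        manifest["ago2_reduction"] = {"overall": ratio, **per_subnet}
    stage("ago2", n_input=len(edges), n_level4=len(level4_edges))

    # keyword sub-networks + enrichment
    enr_rows = []
    if config.annotations:
        annotations = io.read_annotations(config.annotations)
        kw = keyword_networks(edges, annotations)
        for cat, es in kw.items():
            export_network(es, outdir / f"network_keyword_{cat}.tsv", "edge-tsv")
        stage("keywords", **{f"{c}_edges": len(es) for c, es in kw.items()})
        term_sets = (
            read_gmt(config.term_sets_gmt)
            if config.term_sets_gmt
            else io.annotations_to_term_sets(annotations)
        )
        background = {
            g
            for g, t in gene_profiles.items()
        }  # expressed (filter-passing) genes
        query = {e.target for e in edges} & background
        if query and term_sets:
            results = enrich(
                query,
                term_sets,
                background,
                correction=config.enrichment_correction,
                top=config.enrichment_top,
            )
            enr_rows = [dataclasses.asdict(r) for r in results]
            pd.DataFrame(
                enr_rows, columns=["term", "k", "K", "n", "N", "p_value", "adjusted_p"]
            ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    stage("enrichment", n_terms_reported=len(enr_rows))

    manifest["summaries"] = summaries
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return manifest
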