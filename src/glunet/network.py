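"""Inverse-expression network assembly, TF layer, and graph export.

A miRNA->gene edge is created when (a) the pair has resolved evidence
level 1-3, (b) both entities are differentially expressed (non-FLAT
profile), (c) the gene's profile is the inverse of the miRNA's, and
(d) the miRNA actually changes under the requested glucose condition.
Profile types spanning both comparisons (I/D/M/V) contribute to both
conditions' networks; single-condition types (LD/LI/HI/HD) contribute
only to theirs.

Edges are split into four sub-networks by (condition, miRNA direction):
high-DN, high-UP, low-DN, low-UP.  A TF->miRNA layer overlays
TransmiR-style regulation rows restricted to DE TFs and DE miRNAs.
Networks export as SIF, GraphML, or a round-trippable edge TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from glunet.mti import ConsensusParams, MTIEvidence, evidence_level
from glunet.profiles import PROFILE_VERDICTS, ProfileType, inverse_type

TF_SIGNS = ("activate", "repress", "unknown")


@dataclass(frozen=True)
class NetworkEdge:
    """A directed regulatory edge: miRNA->gene (mti) or TF->miRNA (tf_mirna)."""

    source: str
    target: str
    edge_kind: str  # "mti" | "tf_mirna"
    condition: Optional[str] = None  # "low" | "high" (mti edges)
    mirna_direction: Optional[str] = None  # miRNA verdict in that condition
    level: Optional[int] = None  # 1..4 for mti edges
    sign: Optional[str] = None  # activate/repress/unknown for tf_mirna
    source_profile: Optional[ProfileType] = None
    target_profile: Optional[ProfileType] = None


@dataclass(frozen=True)
class KeywordAnnotation:
    """Functional keyword tags for one gene.

    Categories follow the beta-cell functional keyword classes:
    G = glucose/carbon/insulin, O = ion/calcium, E =
    exocytosis/homeostasis, C = CREB/cAMP/transcription factor.
    """

    gene: str
    categories: frozenset[str]
    term_sets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = self.categories - {"G", "O", "E", "C"}
        if bad:
            raise ValueError(f"unknown keyword categories {sorted(bad)} for {self.gene}")


def pair_inverse(
    mirna_profiles: Mapping[str, ProfileType],
    gene_profiles: Mapping[str, ProfileType],
    evidence: Mapping[tuple[str, str], MTIEvidence],
    condition: str,
    params: ConsensusParams = ConsensusParams(),
) -> list[NetworkEdge]:
    """Pair DE miRNAs with inversely expressed DE target genes.

    Returns deduplicated edges sorted by (mirna, gene).  Evidence rows
    naming entities absent from the profile maps are skipped with a
    warning (they were filtered upstream or never measured).
    """
    if condition not in ("low", "high"):
        raise ValueError(f"condition must be 'low' or 'high', got {condition!r}")
    verdict_idx = 0 if condition == "low" else 1
    edges: dict[tuple[str, str], NetworkEdge] = {}
    n_unknown = 0
    for (mirna, gene), e in evidence.items():
        level = evidence_level(e, params)
        if level is None:
            continue
        if mirna not in mirna_profiles or gene not in gene_profiles:
            n_unknown += 1
            continue
        mt, gt = mirna_profiles[mirna], gene_profiles[gene]
        if mt is ProfileType.FLAT or gt is ProfileType.FLAT:
            continue
        if gt is not inverse_type(mt):
            continue
        direction = PROFILE_VERDICTS[mt][verdict_idx]
        if direction == "nc":  # miRNA unchanged under this condition
            continue
        edges[(mirna, gene)] = NetworkEdge(
            source=mirna,
            target=gene,
            edge_kind="mti",
            condition=condition,
            mirna_direction=direction,
            level=level,
            source_profile=mt,
            target_profile=gt,
        )
    if n_unknown:
        warnings.warn(
            f"{n_unknown} evidence rows referenced entities absent from the "
            "expression profiles; skipped",
            stacklevel=2,
        )
    return [edges[k] for k in sorted(edges)]


def split_networks(
    edges: Iterable[NetworkEdge],
) -> dict[str, list[NetworkEdge]]:
    """Partition mti edges into {high_dn, high_up, low_dn, low_up}."""
    subnets: dict[str, list[NetworkEdge]] = {
        "high_dn": [],
        "high_up": [],
        "low_dn": [],
        "low_up": [],
    }
    for e in edges:
        if e.edge_kind != "mti":
            continue
        key = f"{e.condition}_{'dn' if e.mirna_direction == 'down' else 'up'}"
        subnets[key].append(e)
    return subnets


def network_summary(edges: Sequence[NetworkEdge]) -> dict[str, int]:
    """(n miRNAs, n genes, n edges) for one mti sub-network."""
    return {
        "n_mirnas": len({e.source for e in edges}),
        "n_genes": len({e.target for e in edges}),
        "n_edges": len(edges),
    }


def hub_mirnas(edges: Sequence[NetworkEdge], min_targets: int = 10) -> list[tuple[str, int]]:
    """miRNAs regulating strictly more than ``min_targets`` genes.

    Sorted by out-degree descending, ties broken by id.
    """
    degree: dict[str, set[str]] = {}
    for e in edges:
        if e.edge_kind == "mti":
            degree.setdefault(e.source, set()).add(e.target)
    ranked = [(m, len(gs)) for m, gs in degree.items() if len(gs) > min_targets]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


def build_tf_layer(
    tf_table: pd.DataFrame,
    mirna_profiles: Mapping[str, ProfileType],
    gene_profiles: Mapping[str, ProfileType],
) -> list[NetworkEdge]:
    """TF->miRNA edges for DE TF genes regulating DE miRNAs.

    ``tf_table`` columns: tf_gene, mirna, sign (activate/repress/unknown).
    TFs absent from the gene expression profiles are skipped with a
    warning; FLAT TFs or FLAT miRNAs yield no edges.
    """
    for col in ("tf_gene", "mirna", "sign"):
        if col not in tf_table.columns:
            raise ValueError(f"TF table missing column {col!r}")
    edges: dict[tuple[str, str], NetworkEdge] = {}
    n_missing = 0
    for row in tf_table.itertuples(index=False):
        tf, mirna, sign = row.tf_gene, row.mirna, row.sign
        if sign not in TF_SIGNS:
            raise ValueError(f"unknown TF regulation sign {sign!r}")
        if tf not in gene_profiles:
            n_missing += 1
            continue
        if mirna not in mirna_profiles:
            continue
        tft, mt = gene_profiles[tf], mirna_profiles[mirna]
        if tft is ProfileType.FLAT or mt is ProfileType.FLAT:
            continue
        edges[(tf, mirna)] = NetworkEdge(
            source=tf,
            target=mirna,
            edge_kind="tf_mirna",
            sign=sign,
            source_profile=tft,
            target_profile=mt,
        )
    if n_missing:
        warnings.warn(
            f"{n_missing} TF rows named genes absent from the expression matrix; skipped",
            stacklevel=2,
        )
    return [edges[k] for k in sorted(edges)]


def _interaction_label(e: NetworkEdge) -> str:
    return f"mti_L{e.level}" if e.edge_kind == "mti" else "tf_mirna"


def edges_to_frame(edges: Iterable[NetworkEdge]) -> pd.DataFrame:
    rows = []
    for e in edges:
        rows.append(
            {
                "source": e.source,
                "target": e.target,
                "edge_kind": e.edge_kind,
                "condition": e.condition or "",
                "mirna_direction": e.mirna_direction or "",
                "level": "" if e.level is None else str(e.level),
                "sign": e.sign or "",
                "source_profile": str(e.source_profile) if e.source_profile else "",
                "target_profile": str(e.target_profile) if e.target_profile else "",
            }
        )
    cols = [
        "source",
        "target",
        "edge_kind",
        "condition",
        "mirna_direction",
        "level",
        "sign",
        "source_profile",
        "target_profile",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["source", "target", "edge_kind"]).reset_index(drop=True)


def frame_to_edges(df: pd.DataFrame) -> list[NetworkEdge]:
    edges = []
    for row in df.itertuples(index=False):
        edges.append(
            NetworkEdge(
                source=row.source,
                target=row.target,
                edge_kind=row.edge_kind,
                condition=row.condition or None,
                mirna_direction=row.mirna_direction or None,
                level=int(row.level) if str(row.level) not in ("", "nan") else None,
                sign=row.sign or None,
                source_profile=ProfileType(row.source_profile) if row.source_profile else None,
                target_profile=ProfileType(row.target_profile) if row.target_profile else None,
            )
        )
    return edges


def to_graph(edges: Iterable[NetworkEdge]) -> nx.DiGraph:
    """Build a networkx DiGraph with per-edge and per-node attributes."""
    g = nx.DiGraph()
    for e in edges:
        src_kind = "tf" if e.edge_kind == "tf_mirna" else "mirna"
        tgt_kind = "mirna" if e.edge_kind == "tf_mirna" else "gene"
        g.add_node(e.source, kind=src_kind, profile=str(e.source_profile or ""))
        g.add_node(e.target, kind=tgt_kind, profile=str(e.target_profile or ""))
        g.add_edge(
            e.source,
            e.target,
            interaction=_interaction_label(e),
            edge_kind=e.edge_kind,
            condition=e.condition or "",
            mirna_direction=e.mirna_direction or "",
            level=0 if e.level is None else e.level,
            sign=e.sign or "",
        )
    return g


def export_network(
    edges: Sequence[NetworkEdge],
    path: str | Path,
    fmt: str = "edge-tsv",
) -> Path:
    """Write edges as 'sif', 'graphml' or 'edge-tsv'; returns the path.

    SIF lines read ``source<TAB>interaction<TAB>target`` with interaction
    labels mti_L1..mti_L4 and tf_mirna.  Edge TSV round-trips exactly via
    :func:`read_edge_tsv`.
    """
    path = Path(path)
    if fmt == "edge-tsv":
        edges_to_frame(edges).to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        lines = sorted(
            f"{e.source}\t{_interaction_label(e)}\t{e.target}" for e in edges
        )
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(to_graph(edges), path, named_key_ids=True)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use sif, graphml or edge-tsv")
    return path


def read_edge_tsv(path: str | Path) -> list[NetworkEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return frame_to_edges(df)
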