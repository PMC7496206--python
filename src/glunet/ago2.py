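"""Ago2 IP-seq support: abundance filtering and Level-4 promotion.

RNA co-immunoprecipitated with Argonaute-2 enriches for RISC-loaded
miRNAs and their bound targets.  Entities are counted as IP-supported
when their IP-library abundance reaches the detection floor (genes:
FPKM >= 8; miRNAs: RPM >= 100 — abundances *below* the floor are
filtered, so a value exactly at it is retained).  Candidate edges whose
miRNA and gene are both IP-supported are promoted to evidence level 4;
the rest are dropped, so the promoted set is always a subset of the
input (the IP step only ever reduces a network).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from glunet.network import NetworkEdge


@dataclass(frozen=True)
class IPFilter:
    min_gene_fpkm: float = 8.0
    min_mirna_rpm: float = 100.0

    def __post_init__(self) -> None:
        if self.min_gene_fpkm < 0 or self.min_mirna_rpm < 0:
            raise ValueError("IP filter thresholds must be non-negative")


def _supported(table: pd.DataFrame, floor: float) -> set[str]:
    vals = table.max(axis=1, numeric_only=True)
    if (vals.dropna() < 0).any():
        raise ValueError("negative IP abundances")
    return set(vals.index[vals >= floor])


def ip_supported_entities(
    gene_ip: pd.DataFrame,
    mirna_ip: pd.DataFrame,
    f: IPFilter = IPFilter(),
) -> tuple[set[str], set[str]]:
    """IP-detected (gene set, miRNA set) from IP expression tables.

    Tables are indexed by entity id with one or more abundance columns
    (a single IP library, or condition-matched libraries); an entity is
    supported when any column reaches the floor.
    """
    return _supported(gene_ip, f.min_gene_fpkm), _supported(mirna_ip, f.min_mirna_rpm)


def promote_level4(
    edges: Sequence[NetworkEdge],
    gene_set: set[str],
    mirna_set: set[str],
) -> tuple[list[NetworkEdge], float]:
    """Keep edges with both endpoints IP-supported, at level 4.

    Returns (promoted edges, reduction ratio n_out / n_in; 1.0 for an
    empty input).  Intersection is entity-level: the miRNA must be in
    ``mirna_set`` and the gene in ``gene_set``.
    """
    kept = [
        replace(e, level=4)
        for e in edges
        if e.edge_kind == "mti" and e.source in mirna_set and e.target in gene_set
    ]
    ratio = len(kept) / len(edges) if edges else 1.0
    return kept, ratio
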