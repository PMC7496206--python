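"""Fold-change differential expression calling across glucose conditions.

The study design has one sequencing library per condition (no replicates),
so differential expression is defined purely by fold change relative to
the moderate-glucose condition, after removing entities whose abundance
is below a floor in *both* compared samples.  Default thresholds:

* genes (FPKM):   up if FC >= 1.5, down if FC <= 0.67, floor 10
* miRNAs (RPM):   up if FC >= 1.4, down if FC <= 0.71, floor 10

A stricter/looser preset (1.2 / 0.83, exclusive bounds) is provided as
``METHODS_MRNA_THRESHOLDS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

CONDITIONS = ("low", "moderate", "high")
COMPARISONS = ("low_vs_mod", "high_vs_mod")
Comparison = Literal["low_vs_mod", "high_vs_mod"]
Verdict = Literal["up", "down", "nc", "filtered"]

#: sample column used by each comparison (reference is always "moderate")
_SAMPLE_COL = {"low_vs_mod": "low", "high_vs_mod": "high"}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Entity x condition abundance table for one entity kind.

    ``data`` is indexed by entity id with columns ``low``, ``moderate``,
    ``high``; values are FPKM (genes) or RPM (miRNAs), all >= 0.
    """

    entity_kind: Literal["gene", "mirna"]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.entity_kind not in ("gene", "mirna"):
            raise ValueError(f"unknown entity kind: {self.entity_kind!r}")
        missing = [c for c in CONDITIONS if c not in self.data.columns]
        if missing:
            raise ValueError(f"expression matrix missing conditions: {missing}")
        if not self.data.index.is_unique:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate entity ids: {dups[:5]}")
        vals = self.data[list(CONDITIONS)].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("expression matrix contains NaN")
        if (vals < 0).any():
            raise ValueError("negative abundance values")

    @property
    def entities(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class Thresholds:
    """Fold-change cutoffs and the low-abundance floor for one entity kind.

    ``up_inclusive`` / ``down_inclusive`` control whether a fold change
    exactly at the bound is called (>= / <=) or not (> / <).
    """

    up_fc: float
    down_fc: float
    min_abundance: float = 10.0
    up_inclusive: bool = True
    down_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.down_fc < 1 < self.up_fc):
            raise ValueError(
                f"need down_fc < 1 < up_fc, got {self.down_fc}, {self.up_fc}"
            )
        if self.min_abundance < 0:
            raise ValueError("min_abundance must be >= 0")

    def verdict(self, fc: float) -> Verdict:
        """Classify a single fold change (entity assumed to pass the floor)."""
        if (fc >= self.up_fc) if self.up_inclusive else (fc > self.up_fc):
            return "up"
        if (fc <= self.down_fc) if self.down_inclusive else (fc < self.down_fc):
            return "down"
        return "nc"


#: Results-level DEG definition for genes (FPKM), inclusive bounds.
GENE_THRESHOLDS = Thresholds(up_fc=1.5, down_fc=0.67, min_abundance=10.0)
#: DEmiR definition for miRNAs (RPM), inclusive bounds.
MIRNA_THRESHOLDS = Thresholds(up_fc=1.4, down_fc=0.71, min_abundance=10.0)
#: Alternative mRNA preset (exclusive bounds, as worded for this pair).
METHODS_MRNA_THRESHOLDS = Thresholds(
    up_fc=1.2, down_fc=0.83, min_abundance=10.0, up_inclusive=False, down_inclusive=False
)


@dataclass(frozen=True)
class DifferentialCall:
    entity: str
    comparison: Comparison
    fold_change: float
    log2_fc: float
    verdict: Verdict


def fold_change(sample_value: float, reference_value: float, pseudocount: float = 0.0) -> float:
    """Ratio (sample + pseudocount) / (reference + pseudocount).

    With pseudocount 0 and a zero reference the result is ``inf`` if the
    sample is expressed, else 1.0 (no change between two zeros).
    """
    if sample_value < 0 or reference_value < 0:
        raise ValueError("abundances must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    denom = reference_value + pseudocount
    if denom == 0:
        return math.inf if sample_value > 0 else 1.0
    return (sample_value + pseudocount) / denom


def call_differential(
    matrix: ExpressionMatrix,
    thresholds: Thresholds,
    comparison: Comparison,
    pseudocount: float = 0.0,
) -> list[DifferentialCall]:
    """Call up / down / nc / filtered for every entity in one comparison.

    An entity is ``filtered`` when its abundance is strictly below
    ``thresholds.min_abundance`` in *both* compared samples (the sample
    condition and moderate); the floor is applied per comparison.
    Output preserves the matrix row order.
    """
    if comparison not in _SAMPLE_COL:
        raise ValueError(f"unknown comparison {comparison!r}; expected one of {COMPARISONS}")
    sample = matrix.data[_SAMPLE_COL[comparison]]
    reference = matrix.data["moderate"]
    calls: list[DifferentialCall] = []
    floor = thresholds.min_abundance
    for entity in matrix.data.index:
        s, r = float(sample[entity]), float(reference[entity])
        fc = fold_change(s, r, pseudocount)
        log2fc = math.log2(fc) if 0 < fc < math.inf else (math.inf if fc > 1 else -math.inf)
        if s < floor and r < floor:
            v: Verdict = "filtered"
        else:
            v = thresholds.verdict(fc)
        calls.append(DifferentialCall(entity, comparison, fc, log2fc, v))
    return calls


def de_sets(
    low_calls: Iterable[DifferentialCall], high_calls: Iterable[DifferentialCall]
) -> dict[Comparison, dict[str, set[str]]]:
    """Collect {up, down} id sets per comparison from complete call lists."""
    by_comp = {"low_vs_mod": list(low_calls), "high_vs_mod": list(high_calls)}
    ids = {c: {call.entity for call in calls} for c, calls in by_comp.items()}
    if ids["low_vs_mod"] != ids["high_vs_mod"]:
        odd = ids["low_vs_mod"] ^ ids["high_vs_mod"]
        raise ValueError(f"entities present in only one comparison: {sorted(odd)[:5]}")
    out: dict[Comparison, dict[str, set[str]]] = {}
    for comp, calls in by_comp.items():
        out[comp] = {
            "up": {c.entity for c in calls if c.verdict == "up"},
            "down": {c.entity for c in calls if c.verdict == "down"},
        }
    return out


def calls_to_frame(calls: Iterable[DifferentialCall]) -> pd.DataFrame:
    """Tabulate calls as a DataFrame (id, comparison, fc, log2fc, verdict)."""
    return pd.DataFrame(
        [
            {
                "id": c.entity,
                "comparison": c.comparison,
                "fc": c.fold_change,
                "log2fc": c.log2_fc,
                "verdict": c.verdict,
            }
            for c in calls
        ],
        columns=["id", "comparison", "fc", "log2fc", "verdict"],
    )
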