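"""miRNA-target interaction (MTI) evidence: loading, merging, levels.

Candidate MTIs carry two classes of evidence:

* experimental flags from a miRTarBase-style table — *strong* (reporter
  assay / Western blot) or *weak* (CLIP-seq class);
* per-tool computational predictions from up to four tools (miRanda,
  PITA, TargetScan, RNAhybrid), each with a score and a duplex minimum
  free energy (MFE, kcal/mol, negative for stable duplexes).

Predicted-only candidates are accepted by a consensus rule: predicted by
at least three tools, duplex MFE at most -10 kcal/mol, and — when a
miRanda hit is among the supporters — miRanda score at least 140.

Each candidate resolves to an evidence level: 1 (strong experimental),
2 (weak experimental), 3 (consensus prediction), or none (discarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

TOOLS = ("miranda", "pita", "targetscan", "rnahybrid")


@dataclass(frozen=True)
class PredictionHit:
    tool: str
    score: float
    mfe: float  # kcal/mol; <= 0 by convention

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown prediction tool {self.tool!r}; expected one of {TOOLS}")


@dataclass
class MTIEvidence:
    """All evidence for one (miRNA, gene) candidate; at most one hit per tool."""

    mirna: str
    gene: str
    experimental_strong: bool = False
    experimental_weak: bool = False
    hits: dict[str, PredictionHit] = field(default_factory=dict)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna, self.gene)


@dataclass(frozen=True)
class ConsensusParams:
    """Constants of the consensus prediction rule.

    ``mfe_cutoff`` is expressed on the physical (negative) scale: a hit
    satisfies it when its MFE <= cutoff.  ``mfe_all_hits`` requires every
    supporting hit to pass instead of at least one.  ``require_miranda``
    makes a miRanda hit mandatory rather than only constrained when
    present.
    """

    min_tools: int = 3
    min_miranda_score: float = 140.0
    mfe_cutoff: float = -10.0
    require_miranda: bool = False
    mfe_all_hits: bool = False


def consensus_accept(e: MTIEvidence, params: ConsensusParams = ConsensusParams()) -> bool:
    """Does the candidate's prediction evidence pass the consensus rule?"""
    hits = e.hits
    if len(hits) < params.min_tools:
        return False
    mfes = [h.mfe for h in hits.values()]
    if params.mfe_all_hits:
        if not all(m <= params.mfe_cutoff for m in mfes):
            return False
    elif not any(m <= params.mfe_cutoff for m in mfes):
        return False
    miranda = hits.get("miranda")
    if miranda is None:
        return not params.require_miranda
    return miranda.score >= params.min_miranda_score


def evidence_level(
    e: MTIEvidence, params: ConsensusParams = ConsensusParams()
) -> Optional[int]:
    """Resolve to level 1, 2, 3 or None (precedence: strong > weak > predicted)."""
    if e.experimental_strong:
        return 1
    if e.experimental_weak:
        return 2
    if consensus_accept(e, params):
        return 3
    return None


def _better_hit(a: PredictionHit, b: PredictionHit) -> PredictionHit:
    # lowest (most stable) MFE wins, then highest score
    if (a.mfe, -a.score) <= (b.mfe, -b.score):
        return a
    return b


def merge_evidence(fragments: Iterable[MTIEvidence]) -> dict[tuple[str, str], MTIEvidence]:
    """Merge fragments keyed on (mirna, gene).

    Experimental flags are OR-combined (evidence never downgrades); hit
    sets are unioned keeping the best duplicate per tool.  Merging is
    order-independent.
    """
    table: dict[tuple[str, str], MTIEvidence] = {}
    for frag in fragments:
        key = frag.pair
        if key not in table:
            table[key] = MTIEvidence(
                frag.mirna,
                frag.gene,
                frag.experimental_strong,
                frag.experimental_weak,
                dict(frag.hits),
            )
            continue
        cur = table[key]
        cur.experimental_strong |= frag.experimental_strong
        cur.experimental_weak |= frag.experimental_weak
        for tool, hit in frag.hits.items():
            cur.hits[tool] = _better_hit(cur.hits[tool], hit) if tool in cur.hits else hit
    return table


def load_experimental(path: str | Path, strict: bool = True) -> list[MTIEvidence]:
    """Read a miRTarBase-style TSV: columns mirna, gene, evidence_class.

    ``evidence_class`` is ``strong`` or ``weak``.  Malformed rows are
    reported with their line number and either abort (strict) or are
    skipped.
    """
    frags: list[MTIEvidence] = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["mirna", "gene", "evidence_class"], path)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        mirna, gene, cls = row.mirna, row.gene, row.evidence_class
        if not mirna or not gene or cls not in ("strong", "weak") or pd.isna(mirna) or pd.isna(gene):
            msg = f"{path}:{i}: malformed experimental row {tuple(row)!r}"
            if strict:
                raise ValueError(msg)
            import warnings

            warnings.warn(msg + " (skipped)", stacklevel=2)
            continue
        frags.append(
            MTIEvidence(
                mirna,
                gene,
                experimental_strong=(cls == "strong"),
                experimental_weak=(cls == "weak"),
            )
        )
    return frags


def load_predictions(paths: dict[str, str | Path], strict: bool = True) -> list[MTIEvidence]:
    """Read per-tool prediction TSVs: columns mirna, gene, score, mfe."""
    frags: list[MTIEvidence] = []
    for tool, path in paths.items():
        if tool not in TOOLS:
            raise ValueError(f"unknown prediction tool {tool!r}")
        df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
        _require_columns(df, ["mirna", "gene", "score", "mfe"], path)
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                if pd.isna(row.mirna) or pd.isna(row.gene) or not row.mirna or not row.gene:
                    raise ValueError("empty id")
                hit = PredictionHit(tool, float(row.score), float(row.mfe))
            except (TypeError, ValueError) as exc:
                msg = f"{path}:{i}: malformed prediction row {tuple(row)!r} ({exc})"
                if strict:
                    raise ValueError(msg) from exc
                import warnings

                warnings.warn(msg + " (skipped)", stacklevel=2)
                continue
            frags.append(MTIEvidence(row.mirna, row.gene, hits={tool: hit}))
    return frags


def evidence_to_frame(
    table: dict[tuple[str, str], MTIEvidence], params: ConsensusParams = ConsensusParams()
) -> pd.DataFrame:
    """Summarise merged evidence: mirna, gene, level, n_tools, best_mfe, miranda_score."""
    rows = []
    for (mirna, gene), e in sorted(table.items()):
        level = evidence_level(e, params)
        rows.append(
            {
                "mirna": mirna,
                "gene": gene,
                "level": level if level is not None else "none",
                "n_tools": len(e.hits),
                "best_mfe": min((h.mfe for h in e.hits.values()), default=float("nan")),
                "miranda_score": e.hits["miranda"].score if "miranda" in e.hits else float("nan"),
            }
        )
    return pd.DataFrame(
        rows, columns=["mirna", "gene", "level", "n_tools", "best_mfe", "miranda_score"]
    )


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
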