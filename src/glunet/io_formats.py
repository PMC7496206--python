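"""Tab-separated input/output formats shared by all pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from glunet.diffexpr import CONDITIONS, DifferentialCall, ExpressionMatrix, calls_to_frame
from glunet.mti import TOOLS, MTIEvidence
from glunet.network import KeywordAnnotation
from glunet.profiles import ProfileType


def read_expression(path: str | Path, entity_kind: str) -> ExpressionMatrix:
    """Read an expression TSV with columns id, low, moderate, high."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in ("id", *CONDITIONS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.set_index("id")[list(CONDITIONS)].astype(float)
    return ExpressionMatrix(entity_kind=entity_kind, data=df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = matrix.data[list(CONDITIONS)].copy()
    out.insert(0, "id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_calls(calls: Iterable[DifferentialCall], path: str | Path) -> Path:
    path = Path(path)
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_profiles(assignments: dict[str, ProfileType], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        sorted((e, str(t)) for e, t in assignments.items()), columns=["id", "profile"]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_profiles(path: str | Path) -> dict[str, ProfileType]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.id: ProfileType(row.profile) for row in df.itertuples(index=False)}


def write_evidence_tables(evidence: Sequence[MTIEvidence], outdir: str | Path) -> dict[str, Path]:
    """Split evidence into the experimental TSV and one TSV per tool."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    exp_rows = []
    tool_rows: dict[str, list[dict]] = {t: [] for t in TOOLS}
    for e in evidence:
        if e.experimental_strong:
            exp_rows.append({"mirna": e.mirna, "gene": e.gene, "evidence_class": "strong"})
        if e.experimental_weak:
            exp_rows.append({"mirna": e.mirna, "gene": e.gene, "evidence_class": "weak"})
        for tool, hit in e.hits.items():
            tool_rows[tool].append(
                {"mirna": e.mirna, "gene": e.gene, "score": hit.score, "mfe": hit.mfe}
            )
    paths["experimental"] = outdir / "experimental_mti.tsv"
    pd.DataFrame(exp_rows, columns=["mirna", "gene", "evidence_class"]).to_csv(
        paths["experimental"], sep="\t", index=False
    )
    for tool in TOOLS:
        paths[f"predictions_{tool}"] = outdir / f"predictions_{tool}.tsv"
        pd.DataFrame(tool_rows[tool], columns=["mirna", "gene", "score", "mfe"]).to_csv(
            paths[f"predictions_{tool}"], sep="\t", index=False, float_format="%.6g"
        )
    return paths


def read_ip_table(path: str | Path) -> pd.DataFrame:
    """IP expression table: id column plus one or more abundance columns."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: need an id column and at least one abundance column")
    return df.set_index("id").astype(float)


def write_ip_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = table.copy()
    out.insert(0, "id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_tf_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("tf_gene", "mirna", "sign") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_annotations(path: str | Path) -> list[KeywordAnnotation]:
    """Annotation TSV: gene, categories (comma-joined G/O/E/C), terms."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene", "categories") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        cats = frozenset(c for c in str(row.categories).split(",") if c)
        terms = frozenset(
            t for t in str(getattr(row, "terms", "")).split(",") if t
        )
        out.append(KeywordAnnotation(gene=row.gene, categories=cats, term_sets=terms))
    return out


def annotations_to_term_sets(annotations: Iterable[KeywordAnnotation]) -> dict[str, set[str]]:
    term_sets: dict[str, set[str]] = {}
    for a in annotations:
        for t in a.term_sets:
            term_sets.setdefault(t, set()).add(a.gene)
    return term_sets
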