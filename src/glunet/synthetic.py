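"""Synthetic three-condition expression data with planted ground truth.

Emulates the inputs of the glucose-response network pipeline so every
downstream stage can be tested against a known answer:

* gene (FPKM) and miRNA (RPM) abundance matrices over low / moderate /
  high glucose, one library per condition, with each entity planted as
  one of the nine profile types;
* a miRNA-target evidence table in which planted true interactions carry
  tiered evidence (strong experimental, weak experimental, or a
  consensus-passing prediction profile) and decoy pairs carry evidence
  that fails the consensus rule;
* Ago2 IP expression tables in which entities of IP-supported true
  interactions exceed the IP detection floors and all others fall below;
* a TF->miRNA regulation table and G/O/E/C keyword + term annotations.

Moderate-condition abundances are log2-normal, truncated from below so
that a planted effect can never be erased by the low-abundance floor;
low/high abundances are moderate x 2^(+-effect) per the planted type's
signature, times optional multiplicative log-normal noise.  All sampling
is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from glunet.diffexpr import CONDITIONS, ExpressionMatrix
from glunet.mti import TOOLS, MTIEvidence, PredictionHit
from glunet.profiles import PROFILE_VERDICTS, ProfileType, inverse_type

TIERS = ("strong", "weak", "predicted")

#: (low, high) log2 multiplier signs relative to moderate, per profile type
_SIGNATURE: dict[ProfileType, tuple[int, int]] = {
    ProfileType.I: (-1, +1),
    ProfileType.D: (+1, -1),
    ProfileType.M: (-1, -1),
    ProfileType.V: (+1, +1),
    ProfileType.LD: (-1, 0),
    ProfileType.LI: (+1, 0),
    ProfileType.HI: (0, +1),
    ProfileType.HD: (0, -1),
    ProfileType.FLAT: (0, 0),
}

_DEFAULT_MIX = {
    ProfileType.I: 0.0625,
    ProfileType.D: 0.0625,
    ProfileType.M: 0.0625,
    ProfileType.V: 0.0625,
    ProfileType.LD: 0.0625,
    ProfileType.LI: 0.0625,
    ProfileType.HI: 0.0625,
    ProfileType.HD: 0.0625,
    ProfileType.FLAT: 0.5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design at desk scale: 200 genes and 60
    miRNAs per library, half of each matrix flat and the rest spread
    evenly over the eight response types, 2-fold planted effects
    (comfortably beyond the 1.5x / 1.4x differential-expression cutoffs
    they must survive), mild multiplicative noise, and ~50 planted true
    interactions with a mixed evidence profile.
    """

    n_genes: int = 200
    n_mirnas: int = 60
    profile_mix: Mapping[ProfileType, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    base_abundance_log_mean: float = 6.0  # log2 FPKM/RPM of a typical entity
    base_abundance_log_sd: float = 1.5
    effect_size_log2: float = 1.0  # planted |log2 FC|
    noise_log2_sd: float = 0.1
    frac_true_mti: float = 50 / (200 * 60)  # of all miRNA x gene pairs
    evidence_tier_mix: Mapping[str, float] = field(
        default_factory=lambda: {"strong": 0.2, "weak": 0.2, "predicted": 0.6}
    )
    decoy_rate: float = 0.5  # decoy rows per true interaction
    ip_support_prob: float = 0.4
    abundance_floor: float = 10.0  # low-abundance filter the data must survive
    gene_up_fc: float = 1.5  # downstream thresholds the effect must beat
    gene_down_fc: float = 0.67
    mirna_up_fc: float = 1.4
    mirna_down_fc: float = 0.71
    n_tfs: int = 5
    tf_out_degree: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 1:
            raise ValueError("need at least one gene and one miRNA")
        for name, mix, keys in (
            ("profile_mix", self.profile_mix, set(ProfileType)),
            ("evidence_tier_mix", self.evidence_tier_mix, set(TIERS)),
        ):
            if not set(mix) <= keys:
                raise ValueError(f"{name} has unknown keys: {set(mix) - keys}")
            vals = list(mix.values())
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1, got {sum(vals)}")
        for name, v in (
            ("frac_true_mti", self.frac_true_mti),
            ("decoy_rate", self.decoy_rate),
            ("ip_support_prob", self.ip_support_prob),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frac_true_mti > 1 or self.ip_support_prob > 1:
            raise ValueError("frac_true_mti and ip_support_prob must be <= 1")
        if self.noise_log2_sd < 0:
            raise ValueError("noise_log2_sd must be >= 0")
        needed = max(
            math.log2(self.gene_up_fc),
            -math.log2(self.gene_down_fc),
            math.log2(self.mirna_up_fc),
            -math.log2(self.mirna_down_fc),
        )
        if not self.effect_size_log2 > needed:
            raise ValueError(
                f"effect_size_log2={self.effect_size_log2} must strictly exceed "
                f"log2 of every downstream fold-change threshold ({needed:.3f}); "
                "planted profile types would not be recoverable"
            )


@dataclass
class GroundTruth:
    """What was planted: the answer key for every downstream stage."""

    entity_profiles: dict[str, ProfileType] = field(default_factory=dict)
    true_mtis: set[tuple[str, str, str]] = field(default_factory=set)  # (mirna, gene, tier)
    ip_supported: set[tuple[str, str]] = field(default_factory=set)
    tf_links: set[tuple[str, str, str]] = field(default_factory=set)  # (tf, mirna, sign)

    @property
    def true_pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.true_mtis}

    @property
    def ip_gene_entities(self) -> set[str]:
        return {g for _, g in self.ip_supported}

    @property
    def ip_mirna_entities(self) -> set[str]:
        return {m for m, _ in self.ip_supported}


@dataclass
class SyntheticDataset:
    """All generated pipeline inputs plus the ground truth."""

    config: SimulationConfig
    gene_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    evidence: list[MTIEvidence]
    gene_ip: pd.DataFrame
    mirna_ip: pd.DataFrame
    tf_table: pd.DataFrame
    annotations: pd.DataFrame
    truth: GroundTruth


def _exact_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment: integer counts summing to n."""
    raw = [p * n for p in proportions]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _assign_profiles(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> list[ProfileType]:
    types = sorted(config.profile_mix, key=lambda t: t.value)
    counts = _exact_counts([config.profile_mix[t] for t in types], n)
    assigned = [t for t, c in zip(types, counts) for _ in range(c)]
    rng.shuffle(assigned)
    return assigned


def generate_expression(
    config: SimulationConfig,
    kind: Literal["gene", "mirna"],
    rng: Optional[np.random.Generator] = None,
    ids: Optional[Sequence[str]] = None,
) -> tuple[ExpressionMatrix, dict[str, ProfileType]]:
    """One abundance matrix with planted profile types.

    ``ids`` overrides the synthetic naming (g0001... / mir0001...) with a
    user-supplied list.  Returns the matrix and the id -> type map.
    """
    if kind not in ("gene", "mirna"):
        raise ValueError(f"kind must be 'gene' or 'mirna', got {kind!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes if kind == "gene" else config.n_mirnas
    if ids is None:
        prefix = "g" if kind == "gene" else "mir"
        ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    elif len(ids) != n or len(set(ids)) != n:
        raise ValueError(f"need {n} unique ids, got {len(ids)}")
    types = _assign_profiles(config, n, rng)

    # truncate the moderate abundance so a planted 2^-effect drop can
    # never fall through the low-abundance floor
    lo = math.log2(config.abundance_floor) + config.effect_size_log2
    log_mod = rng.normal(config.base_abundance_log_mean, config.base_abundance_log_sd, size=n)
    for _ in range(1000):
        below = log_mod <= lo
        if not below.any():
            break
        log_mod[below] = rng.normal(
            config.base_abundance_log_mean, config.base_abundance_log_sd, size=int(below.sum())
        )
    else:
        raise RuntimeError(
            "could not draw abundances above the floor; raise base_abundance_log_mean"
        )

    e = config.effect_size_log2
    log_vals = np.empty((n, 3))
    for i, t in enumerate(types):
        slo, shi = _SIGNATURE[t]
        log_vals[i] = (log_mod[i] + slo * e, log_mod[i], log_mod[i] + shi * e)
    if config.noise_log2_sd > 0:
        log_vals += rng.normal(0.0, config.noise_log2_sd, size=log_vals.shape)
    data = pd.DataFrame(2.0 ** log_vals, index=list(ids), columns=list(CONDITIONS))
    matrix = ExpressionMatrix(entity_kind=kind, data=data)
    return matrix, dict(zip(ids, types))


def _plant_true_mtis(
    config: SimulationConfig,
    gene_profiles: Mapping[str, ProfileType],
    mirna_profiles: Mapping[str, ProfileType],
    rng: np.random.Generator,
) -> set[tuple[str, str, str]]:
    """Sample true interactions among inverse-profile DE pairs, with tiers."""
    genes_by_type: dict[ProfileType, list[str]] = {}
    for g, t in gene_profiles.items():
        genes_by_type.setdefault(t, []).append(g)
    compatible: list[tuple[str, str]] = []
    for m, mt in sorted(mirna_profiles.items()):
        if mt is ProfileType.FLAT:
            continue
        for g in sorted(genes_by_type.get(inverse_type(mt), [])):
            compatible.append((m, g))
    n_true = round(config.frac_true_mti * config.n_genes * config.n_mirnas)
    if n_true > len(compatible):
        raise ValueError(
            f"cannot plant {n_true} true interactions: only {len(compatible)} "
            "inverse-profile DE pairs exist; lower frac_true_mti or raise the "
            "non-FLAT profile proportions"
        )
    chosen_idx = rng.choice(len(compatible), size=n_true, replace=False)
    chosen = [compatible[i] for i in sorted(chosen_idx)]
    tier_names = list(TIERS)
    tier_counts = _exact_counts([config.evidence_tier_mix.get(t, 0.0) for t in tier_names], n_true)
    tiers = [t for t, c in zip(tier_names, tier_counts) for _ in range(c)]
    rng.shuffle(tiers)
    return {(m, g, tier) for (m, g), tier in zip(chosen, tiers)}


def generate_mti_evidence(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[MTIEvidence]:
    """Evidence rows for every true interaction plus consensus-failing decoys.

    True tiers: ``strong``/``weak`` set the corresponding experimental
    flag; ``predicted`` rows carry hits from >= 3 tools with MFE <= -10
    and (when miRanda supports) miRanda score >= 140.  Decoys are
    non-true pairs whose prediction profile violates the consensus rule
    in one of three ways: too few tools, miRanda score below 140, or no
    sufficiently stable duplex.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows: list[MTIEvidence] = []
    for mirna, gene, tier in sorted(truth.true_mtis):
        if tier == "strong":
            rows.append(MTIEvidence(mirna, gene, experimental_strong=True))
        elif tier == "weak":
            rows.append(MTIEvidence(mirna, gene, experimental_weak=True))
        elif tier == "predicted":
            n_tools = int(rng.integers(3, 5))
            tools = sorted(rng.choice(TOOLS, size=n_tools, replace=False))
            hits = {}
            for tool in tools:
                score = float(rng.uniform(145, 200)) if tool == "miranda" else float(
                    rng.uniform(0.5, 1.0) if tool == "targetscan" else rng.uniform(60, 200)
                )
                hits[tool] = PredictionHit(tool, score, float(rng.uniform(-28, -10.5)))
            rows.append(MTIEvidence(mirna, gene, hits=hits))
        else:
            raise ValueError(f"unknown evidence tier {tier!r}")

    mirnas = sorted({e for e, t in truth.entity_profiles.items() if not e.startswith("g")})
    genes = sorted({e for e in truth.entity_profiles if e.startswith("g")})
    # fall back to ids seen in true pairs when naming is user-supplied
    if not mirnas or not genes:
        mirnas = sorted(truth.ip_mirna_entities | {m for m, _, _ in truth.true_mtis})
        genes = sorted(truth.ip_gene_entities | {g for _, g, _ in truth.true_mtis})
    n_decoys = round(config.decoy_rate * len(truth.true_mtis))
    true_pairs = truth.true_pairs
    seen: set[tuple[str, str]] = set()
    while len(seen) < n_decoys and mirnas and genes:
        pair = (str(rng.choice(mirnas)), str(rng.choice(genes)))
        if pair in true_pairs or pair in seen:
            continue
        seen.add(pair)
        mode = int(rng.integers(0, 3))
        if mode == 0:  # too few tools
            tools = sorted(rng.choice(TOOLS, size=int(rng.integers(0, 3)), replace=False))
            hits = {
                t: PredictionHit(
                    t,
                    float(rng.uniform(145, 200)) if t == "miranda" else float(rng.uniform(60, 200)),
                    float(rng.uniform(-28, -10.5)),
                )
                for t in tools
            }
        elif mode == 1:  # miRanda score below the cutoff
            others = sorted(rng.choice([t for t in TOOLS if t != "miranda"], size=2, replace=False))
            hits = {
                "miranda": PredictionHit("miranda", float(rng.uniform(20, 135)), float(rng.uniform(-28, -10.5)))
            }
            for t in others:
                hits[t] = PredictionHit(t, float(rng.uniform(60, 200)), float(rng.uniform(-28, -10.5)))
        else:  # no stable duplex anywhere
            tools = sorted(rng.choice(TOOLS, size=3, replace=False))
            hits = {
                t: PredictionHit(
                    t,
                    float(rng.uniform(145, 200)) if t == "miranda" else float(rng.uniform(60, 200)),
                    float(rng.uniform(-8, -1)),
                )
                for t in tools
            }
        rows.append(MTIEvidence(pair[0], pair[1], hits=hits))
    return rows


def generate_ago2_tables(
    truth: GroundTruth,
    config: SimulationConfig,
    gene_ids: Sequence[str],
    mirna_ids: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IP expression tables consistent with the planted IP support.

    Entities of IP-supported pairs exceed the detection floors (gene
    FPKM >= 8, miRNA RPM >= 100); every other entity falls below.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    gene_on, mirna_on = truth.ip_gene_entities, truth.ip_mirna_entities
    gene_vals = [
        float(rng.uniform(20, 300)) if g in gene_on else float(rng.uniform(0, 7.9))
        for g in gene_ids
    ]
    mirna_vals = [
        float(rng.uniform(200, 5000)) if m in mirna_on else float(rng.uniform(0, 99))
        for m in mirna_ids
    ]
    gene_ip = pd.DataFrame({"ip": gene_vals}, index=list(gene_ids))
    mirna_ip = pd.DataFrame({"ip": mirna_vals}, index=list(mirna_ids))
    return gene_ip, mirna_ip


def generate_tf_table(
    truth: GroundTruth,
    config: SimulationConfig,
    gene_profiles: Mapping[str, ProfileType],
    mirna_profiles: Mapping[str, ProfileType],
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """TransmiR-style TF->miRNA rows among DE genes and DE miRNAs.

    Chosen TFs and their planted links are recorded in ``truth.tf_links``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    de_genes = sorted(g for g, t in gene_profiles.items() if t is not ProfileType.FLAT)
    de_mirnas = sorted(m for m, t in mirna_profiles.items() if t is not ProfileType.FLAT)
    n_tfs = min(config.n_tfs, len(de_genes))
    tfs = sorted(str(t) for t in rng.choice(de_genes, size=n_tfs, replace=False))
    rows = []
    for tf in tfs:
        k = min(config.tf_out_degree, len(de_mirnas))
        targets = sorted(str(m) for m in rng.choice(de_mirnas, size=k, replace=False))
        for m in targets:
            sign = str(rng.choice(["activate", "repress"]))
            truth.tf_links.add((tf, m, sign))
            rows.append({"tf_gene": tf, "mirna": m, "sign": sign})
    return pd.DataFrame(rows, columns=["tf_gene", "mirna", "sign"])


def generate_annotations(
    gene_ids: Sequence[str],
    rng: Optional[np.random.Generator] = None,
    category_prob: float = 0.15,
    n_terms: int = 20,
    term_prob: float = 0.1,
    enriched_term: Optional[str] = None,
    enriched_in: Optional[set[str]] = None,
    enrichment_fold: float = 5.0,
) -> pd.DataFrame:
    """Keyword (G/O/E/C) and term-set annotations per gene.

    When ``enriched_term`` is given, genes in ``enriched_in`` join that
    term with probability ``enrichment_fold x term_prob`` (capped at 1)
    versus ``term_prob`` for the rest — a planted over-representation.
    Returns a TSV-ready frame: gene, categories (comma-joined), terms.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    enriched_in = enriched_in or set()
    rows = []
    for g in gene_ids:
        cats = [c for c in ("G", "O", "E", "C") if rng.random() < category_prob]
        terms = [f"term{j + 1:03d}" for j in range(n_terms) if rng.random() < term_prob]
        if enriched_term is not None:
            p = min(1.0, enrichment_fold * term_prob) if g in enriched_in else term_prob
            if rng.random() < p:
                terms.append(enriched_term)
        rows.append({"gene": g, "categories": ",".join(cats), "terms": ",".join(sorted(set(terms)))})
    return pd.DataFrame(rows, columns=["gene", "categories", "terms"])


def generate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate every pipeline input plus the ground-truth answer key."""
    rng = np.random.default_rng(config.seed)
    gene_expr, gene_profiles = generate_expression(config, "gene", rng)
    mirna_expr, mirna_profiles = generate_expression(config, "mirna", rng)
    truth = GroundTruth(entity_profiles={**gene_profiles, **mirna_profiles})
    truth.true_mtis = _plant_true_mtis(config, gene_profiles, mirna_profiles, rng)
    for pair in sorted(truth.true_pairs):
        if rng.random() < config.ip_support_prob:
            truth.ip_supported.add(pair)
    evidence = generate_mti_evidence(truth, config, rng)
    gene_ip, mirna_ip = generate_ago2_tables(
        truth, config, gene_expr.entities, mirna_expr.entities, rng
    )
    tf_table = generate_tf_table(truth, config, gene_profiles, mirna_profiles, rng)
    annotations = generate_annotations(gene_expr.entities, rng)
    return SyntheticDataset(
        config=config,
        gene_expr=gene_expr,
        mirna_expr=mirna_expr,
        evidence=evidence,
        gene_ip=gene_ip,
        mirna_ip=mirna_ip,
        tf_table=tf_table,
        annotations=annotations,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all inputs in the pipeline's TSV formats, truth as TSV + JSON."""
    from glunet import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["gene_expression"] = io.write_expression(ds.gene_expr, outdir / "gene_expression.tsv")
    paths["mirna_expression"] = io.write_expression(ds.mirna_expr, outdir / "mirna_expression.tsv")
    exp_paths = io.write_evidence_tables(ds.evidence, outdir)
    paths.update(exp_paths)
    paths["gene_ip"] = io.write_ip_table(ds.gene_ip, outdir / "gene_ip.tsv")
    paths["mirna_ip"] = io.write_ip_table(ds.mirna_ip, outdir / "mirna_ip.tsv")
    paths["tf_table"] = outdir / "tf_table.tsv"
    ds.tf_table.to_csv(paths["tf_table"], sep="\t", index=False)
    paths["annotations"] = outdir / "annotations.tsv"
    ds.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    paths["truth_pairs"] = outdir / "truth_mtis.tsv"
    pd.DataFrame(
        sorted(ds.truth.true_mtis), columns=["mirna", "gene", "tier"]
    ).to_csv(paths["truth_pairs"], sep="\t", index=False)
    paths["truth_json"] = outdir / "truth.json"
    paths["truth_json"].write_text(
        json.dumps(
            {
                "entity_profiles": {e: str(t) for e, t in sorted(ds.truth.entity_profiles.items())},
                "ip_supported": sorted(list(p) for p in ds.truth.ip_supported),
                "tf_links": sorted(list(l) for l in ds.truth.tf_links),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return paths
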