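"""Synthetic discordant sib-pair studies with known ground truth.

The generator emulates the study design end to end: a cohort of affected male
sib pairs whose ADI-R social scores (SOCT_CS, 0–30) are drawn so that pairs
fall in the large-difference (Δ ≥ 10) or small-difference (Δ ≤ 4) stratum; a
per-sib pool of rare, predicted-deleterious ("qualifying") variants spread
over a synaptome-sized gene panel; and the external resources the downstream
analysis consumes — a modular protein-interaction graph with the risk genes
planted in one module, gene-set collections overlapping that module, and the
risk-gene list itself.

Variant model.  Each pair draws a *shared* pool of Poisson(λ_bg · s)
qualifying variants carried by both sibs (s = ``shared_fraction``, default
0.5, reflecting expected sib genome sharing) and each sib draws
Poisson(λ_bg · (1 − s)) private qualifying variants, all placed uniformly over
the gene panel.  In large-Δ pairs the severe sib additionally draws
Poisson(λ_effect) variants placed uniformly over the risk genes and absent in
the mild sib — the planted signal the burden comparison should detect.  Every
planted variant is annotated to pass the default qualifying-variant filter;
controlled numbers of decoy variants failing exactly one rule each
(missingness, Hardy–Weinberg, rarity, deleteriousness) exercise the filter.

All randomness flows from per-purpose substreams of the single config seed,
so identical configs produce byte-identical studies and adding one stage does
not perturb another's draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Set

import networkx as nx
import numpy as np
import pandas as pd

from . import io as sio
from .filters import FilterConfig, GenotypeMatrix, hwe_exact_p
from .genesets import GeneSetCollection, read_gmt, write_gmt

__all__ = [
    "ScoreParams",
    "AnnotationParams",
    "PPIParams",
    "GeneSetParams",
    "SimulationConfig",
    "SyntheticStudy",
    "StudyTruth",
    "simulate_study",
    "simulate_ppi",
    "simulate_gene_sets",
    "write_study",
    "read_study",
]

_AF_COLS = ("af_espEA", "af_espALL", "af_1kgEA", "af_1kgALL")

# fixed substream ids: stage randomness is keyed by (seed, purpose) so stages
# are independent and stable when new stages are added
_PURPOSE = {"genes": 11, "scores": 23, "variants": 37, "annotations": 41, "ppi": 53, "genesets": 67}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, _PURPOSE[purpose]]))


def _check_prob(name: str, value: float) -> None:
    if not (math.isfinite(value) and 0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


def _check_rate(name: str, value: float) -> None:
    if not (math.isfinite(value) and value >= 0.0):
        raise ValueError(f"{name} must be a finite non-negative rate, got {value}")


@dataclass(frozen=True)
class ScoreParams:
    """SOCT_CS generation per stratum: severe-sib mean/SD and mean Δ (score units).

    Scores are discrete on [score_min, score_max]; Δ is drawn so every
    large-stratum pair has Δ ≥ delta_min_large and every small-stratum pair
    has Δ ≤ delta_max_small.
    """

    severe_mean_large: float = 25.3
    severe_sd_large: float = 2.7
    delta_mean_large: float = 11.6
    severe_mean_small: float = 24.6
    severe_sd_small: float = 4.6
    delta_mean_small: float = 2.1
    delta_min_large: int = 10
    delta_max_small: int = 4
    score_min: int = 0
    score_max: int = 30

    def __post_init__(self) -> None:
        if not (self.score_min <= self.score_max):
            raise ValueError("score_min must not exceed score_max")
        if self.delta_mean_large < self.delta_min_large:
            raise ValueError("delta_mean_large must be >= delta_min_large")
        if not (0 <= self.delta_mean_small <= self.delta_max_small):
            raise ValueError("delta_mean_small must lie in [0, delta_max_small]")
        for name in ("severe_sd_large", "severe_sd_small"):
            _check_rate(name, getattr(self, name))


@dataclass(frozen=True)
class AnnotationParams:
    """Annotation distributions for planted (qualifying) and decoy variants.

    ``class_fractions`` gives the functional-class mix of qualifying variants;
    missense variants receive SIFT/PolyPhen scores clearing both default
    thresholds so the planted truth is invariant to the either/both missense
    rule.  ``decoy_*`` are expected decoy counts per planted variant, each
    decoy failing exactly the named filter rule under the default
    :class:`~sibnet.filters.FilterConfig`.
    """

    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "missense": 0.70,
            "stopgain": 0.08,
            "stoploss": 0.02,
            "frameshift": 0.10,
            "splicing": 0.10,
        }
    )
    af_present_prob: float = 0.7
    hom_fraction: float = 0.02
    decoy_common: float = 0.08
    decoy_benign: float = 0.10
    decoy_missing: float = 0.02
    decoy_hwe: float = 0.005
    missing_call_fraction: float = 0.2  # missing-call rate planted in decoy_missing sites

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        for name in ("af_present_prob", "hom_fraction", "missing_call_fraction"):
            _check_prob(name, getattr(self, name))
        for name in ("decoy_common", "decoy_benign", "decoy_missing", "decoy_hwe"):
            _check_rate(name, getattr(self, name))


@dataclass(frozen=True)
class PPIParams:
    """Planted-partition interactome: module count and within/between edge probabilities."""

    n_modules: int = 8
    p_in: float = 0.1
    p_out: float = 0.002

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        _check_prob("p_in", self.p_in)
        _check_prob("p_out", self.p_out)


@dataclass(frozen=True)
class GeneSetParams:
    """Synthetic gene-set collection: one set overlaps the risk module, the rest do not."""

    n_sets: int = 50
    size_min: int = 10
    size_max: int = 50
    risk_overlap: float = 0.8

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if not (1 <= self.size_min <= self.size_max):
            raise ValueError("need 1 <= size_min <= size_max")
        _check_prob("risk_overlap", self.risk_overlap)


@dataclass(frozen=True)
class SimulationConfig:
    """Full study configuration; the defaults are the emulated study conditions.

    ``lambda_background`` is the mean number of qualifying variants per sib
    (split ``shared_fraction`` : 1−``shared_fraction`` between a family-shared
    pool and private draws); ``lambda_effect`` is the mean number of EXTRA
    severe-sib-only risk-gene variants planted in large-Δ pairs.
    """

    n_pairs_large: int = 92
    n_pairs_small: int = 108
    n_genes: int = 1886
    n_risk_genes: int = 100
    lambda_background: float = 700.0
    lambda_effect: float = 37.0
    shared_fraction: float = 0.5
    score_params: ScoreParams = field(default_factory=ScoreParams)
    annotation_params: AnnotationParams = field(default_factory=AnnotationParams)
    ppi_params: PPIParams = field(default_factory=PPIParams)
    geneset_params: GeneSetParams = field(default_factory=GeneSetParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs_large < 0 or self.n_pairs_small < 0:
            raise ValueError("pair counts must be non-negative")
        if self.n_pairs_large + self.n_pairs_small == 0:
            raise ValueError("at least one sib pair is required")
        if not (0 < self.n_genes):
            raise ValueError("n_genes must be positive")
        if not (0 < self.n_risk_genes <= self.n_genes):
            raise ValueError("need 0 < n_risk_genes <= n_genes")
        _check_rate("lambda_background", self.lambda_background)
        _check_rate("lambda_effect", self.lambda_effect)
        _check_prob("shared_fraction", self.shared_fraction)

    @property
    def n_pairs(self) -> int:
        return self.n_pairs_large + self.n_pairs_small


@dataclass
class StudyTruth:
    """Ground truth recorded at generation time."""

    risk_genes: List[str]
    module_of: Dict[str, int]  # planted PPI module label per gene
    effect_keys: Set[str]  # planted severe-only risk variants
    per_sib: pd.DataFrame  # sample_id, n_background, n_effect (realized planted counts)
    qualifying_keys: Set[str]  # variants that pass the default filter
    exclusion_rules: Dict[str, str]  # decoy key -> first-failing rule
    stratum_of: Dict[str, str]  # family -> "large" | "small"


@dataclass
class SyntheticStudy:
    phenotypes: pd.DataFrame
    pairs: pd.DataFrame
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    ppi: nx.Graph
    gene_sets: GeneSetCollection
    truth: StudyTruth

    def __post_init__(self) -> None:
        paired = set(self.pairs["sib_a"]) | set(self.pairs["sib_b"])
        known = set(self.phenotypes["sample_id"])
        if not paired <= known:
            raise ValueError(f"paired samples missing from phenotypes: {sorted(paired - known)[:5]}")
        if not paired <= set(self.genotypes.samples):
            raise ValueError("paired samples missing from genotype matrix")


def _gene_names(n_genes: int) -> List[str]:
    return [f"G{i + 1:05d}" for i in range(n_genes)]


def _plan_modules(config: SimulationConfig):
    """Deterministic gene panel, risk-gene list, and planted module labels.

    Module 0 holds every risk gene (padded with random non-risk genes up to
    the even module size when the risk list is smaller); remaining genes are
    spread near-evenly over the other modules.
    """
    genes = _gene_names(config.n_genes)
    rng = _rng(config.seed, "genes")
    perm = rng.permutation(config.n_genes)
    risk_idx = perm[: config.n_risk_genes]
    risk_genes = [genes[i] for i in risk_idx]
    n_mod = config.ppi_params.n_modules
    base = max(config.n_genes // n_mod, 1)
    size0 = max(base, config.n_risk_genes)
    blocks: List[List[str]] = [[genes[i] for i in perm[:size0]]]
    rest = [genes[i] for i in perm[size0:]]
    if n_mod > 1 and rest:
        splits = np.array_split(np.arange(len(rest)), n_mod - 1)
        blocks.extend([[rest[i] for i in chunk] for chunk in splits if len(chunk)])
    module_of = {g: b for b, block in enumerate(blocks) for g in block}
    return genes, risk_genes, module_of, blocks


def _simulate_phenotypes(config: SimulationConfig):
    sp = config.score_params
    rng = _rng(config.seed, "scores")
    rows, pair_rows, meta = [], [], []
    fam = 0
    for stratum, n_pairs in (("large", config.n_pairs_large), ("small", config.n_pairs_small)):
        if stratum == "large":
            mean, sd, dmean = sp.severe_mean_large, sp.severe_sd_large, sp.delta_mean_large
        else:
            mean, sd, dmean = sp.severe_mean_small, sp.severe_sd_small, sp.delta_mean_small
        for _ in range(n_pairs):
            fam += 1
            family = f"F{fam:04d}"
            if stratum == "large":
                delta = sp.delta_min_large + rng.poisson(dmean - sp.delta_min_large)
            else:
                delta = rng.binomial(sp.delta_max_small, dmean / sp.delta_max_small) if sp.delta_max_small else 0
            severe = int(np.clip(round(rng.normal(mean, sd)), sp.score_min, sp.score_max))
            severe = max(severe, sp.score_min + delta)  # keep the mild score in range
            mild = severe - delta
            s1, s2 = f"{family}S1", f"{family}S2"
            severe_first = bool(rng.integers(2))
            scores = (severe, mild) if severe_first else (mild, severe)
            for sib, score in zip((s1, s2), scores):
                rows.append(
                    {
                        "sample_id": sib,
                        "family_id": family,
                        "sex": "M",
                        "age_years": float(np.clip(round(rng.normal(9.0, 2.5), 1), 3.0, 17.9)),
                        "soct_cs": int(score),
                    }
                )
            pair_rows.append({"family_id": family, "sib_a": s1, "sib_b": s2})
            meta.append(
                {
                    "family": family,
                    "sibs": (s1, s2),
                    "severe": s1 if severe_first else s2,
                    "stratum": stratum,
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(pair_rows), meta


def _qualifying_annotations(rng: np.random.Generator, n: int, params: AnnotationParams):
    """Annotation fields guaranteed to pass the default qualifying filter."""
    classes = list(params.class_fractions)
    probs = np.array([params.class_fractions[c] for c in classes])
    fclass = rng.choice(classes, size=n, p=probs).astype(object)
    sift = np.full(n, np.nan)
    pph = np.full(n, np.nan)
    mis = fclass == "missense"
    sift[mis] = np.round(rng.uniform(0.9501, 1.0, mis.sum()), 4)
    pph[mis] = np.round(rng.uniform(0.8501, 1.0, mis.sum()), 4)
    af = np.full((n, len(_AF_COLS)), np.nan)
    present = rng.random((n, len(_AF_COLS))) < params.af_present_prob
    af[present] = np.round(rng.uniform(0.0001, 0.0095, int(present.sum())), 4)
    return fclass, sift, pph, af


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full synthetic study (phenotypes, genotypes, PPI, gene sets, truth).

    Deterministic given ``config.seed``.  See the module docstring for the
    generative model.
    """
    ap = config.annotation_params
    phenotypes, pairs_df, meta = _simulate_phenotypes(config)
    genes, risk_genes, module_of, _ = _plan_modules(config)

    samples: List[str] = []
    for m in meta:
        samples.extend(m["sibs"])
    sidx = {s: i for i, s in enumerate(samples)}
    n_samples = len(samples)
    n_pairs = len(meta)

    rng = _rng(config.seed, "variants")
    lam_shared = config.lambda_background * config.shared_fraction
    lam_priv = config.lambda_background * (1.0 - config.shared_fraction)
    n_shared = rng.poisson(lam_shared, n_pairs)
    n_priv = rng.poisson(lam_priv, n_samples)
    large = np.array([m["stratum"] == "large" for m in meta])
    n_eff = np.where(large, rng.poisson(config.lambda_effect, n_pairs), 0)

    shared_pair = np.repeat(np.arange(n_pairs), n_shared)
    priv_sample = np.repeat(np.arange(n_samples), n_priv)
    eff_pair = np.repeat(np.arange(n_pairs), n_eff)
    v_sh, v_pr, v_ef = len(shared_pair), len(priv_sample), len(eff_pair)
    n_planted = v_sh + v_pr + v_ef

    gene_idx = np.concatenate(
        [
            rng.integers(0, config.n_genes, v_sh + v_pr),
            rng.integers(0, config.n_risk_genes, v_ef),
        ]
    )
    risk_gene_pos = np.array([genes.index(g) for g in risk_genes])
    gene_idx[v_sh + v_pr:] = risk_gene_pos[gene_idx[v_sh + v_pr:]]

    # carrier events: (variant row, sample column, allele count)
    sib1 = np.array([sidx[m["sibs"][0]] for m in meta])
    sib2 = np.array([sidx[m["sibs"][1]] for m in meta])
    severe_col = np.array([sidx[m["severe"]] for m in meta])
    ev_var = np.concatenate(
        [
            np.arange(v_sh), np.arange(v_sh),  # shared: both sibs carry
            v_sh + np.arange(v_pr),
            v_sh + v_pr + np.arange(v_ef),
        ]
    )
    ev_sample = np.concatenate(
        [sib1[shared_pair], sib2[shared_pair], priv_sample, severe_col[eff_pair]]
    )
    ev_gt = np.where(rng.random(len(ev_var)) < ap.hom_fraction, 2, 1).astype(np.int8)

    # decoys, each failing exactly one rule under the default filter config
    default_filter = FilterConfig()
    n_common = rng.poisson(ap.decoy_common * n_planted)
    n_benign = rng.poisson(ap.decoy_benign * n_planted)
    n_missing = rng.poisson(ap.decoy_missing * n_planted)
    hwe_feasible = n_samples >= 2 and hwe_exact_p(0, n_samples, 0) < default_filter.hwe_alpha
    n_hwe = rng.poisson(ap.decoy_hwe * n_planted) if hwe_feasible else 0
    n_decoy = n_common + n_benign + n_missing + n_hwe
    decoy_rules = np.concatenate(
        [
            np.repeat("rarity", n_common),
            np.repeat("deleteriousness", n_benign),
            np.repeat("missingness", n_missing),
            np.repeat("hwe", n_hwe),
        ]
    ).astype(object)
    n_total = n_planted + n_decoy
    gene_idx = np.concatenate([gene_idx, rng.integers(0, config.n_genes, n_decoy)])

    rng_a = _rng(config.seed, "annotations")
    fclass, sift, pph, af = _qualifying_annotations(rng_a, n_total, ap)
    d0 = n_planted
    # rarity decoys: force one panel above the 1% threshold
    if n_common:
        panels = rng_a.integers(0, len(_AF_COLS), n_common)
        af[d0 + np.arange(n_common), panels] = np.round(rng_a.uniform(0.02, 0.2, n_common), 4)
    # deleteriousness decoys: synonymous, or missense with sub-threshold scores
    if n_benign:
        b = d0 + n_common + np.arange(n_benign)
        syn = rng_a.random(n_benign) < 0.5
        fclass[b[syn]] = "synonymous"
        sift[b[syn]] = np.nan
        pph[b[syn]] = np.nan
        fclass[b[~syn]] = "missense"
        sift[b[~syn]] = np.round(rng_a.uniform(0.0, 0.5, int((~syn).sum())), 4)
        pph[b[~syn]] = np.round(rng_a.uniform(0.0, 0.5, int((~syn).sum())), 4)

    genotypes = np.zeros((n_total, n_samples), dtype=np.int8)
    genotypes[ev_var, ev_sample] = ev_gt
    if n_decoy:
        carriers = rng.integers(0, n_samples, n_decoy)
        genotypes[d0 + np.arange(n_decoy), carriers] = 1
    if n_missing:
        m0 = d0 + n_common + n_benign
        k = max(1, math.ceil(ap.missing_call_fraction * n_samples))
        for i in range(n_missing):
            miss = rng.choice(n_samples, size=k, replace=False)
            genotypes[m0 + i, miss] = GenotypeMatrix.MISSING
    if n_hwe:
        genotypes[d0 + n_common + n_benign + n_missing:, :] = 1

    # site coordinates: contiguous chromosome blocks keep the table VCF-sorted
    chrom_ids = np.minimum(np.arange(n_total) // max(1, -(-n_total // 22)), 21) + 1
    pos = np.zeros(n_total, dtype=int)
    for c in np.unique(chrom_ids):
        mask = chrom_ids == c
        pos[mask] = 10_000 + 13 * np.arange(mask.sum())
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n_total)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + 1 + rng.integers(0, 3, n_total)) % 4]

    variants = pd.DataFrame(
        {
            "chrom": chrom_ids.astype(str),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": [genes[i] for i in gene_idx],
            "functional_class": fclass,
            "sift_damage": sift,
            "polyphen": pph,
        }
    )
    for j, col in enumerate(_AF_COLS):
        variants[col] = af[:, j]
    variants.insert(
        0,
        "key",
        variants["chrom"] + ":" + variants["pos"].astype(str) + ":" + variants["ref"] + ":" + variants["alt"],
    )

    keys = list(variants["key"])
    planted_keys = keys[:n_planted]
    effect_keys = set(keys[v_sh + v_pr: n_planted])
    exclusion_rules = dict(zip(keys[n_planted:], decoy_rules))

    n_bg = np.zeros(n_samples, dtype=int)
    np.add.at(n_bg, sib1[shared_pair], 1)
    np.add.at(n_bg, sib2[shared_pair], 1)
    np.add.at(n_bg, priv_sample, 1)
    n_fx = np.zeros(n_samples, dtype=int)
    np.add.at(n_fx, severe_col[eff_pair], 1)
    per_sib = pd.DataFrame({"sample_id": samples, "n_background": n_bg, "n_effect": n_fx})

    truth = StudyTruth(
        risk_genes=risk_genes,
        module_of=module_of,
        effect_keys=effect_keys,
        per_sib=per_sib,
        qualifying_keys=set(planted_keys),
        exclusion_rules=exclusion_rules,
        stratum_of={m["family"]: m["stratum"] for m in meta},
    )
    ppi = simulate_ppi(config)
    gene_sets = simulate_gene_sets(config, ppi)
    return SyntheticStudy(
        phenotypes=phenotypes,
        pairs=pairs_df,
        variants=variants,
        genotypes=GenotypeMatrix(keys, samples, genotypes),
        ppi=ppi,
        gene_sets=gene_sets,
        truth=truth,
    )


def simulate_ppi(config: SimulationConfig) -> nx.Graph:
    """Planted-partition interactome over the gene panel.

    Risk genes are concentrated in module 0; within-module edges appear with
    probability ``p_in``, between-module edges with ``p_out``.  Node attribute
    ``module`` records the planted label.  Simple, undirected, no self-loops;
    deterministic given the config seed.
    """
    _, _, module_of, blocks = _plan_modules(config)
    sizes = [len(b) for b in blocks]
    k = len(sizes)
    pp = config.ppi_params
    pmat = np.full((k, k), pp.p_out)
    np.fill_diagonal(pmat, pp.p_in)
    seed = int(np.random.SeedSequence([config.seed & 0x7FFFFFFF, _PURPOSE["ppi"]]).generate_state(1)[0] % (2**31))
    graph = nx.stochastic_block_model(sizes, pmat.tolist(), seed=seed)
    order = [g for block in blocks for g in block]
    graph = nx.relabel_nodes(graph, dict(enumerate(order)))
    # strip sbm bookkeeping so graphs compare cleanly after IO round trips
    graph.graph.clear()
    nx.set_node_attributes(graph, module_of, "module")
    return graph


def simulate_gene_sets(config: SimulationConfig, ppi: nx.Graph) -> GeneSetCollection:
    """Synthetic curated gene-set collection.

    The first set overlaps the planted risk module at ``risk_overlap`` (its
    size equals the module size; non-overlapping members come from outside the
    module).  All other sets are drawn from outside the risk module with sizes
    uniform in [size_min, size_max].
    """
    gp = config.geneset_params
    module_of = nx.get_node_attributes(ppi, "module")
    if not module_of:
        raise ValueError("PPI graph lacks planted module labels")
    module0 = sorted(g for g, m in module_of.items() if m == 0)
    others = sorted(g for g, m in module_of.items() if m != 0)
    rng = _rng(config.seed, "genesets")
    coll = GeneSetCollection()
    k = int(round(gp.risk_overlap * len(module0)))
    fill = len(module0) - k
    if fill > len(others):
        raise ValueError("not enough genes outside the risk module to pad the risk set")
    members = list(rng.choice(module0, size=k, replace=False)) + list(
        rng.choice(others, size=fill, replace=False)
    )
    coll.add("SET_RISK_MODULE", members, "set overlapping the planted risk module")
    for i in range(gp.n_sets - 1):
        size = int(rng.integers(gp.size_min, gp.size_max + 1))
        size = min(size, len(others))
        coll.add(
            f"SET_{i + 1:04d}",
            list(rng.choice(others, size=size, replace=False)),
            "background set",
        )
    return coll


_STUDY_FILES = {
    "vcf": "study.vcf",
    "phenotypes": "phenotypes.tsv",
    "pairs": "pairs.tsv",
    "ppi": "ppi_edges.tsv",
    "gene_sets": "gene_sets.gmt",
    "risk_genes": "risk_genes.txt",
    "truth": "truth.json",
    "sidecar": "annotations.tsv",
}


def write_study(
    study: SyntheticStudy, directory, overwrite: bool = False, annotation: str = "info"
) -> Dict[str, Dict[str, str]]:
    """Write every study artefact to ``directory``; returns a file manifest.

    Emits the VCF (with INFO annotations, or a plain VCF plus sidecar TSV when
    ``annotation="sidecar"``), phenotype/pairs TSVs, the PPI edge list, the
    GMT collection, the risk-gene list, and the ground-truth record.  Refuses
    to overwrite existing files unless ``overwrite`` is set.  The output
    round-trips through :func:`read_study`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    targets = dict(_STUDY_FILES)
    if annotation != "sidecar":
        targets.pop("sidecar")
    paths = {name: directory / fname for name, fname in targets.items()}
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite without overwrite=True: {existing}")
    sio.write_vcf(
        study.variants,
        study.genotypes,
        paths["vcf"],
        annotation=annotation,
        sidecar_path=paths.get("sidecar"),
    )
    sio.write_phenotypes(study.phenotypes, paths["phenotypes"])
    sio.write_pairs(study.pairs, paths["pairs"])
    sio.write_ppi(study.ppi, paths["ppi"])
    write_gmt(study.gene_sets, paths["gene_sets"])
    sio.write_gene_list(study.truth.risk_genes, paths["risk_genes"])
    truth = study.truth
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "risk_genes": truth.risk_genes,
                "module_of": truth.module_of,
                "effect_keys": sorted(truth.effect_keys),
                "per_sib": truth.per_sib.to_dict(orient="list"),
                "qualifying_keys": sorted(truth.qualifying_keys),
                "exclusion_rules": truth.exclusion_rules,
                "stratum_of": truth.stratum_of,
            },
            fh,
            indent=1,
        )
    return {name: {"path": str(p), "sha256": sio.sha256_of(p)} for name, p in paths.items()}


def read_study(directory) -> SyntheticStudy:
    """Read a written study back; inverse of :func:`write_study`."""
    directory = Path(directory)
    sidecar = directory / _STUDY_FILES["sidecar"]
    variants, genotypes = sio.read_vcf(
        directory / _STUDY_FILES["vcf"], sidecar_path=sidecar if sidecar.exists() else None
    )
    with open(directory / _STUDY_FILES["truth"]) as fh:
        t = json.load(fh)
    truth = StudyTruth(
        risk_genes=list(t["risk_genes"]),
        module_of={g: int(m) for g, m in t["module_of"].items()},
        effect_keys=set(t["effect_keys"]),
        per_sib=pd.DataFrame(t["per_sib"]),
        qualifying_keys=set(t["qualifying_keys"]),
        exclusion_rules=dict(t["exclusion_rules"]),
        stratum_of=dict(t["stratum_of"]),
    )
    ppi = sio.read_ppi(directory / _STUDY_FILES["ppi"])
    ppi.add_nodes_from(truth.module_of)  # restore isolated nodes
    nx.set_node_attributes(ppi, truth.module_of, "module")
    return SyntheticStudy(
        phenotypes=sio.read_phenotypes(directory / _STUDY_FILES["phenotypes"]),
        pairs=sio.read_pairs(directory / _STUDY_FILES["pairs"]),
        variants=variants,
        genotypes=genotypes,
        ppi=ppi,
        gene_sets=read_gmt(directory / _STUDY_FILES["gene_sets"]),
        truth=truth,
    )
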