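"""End-to-end orchestration: simulate/load → filter → cohorts → burden → network → report.

A run is driven by a single declarative :class:`PipelineConfig` (YAML-friendly)
holding either a simulation block or paths to input files, plus per-stage
options.  Every stochastic stage draws its seed from the single global seed
keyed by stage name, so runs are reproducible and adding a stage does not
perturb the randomness of earlier ones.  Outputs and a manifest (config echo,
checksums, record counts) are written to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .burden import (
    compare_burdens,
    gene_recurrence,
    hypergeom_enrichment,
    select_top_genes,
    unshared_variant_sets,
)
from .cohorts import cohort_summary, label_pairs, partition_pairs
from .filters import FilterConfig, qualifying_variants
from .genesets import GmtFormatError, read_gmt
from .membership import build_membership_matrix
from .network import curate_gene_sets, evaluate_communities, community_enrichment, validate_ppi
from .synthdata import SimulationConfig, SyntheticStudy, simulate_study

logger = logging.getLogger(__name__)

STAGES = ("load", "filter", "cohorts", "burden", "network", "report")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, sum(ord(c) for c in stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Declarative run configuration; one of ``simulation`` / ``inputs`` must be set."""

    outdir: str = "sibnet_out"
    seed: int = 0
    log_level: str = "INFO"
    simulation: Optional[SimulationConfig] = None
    inputs: Optional[Dict[str, str]] = None  # vcf, phenotypes, pairs, ppi, gene_sets, risk_genes[, sidecar]
    filter: FilterConfig = field(default_factory=FilterConfig)
    large_min: float = 10
    small_max: float = 4
    burden_mode: str = "welch"
    burden_n_perm: int = 10_000
    burden_unit: str = "site"
    min_pairs: int = 3
    top_k: int = 250
    network_n_perm: int = 1000
    degree_bins: int = 10
    max_jaccard: float = 0.5
    connectivity_alpha: float = 2e-3
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulation' or 'inputs' must be configured")
        if self.inputs is not None:
            required = {"vcf", "phenotypes", "pairs", "ppi", "gene_sets", "risk_genes"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing paths: {sorted(missing)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            from .synthdata import AnnotationParams, GeneSetParams, PPIParams, ScoreParams

            sim = dict(sim)
            for key, sub in (
                ("score_params", ScoreParams),
                ("annotation_params", AnnotationParams),
                ("ppi_params", PPIParams),
                ("geneset_params", GeneSetParams),
            ):
                if key in sim and isinstance(sim[key], dict):
                    sim[key] = sub(**sim[key])
            sim = SimulationConfig(**sim)
        filt = d.pop("filter", None)
        if isinstance(filt, dict):
            if "damaging_indel_classes" in filt:
                filt["damaging_indel_classes"] = frozenset(filt["damaging_indel_classes"])
            filt = FilterConfig(**filt)
        kwargs = dict(d)
        if sim is not None:
            kwargs["simulation"] = sim
        if filt is not None:
            kwargs["filter"] = filt
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict(orient="list")
            return obj

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class ValidationIssue:
    level: str  # "fatal" | "warning"
    file: str
    message: str
    line: Optional[int] = None


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def fatal(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.level == "fatal"]

    @property
    def warnings(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.level == "warning"]

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(paths: Dict[str, str]) -> ValidationReport:
    """Format and cross-file consistency checks on a set of input paths.

    Fatal issues: unreadable or malformed files, paired samples missing from
    the phenotype table or VCF.  Warnings: gene-symbol sets of the variant
    table, PPI network and gene sets that do not overlap (the downstream
    analysis would be vacuous).
    """
    report = ValidationReport()

    def fatal(file, message, line=None):
        report.issues.append(ValidationIssue("fatal", str(file), message, line))

    def warn(file, message):
        report.issues.append(ValidationIssue("warning", str(file), message))

    phen = pairs = variants = genotypes = ppi = sets = None
    try:
        phen = sio.read_phenotypes(paths["phenotypes"])
    except Exception as exc:
        fatal(paths["phenotypes"], str(exc))
    try:
        pairs = sio.read_pairs(paths["pairs"])
    except Exception as exc:
        fatal(paths["pairs"], str(exc))
    try:
        variants, genotypes = sio.read_vcf(paths["vcf"], sidecar_path=paths.get("sidecar"))
        if variants["gene"].isna().any():
            fatal(paths["vcf"], "variants without gene annotation (GENE info or sidecar)")
    except Exception as exc:
        fatal(paths["vcf"], str(exc))
    try:
        ppi = sio.read_ppi(paths["ppi"])
    except Exception as exc:
        fatal(paths["ppi"], str(exc))
    try:
        sets = read_gmt(paths["gene_sets"])
    except GmtFormatError as exc:
        fatal(exc.path, str(exc), line=exc.line_no)
    except Exception as exc:
        fatal(paths["gene_sets"], str(exc))
    try:
        sio.read_gene_list(paths["risk_genes"])
    except Exception as exc:
        fatal(paths["risk_genes"], str(exc))

    if phen is not None and pairs is not None:
        paired = set(pairs["sib_a"]) | set(pairs["sib_b"])
        missing = paired - set(phen["sample_id"])
        if missing:
            fatal(paths["phenotypes"], f"paired samples missing from phenotypes: {sorted(missing)[:5]}")
        if genotypes is not None:
            missing = paired - set(genotypes.samples)
            if missing:
                fatal(paths["vcf"], f"paired samples missing from VCF: {sorted(missing)[:5]}")
    if variants is not None and ppi is not None:
        vg = set(variants["gene"].dropna())
        if vg and not (vg & set(ppi.nodes)):
            warn(paths["ppi"], "PPI gene symbols are disjoint from variant genes")
        if sets is not None and vg and not (vg & sets.all_genes()):
            warn(paths["gene_sets"], "gene-set symbols are disjoint from variant genes")
    return report


@dataclass
class RunManifest:
    config: dict
    versions: Dict[str, str]
    started: str
    finished: str
    counts: Dict[str, int]
    checksums: Dict[str, str]  # output file name -> sha256

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


@dataclass
class RunResult:
    manifest: RunManifest
    study: Optional[SyntheticStudy]
    qualifying: Optional[pd.DataFrame] = None
    exclusions: Optional[dict] = None
    partition: object = None
    cohort_table: Optional[pd.DataFrame] = None
    burden: object = None
    recurrence: Optional[pd.DataFrame] = None
    top_genes: Optional[list] = None
    risk_enrichment: object = None
    communities: object = None
    enrichment: Optional[pd.DataFrame] = None
    membership: object = None


def _load_stage(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = dataclasses.replace(sim, seed=_stage_seed(config.seed, "simulate"))
        study = simulate_study(sim)
        risk_genes = study.truth.risk_genes
        return study.phenotypes, study.pairs, study.variants, study.genotypes, study.ppi, study.gene_sets, risk_genes, study
    paths = config.inputs
    report = validate_inputs(paths)
    if not report.ok:
        first = report.fatal[0]
        raise PipelineError("load", f"{first.file}: {first.message}")
    variants, genotypes = sio.read_vcf(paths["vcf"], sidecar_path=paths.get("sidecar"))
    return (
        sio.read_phenotypes(paths["phenotypes"]),
        sio.read_pairs(paths["pairs"]),
        variants,
        genotypes,
        validate_ppi(sio.read_ppi(paths["ppi"])),
        read_gmt(paths["gene_sets"]),
        sio.read_gene_list(paths["risk_genes"]),
        None,
    )


def run_pipeline(config: PipelineConfig, upto: str = "report") -> RunResult:
    """Execute the pipeline through stage ``upto`` and write outputs + manifest.

    Stage order: load → filter → cohorts → burden → network → report.  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; expected one of {STAGES}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    counts: Dict[str, int] = {}
    outputs: Dict[str, Path] = {}
    last = STAGES.index(upto)

    def do(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    phen, pairs_df, variants, genotypes, ppi, gene_sets, risk_genes, study = do(
        "load", _load_stage, config
    )
    counts["samples"] = len(phen)
    counts["pairs"] = len(pairs_df)
    counts["variants"] = len(variants)
    result = RunResult(manifest=None, study=study)

    if last >= STAGES.index("filter"):
        qualifying, exclusions, rule_of = do(
            "filter", qualifying_variants, variants, genotypes, config.filter
        )
        counts["qualifying_variants"] = len(qualifying)
        result.qualifying, result.exclusions = qualifying, exclusions
        excl = pd.DataFrame({"key": rule_of.index, "rule": rule_of.values})
        outputs["exclusions"] = outdir / "filter_exclusions.tsv"
        excl.to_csv(outputs["exclusions"], sep="\t", index=False)

    if last >= STAGES.index("cohorts"):
        def _cohorts():
            labelled, rejected = label_pairs(pairs_df, phen)
            if len(rejected):
                raise PipelineError(
                    "cohorts",
                    "pairs rejected for missing scores: "
                    + "; ".join(rejected["reason"].head(3)),
                )
            part = partition_pairs(labelled, config.large_min, config.small_max)
            return part, cohort_summary(part, phen)

        partition, cohort_table = do("cohorts", _cohorts)
        counts["pairs_large"] = len(partition.large)
        counts["pairs_small"] = len(partition.small)
        counts["pairs_excluded"] = len(partition.excluded)
        result.partition, result.cohort_table = partition, cohort_table
        outputs["cohorts"] = outdir / "cohorts.tsv"
        partition.to_frame().to_csv(outputs["cohorts"], sep="\t", index=False)
        outputs["cohort_summary"] = outdir / "cohort_summary.tsv"
        cohort_table.to_csv(outputs["cohort_summary"], sep="\t", index=False)

    if last >= STAGES.index("burden"):
        def _burden():
            sets = unshared_variant_sets(
                partition.large + partition.small, result.qualifying, genotypes
            )
            comparison = compare_burdens(
                partition,
                sets,
                mode=config.burden_mode,
                n_perm=config.burden_n_perm,
                seed=_stage_seed(config.seed, "burden"),
                unit=config.burden_unit,
            )
            gene_of = dict(zip(result.qualifying["key"], result.qualifying["gene"]))
            large_sets = {p.family_id: sets[p.family_id] for p in partition.large if p.family_id in sets}
            recurrence = gene_recurrence(large_sets, gene_of)
            top = select_top_genes(recurrence, config.min_pairs, config.top_k)
            universe = sorted(set(variants["gene"].dropna()) | set(risk_genes))
            enr = hypergeom_enrichment(top, set(risk_genes) & set(universe), universe)
            return sets, comparison, recurrence, top, enr, large_sets

        sets, comparison, recurrence, top, risk_enr, large_sets = do("burden", _burden)
        counts["recurrent_genes"] = int((recurrence["n_pairs"] >= config.min_pairs).sum())
        counts["top_genes"] = len(top)
        result.burden, result.recurrence, result.top_genes, result.risk_enrichment = (
            comparison, recurrence, top, risk_enr,
        )
        burdens = pd.DataFrame(
            [
                {"family_id": p.family_id, "cohort": cohort, "burden": sets[p.family_id].burden}
                for cohort, plist in (("large", partition.large), ("small", partition.small))
                for p in plist
                if p.family_id in sets
            ]
        )
        outputs["burdens"] = outdir / "burdens.tsv"
        burdens.to_csv(outputs["burdens"], sep="\t", index=False)
        outputs["recurrence"] = outdir / "gene_recurrence.tsv"
        recurrence.to_csv(outputs["recurrence"], sep="\t", index=False)
        outputs["burden_comparison"] = outdir / "burden_comparison.json"
        with open(outputs["burden_comparison"], "w") as fh:
            json.dump(
                {**dataclasses.asdict(comparison), "risk_enrichment": dataclasses.asdict(risk_enr)},
                fh,
                indent=1,
            )

    if last >= STAGES.index("network"):
        def _network():
            curated = curate_gene_sets(gene_sets, config.max_jaccard)
            communities, unmatched = evaluate_communities(
                ppi,
                result.top_genes,
                n_perm=config.network_n_perm,
                degree_bins=config.degree_bins,
                seed=_stage_seed(config.seed, "network"),
            )
            universe = sorted(ppi.nodes)
            enrichment = community_enrichment(
                communities, curated, universe, alpha=config.enrichment_alpha
            )
            return curated, communities, unmatched, enrichment

        curated, communities, unmatched, enrichment = do("network", _network)
        counts["connected_genes"] = sum(len(c) for c in communities.communities.values())
        counts["communities"] = len(communities.communities)
        counts["gene_sets_curated"] = len(curated)
        result.communities, result.enrichment = communities, enrichment
        outputs["communities"] = outdir / "communities.tsv"
        comm_df = communities.to_frame()
        comm_df["density"] = comm_df["community"].map(communities.densities)
        comm_df["permutation_p"] = comm_df["community"].map(communities.permutation_p)
        comm_df.to_csv(outputs["communities"], sep="\t", index=False)
        outputs["enrichment"] = outdir / "community_enrichment.tsv"
        enrichment.to_csv(outputs["enrichment"], sep="\t", index=False)

        def _membership():
            sig_comms = [
                cid
                for cid, p in communities.permutation_p.items()
                if p <= config.connectivity_alpha
            ]
            sig = enrichment[
                enrichment["significant"] & enrichment["community"].isin(sig_comms)
            ]
            member_genes = sorted(set().union(*(communities.communities[c] for c in sig_comms)) if sig_comms else set())
            gene_of = dict(zip(result.qualifying["key"], result.qualifying["gene"]))
            pair_counts = gene_recurrence(large_sets, gene_of).set_index("gene")["n_pairs"]
            patient_counts = {g: int(pair_counts.get(g, 0)) for g in member_genes}
            networks = {
                name: set(curated[name]) & set(member_genes)
                for name in dict.fromkeys(sig["gene_set"])
            }
            return build_membership_matrix(
                member_genes, networks, patient_counts, total_patients=len(partition.large)
            )

        membership = do("network", _membership)
        result.membership = membership
        counts["membership_genes"] = len(membership.genes)
        counts["membership_networks"] = len(membership.networks)
        outputs["membership"] = outdir / "membership_matrix.tsv"
        membership.to_frame().to_csv(outputs["membership"], sep="\t", index_label="gene")

    checksums = {name: sio.sha256_of(path) for name, path in outputs.items()}
    manifest = RunManifest(
        config=config.to_dict(),
        versions={
            "sibnet": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        counts=counts,
        checksums=checksums,
    )
    manifest.to_json(outdir / "manifest.json")
    result.manifest = manifest
    return result
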