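"""Site QC and the rare/deleterious "qualifying variant" definition.

A qualifying variant is one that survives, in order:

1. call-rate QC  — removed if more than ``missingness_max`` of sample calls are missing;
2. Hardy–Weinberg QC — removed if the exact (Levene–Haldane) two-sided test gives
   p < ``hwe_alpha`` across all supplied samples;
3. rarity — removed if its allele frequency exceeds ``maf_max`` in ANY annotated
   reference panel (missing panel frequencies never disqualify);
4. predicted deleteriousness — loss-of-function classes (stopgain, stoploss,
   frameshift, splicing) always qualify; missense variants qualify when their
   SIFT / PolyPhen-2 scores clear the configured thresholds; synonymous and
   other classes never qualify.

SIFT scores are handled on a *damaging-confidence* scale (1 = confidently
damaging), so the threshold is "greater than 0.95".  Conventional SIFT scores
(damaging when small) can be supplied by setting ``sift_conventional=True`` on
the config, in which case they are flipped to the confidence scale on entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "FUNCTIONAL_CLASSES",
    "AF_PANELS",
    "AnnotatedVariant",
    "GenotypeMatrix",
    "FilterConfig",
    "missingness",
    "hwe_exact_p",
    "is_rare",
    "is_damaging",
    "qualifying_variants",
    "FILTER_RULES",
]

FUNCTIONAL_CLASSES = frozenset(
    {"missense", "stopgain", "stoploss", "frameshift", "splicing", "synonymous", "other"}
)

#: canonical reference-panel names; the variant table stores them as ``af_<panel>`` columns
AF_PANELS = ("espEA", "espALL", "1kgEA", "1kgALL")

#: fixed order in which rules are applied; exclusion counts attribute each removed
#: variant to the first rule it fails
FILTER_RULES = ("missingness", "hwe", "rarity", "deleteriousness")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A single annotated variant site.

    ``sift_damage`` and ``polyphen`` are probabilities of damage in [0, 1] or
    ``None`` when the annotation is absent; ``af`` maps reference-panel name to
    allele frequency and may omit panels.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    functional_class: str
    sift_damage: Optional[float] = None
    polyphen: Optional[float] = None
    af: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")
        for name, value in (("sift_damage", self.sift_damage), ("polyphen", self.polyphen)):
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for panel, freq in self.af.items():
            if not (0.0 <= freq <= 1.0) or not math.isfinite(freq):
                raise ValueError(f"allele frequency for panel {panel!r} out of [0, 1]: {freq}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class GenotypeMatrix:
    """Per-sample alternate-allele counts for a set of variant sites.

    Data is a ``(n_variants, n_samples)`` int8 array with entries in
    {0, 1, 2} and -1 for a missing call.
    """

    MISSING = -1

    def __init__(self, variant_keys, samples, data) -> None:
        self.variant_keys = list(variant_keys)
        self.samples = list(samples)
        data = np.asarray(data, dtype=np.int8)
        if data.shape != (len(self.variant_keys), len(self.samples)):
            raise ValueError(
                f"genotype data shape {data.shape} inconsistent with "
                f"{len(self.variant_keys)} variants x {len(self.samples)} samples"
            )
        if data.size and (data.min() < -1 or data.max() > 2):
            raise ValueError("allele counts must be in {0, 1, 2} or -1 for missing")
        self.data = data
        self._vidx = {k: i for i, k in enumerate(self.variant_keys)}
        self._sidx = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant_row(self, key: str) -> np.ndarray:
        try:
            return self.data[self._vidx[key]]
        except KeyError:
            raise KeyError(f"unknown variant key {key!r}") from None

    def sample_column(self, sample: str) -> np.ndarray:
        try:
            return self.data[:, self._sidx[sample]]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def allele_count(self, key: str, sample: str) -> int:
        return int(self.variant_row(key)[self._sidx[sample]])

    def missing_fraction(self) -> np.ndarray:
        """Fraction of missing calls per variant, aligned to ``variant_keys``."""
        return (self.data == self.MISSING).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """(n_variants, 3) counts of hom-ref / het / hom-alt calls (missing excluded)."""
        out = np.empty((self.n_variants, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.data == g).sum(axis=1)
        return out

    def subset(self, keys) -> "GenotypeMatrix":
        idx = [self._vidx[k] for k in keys]
        return GenotypeMatrix(list(keys), self.samples, self.data[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.variant_keys, columns=self.samples)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variant_keys == other.variant_keys
            and self.samples == other.samples
            and np.array_equal(self.data, other.data)
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the qualifying-variant definition (strict inequalities)."""

    maf_max: float = 0.01
    sift_min: float = 0.95
    polyphen_min: float = 0.85
    missense_rule: str = "either"  # "either" or "both"
    damaging_indel_classes: frozenset = frozenset({"stopgain", "stoploss", "frameshift", "splicing"})
    missingness_max: float = 0.10
    hwe_alpha: float = 1e-6
    sift_conventional: bool = False
    missing_scores_damaging: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_max", "sift_min", "polyphen_min", "missingness_max", "hwe_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.missense_rule not in ("either", "both"):
            raise ValueError(f"missense_rule must be 'either' or 'both', got {self.missense_rule!r}")
        unknown = set(self.damaging_indel_classes) - FUNCTIONAL_CLASSES
        if unknown:
            raise ValueError(f"unknown functional classes in damaging_indel_classes: {unknown}")


def missingness(variant_key: str, genotypes: GenotypeMatrix) -> float:
    """Fraction of samples with a missing call at ``variant_key``."""
    row = genotypes.variant_row(variant_key)
    return float((row == GenotypeMatrix.MISSING).mean())


@lru_cache(maxsize=100_000)
def _hwe_exact_p_cached(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    m = min(n_alt, 2 * n - n_alt)  # rarer allele count
    if m == 0:
        return 1.0
    # Conditional distribution of the heterozygote count given allele counts:
    # unnormalised weight w(h) ∝ 2^h * n! / (hom_rare! h! hom_common!), with
    # hom_rare = (m - h) / 2.  Enumerate h over the parity class of m.
    hs = np.arange(m % 2, m + 1, 2)
    hom_rare = (m - hs) // 2
    hom_common = n - hs - hom_rare
    logw = (
        hs * math.log(2.0)
        - gammaln(hom_rare + 1.0)
        - gammaln(hs + 1.0)
        - gammaln(hom_common + 1.0)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    obs = probs[np.nonzero(hs == n_het)[0][0]]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test (Levene–Haldane conditional).

    The p-value is the total conditional probability, given the observed allele
    counts, of heterozygote counts no more probable than the observed one.
    Monomorphic sites return 1.  Raises on negative or all-zero counts.
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0 or v != int(v):
            raise ValueError(f"genotype counts must be non-negative integers, got {v}")
    if n_hom_ref + n_het + n_hom_alt == 0:
        raise ValueError("at least one genotyped sample required")
    return _hwe_exact_p_cached(int(n_hom_ref), int(n_het), int(n_hom_alt))


def is_rare(variant: AnnotatedVariant, config: FilterConfig = FilterConfig()) -> bool:
    """True iff no annotated reference panel reports frequency above ``maf_max``.

    A variant absent from every panel is treated as unobserved, hence rare.
    """
    return all(freq <= config.maf_max for freq in variant.af.values())


def _sift_confidence(score: Optional[float], config: FilterConfig) -> Optional[float]:
    if score is None:
        return None
    return 1.0 - score if config.sift_conventional else score


def is_damaging(variant: AnnotatedVariant, config: FilterConfig = FilterConfig()) -> bool:
    """Predicted-deleteriousness rule.

    Loss-of-function classes always count as damaging.  Missense variants are
    scored against the SIFT/PolyPhen thresholds under the configured
    combination rule; a missing score counts as non-damaging unless
    ``missing_scores_damaging`` is set.  All other classes are benign.
    """
    fc = variant.functional_class
    if fc in config.damaging_indel_classes:
        return True
    if fc != "missense":
        return False
    sift = _sift_confidence(variant.sift_damage, config)
    default = config.missing_scores_damaging
    pass_sift = sift > config.sift_min if sift is not None else default
    pass_pph = variant.polyphen > config.polyphen_min if variant.polyphen is not None else default
    if config.missense_rule == "either":
        return pass_sift or pass_pph
    return pass_sift and pass_pph


def _af_columns(variants: pd.DataFrame):
    return [c for c in variants.columns if c.startswith("af_")]


def qualifying_variants(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: FilterConfig = FilterConfig(),
):
    """Apply the full qualifying-variant filter to an annotated variant table.

    ``variants`` must carry columns ``key, gene, functional_class, sift_damage,
    polyphen`` plus ``af_<panel>`` frequency columns (NaN = missing), with rows
    matching ``genotypes.variant_keys``.

    Returns ``(retained, exclusions, rule_of)`` where ``retained`` is the
    filtered table, ``exclusions`` maps each rule name to the number of
    variants it removed (attributed to the first failing rule in the fixed
    order missingness → HWE → rarity → deleteriousness) and ``rule_of`` is a
    Series mapping every input key to its first-failing rule or ``"pass"``.
    The operation is idempotent.
    """
    keys = list(variants["key"])
    if keys != genotypes.variant_keys:
        if set(keys) - set(genotypes.variant_keys):
            raise ValueError("variant table contains keys absent from the genotype matrix")
        genotypes = genotypes.subset(keys)

    fail_miss = genotypes.missing_fraction() > config.missingness_max

    counts = genotypes.genotype_counts()
    if len(counts):
        uniq, inv = np.unique(counts, axis=0, return_inverse=True)
        p_uniq = np.array([hwe_exact_p(*c) if c.sum() > 0 else 1.0 for c in uniq])
        hwe_p = p_uniq[inv]
    else:
        hwe_p = np.empty(0)
    fail_hwe = hwe_p < config.hwe_alpha

    af = variants[_af_columns(variants)].to_numpy(dtype=float)
    fail_rare = np.nan_to_num(af, nan=-1.0).max(axis=1, initial=-1.0) > config.maf_max

    fc = variants["functional_class"].to_numpy()
    sift = variants["sift_damage"].to_numpy(dtype=float)
    if config.sift_conventional:
        sift = 1.0 - sift
    pph = variants["polyphen"].to_numpy(dtype=float)
    default = config.missing_scores_damaging
    pass_sift = np.where(np.isnan(sift), default, sift > config.sift_min)
    pass_pph = np.where(np.isnan(pph), default, pph > config.polyphen_min)
    score_ok = (pass_sift | pass_pph) if config.missense_rule == "either" else (pass_sift & pass_pph)
    damaging = np.isin(fc, list(config.damaging_indel_classes)) | ((fc == "missense") & score_ok)
    fail_damage = ~damaging

    rule = np.full(len(variants), "pass", dtype=object)
    for name, fails in zip(
        reversed(FILTER_RULES), (fail_damage, fail_rare, fail_hwe, fail_miss)
    ):
        rule[fails] = name

    rule_of = pd.Series(rule, index=keys, name="rule")
    exclusions = {name: int((rule == name).sum()) for name in FILTER_RULES}
    retained = variants.loc[(rule == "pass")].reset_index(drop=True)
    return retained, exclusions, rule_of
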