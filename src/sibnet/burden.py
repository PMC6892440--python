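"""Severe-sib-only variant extraction, burden comparison, and gene enrichment.

For every labelled sib pair the *unshared* variants are the qualifying sites
where the severe sib carries at least one alternate allele and the mild sib
carries none.  Sites where the mild sib's genotype is missing are excluded
from the set (treating missing as reference would overcall unshared variants)
and tallied separately.  Per-pair burdens — distinct qualifying sites by
default, total alternate alleles in ``allele`` mode — are compared between the
large-Δ and small-Δ cohorts with a Welch t-test or a label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import CohortPartition, SibPair
from .filters import GenotypeMatrix

__all__ = [
    "UnsharedVariantSet",
    "BurdenComparison",
    "EnrichmentTestResult",
    "unshared_variants",
    "unshared_variant_sets",
    "compare_burdens",
    "gene_recurrence",
    "select_top_genes",
    "hypergeom_enrichment",
]


@dataclass
class UnsharedVariantSet:
    """Severe-only qualifying variants of one pair."""

    family_id: str
    severe_id: str
    mild_id: str
    variants: List[str]
    mild_missing: List[str]  # sites dropped because the mild sib's call is missing
    allele_burden: int

    @property
    def burden(self) -> int:
        """Distinct severe-only qualifying sites (homozygotes count once)."""
        return len(self.variants)


def unshared_variants(
    pair: SibPair,
    qualifying: pd.DataFrame,
    genotypes: GenotypeMatrix,
    allow_ties: bool = False,
) -> UnsharedVariantSet:
    """Extract the severe-only qualifying variants of a labelled pair.

    A site is included iff the severe sib's allele count is ≥ 1 and the mild
    sib's is exactly 0.  Tie pairs (Δ = 0) have no defined severe sib and are
    rejected unless ``allow_ties`` (which then uses the lexicographic label).
    """
    if not pair.labeled:
        raise ValueError(f"pair {pair.family_id} is not severity-labelled")
    if pair.tie and not allow_ties:
        raise ValueError(
            f"pair {pair.family_id} is a score tie; severe-only extraction undefined "
            "(pass allow_ties=True to use the deterministic tie-break)"
        )
    keys = list(qualifying["key"])
    sub = genotypes if genotypes.variant_keys == keys else genotypes.subset(keys)
    sev = sub.sample_column(pair.severe_id)
    mild = sub.sample_column(pair.mild_id)
    carried = sev >= 1
    included = carried & (mild == 0)
    missing = carried & (mild == GenotypeMatrix.MISSING)
    karr = np.asarray(keys, dtype=object)
    return UnsharedVariantSet(
        family_id=pair.family_id,
        severe_id=pair.severe_id,
        mild_id=pair.mild_id,
        variants=list(karr[included]),
        mild_missing=list(karr[missing]),
        allele_burden=int(sev[included].sum()),
    )


def unshared_variant_sets(
    pairs: Sequence[SibPair],
    qualifying: pd.DataFrame,
    genotypes: GenotypeMatrix,
    allow_ties: bool = False,
    skip_ties: bool = True,
) -> Dict[str, UnsharedVariantSet]:
    """Severe-only sets for many pairs, keyed by family id.

    Tie pairs are silently skipped by default (the severe sib is undefined);
    with ``allow_ties`` they are processed under the deterministic tie-break.
    """
    out: Dict[str, UnsharedVariantSet] = {}
    keys = list(qualifying["key"])
    sub = genotypes if genotypes.variant_keys == keys else genotypes.subset(keys)
    karr = np.asarray(keys, dtype=object)
    for pair in pairs:
        if pair.tie and not allow_ties:
            if skip_ties:
                continue
            raise ValueError(f"pair {pair.family_id} is a score tie")
        if not pair.labeled:
            raise ValueError(f"pair {pair.family_id} is not severity-labelled")
        sev = sub.sample_column(pair.severe_id)
        mild = sub.sample_column(pair.mild_id)
        carried = sev >= 1
        included = carried & (mild == 0)
        missing = carried & (mild == GenotypeMatrix.MISSING)
        out[pair.family_id] = UnsharedVariantSet(
            family_id=pair.family_id,
            severe_id=pair.severe_id,
            mild_id=pair.mild_id,
            variants=list(karr[included]),
            mild_missing=list(karr[missing]),
            allele_burden=int(sev[included].sum()),
        )
    return out


@dataclass
class BurdenComparison:
    """Cohort-level comparison of per-pair severe-only burdens."""

    n_large: int
    mean_large: float
    sem_large: float
    n_small: int
    mean_small: float
    sem_small: float
    t: float
    p: float
    mode: str = "welch"
    p_permutation: Optional[float] = None
    n_perm: int = 0
    seed: Optional[int] = None

    @property
    def large_exceeds_small(self) -> bool:
        return self.mean_large > self.mean_small


def _burden_vector(pairs, sets: Mapping[str, UnsharedVariantSet], unit: str) -> np.ndarray:
    vals = []
    for p in pairs:
        s = sets.get(p.family_id)
        if s is not None:
            vals.append(s.allele_burden if unit == "allele" else s.burden)
    return np.asarray(vals, dtype=float)


def compare_burdens(
    partition: CohortPartition,
    sets: Mapping[str, UnsharedVariantSet],
    mode: str = "welch",
    n_perm: int = 10_000,
    seed: int = 0,
    unit: str = "site",
) -> BurdenComparison:
    """Compare severe-only burdens between the large-Δ and small-Δ cohorts.

    ``mode="welch"`` gives a two-sided unequal-variance t-test;
    ``mode="permutation"`` additionally shuffles cohort labels over pairs and
    reports the empirical two-sided p with the +1 correction,
    p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (1 + n_perm).
    """
    if mode not in ("welch", "permutation"):
        raise ValueError(f"unknown mode {mode!r}")
    a = _burden_vector(partition.large, sets, unit)
    b = _burden_vector(partition.small, sets, unit)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two pairs with burdens in each cohort")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    result = BurdenComparison(
        n_large=len(a),
        mean_large=float(a.mean()),
        sem_large=float(stats.sem(a)),
        n_small=len(b),
        mean_small=float(b.mean()),
        sem_small=float(stats.sem(b)),
        t=float(t),
        p=float(p),
        mode=mode,
    )
    if mode == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            diff = abs(perm[: len(a)].mean() - perm[len(a):].mean())
            if diff >= obs - 1e-12:
                hits += 1
        result.p_permutation = (1 + hits) / (1 + n_perm)
        result.n_perm = n_perm
        result.seed = seed
    return result


def gene_recurrence(
    sets: Mapping[str, UnsharedVariantSet], gene_of: Mapping[str, str]
) -> pd.DataFrame:
    """Count, per gene, the pairs with ≥ 1 severe-only qualifying variant.

    A gene hit by several variants in the same pair counts once for that pair
    (``n_pairs``); ``n_variants`` additionally counts every severe-only
    variant of the gene across pairs.  Returns a DataFrame with columns
    ``gene, n_pairs, n_variants`` sorted by the selection order.
    """
    pair_hits: Dict[str, set] = {}
    var_counts: Dict[str, int] = {}
    for fam, s in sets.items():
        for key in s.variants:
            gene = gene_of[key]
            pair_hits.setdefault(gene, set()).add(fam)
            var_counts[gene] = var_counts.get(gene, 0) + 1
    df = pd.DataFrame(
        {
            "gene": list(pair_hits),
            "n_pairs": [len(v) for v in pair_hits.values()],
            "n_variants": [var_counts[g] for g in pair_hits],
        }
    )
    return df.sort_values(
        ["n_pairs", "n_variants", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)


def select_top_genes(
    recurrence: pd.DataFrame, min_pairs: int = 3, top_k: int = 250
) -> List[str]:
    """Recurrent genes (≥ ``min_pairs`` pairs), ranked and truncated to ``top_k``.

    Ordering is deterministic: recurrence descending, then total variant count
    descending, then gene symbol ascending.
    """
    elig = recurrence.loc[recurrence["n_pairs"] >= min_pairs]
    elig = elig.sort_values(["n_pairs", "n_variants", "gene"], ascending=[False, False, True])
    return list(elig["gene"].head(top_k))


@dataclass(frozen=True)
class EnrichmentTestResult:
    """Upper-tail hypergeometric overlap test of a query list against a reference set."""

    k: int  # overlap
    n: int  # query size
    K: int  # reference size
    N: int  # universe size
    p: float

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N


def hypergeom_enrichment(
    query: Iterable[str], reference: Iterable[str], universe: Iterable[str]
) -> EnrichmentTestResult:
    """Exact upper-tail hypergeometric enrichment p-value, P(X ≥ k).

    ``query`` and ``reference`` must be subsets of ``universe``; the overlap k
    is tested against Hypergeometric(N=|universe|, K=|reference|, n=|query|).
    """
    q, r, u = set(query), set(reference), set(universe)
    if not q <= u:
        raise ValueError(f"query contains genes outside the universe: {sorted(q - u)[:5]} ...")
    if not r <= u:
        raise ValueError(f"reference contains genes outside the universe: {sorted(r - u)[:5]} ...")
    k, n, K, N = len(q & r), len(q), len(r), len(u)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentTestResult(k=k, n=n, K=K, N=N, p=min(max(p, 0.0), 1.0))
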