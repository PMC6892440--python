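"""Independent oracles used by the test suite.

These deliberately re-derive expected values by brute force (exact rational
arithmetic, exhaustive enumeration) rather than calling the library code they
check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, factorial

import numpy as np
import pandas as pd

from sibnet.filters import GenotypeMatrix


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact summation."""
    total = comb(N, n)
    s = Fraction(0)
    for x in range(k, min(n, K) + 1):
        if n - x <= N - K:
            s += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return s


def hwe_two_sided(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Levene–Haldane exact two-sided p by full enumeration in exact rationals."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    m = min(n_alt, 2 * n - n_alt)
    if m == 0:
        return Fraction(1)
    weights = {}
    for h in range(m % 2, m + 1, 2):
        hom_rare = (m - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = Fraction(2**h * factorial(n), factorial(hom_rare) * factorial(h) * factorial(hom_common))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs)


def permutation_p_exhaustive(a, b) -> Fraction:
    """Two-sided label-permutation p over all C(n, |a|) splits of the pooled burdens."""
    pooled = list(a) + list(b)
    na = len(a)
    obs = abs(sum(a) / na - sum(b) / len(b))
    hits = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diff = abs(sum(ga) / na - sum(gb) / len(gb))
        total += 1
        if diff >= obs - 1e-12:
            hits += 1
    return Fraction(hits, total)


def toy_variant_table():
    """A hand-labelled 20-variant fixture with its expected first-failing rules.

    Returns (variants DataFrame, GenotypeMatrix over 12 samples, expected rule
    per key) under the default filter configuration.
    """
    samples = [f"S{i:02d}" for i in range(1, 13)]
    nan = np.nan
    rows = [
        # key parts, gene, class, sift, pph, af_espEA, af_1kgALL, expected
        ("1", 100, "A", "T", "GENE01", "stopgain", nan, nan, 0.001, nan, "pass"),
        ("1", 200, "C", "G", "GENE02", "stoploss", nan, nan, nan, nan, "pass"),
        ("1", 300, "G", "A", "GENE03", "frameshift", nan, nan, nan, 0.005, "pass"),
        ("1", 400, "T", "C", "GENE04", "splicing", nan, nan, nan, nan, "pass"),
        ("2", 100, "A", "G", "GENE05", "missense", 0.99, 0.90, 0.002, nan, "pass"),
        ("2", 200, "A", "C", "GENE06", "missense", 0.99, 0.20, nan, nan, "pass"),
        ("2", 300, "C", "T", "GENE07", "missense", nan, 0.90, nan, nan, "pass"),
        ("2", 400, "G", "T", "GENE08", "missense", 0.50, 0.95, nan, nan, "pass"),
        ("3", 100, "A", "T", "GENE09", "stopgain", nan, nan, 0.01, nan, "pass"),
        ("3", 200, "C", "A", "GENE10", "missense", 0.951, 0.851, nan, nan, "pass"),
        ("3", 300, "G", "C", "GENE11", "synonymous", nan, nan, nan, nan, "deleteriousness"),
        ("3", 400, "T", "A", "GENE12", "other", nan, nan, nan, nan, "deleteriousness"),
        ("4", 100, "A", "C", "GENE13", "missense", 0.50, 0.50, nan, nan, "deleteriousness"),
        ("4", 200, "C", "G", "GENE14", "missense", nan, nan, nan, nan, "deleteriousness"),
        ("4", 300, "G", "T", "GENE15", "stopgain", nan, nan, nan, 0.02, "rarity"),
        ("4", 400, "T", "G", "GENE16", "missense", 0.99, nan, 0.50, nan, "rarity"),
        ("5", 100, "A", "G", "GENE17", "stopgain", nan, nan, nan, nan, "missingness"),
        ("5", 200, "C", "T", "GENE18", "stopgain", nan, nan, nan, nan, "pass"),
        ("5", 300, "G", "A", "GENE19", "synonymous", nan, nan, 0.02, nan, "rarity"),
        ("5", 400, "T", "C", "GENE20", "stopgain", nan, nan, 0.005, 0.009, "pass"),
    ]
    variants = pd.DataFrame(
        [
            {
                "key": f"{c}:{p}:{r}:{a}",
                "chrom": c,
                "pos": p,
                "ref": r,
                "alt": a,
                "gene": g,
                "functional_class": fc,
                "sift_damage": sift,
                "polyphen": pph,
                "af_espEA": af1,
                "af_espALL": nan,
                "af_1kgEA": nan,
                "af_1kgALL": af2,
            }
            for c, p, r, a, g, fc, sift, pph, af1, af2, _ in rows
        ]
    )
    expected = {f"{c}:{p}:{r}:{a}": exp for c, p, r, a, *_, exp in rows}
    data = np.zeros((len(rows), len(samples)), dtype=np.int8)
    data[:, 0] = 1  # one het carrier everywhere
    v17 = variants.index[variants["gene"] == "GENE17"][0]
    data[v17, 1:3] = GenotypeMatrix.MISSING  # 2/12 missing > 10%
    v18 = variants.index[variants["gene"] == "GENE18"][0]
    data[v18, 1] = GenotypeMatrix.MISSING  # 1/12 missing, retained under strict ">"
    gm = GenotypeMatrix(list(variants["key"]), samples, data)
    return variants, gm, expected
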