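"""Per-locus diversity metrics, HWE/LD permutation tests, FDR, and the
multi-locality repeated-measures heterozygosity comparison."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .identity import MultilocusGenotype


@dataclass
class LocusDiversity:
    locus: str
    n: int          # individuals with non-missing calls
    na: int
    ar: float       # allelic richness rarefied to the smallest gene count
    ho: float
    he: float
    fis: Optional[float]


@dataclass
class DiversityTable:
    rows: List[LocusDiversity]
    means: Dict[str, float]
    ses: Dict[str, float]
    fis_multilocus: Optional[float]
    excluded_loci: List[str]


def column_summary(values: Sequence[float]) -> Tuple[float, float]:
    """Across-loci mean and standard error (sd/sqrt(L), ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty column")
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), se


def _rarefied_richness(counts: Dict[int, int], g: int) -> float:
    """AR = sum_a [1 - C(N - N_a, g) / C(N, g)] at rarefaction depth g."""
    n = sum(counts.values())
    if g > n:
        raise ValueError("rarefaction depth exceeds gene count")
    lden = gammaln(n + 1) - gammaln(g + 1) - gammaln(n - g + 1)
    ar = 0.0
    for na in counts.values():
        if n - na < g:
            ar += 1.0
        else:
            lnum = gammaln(n - na + 1) - gammaln(g + 1) - gammaln(n - na - g + 1)
            ar += 1.0 - math.exp(lnum - lden)
    return ar


def _wc_components(calls: List[Tuple[int, int]]) -> Tuple[float, float]:
    """Weir & Cockerham (1984) single-population variance components summed
    over alleles: returns (sum_b, sum_c); f = 1 - sum_c / (sum_b + sum_c)."""
    n = len(calls)
    alleles = sorted({a for c in calls for a in c})
    sum_b = sum_c = 0.0
    for a in alleles:
        p = sum(c.count(a) for c in calls) / (2.0 * n)
        h = sum(1 for c in calls if c[0] != c[1] and a in c) / n
        b = n / (n - 1.0) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
        sum_b += b
        sum_c += h / 2.0
    return sum_b, sum_c


def diversity_table(
    genotypes: Dict[str, MultilocusGenotype],
    unbiased_he: bool = False,
) -> DiversityTable:
    """Na, rarefied AR, Ho, He (1 - sum p^2 by default; Nei's unbiased
    variant optional), and Weir & Cockerham F_IS, with across-loci
    mean +/- SE.  Loci with all-missing or single-genotype data are
    excluded and reported."""
    loci = sorted({loc for g in genotypes.values() for loc in g})
    calls_by_locus: Dict[str, List[Tuple[int, int]]] = {loc: [] for loc in loci}
    for g in genotypes.values():
        for loc, call in g.items():
            if call is not None:
                calls_by_locus[loc].append(call)

    excluded = [loc for loc in loci if len(calls_by_locus[loc]) < 2]
    usable = [loc for loc in loci if loc not in excluded]
    if not usable:
        raise ValueError("no locus has two or more non-missing genotypes")
    g_min = min(2 * len(calls_by_locus[loc]) for loc in usable)

    rows = []
    b_tot = c_tot = 0.0
    for loc in usable:
        calls = calls_by_locus[loc]
        n = len(calls)
        counts: Dict[int, int] = {}
        for c in calls:
            for a in c:
                counts[a] = counts.get(a, 0) + 1
        tot = 2 * n
        p2 = sum((c / tot) ** 2 for c in counts.values())
        he = 1.0 - p2
        if unbiased_he:
            he *= tot / (tot - 1.0)
        ho = sum(1 for c in calls if c[0] != c[1]) / n
        if len(counts) > 1:
            b, cc = _wc_components(calls)
            b_tot += b
            c_tot += cc
            fis = 1.0 - cc / (b + cc) if (b + cc) != 0 else None
        else:
            fis = None
        rows.append(LocusDiversity(
            locus=loc, n=n, na=len(counts),
            ar=_rarefied_richness(counts, g_min), ho=ho, he=he, fis=fis))

    means, ses = {}, {}
    for name in ("na", "ar", "ho", "he"):
        means[name], ses[name] = column_summary([getattr(r, name) for r in rows])
    fis_vals = [r.fis for r in rows if r.fis is not None]
    if fis_vals:
        means["fis"], ses["fis"] = column_summary(fis_vals)
    fis_multi = 1.0 - c_tot / (b_tot + c_tot) if (b_tot + c_tot) != 0 else None
    return DiversityTable(rows=rows, means=means, ses=ses,
                          fis_multilocus=fis_multi, excluded_loci=excluded)


def _log_array_probability(calls: List[Tuple[int, int]]) -> float:
    """Log conditional probability of the genotype array given allele counts
    (Guo & Thompson): n! 2^h prod(n_i!) / [(2n)! prod(n_ij!)]."""
    n = len(calls)
    allele_counts: Dict[int, int] = {}
    geno_counts: Dict[Tuple[int, int], int] = {}
    h = 0
    for c in calls:
        geno_counts[c] = geno_counts.get(c, 0) + 1
        if c[0] != c[1]:
            h += 1
        for a in c:
            allele_counts[a] = allele_counts.get(a, 0) + 1
    lp = gammaln(n + 1) + h * math.log(2.0)
    lp += sum(gammaln(c + 1) for c in allele_counts.values())
    lp -= gammaln(2 * n + 1)
    lp -= sum(gammaln(c + 1) for c in geno_counts.values())
    return lp


def hwe_exact_test(
    genotypes: Dict[str, MultilocusGenotype],
    locus: str,
    n_perm: int = 9999,
    seed: int = 0,
) -> float:
    """Monte Carlo exact HWE test: alleles reshuffled among individuals,
    p = fraction of arrays no more probable than the observed one, with
    the +1/+1 correction.  Monomorphic loci return 1.0."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    calls = [g[locus] for g in genotypes.values()
             if g.get(locus) is not None]
    if len(calls) < 2:
        raise ValueError(f"fewer than two genotypes at {locus}")
    alleles = np.array([a for c in calls for a in c])
    if len(np.unique(alleles)) < 2:
        return 1.0
    obs = _log_array_probability(calls)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(alleles)
        perm = [tuple(sorted((alleles[2 * i], alleles[2 * i + 1])))
                for i in range(len(calls))]
        if _log_array_probability(perm) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _g_statistic(col1: List[Tuple[int, int]], col2: List[Tuple[int, int]]) -> float:
    """Log-likelihood-ratio statistic for genotypic association."""
    table: Dict[Tuple, int] = {}
    r1: Dict[Tuple, int] = {}
    r2: Dict[Tuple, int] = {}
    n = len(col1)
    for a, b in zip(col1, col2):
        table[(a, b)] = table.get((a, b), 0) + 1
        r1[a] = r1.get(a, 0) + 1
        r2[b] = r2.get(b, 0) + 1
    g = 0.0
    for (a, b), o in table.items():
        e = r1[a] * r2[b] / n
        g += 2.0 * o * math.log(o / e)
    return g


def ld_pairwise_test(
    genotypes: Dict[str, MultilocusGenotype],
    n_perm: int = 9999,
    seed: int = 0,
) -> Dict[Tuple[str, str], Optional[float]]:
    """Permutation test of genotypic association for every locus pair.

    One locus's genotypes are permuted across individuals; +1/+1-corrected
    p-values.  Pairs with fewer than 5 complete observations get ``None``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    loci = sorted({loc for g in genotypes.values() for loc in g})
    poly = []
    for loc in loci:
        alleles = {a for g in genotypes.values()
                   for a in (g.get(loc) or ())}
        if len(alleles) > 1:
            poly.append(loc)
    rng = np.random.default_rng(seed)
    out: Dict[Tuple[str, str], Optional[float]] = {}
    for l1, l2 in itertools.combinations(poly, 2):
        pairs = [(g[l1], g[l2]) for g in genotypes.values()
                 if g.get(l1) is not None and g.get(l2) is not None]
        if len(pairs) < 5:
            out[(l1, l2)] = None
            continue
        col1 = [p[0] for p in pairs]
        col2 = [p[1] for p in pairs]
        obs = _g_statistic(col1, col2)
        idx = np.arange(len(col2))
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(idx)
            if _g_statistic(col1, [col2[i] for i in idx]) >= obs - 1e-12:
                hits += 1
        out[(l1, l2)] = (hits + 1) / (n_perm + 1)
    return out


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj.tolist()


def _friedman_statistic(matrix: np.ndarray) -> float:
    """Friedman chi-square with tie correction (blocks = rows)."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    ssbn = float(np.sum(ranks.sum(axis=0) ** 2))
    chi2 = 12.0 / (n * k * (k + 1)) * ssbn - 3 * n * (k + 1)
    ties = 0.0
    for row in matrix:
        _, reps = np.unique(row, return_counts=True)
        ties += float(np.sum(reps ** 3 - reps))
    c = 1.0 - ties / (n * (k ** 3 - k))
    if c <= 0:
        return 0.0
    return chi2 / c


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    method: str  # "exact" or "asymptotic"
    pairwise: Optional[List[Dict]]  # Wilcoxon + BH, only when p < 0.05


def friedman_locality_comparison(
    he_matrix,
    localities: Optional[Sequence[str]] = None,
    max_exact: int = 50_000,
    alpha: float = 0.05,
) -> FriedmanResult:
    """Friedman test on a loci x localities He matrix (loci are repeated
    measures).  Small designs use exact within-block permutation
    enumeration; otherwise the chi-square approximation.  If significant,
    all pairwise two-sided Wilcoxon signed-rank tests with BH adjustment.
    """
    mat = np.asarray(he_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need >=2 loci (rows) and >=2 localities (columns)")
    if np.isnan(mat).any():
        cells = [tuple(int(x) for x in idx) for idx in np.argwhere(np.isnan(mat))]
        raise ValueError(f"missing cells at (locus, locality) indices {cells}")
    n, k = mat.shape
    if localities is None:
        localities = [f"loc{i + 1}" for i in range(k)]

    chi2 = _friedman_statistic(mat)
    n_configs = math.factorial(k) ** n
    if n_configs <= max_exact:
        perms = list(itertools.permutations(range(k)))
        hits = total = 0
        for combo in itertools.product(perms, repeat=n):
            permuted = np.vstack([mat[i, list(combo[i])] for i in range(n)])
            total += 1
            if _friedman_statistic(permuted) >= chi2 - 1e-12:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
        method = "asymptotic"

    pairwise = None
    if p < alpha:
        pairwise = []
        raw = []
        pairs = list(itertools.combinations(range(k), 2))
        for i, j in pairs:
            diff = mat[:, i] - mat[:, j]
            if np.allclose(diff, 0):
                raw.append(1.0)
            else:
                raw.append(float(stats.wilcoxon(
                    mat[:, i], mat[:, j], zero_method="wilcox",
                    method="auto").pvalue))
        adj = bh_fdr(raw)
        for (i, j), pr, pa in zip(pairs, raw, adj):
            pairwise.append({"pair": (localities[i], localities[j]),
                             "p_raw": pr, "p_adj": pa})
    return FriedmanResult(chi2=chi2, df=k - 1, p=p, method=method,
                          pairwise=pairwise)
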