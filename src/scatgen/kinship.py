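"""Maximum-likelihood pairwise relationship classification and relatedness.

Each dyad is scored under the four fixed IBD-coefficient vectors
U=(1,0,0), HS=(0.5,0.5,0), FS=(0.25,0.5,0.25), PO=(0,1,0) (k0,k1,k2 =
probabilities of sharing 0/1/2 alleles identical by descent), with a
continuous maximum over the whole simplex for the relatedness point
estimate r = k1/2 + k2.  A moment-based Wang-type estimator with
small-sample allele-moment corrections provides an independent cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .identity import AlleleFrequencies, Individual, MultilocusGenotype

Genotype = Tuple[int, int]

CATEGORY_K = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}


@dataclass
class DyadResult:
    id1: str
    id2: str
    category: str               # U / HS / FS / PO / unresolved
    r_ml: Optional[float]
    r_wang: Optional[float]
    delta_lnl: Optional[float]  # support margin over the runner-up category
    n_loci: int
    sim_support: Optional[float] = None


def _p_geno(g: Genotype, p: Dict[int, float]) -> float:
    a, b = g
    return p[a] * p[a] if a == b else 2.0 * p[a] * p[b]


def _trans_one_ibd(g1: Genotype, g2: Genotype, p: Dict[int, float]) -> float:
    """P(G2 | G1, exactly one pair of alleles IBD)."""
    a, b = g1
    c, d = g2
    if a == b:
        if c == d:
            return p[a] if c == a else 0.0
        if c == a:
            return p[d]
        if d == a:
            return p[c]
        return 0.0
    t = 0.0
    for shared, other in ((a, b), (b, a)):
        if c == d:
            if c == shared:
                t += 0.5 * p[c]
        elif c == shared:
            t += 0.5 * p[d]
        elif d == shared:
            t += 0.5 * p[c]
    return t


def _mode_probs(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    freqs: AlleleFrequencies,
) -> Tuple[np.ndarray, List[str]]:
    """Per-locus (P0, P1, P2) over the shared non-missing loci."""
    loci = sorted(set(g1) & set(g2) & set(freqs.freqs))
    rows = []
    used = []
    for loc in loci:
        c1, c2 = g1[loc], g2[loc]
        if c1 is None or c2 is None:
            continue
        p = freqs.freqs[loc]
        for allele in (*c1, *c2):
            if allele not in p:
                raise ValueError(f"allele {allele} at {loc} absent from frequencies")
        pg1 = _p_geno(c1, p)
        p0 = pg1 * _p_geno(c2, p)
        p1 = pg1 * _trans_one_ibd(c1, c2, p)
        p2 = pg1 if c1 == c2 else 0.0
        rows.append((p0, p1, p2))
        used.append(loc)
    return np.asarray(rows, dtype=float), used


def dyad_log_likelihood(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    freqs: AlleleFrequencies,
    k: Tuple[float, float, float],
) -> float:
    """Sum over loci of log[k0*P0 + k1*P1 + k2*P2]; -inf on exclusion."""
    if any(x < -1e-12 for x in k) or abs(sum(k) - 1.0) > 1e-9:
        raise ValueError(f"k must lie on the simplex: {k}")
    probs, _ = _mode_probs(g1, g2, freqs)
    if probs.size == 0:
        raise ValueError("no shared informative loci")
    per_locus = probs @ np.asarray(k, dtype=float)
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(per_locus)))


def _simplex_grid(step: float) -> np.ndarray:
    pts = []
    n = int(round(1.0 / step))
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i * step, j * step, 1.0 - i * step - j * step))
    return np.asarray(pts)


_GRID_COARSE = _simplex_grid(0.01)


def _continuous_ml(probs: np.ndarray) -> Tuple[Tuple[float, float, float], float]:
    """Grid search (0.01 step) plus one local refinement (0.001 step)."""

    def lnl(grid: np.ndarray) -> np.ndarray:
        per = grid @ probs.T  # (G, L)
        with np.errstate(divide="ignore"):
            return np.where(np.all(per > 0, axis=1),
                            np.sum(np.log(np.maximum(per, 1e-300)), axis=1),
                            -np.inf)

    vals = lnl(_GRID_COARSE)
    best = int(np.argmax(vals))
    # deterministic tie-break toward larger k0
    ties = np.flatnonzero(vals >= vals[best] - 1e-12)
    best = ties[int(np.argmax(_GRID_COARSE[ties, 0]))]
    k0, k1, _ = _GRID_COARSE[best]

    fine = []
    for dk0 in np.arange(-0.01, 0.0101, 0.001):
        for dk1 in np.arange(-0.01, 0.0101, 0.001):
            a, b = k0 + dk0, k1 + dk1
            if a >= -1e-12 and b >= -1e-12 and a + b <= 1 + 1e-12:
                a, b = max(a, 0.0), max(b, 0.0)
                fine.append((a, b, max(1.0 - a - b, 0.0)))
    fine_arr = np.asarray(fine)
    fvals = lnl(fine_arr)
    fb = int(np.argmax(fvals))
    fties = np.flatnonzero(fvals >= fvals[fb] - 1e-12)
    fb = fties[int(np.argmax(fine_arr[fties, 0]))]
    k = tuple(float(x) for x in fine_arr[fb])
    return k, float(fvals[fb])  # type: ignore[return-value]


def _simulate_dyad(
    rng: np.random.Generator,
    freqs: AlleleFrequencies,
    loci: Sequence[str],
    k: Tuple[float, float, float],
) -> Tuple[MultilocusGenotype, MultilocusGenotype]:
    g1: MultilocusGenotype = {}
    g2: MultilocusGenotype = {}
    for loc in loci:
        p = freqs.freqs[loc]
        alleles = sorted(p)
        pv = np.array([p[a] for a in alleles])
        draw = lambda: int(alleles[int(rng.choice(len(alleles), p=pv))])
        a, b = draw(), draw()
        g1[loc] = tuple(sorted((a, b)))  # type: ignore[assignment]
        mode = int(rng.choice(3, p=np.asarray(k)))
        if mode == 0:
            g2[loc] = tuple(sorted((draw(), draw())))  # type: ignore[assignment]
        elif mode == 1:
            shared = g1[loc][int(rng.integers(2))]
            g2[loc] = tuple(sorted((shared, draw())))  # type: ignore[assignment]
        else:
            g2[loc] = g1[loc]
    return g1, g2


def classify_dyad(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    freqs: AlleleFrequencies,
    n_sim: int = 0,
    seed: int = 0,
    id1: str = "A",
    id2: str = "B",
) -> DyadResult:
    """Best of the four fixed categories, continuous-ML relatedness, and the
    log-likelihood margin over the runner-up.  Dyads sharing fewer than 4
    informative loci are 'unresolved'."""
    probs, loci = _mode_probs(g1, g2, freqs)
    if len(loci) < 4:
        return DyadResult(id1, id2, "unresolved", None, None, None, len(loci))

    lnls = {}
    for cat, k in CATEGORY_K.items():
        per = probs @ np.asarray(k)
        with np.errstate(divide="ignore"):
            lnls[cat] = float(np.sum(np.log(np.maximum(per, 0.0)))
                              if np.all(per > 0) else -np.inf)
    ordered = sorted(lnls, key=lambda c: (-lnls[c], c))
    category, runner = ordered[0], ordered[1]
    delta = lnls[category] - lnls[runner]

    k_hat, _ = _continuous_ml(probs)
    r_ml = k_hat[1] / 2.0 + k_hat[2]

    support = None
    if n_sim > 0 and np.isfinite(delta):
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_sim):
            s1, s2 = _simulate_dyad(rng, freqs, loci, CATEGORY_K[runner])
            sp, _ = _mode_probs(s1, s2, freqs)
            sl = {}
            for cat, k in CATEGORY_K.items():
                per = sp @ np.asarray(k)
                sl[cat] = float(np.sum(np.log(np.maximum(per, 1e-300)))
                                if np.all(per > 0) else -np.inf)
            margin = sl[category] - max(v for c, v in sl.items() if c != category)
            if margin >= delta:
                exceed += 1
        support = exceed / n_sim
    return DyadResult(id1, id2, category, float(r_ml), None,
                      float(delta), len(loci), support)


def _unbiased_moments(p: Dict[int, float],
                      counts: Optional[Dict[int, int]]) -> Tuple[float, float, float]:
    """(a2, a3, a4) = E[sum p^m]; unbiased from allele counts when sample
    counts are available, raw plug-in moments otherwise."""
    if counts and sum(counts.values()) > 4:
        x = np.array(list(counts.values()), dtype=float)
        n = float(x.sum())
        a2 = float(np.sum(x * (x - 1)) / (n * (n - 1)))
        a3 = float(np.sum(x * (x - 1) * (x - 2)) / (n * (n - 1) * (n - 2)))
        a4 = float(np.sum(x * (x - 1) * (x - 2) * (x - 3))
                   / (n * (n - 1) * (n - 2) * (n - 3)))
        return a2, a3, a4
    vals = np.array(list(p.values()))
    return (float(np.sum(vals ** 2)), float(np.sum(vals ** 3)),
            float(np.sum(vals ** 4)))


def _similarity_class(c1: Genotype, c2: Genotype) -> int:
    """1: identical; 2: one homozygote, one heterozygote sharing its allele;
    3: two heterozygotes sharing exactly one allele; 4: no shared allele."""
    if c1 == c2:
        return 1
    s1, s2 = set(c1), set(c2)
    shared = s1 & s2
    if not shared:
        return 4
    h1, h2 = c1[0] == c1[1], c2[0] == c2[1]
    if h1 != h2:
        return 2 if (c1[0] in s2 if h1 else c2[0] in s1) else 4
    if h1 and h2:
        return 4  # different homozygotes share nothing
    return 3


def wang_relatedness(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    freqs: AlleleFrequencies,
) -> float:
    """Wang-type moment estimator of r = phi/2 + delta.

    Per locus the three similarity-class indicators are linear in the
    two-gene (phi) and four-gene (delta) IBD coefficients; the estimator
    solves the stacked weighted least-squares system with per-locus weights
    1/(2 a2 - a4) and unbiased allele moments.  Unbounded below.
    """
    loci = sorted(set(g1) & set(g2) & set(freqs.freqs))
    rows_a = []
    rows_y = []
    for loc in loci:
        c1, c2 = g1.get(loc), g2.get(loc)
        if c1 is None or c2 is None:
            continue
        p = freqs.freqs[loc]
        if len(p) < 2:
            continue
        a2, a3, a4 = _unbiased_moments(p, freqs.counts.get(loc))
        # class probabilities: under delta (2 IBD pairs), under phi (1 pair),
        # under neither (independent genotypes)
        b = 2 * a2 ** 2 - a4                    # P(class1 | 0 IBD)
        d = 4 * (a3 - a4)                       # P(class2 | 0 IBD)
        f = 4 * (a2 - a2 ** 2 - 2 * a3 + 2 * a4)  # P(class3 | 0 IBD)
        c1p = a2                                # P(class1 | 1 IBD)
        c2p = 2 * (a2 - a3)                     # P(class2 | 1 IBD)
        c3p = 1 - 3 * a2 + 2 * a3               # P(class3 | 1 IBD)
        u = 2 * a2 - a4
        w = 1.0 / u if u > 0 else 1.0
        cls = _similarity_class(c1, c2)
        y = np.array([1.0 if cls == 1 else 0.0,
                      1.0 if cls == 2 else 0.0,
                      1.0 if cls == 3 else 0.0])
        base = np.array([b, d, f])
        design = np.array([[c1p - b, 1.0 - b],
                           [c2p - d, 0.0 - d],
                           [c3p - f, 0.0 - f]])
        sw = np.sqrt(w)
        rows_a.append(design * sw)
        rows_y.append((y - base) * sw)
    if not rows_a:
        raise ValueError("no shared polymorphic loci for the Wang estimator")
    A = np.vstack(rows_a)
    yv = np.concatenate(rows_y)
    theta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    phi, delta = float(theta[0]), float(theta[1])
    return phi / 2.0 + delta


def kin_matrix(
    individuals: Sequence[Individual],
    freqs: AlleleFrequencies,
    seed: int = 0,
    n_sim: int = 0,
) -> List[DyadResult]:
    """Classify every pair of individuals; n(n-1)/2 dyads."""
    if len(individuals) < 2:
        raise ValueError("need at least two individuals")
    results = []
    for i, j in itertools.combinations(range(len(individuals)), 2):
        a, b = individuals[i], individuals[j]
        res = classify_dyad(a.genotype, b.genotype, freqs,
                            n_sim=n_sim, seed=seed + 7919 * i + j,
                            id1=a.individual_id, id2=b.individual_id)
        if res.category != "unresolved":
            try:
                res.r_wang = wang_relatedness(a.genotype, b.genotype, freqs)
            except ValueError:
                res.r_wang = None
        results.append(res)
    return results


def category_counts(results: Sequence[DyadResult]) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for r in results:
        counts[r.category] = counts.get(r.category, 0) + 1
    return counts
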