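"""Diet metabarcoding metrics from taxon-assigned read tables.

Filtering follows the two quality-control steps (within-replicate
proportional read threshold, then replicate-concordance), after removing
predator and human reads.  Composition metrics are frequency of occurrence
(FOO) and weighted percent of occurrence (wPOO); community comparison uses
Bray-Curtis dissimilarity with a permutation PERMANOVA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np


@dataclass
class DietReadTable:
    """Long-format records (sample_id, pcr_replicate, taxon, reads)."""

    records: List[Tuple[str, int, str, int]]
    sample_to_individual: Dict[str, str] = field(default_factory=dict)
    individual_sex: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, rep, taxon, reads in self.records:
            if rep not in (1, 2, 3):
                raise ValueError(f"pcr_replicate must be 1-3, got {rep} ({sid})")
            if reads < 0:
                raise ValueError(f"negative read count for {sid}/{taxon}")


@dataclass
class DietDetections:
    """Filtered per-sample prey-taxon sets."""

    detections: Dict[str, Set[str]]  # sample -> retained prey taxa
    excluded_samples: List[str]

    @property
    def n_samples(self) -> int:
        return len(self.detections)

    def taxa(self) -> List[str]:
        return sorted({t for s in self.detections.values() for t in s})


def filter_reads(
    table: DietReadTable,
    predator_taxa: Sequence[str] = (),
    min_prop: float = 0.005,
    min_reps: int = 2,
) -> DietDetections:
    """Two-step QC.

    (i) remove predator/host taxa, then drop taxa at <= ``min_prop`` of a
    replicate's total reads (inclusive); (ii) keep a taxon for a sample only
    if it survives step (i) in >= ``min_reps`` replicates.  Samples with no
    retained prey (or zero reads) are excluded from N.
    """
    predator = set(predator_taxa)
    per_rep: Dict[Tuple[str, int], Dict[str, int]] = {}
    all_samples: Set[str] = set()
    for sid, rep, taxon, reads in table.records:
        all_samples.add(sid)
        if taxon in predator:
            continue
        per_rep.setdefault((sid, rep), {})[taxon] = \
            per_rep.get((sid, rep), {}).get(taxon, 0) + reads

    votes: Dict[str, Dict[str, int]] = {}
    for (sid, rep), taxa in per_rep.items():
        total = sum(taxa.values())
        if total == 0:
            continue
        for taxon, reads in taxa.items():
            if reads > min_prop * total:
                votes.setdefault(sid, {})[taxon] = votes.get(sid, {}).get(taxon, 0) + 1

    detections = {}
    for sid, taxon_votes in votes.items():
        retained = {t for t, v in taxon_votes.items() if v >= min_reps}
        if retained:
            detections[sid] = retained
    excluded = sorted(all_samples - set(detections))
    return DietDetections(detections=detections, excluded_samples=excluded)


def foo(detections: DietDetections) -> Dict[str, float]:
    """Frequency of occurrence: fraction of retained samples containing
    each taxon."""
    n = detections.n_samples
    if n < 1:
        raise ValueError("no retained samples")
    out: Dict[str, float] = {}
    for taxa in detections.detections.values():
        for t in taxa:
            out[t] = out.get(t, 0.0) + 1.0
    return {t: c / n for t, c in sorted(out.items())}


def wpoo(detections: DietDetections) -> Dict[str, float]:
    """Weighted percent of occurrence: each detection weighted by 1/T_s;
    sums to 1 over taxa."""
    n = detections.n_samples
    if n < 1:
        raise ValueError("no retained samples")
    out: Dict[str, float] = {}
    for taxa in detections.detections.values():
        w = 1.0 / len(taxa)
        for t in taxa:
            out[t] = out.get(t, 0.0) + w
    return {t: v / n for t, v in sorted(out.items())}


def individual_profiles(
    detections: DietDetections,
    sample_to_individual: Dict[str, str],
) -> Dict[str, Dict[str, float]]:
    """Per-individual mean wPOO profile across that individual's samples."""
    per_ind: Dict[str, List[Dict[str, float]]] = {}
    for sid, taxa in detections.detections.items():
        ind = sample_to_individual.get(sid)
        if ind is None:
            continue
        w = 1.0 / len(taxa)
        per_ind.setdefault(ind, []).append({t: w for t in taxa})
    profiles = {}
    for ind, rows in per_ind.items():
        taxa = sorted({t for r in rows for t in r})
        profiles[ind] = {t: sum(r.get(t, 0.0) for r in rows) / len(rows) for t in taxa}
    return profiles


def bray_curtis(profiles: Sequence[Dict[str, float]]) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity matrix for non-negative
    composition vectors."""
    taxa = sorted({t for p in profiles for t in p})
    mat = np.array([[p.get(t, 0.0) for t in taxa] for p in profiles], dtype=float)
    if np.any(mat < 0):
        raise ValueError("negative entries in composition vectors")
    if np.any(mat.sum(axis=1) == 0):
        raise ValueError("all-zero composition vector")
    n = mat.shape[0]
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        num = float(np.abs(mat[i] - mat[j]).sum())
        den = float((mat[i] + mat[j]).sum())
        out[i, j] = out[j, i] = num / den
    return out


def permanova(
    dist: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 9999,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """One-way PERMANOVA on a distance matrix: (R2, F, p).

    Pseudo-F from the Gower-centered partition of squared distances;
    p-value by permuting group labels with the +1/+1 correction.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    n = d.shape[0]
    if d.shape != (n, n) or labels.size != n:
        raise ValueError("distance matrix and labels are inconsistent")
    uniq, inv = np.unique(labels, return_inverse=True)
    g = uniq.size
    if g < 2:
        raise ValueError("need at least two groups")
    if np.any(np.bincount(inv) < 1):
        raise ValueError("every group needs at least one unit")
    d2 = d ** 2
    ss_total = float(d2[np.triu_indices(n, 1)].sum()) / n

    def ss_within(assign: np.ndarray) -> float:
        ss = 0.0
        for gi in range(g):
            idx = np.flatnonzero(assign == gi)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                ss += float(sub[np.triu_indices(idx.size, 1)].sum()) / idx.size
        return ss

    def pseudo_f(assign: np.ndarray) -> float:
        ssw = ss_within(assign)
        ssb = ss_total - ssw
        if ssw <= 0:
            return math_inf_like(ssb)
        return (ssb / (g - 1)) / (ssw / (n - g))

    def math_inf_like(ssb: float) -> float:
        return float("inf") if ssb > 0 else 0.0

    f_obs = pseudo_f(inv)
    ss_b = ss_total - ss_within(inv)
    r2 = ss_b / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    perm = inv.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        if pseudo_f(perm) >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(r2), float(f_obs), float(p)
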