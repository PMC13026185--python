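"""Individual identification, discriminatory power, sex, and demography.

Samples are grouped into individuals by exact genotype agreement across at
least ``min_overlap`` shared loci; near-matches (1-2 mismatching loci) are
reported for manual review, never merged automatically.  Probability-of-
identity statistics quantify the marker panel's discriminatory power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .consensus import ConsensusGenotype, Genotype

MultilocusGenotype = Dict[str, Genotype]


@dataclass
class AlleleFrequencies:
    """Per-locus allele -> frequency maps with gene counts."""

    freqs: Dict[str, Dict[int, float]]
    n_genes: Dict[str, int]
    counts: Dict[str, Dict[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for loc, fr in self.freqs.items():
            if any(v < 0 for v in fr.values()):
                raise ValueError(f"negative frequency at {loc}")
            if fr and abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {loc} do not sum to 1")

    @classmethod
    def from_genotypes(cls, genotypes: Dict[str, MultilocusGenotype]) -> "AlleleFrequencies":
        counts: Dict[str, Dict[int, int]] = {}
        for g in genotypes.values():
            for loc, call in g.items():
                if call is None:
                    continue
                d = counts.setdefault(loc, {})
                for a in call:
                    d[a] = d.get(a, 0) + 1
        freqs = {}
        n_genes = {}
        for loc, d in counts.items():
            n = sum(d.values())
            n_genes[loc] = n
            freqs[loc] = {a: c / n for a, c in sorted(d.items())}
        return cls(freqs=freqs, n_genes=n_genes, counts=counts)


def pid_per_locus(freqs: Dict[int, float]) -> Tuple[float, float]:
    """Probability of identity for unrelated individuals and for siblings.

    PID = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2
    PIDsibs = 0.25 + 0.5*S2 + 0.5*S2^2 - 0.25*S4  with Sm = sum p_i^m.
    A monomorphic locus returns (1.0, 1.0).
    """
    p = list(freqs.values())
    s2 = sum(x * x for x in p)
    s4 = sum(x ** 4 for x in p)
    pid = s4 + sum((2 * p[i] * p[j]) ** 2
                   for i in range(len(p)) for j in range(i + 1, len(p)))
    pid_sibs = 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4
    return pid, pid_sibs


def cumulative_pid(
    per_locus_values: Sequence[float],
    threshold: float,
) -> Tuple[List[float], Optional[int]]:
    """Cumulative products in locus order and the smallest prefix length
    whose product drops below ``threshold`` (``None`` if never reached)."""
    if not per_locus_values:
        raise ValueError("need at least one locus")
    out: List[float] = []
    acc = 1.0
    reached = None
    for i, v in enumerate(per_locus_values, start=1):
        acc *= v
        out.append(acc)
        if reached is None and acc < threshold:
            reached = i
    return out, reached


@dataclass
class Individual:
    individual_id: str
    sex: str  # "M", "F", or "unknown"
    genotype: MultilocusGenotype
    samples: List[str] = field(default_factory=list)
    sessions: Dict[str, str] = field(default_factory=dict)  # sample -> session


@dataclass
class MatchResult:
    individuals: List[Individual]
    review: List[Dict]      # near-match reports, excluded from the roster
    unassigned: List[str]   # samples with < min_overlap scored loci
    conflicts: List[str]


def _genotype_of(
    consensus: Dict[Tuple[str, str], ConsensusGenotype],
    sample: str,
    loci: Set[str],
) -> MultilocusGenotype:
    g = {}
    for (sid, loc), cons in consensus.items():
        if sid == sample and loc in loci and cons.call is not None:
            g[loc] = cons.call
    return g


def _compare(g1: MultilocusGenotype, g2: MultilocusGenotype) -> Tuple[int, List[str]]:
    shared = sorted(set(g1) & set(g2))
    mismatches = [loc for loc in shared if g1[loc] != g2[loc]]
    return len(shared), mismatches


def _dropout_artifact_of(a: Genotype, b: Genotype) -> bool:
    """True when call ``a`` could arise from ``b`` by allelic dropout:
    ``a`` homozygous for one allele of heterozygote ``b``."""
    return a[0] == a[1] and b[0] != b[1] and a[0] in b


def _false_allele_artifact_of(a: Genotype, b: Genotype) -> bool:
    """True when call ``a`` could arise from homozygote ``b`` by a
    confirmed false allele: ``a`` heterozygous containing ``b``'s allele."""
    return a[0] != a[1] and b[0] == b[1] and b[0] in a


def match_individuals(
    consensus: Dict[Tuple[str, str], ConsensusGenotype],
    min_overlap: int = 6,
    loci: Optional[Sequence[str]] = None,
    sample_sex: Optional[Dict[str, str]] = None,
    sample_session: Optional[Dict[str, str]] = None,
) -> MatchResult:
    """Group samples into individuals by exact multilocus agreement.

    Samples scored at fewer than ``min_overlap`` loci are unassigned.
    Samples are processed in sorted order (permutation invariant); each one
    joins the first existing group whose merged profile it matches exactly
    at >= ``min_overlap`` overlapping loci, otherwise it opens a new group.
    Afterwards, a singleton group whose profile differs from some other
    group at only 1-2 loci, every difference being explainable as an
    allelic dropout in the singleton (singleton homozygous for one allele
    of the other profile's heterozygote), is diverted to the review list
    rather than promoted to a new individual.
    """
    locus_set = set(loci) if loci is not None else {loc for _, loc in consensus}
    samples = sorted({sid for sid, _ in consensus})
    genos = {s: _genotype_of(consensus, s, locus_set) for s in samples}

    unassigned = [s for s in samples if len(genos[s]) < min_overlap]
    eligible = [s for s in samples if len(genos[s]) >= min_overlap]

    groups: List[Dict] = []  # {"profile": MultilocusGenotype, "samples": [...]}
    conflicts: List[str] = []
    for s in eligible:
        placed = False
        for grp in groups:
            overlap, mism = _compare(genos[s], grp["profile"])
            if overlap >= min_overlap and not mism:
                grp["profile"] = {**grp["profile"], **genos[s]}
                grp["samples"].append(s)
                placed = True
                break
        if not placed:
            groups.append({"profile": dict(genos[s]), "samples": [s]})

    # transitive-consistency audit within groups
    for grp in groups:
        for i, s1 in enumerate(grp["samples"]):
            for s2 in grp["samples"][i + 1:]:
                _, mism = _compare(genos[s1], genos[s2])
                if mism:
                    conflicts.append(
                        f"transitive conflict {s1}/{s2} at loci {sorted(mism)}")

    review: List[Dict] = []
    kept: List[Dict] = []
    for grp in groups:
        size = len(grp["samples"])
        if size > 2:
            kept.append(grp)
            continue
        near = None
        for other in groups:
            if other is grp or len(other["samples"]) < size:
                continue
            overlap, mism = _compare(grp["profile"], other["profile"])
            if not (overlap >= min_overlap and 1 <= len(mism) <= 2):
                continue
            ok = True
            for m in mism:
                ga, gb = grp["profile"][m], other["profile"][m]
                if _dropout_artifact_of(ga, gb):
                    continue
                if size == 1 and len(other["samples"]) > 1 \
                        and _false_allele_artifact_of(ga, gb):
                    continue
                ok = False
                break
            if ok:
                near = (other, mism)
                break
        if near is not None:
            other, mism = near
            review.append({
                "samples": list(grp["samples"]),
                "near_match_of": other["samples"][0],
                "mismatch_loci": sorted(mism),
                "reason": "error-compatible near match; manual review required",
            })
        else:
            kept.append(grp)

    individuals = []
    for i, grp in enumerate(sorted(kept, key=lambda g: (-len(g["samples"]), g["samples"][0]))):
        sex = "unknown"
        if sample_sex:
            sexes = {sample_sex.get(s, "unknown") for s in grp["samples"]} - {"unknown"}
            sex = sexes.pop() if len(sexes) == 1 else "unknown"
            if sample_sex and len({sample_sex.get(s) for s in grp["samples"]}
                                  - {None, "unknown"}) > 1:
                conflicts.append(f"sex conflict within group {grp['samples']}")
        sessions = {s: sample_session.get(s, "") for s in grp["samples"]} \
            if sample_session else {}
        individuals.append(Individual(
            individual_id=f"IND{i + 1:02d}",
            sex=sex,
            genotype=grp["profile"],
            samples=sorted(grp["samples"]),
            sessions=sessions,
        ))
    return MatchResult(individuals=individuals, review=review,
                       unassigned=unassigned, conflicts=conflicts)


def assign_sex(
    replicates: Sequence[Optional[Genotype]],
    x_allele: int,
    y_allele: int,
) -> str:
    """Male iff X and Y are each confirmed in >=2 replicates; female iff
    >=3 successful replicates are all X-only; otherwise unknown."""
    succ = [r for r in replicates if r is not None]
    n_x = sum(1 for r in succ if x_allele in r)
    n_y = sum(1 for r in succ if y_allele in r)
    if n_x >= 2 and n_y >= 2:
        return "M"
    if len(succ) >= 3 and all(set(r) == {x_allele} for r in succ):
        return "F"
    return "unknown"


def _ratio_label(m: int, f: int) -> str:
    if f == 0:
        return f"{m}:0"
    g = math.gcd(m, f)
    return f"{m // g}:{f // g}"


def demography_summary(
    individuals: Sequence[Individual],
    sessions: Optional[Sequence[str]] = None,
    area_ha: Optional[float] = None,
    n_collected: Optional[int] = None,
    n_genotyped: Optional[int] = None,
) -> Dict:
    """Sex ratio, per-session minimum counts, interannual recapture rates,
    density per km^2, and (optionally) sample-level genotyping success."""
    if any(not ind.samples for ind in individuals):
        raise ValueError("every individual must have at least one capture event")
    males = sum(1 for i in individuals if i.sex == "M")
    females = sum(1 for i in individuals if i.sex == "F")

    detected: Dict[str, Set[str]] = {}
    for ind in individuals:
        for sess in ind.sessions.values():
            if sess:
                detected.setdefault(sess, set()).add(ind.individual_id)
    if sessions is None:
        sessions = sorted(detected)

    recapture = {}
    for t, t1 in zip(sessions, list(sessions)[1:]):
        base = detected.get(t, set())
        if base:
            recapture[f"{t}->{t1}"] = len(base & detected.get(t1, set())) / len(base)

    out = {
        "n_individuals": len(individuals),
        "males": males,
        "females": females,
        "sex_ratio": (males / females) if females else math.inf,
        "sex_ratio_label": _ratio_label(males, females),
        "per_session_counts": {s: len(detected.get(s, ())) for s in sessions},
        "recapture_rates": recapture,
    }
    if area_ha is not None:
        out["density_per_km2"] = len(individuals) / (area_ha / 100.0)
    if n_collected and n_genotyped is not None:
        out["genotyping_success_pct"] = 100.0 * n_genotyped / n_collected
    return out
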