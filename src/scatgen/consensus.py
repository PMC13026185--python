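"""Multitube consensus genotyping from replicate-PCR allele calls.

Confirmation rules: a heterozygote requires each allele observed in at
least two replicates; a homozygote requires at least three successful
replicates all showing only that allele (a single discordant allele seen
once is tolerated but flagged).  A cell unresolved after six replicates is
missing.  Error rates (allelic dropout and false alleles) are estimated by
comparing replicates against the consensus calls.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

Genotype = Tuple[int, int]

MAX_REPLICATES = 6


@dataclass(frozen=True)
class ReplicateRecord:
    """One PCR replicate of one sample at one locus.

    ``alleles`` is a sorted (low, high) pair in base pairs, or ``None`` for
    a failed reaction.  Homozygous observations repeat the allele.
    """

    sample_id: str
    locus: str
    replicate: int
    alleles: Optional[Genotype]

    def __post_init__(self) -> None:
        if not 1 <= self.replicate <= MAX_REPLICATES:
            raise ValueError(
                f"replicate index {self.replicate} outside 1..{MAX_REPLICATES} "
                f"({self.sample_id}/{self.locus})")
        if self.alleles is not None and tuple(sorted(self.alleles)) != tuple(self.alleles):
            raise ValueError(f"alleles must be sorted ascending: {self.alleles}")


@dataclass
class ReplicateTable:
    records: List[ReplicateRecord]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.sample_id, r.locus, r.replicate)
            if key in seen:
                raise ValueError(f"duplicate replicate record {key}")
            seen.add(key)

    @property
    def samples(self) -> List[str]:
        return sorted({r.sample_id for r in self.records})

    @property
    def loci(self) -> List[str]:
        return sorted({r.locus for r in self.records})

    def by_cell(self) -> Dict[Tuple[str, str], List[ReplicateRecord]]:
        cells: Dict[Tuple[str, str], List[ReplicateRecord]] = {}
        for r in self.records:
            cells.setdefault((r.sample_id, r.locus), []).append(r)
        for reps in cells.values():
            reps.sort(key=lambda r: r.replicate)
        return cells

    def restrict(self, samples: Iterable[str]) -> "ReplicateTable":
        keep = set(samples)
        return ReplicateTable([r for r in self.records if r.sample_id in keep])


@dataclass
class ConsensusGenotype:
    sample_id: str
    locus: str
    call: Optional[Genotype]  # (a, a) homozygote, (a, b) heterozygote, None missing
    support: Dict[int, int] = field(default_factory=dict)
    n_replicates_used: int = 0
    flags: List[str] = field(default_factory=list)

    @property
    def is_heterozygote(self) -> bool:
        return self.call is not None and self.call[0] != self.call[1]


@dataclass
class ErrorRates:
    ado_per_locus: Dict[str, Optional[float]]
    fa_per_locus: Dict[str, Optional[float]]
    ado_cumulative: Optional[float]
    fa_cumulative: Optional[float]


def screen_samples(
    table: ReplicateTable,
    n_loci: int,
    min_fraction: float = 0.40,
    loci: Optional[Sequence[str]] = None,
) -> Set[str]:
    """Initial-duplicate screen: retain samples amplifying at
    >= ceil(min_fraction * n_loci) loci (>=1 success among replicates 1-2).
    """
    if loci is not None:
        known = set(loci)
        offenders = sorted({r.locus for r in table.records} - known - {_sex_locus()})
        if offenders:
            raise ValueError(f"unknown locus names: {offenders}")
    counted = set(loci) if loci is not None else None
    need = math.ceil(min_fraction * n_loci)
    amplified: Dict[str, Set[str]] = {}
    for r in table.records:
        if r.replicate <= 2 and r.alleles is not None:
            if counted is None or r.locus in counted:
                amplified.setdefault(r.sample_id, set()).add(r.locus)
    all_samples = {r.sample_id for r in table.records}
    return {s for s in all_samples if len(amplified.get(s, ())) >= need}


def _sex_locus() -> str:
    from .simulate import SEX_LOCUS  # local import avoids a cycle at load time

    return SEX_LOCUS


def call_cell(
    replicates: Sequence[Optional[Genotype]],
) -> Tuple[Optional[Genotype], Dict[int, int], List[str]]:
    """Apply the confirmation rules to one sample x locus cell.

    Returns (call, per-allele confirmation counts, flags).  A confirmed
    heterozygote takes precedence over a homozygote interpretation; more
    than two alleles confirmed twice is a conflict (missing).
    """
    successful = [r for r in replicates if r is not None]
    support = Counter()
    for rep in successful:
        for allele in set(rep):
            support[allele] += 1
    confirmed = sorted(a for a, c in support.items() if c >= 2)
    flags: List[str] = []

    if len(confirmed) > 2:
        return None, dict(support), ["multi-allele conflict"]
    if len(confirmed) == 2:
        return (confirmed[0], confirmed[1]), dict(support), flags
    if len(confirmed) == 1:
        a = confirmed[0]
        only_a = [r for r in successful if set(r) == {a}]
        if len(only_a) >= 3:
            if len(only_a) < len(successful):
                flags.append("discordant-replicate")
            return (a, a), dict(support), flags
    return None, dict(support), flags


def call_consensus(
    table: ReplicateTable,
    loci: Optional[Sequence[str]] = None,
) -> Dict[Tuple[str, str], ConsensusGenotype]:
    """Consensus call for every sample x locus cell present in the table."""
    wanted = set(loci) if loci is not None else None
    out: Dict[Tuple[str, str], ConsensusGenotype] = {}
    for (sid, loc), reps in table.by_cell().items():
        if wanted is not None and loc not in wanted:
            continue
        call, support, flags = call_cell([r.alleles for r in reps])
        out[(sid, loc)] = ConsensusGenotype(
            sample_id=sid, locus=loc, call=call, support=support,
            n_replicates_used=len(reps), flags=flags)
    return out


def estimate_error_rates(
    table: ReplicateTable,
    consensus: Dict[Tuple[str, str], ConsensusGenotype],
) -> ErrorRates:
    """Per-locus and cumulative ADO / FA frequencies.

    ADO uses only heterozygous-consensus cells: the fraction of successful
    replicates there showing exactly one of the two consensus alleles.  FA
    uses all non-missing cells: the fraction of successful replicates
    containing at least one allele absent from the consensus call.
    Cumulative rates are replicate-count-weighted means across loci.
    """
    cells = table.by_cell()
    ado_num: Dict[str, int] = {}
    ado_den: Dict[str, int] = {}
    fa_num: Dict[str, int] = {}
    fa_den: Dict[str, int] = {}

    for (sid, loc), cons in consensus.items():
        if cons.call is None:
            continue
        reps = [r.alleles for r in cells.get((sid, loc), []) if r.alleles is not None]
        call_set = set(cons.call)
        for rep in reps:
            fa_den[loc] = fa_den.get(loc, 0) + 1
            if set(rep) - call_set:
                fa_num[loc] = fa_num.get(loc, 0) + 1
        if cons.is_heterozygote:
            for rep in reps:
                ado_den[loc] = ado_den.get(loc, 0) + 1
                if len(set(rep) & call_set) == 1:
                    ado_num[loc] = ado_num.get(loc, 0) + 1

    loci = sorted({loc for _, loc in consensus})
    ado = {loc: (ado_num.get(loc, 0) / ado_den[loc]) if ado_den.get(loc) else None
           for loc in loci}
    fa = {loc: (fa_num.get(loc, 0) / fa_den[loc]) if fa_den.get(loc) else None
          for loc in loci}

    tot_ado_den = sum(ado_den.values())
    tot_fa_den = sum(fa_den.values())
    return ErrorRates(
        ado_per_locus=ado,
        fa_per_locus=fa,
        ado_cumulative=(sum(ado_num.values()) / tot_ado_den) if tot_ado_den else None,
        fa_cumulative=(sum(fa_num.values()) / tot_fa_den) if tot_fa_den else None,
    )


def null_allele_frequency(he: float, ho: float) -> float:
    """Brookfield 1 null-allele estimator: (He - Ho) / (1 + He).

    May be negative; negative values indicate no null-allele signal.
    """
    if not (0.0 <= he <= 1.0 and 0.0 <= ho <= 1.0):
        raise ValueError("He and Ho must lie in [0, 1]")
    return (he - ho) / (1.0 + he)
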