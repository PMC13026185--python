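"""Synthetic data generation for a small, kin-structured felid population.

Everything downstream of the wet lab is emulated here: a pedigreed
population of microsatellite genotypes, replicate-PCR tables with allelic
dropout / false alleles / amplification failure, a sex-marker pseudo-locus,
and taxon-assigned diet read tables amplified in triplicate.  All stochastic
operations draw from a single seeded :class:`numpy.random.Generator` in
documented call order, so a fixed seed yields bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .consensus import (
    ReplicateRecord,
    ReplicateTable,
    call_cell,
    screen_samples,
)

SEX_LOCUS = "ZF"
X_ALLELE = 103
Y_ALLELE = 107

#: Default pedigree: 9 sampled individuals connected by exactly 4 full-sib
#: and 5 parent-offspring dyads.  Ids starting with "u" are unsampled mates
#: or founders that exist only to wire the pedigree together.
DEFAULT_PEDIGREE: List[Tuple[str, Optional[str], Optional[str]]] = [
    ("u1", None, None),
    ("u2", None, None),
    ("u3", None, None),
    ("u4", None, None),
    ("u5", None, None),
    ("u6", None, None),
    ("S1", "u1", "u2"),
    ("S2", "u1", "u2"),
    ("S3", "u1", "u2"),
    ("C1", "S1", "u3"),
    ("C2", "S2", "u4"),
    ("G1", None, None),
    ("D1", "u5", "G1"),
    ("D2", "u5", "G1"),
    ("E1", "D1", "u6"),
]

DEFAULT_SAMPLED = ("S1", "S2", "S3", "C1", "C2", "G1", "D1", "D2", "E1")

DEFAULT_SEXES = {
    "S1": "M", "S2": "M", "S3": "F", "C1": "M", "C2": "M",
    "G1": "F", "D1": "M", "D2": "F", "E1": "M",
}

#: Rodent-dominated eight-taxon diet (multinomial probabilities).
DEFAULT_DIET_PROFILE = {
    "Aegialomys xanthaeolus": 0.53,
    "Rallus longirostris": 0.12,
    "Gallinula chloropus": 0.10,
    "Aramides axillaris": 0.08,
    "Tachuris rubrigastra": 0.07,
    "Spatula cyanoptera": 0.05,
    "Mus musculus": 0.02,
    "Platalea ajaja": 0.03,
}

PREDATOR_TAXON = "Leopardus garleppi"


@dataclass
class SimConfig:
    """Parameters of the synthetic study system.

    Defaults emulate a field-realistic system: nine
    individuals in a first-order-kin pedigree, eight autosomal loci with
    2-5 alleles each, per-replicate allelic dropout 0.21 and false-allele
    rate 0.005, roughly 48% sample-level genotyping success, heterogeneous
    per-individual scat counts, and a rodent-dominated diet in triplicate.
    """

    n_individuals: int = 9
    pedigree_spec: List[Tuple[str, Optional[str], Optional[str]]] = field(
        default_factory=lambda: list(DEFAULT_PEDIGREE))
    sampled: Tuple[str, ...] = DEFAULT_SAMPLED
    sexes: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SEXES))
    n_loci: int = 11
    alleles_per_locus: Tuple[int, int] = (2, 5)
    repeat_unit_bp: int = 2
    base_size_bp: int = 100
    ado_rate: float = 0.21
    fa_rate: float = 0.005
    locus_failure_rate: float = 0.05
    poor_sample_failure_rate: float = 0.90
    sample_success_rate: float = 0.48
    scats_per_individual: Optional[Dict[str, float]] = None
    min_scats_per_individual: int = 8
    n_scats: int = 142
    session_sizes: Dict[str, int] = field(
        default_factory=lambda: {"2019": 46, "2020": 78, "2021": 18})
    diet_profile: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIET_PROFILE))
    meal_size_probs: Tuple[float, ...] = (0.50, 0.35, 0.15)
    reads_per_replicate: int = 2000
    contaminant_rate: float = 0.002
    predator_read_rate: float = 0.25
    diet_failure_rate: float = 0.23
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ado_rate", "fa_rate", "locus_failure_rate",
                     "poor_sample_failure_rate", "sample_success_rate",
                     "contaminant_rate", "predator_read_rate",
                     "diet_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.diet_profile:
            total = sum(self.diet_profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"diet_profile sums to {total}, expected 1 within 1e-9")
        lo, hi = self.alleles_per_locus
        if not (2 <= lo <= hi):
            raise ValueError("alleles_per_locus range must satisfy 2 <= lo <= hi")


@dataclass
class TruePopulation:
    """Ground truth: pedigreed multilocus genotypes plus founder frequencies."""

    individuals: Dict[str, Tuple[str, Dict[str, Tuple[int, int]]]]
    sampled: List[str]
    pedigree: Dict[str, Tuple[Optional[str], Optional[str]]]
    founder_freqs: Dict[str, Dict[int, float]]
    loci: List[str]
    repeat_units: Dict[str, int]

    def genotype(self, ind: str) -> Dict[str, Tuple[int, int]]:
        return self.individuals[ind][1]

    def sex(self, ind: str) -> str:
        return self.individuals[ind][0]

    def dyad_categories(self) -> Dict[Tuple[str, str], str]:
        """True relationship category (PO/FS/HS/U) for every sampled dyad."""
        cats = {}
        ids = sorted(self.sampled)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                cats[(a, b)] = self._category(a, b)
        return cats

    def _category(self, a: str, b: str) -> str:
        pa, pb = self.pedigree.get(a, (None, None)), self.pedigree.get(b, (None, None))
        if a in pb or b in pa:
            return "PO"
        shared = len({p for p in pa if p is not None} &
                     {p for p in pb if p is not None})
        if shared == 2:
            return "FS"
        if shared == 1:
            return "HS"
        return "U"


def _check_acyclic(pedigree: Sequence[Tuple[str, Optional[str], Optional[str]]]) -> List[str]:
    """Topologically order the pedigree; raise naming a cycle if one exists."""
    parents = {c: tuple(p for p in (s, d) if p is not None) for c, s, d in pedigree}
    order: List[str] = []
    state: Dict[str, int] = {}  # 0 visiting, 1 done
    stack_path: List[str] = []

    def visit(node: str) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cyc = stack_path[stack_path.index(node):] + [node]
            raise ValueError(f"cyclic pedigree: {' -> '.join(cyc)}")
        state[node] = 0
        stack_path.append(node)
        for p in parents.get(node, ()):
            if p not in parents:
                raise ValueError(f"parent {p!r} of {node!r} not declared in pedigree")
            visit(p)
        stack_path.pop()
        state[node] = 1
        order.append(node)

    for child in parents:
        visit(child)
    return order


def _locus_names(n: int) -> List[str]:
    return [f"L{i + 1:02d}" for i in range(n)]


def simulate_population(config: SimConfig) -> TruePopulation:
    """Draw founder allele frequencies and Mendelian genotypes down the pedigree."""
    rng = np.random.default_rng(config.seed)
    loci = _locus_names(config.n_loci)
    repeat_units = {loc: config.repeat_unit_bp for loc in loci}

    founder_freqs: Dict[str, Dict[int, float]] = {}
    for i, loc in enumerate(loci):
        lo, hi = config.alleles_per_locus
        k = int(rng.integers(lo, hi + 1))
        # Allele ladder with occasional gaps so M-ratio can dip below 1.
        offsets = np.sort(rng.choice(k + 3, size=k, replace=False))
        base = config.base_size_bp + 20 * i
        sizes = base + config.repeat_unit_bp * offsets
        freqs = rng.dirichlet(np.full(k, 2.0))
        founder_freqs[loc] = {int(s): float(f) for s, f in zip(sizes, freqs)}

    order = _check_acyclic(config.pedigree_spec)
    pedigree = {c: (s, d) for c, s, d in config.pedigree_spec}
    sampled = [i for i in config.sampled if i in pedigree]
    if set(config.sampled) - set(pedigree):
        missing = sorted(set(config.sampled) - set(pedigree))
        raise ValueError(f"sampled ids missing from pedigree: {missing}")

    genotypes: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for ind in order:
        sire, dam = pedigree[ind]
        g: Dict[str, Tuple[int, int]] = {}
        for loc in loci:
            alleles = []
            for parent in (sire, dam):
                if parent is None:
                    fr = founder_freqs[loc]
                    keys = sorted(fr)
                    alleles.append(int(rng.choice(keys, p=[fr[a] for a in keys])))
                else:
                    alleles.append(int(rng.choice(genotypes[parent][loc])))
            g[loc] = tuple(sorted(alleles))  # type: ignore[assignment]
        genotypes[ind] = g

    sexes = dict(config.sexes)
    for ind in order:
        if ind not in sexes:
            sexes[ind] = "M" if rng.random() < 0.5 else "F"

    individuals = {}
    for ind in order:
        g = dict(genotypes[ind])
        g[SEX_LOCUS] = (X_ALLELE, Y_ALLELE) if sexes[ind] == "M" else (X_ALLELE, X_ALLELE)
        individuals[ind] = (sexes[ind], g)

    return TruePopulation(
        individuals=individuals,
        sampled=sampled,
        pedigree=pedigree,
        founder_freqs=founder_freqs,
        loci=loci,
        repeat_units=repeat_units,
    )


def _noisy_replicate(
    rng: np.random.Generator,
    true_geno: Tuple[int, int],
    allele_pool: Sequence[int],
    ado_rate: float,
    fa_rate: float,
    failure_rate: float,
) -> Optional[Tuple[int, int]]:
    """One PCR replicate of one locus: failure, dropout, then false allele."""
    if rng.random() < failure_rate:
        return None
    a, b = true_geno
    obs = [a, b]
    if a != b and rng.random() < ado_rate:
        keep = obs[int(rng.integers(2))]
        obs = [keep, keep]
    if rng.random() < fa_rate:
        wrong = [x for x in allele_pool if x not in true_geno]
        if wrong:
            obs[int(rng.integers(2))] = int(wrong[int(rng.integers(len(wrong)))])
    return tuple(sorted(obs))  # type: ignore[return-value]


def _poor_fraction(config: SimConfig) -> float:
    """Fraction of scats that are low quality so that the expected screening
    pass rate matches ``sample_success_rate``."""
    from scipy.stats import binom

    n = config.n_loci
    need = math.ceil(0.40 * n)

    def p_pass(fail: float) -> float:
        p_amp = 1.0 - fail ** 2  # >=1 success in the 2 initial replicates
        return float(binom.sf(need - 1, n, p_amp))

    good, poor = p_pass(config.locus_failure_rate), p_pass(config.poor_sample_failure_rate)
    if good <= poor:
        return 0.0
    q = (good - config.sample_success_rate) / (good - poor)
    return float(min(max(q, 0.0), 1.0))


def simulate_replicate_table(
    pop: TruePopulation,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ReplicateTable, Dict]:
    """Two-step multitube emulation.

    Every scat gets two initial replicates at every locus; scats amplifying
    at fewer than 40% of loci are left as-is (they fail downstream
    screening), while retained scats receive additional replicates (max 6)
    only for cells whose consensus is still unresolved.

    Returns the table plus a truth dictionary (scat owner, session, rates).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    sampled = pop.sampled
    if config.scats_per_individual:
        weights = np.array([config.scats_per_individual.get(i, 1.0) for i in sampled], float)
    else:
        default_w = [10, 8, 2, 7, 2, 5, 7, 10, 2]
        weights = np.array([default_w[i % len(default_w)] for i in range(len(sampled))], float)

    # deterministic largest-remainder allocation with a per-individual floor,
    # so capture heterogeneity is controlled exactly by the weights
    floor = min(config.min_scats_per_individual,
                config.n_scats // max(len(sampled), 1))
    spare = config.n_scats - floor * len(sampled)
    raw = weights / weights.sum() * spare
    alloc = np.floor(raw).astype(int) + floor
    remainder = np.argsort(-(raw - np.floor(raw)))
    for idx in remainder[: config.n_scats - int(alloc.sum())]:
        alloc[idx] += 1
    owners = [ind for ind, n_i in zip(sampled, alloc) for _ in range(int(n_i))]
    owners = [owners[int(i)] for i in rng.permutation(len(owners))]
    sess_names = sorted(config.session_sizes)
    sess_w = np.array([config.session_sizes[s] for s in sess_names], float)
    sessions = [sess_names[int(i)] for i in
                rng.choice(len(sess_names), size=config.n_scats, p=sess_w / sess_w.sum())]

    q_poor = _poor_fraction(config)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_scats)]
    fail_rates = {
        sid: (config.poor_sample_failure_rate if rng.random() < q_poor
              else config.locus_failure_rate)
        for sid in sample_ids
    }

    pools = {loc: sorted(pop.founder_freqs[loc]) for loc in pop.loci}
    pools[SEX_LOCUS] = [X_ALLELE, Y_ALLELE]
    all_loci = pop.loci + [SEX_LOCUS]

    records: List[ReplicateRecord] = []
    cell_reps: Dict[Tuple[str, str], List[Optional[Tuple[int, int]]]] = {}

    def add_rep(sid: str, loc: str) -> None:
        truth = pop.genotype(owners[sample_ids.index(sid)])[loc]
        reps = cell_reps.setdefault((sid, loc), [])
        fa = 0.0 if loc == SEX_LOCUS else config.fa_rate
        obs = _noisy_replicate(rng, truth, pools[loc], config.ado_rate, fa, fail_rates[sid])
        reps.append(obs)
        records.append(ReplicateRecord(sid, loc, len(reps), obs))

    # step 1: initial duplicates everywhere
    for sid in sample_ids:
        for loc in all_loci:
            add_rep(sid, loc)
            add_rep(sid, loc)

    initial = ReplicateTable(list(records))
    retained = screen_samples(initial, n_loci=config.n_loci, min_fraction=0.40,
                              loci=pop.loci)

    # step 2: replicate unresolved cells of retained scats, up to 6 total
    def unresolved(sid: str, loc: str) -> bool:
        reps = cell_reps[(sid, loc)]
        if len(reps) >= 6:
            return False
        if loc == SEX_LOCUS:
            succ = [r for r in reps if r is not None]
            n_y = sum(1 for r in succ if Y_ALLELE in r)
            n_x = sum(1 for r in succ if X_ALLELE in r)
            male = n_y >= 2 and n_x >= 2
            female = len(succ) >= 3 and all(r == (X_ALLELE, X_ALLELE) for r in succ)
            return not (male or female)
        call, _, _ = call_cell(reps)
        return call is None

    for sid in sample_ids:
        if sid not in retained:
            continue
        for loc in all_loci:
            while unresolved(sid, loc):
                add_rep(sid, loc)

    truth = {
        "owner": dict(zip(sample_ids, owners)),
        "session": dict(zip(sample_ids, sessions)),
        "rates": {"ado": config.ado_rate, "fa": config.fa_rate},
        "pedigree": {c: list(p) for c, p in pop.pedigree.items()},
        "sexes": {i: pop.sex(i) for i in pop.sampled},
    }
    return ReplicateTable(records), truth


def simulate_diet_table(
    pop: TruePopulation,
    config: SimConfig,
    sample_owners: Optional[Dict[str, str]] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Triplicate read-count tables over the configured prey profile.

    Each scat's meal is 1-3 iid taxon slots drawn from ``diet_profile``
    (duplicated slots collapse to one detected taxon carrying their summed
    read share), plus predator reads and low-rate contaminant reads.
    """
    from .diet import DietReadTable

    if not config.diet_profile:
        raise ValueError("diet_profile is empty")
    if config.reads_per_replicate <= 0:
        raise ValueError("reads_per_replicate must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    if sample_owners is None:
        sampled = pop.sampled
        ids = [f"D{i + 1:03d}" for i in range(config.n_scats)]
        picks = rng.choice(len(sampled), size=config.n_scats)
        sample_owners = {sid: sampled[int(i)] for sid, i in zip(ids, picks)}

    taxa = sorted(config.diet_profile)
    probs = np.array([config.diet_profile[t] for t in taxa])
    sizes = np.arange(1, len(config.meal_size_probs) + 1)
    records = []
    for sid in sorted(sample_owners):
        failed = rng.random() < config.diet_failure_rate
        t_s = int(rng.choice(sizes, p=np.array(config.meal_size_probs)
                             / sum(config.meal_size_probs)))
        slots = rng.choice(len(taxa), size=t_s, p=probs)
        slot_counts: Dict[str, int] = {}
        for s in slots:
            slot_counts[taxa[int(s)]] = slot_counts.get(taxa[int(s)], 0) + 1
        meal_taxa = sorted(slot_counts)
        meal_p = np.array([slot_counts[t] for t in meal_taxa], float) / t_s

        for rep in (1, 2, 3):
            if failed:
                continue
            total = config.reads_per_replicate
            n_pred = rng.binomial(total, config.predator_read_rate)
            n_cont = rng.binomial(total - n_pred, config.contaminant_rate)
            n_prey = total - n_pred - n_cont
            prey_reads = rng.multinomial(n_prey, meal_p)
            reads = dict(zip(meal_taxa, (int(x) for x in prey_reads)))
            if n_pred:
                reads[PREDATOR_TAXON] = reads.get(PREDATOR_TAXON, 0) + int(n_pred)
            for _ in range(int(n_cont)):
                t = taxa[int(rng.integers(len(taxa)))]
                reads[t] = reads.get(t, 0) + 1
            for taxon in sorted(reads):
                if reads[taxon] > 0:
                    records.append((sid, rep, taxon, reads[taxon]))

    owner_sex = {i: pop.sex(i) for i in pop.individuals}
    return DietReadTable(
        records=records,
        sample_to_individual=dict(sample_owners),
        individual_sex={i: owner_sex.get(i, "unknown") for i in sample_owners.values()},
    )
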