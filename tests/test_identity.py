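import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scatgen.consensus import ConsensusGenotype, call_consensus
from scatgen.identity import (
    AlleleFrequencies,
    Individual,
    assign_sex,
    cumulative_pid,
    demography_summary,
    match_individuals,
    pid_per_locus,
)
from scatgen.simulate import (
    SEX_LOCUS,
    X_ALLELE,
    Y_ALLELE,
    SimConfig,
    simulate_population,
    simulate_replicate_table,
)


class TestPid:
    def test_biallelic_even_unrelated(self):
        pid, _ = pid_per_locus({1: 0.5, 2: 0.5})
        assert pid == pytest.approx(0.375)

    def test_biallelic_even_sibs(self):
        _, sibs = pid_per_locus({1: 0.5, 2: 0.5})
        assert sibs == pytest.approx(0.59375)

    def test_monomorphic(self):
        assert pid_per_locus({1: 1.0}) == (1.0, 1.0)

    def test_sibs_floor_quarter(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            pid, sibs = pid_per_locus({i: float(x) for i, x in enumerate(p)})
            assert sibs >= 0.25 and sibs >= pid


class TestCumulativePid:
    def test_single_locus_not_reached(self):
        cum, n = cumulative_pid([0.5], 0.01)
        assert cum == [0.5] and n is None

    def test_seven_loci_of_051(self):
        cum, n = cumulative_pid([0.51] * 7, 0.01)
        assert cum[-1] == pytest.approx(0.51 ** 7)
        assert cum[-1] < 0.01 and n == 7

    def test_zero_propagates(self):
        cum, n = cumulative_pid([0.5, 0.0, 0.9], 0.01)
        assert cum[1:] == [0.0, 0.0] and n == 2

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_monotone_nonincreasing(self, vals):
        cum, _ = cumulative_pid(vals, 0.01)
        assert all(b <= a + 1e-12 for a, b in zip(cum, cum[1:]))


def _cons(sample, geno):
    return {(sample, loc): ConsensusGenotype(sample, loc, call)
            for loc, call in geno.items()}


class TestMatching:
    def test_identical_samples_merge(self):
        g = {f"L{i}": (100 + i, 102 + i) for i in range(8)}
        cons = {**_cons("a", g), **_cons("b", g)}
        res = match_individuals(cons, min_overlap=6)
        assert len(res.individuals) == 1
        assert res.individuals[0].samples == ["a", "b"]

    def test_five_locus_overlap_not_merged(self):
        shared = {f"L{i}": (100, 102) for i in range(5)}
        ga = {**shared, "L8": (1, 2), "L9": (1, 2)}
        gb = {**shared, "La": (3, 4), "Lb": (3, 4)}
        cons = {**_cons("a", ga), **_cons("b", gb)}
        res = match_individuals(cons, min_overlap=6)
        assert len(res.individuals) == 2  # only 5 overlapping loci: no merge

    def test_below_min_scored_loci_unassigned(self):
        g = {f"L{i}": (100, 102) for i in range(5)}
        res = match_individuals(_cons("a", g), min_overlap=6)
        assert res.unassigned == ["a"] and not res.individuals

    def test_mismatch_splits(self):
        g1 = {f"L{i}": (100, 102) for i in range(8)}
        g2 = dict(g1, L0=(104, 106))  # non-error-compatible difference
        cons = {**_cons("a", g1), **_cons("b", g2)}
        res = match_individuals(cons, min_overlap=6)
        assert len(res.individuals) == 2

    def test_dropout_singleton_sent_to_review(self):
        het = {f"L{i}": (100, 102) for i in range(8)}
        hom = dict(het, L0=(100, 100))
        cons = {**_cons("a", het), **_cons("b", het), **_cons("c", hom)}
        res = match_individuals(cons, min_overlap=6)
        assert len(res.individuals) == 1
        assert len(res.review) == 1 and res.review[0]["samples"] == ["c"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        genos = {}
        for s in "abcdefgh":
            genos[s] = {f"L{i}": tuple(sorted(rng.integers(100, 108, 2)))
                        for i in range(8)}
        cons1 = {}
        for s, g in genos.items():
            cons1.update(_cons(s, g))
        cons2 = {}
        for s in reversed(sorted(genos)):
            cons2.update(_cons(s, genos[s]))
        r1 = match_individuals(cons1, min_overlap=6)
        r2 = match_individuals(cons2, min_overlap=6)
        assert [i.samples for i in r1.individuals] == [i.samples for i in r2.individuals]

    def test_zero_error_recovery_exact(self):
        cfg = SimConfig(seed=13, ado_rate=0.0, fa_rate=0.0,
                        locus_failure_rate=0.0, sample_success_rate=1.0,
                        n_scats=60)
        pop = simulate_population(cfg)
        table, truth = simulate_replicate_table(pop, cfg)
        cons = call_consensus(table, loci=pop.loci)
        res = match_individuals(cons, min_overlap=6, loci=pop.loci)
        assert len(res.individuals) == 9
        for ind in res.individuals:
            owners = {truth["owner"][s] for s in ind.samples}
            assert len(owners) == 1


class TestAssignSex:
    def test_male(self):
        assert assign_sex([(X_ALLELE, Y_ALLELE)] * 2, X_ALLELE, Y_ALLELE) == "M"

    def test_female(self):
        assert assign_sex([(X_ALLELE, X_ALLELE)] * 3, X_ALLELE, Y_ALLELE) == "F"

    def test_ambiguous(self):
        reps = [(X_ALLELE, X_ALLELE), (X_ALLELE, Y_ALLELE)]
        assert assign_sex(reps, X_ALLELE, Y_ALLELE) == "unknown"

    def test_failures_ignored(self):
        reps = [None, (X_ALLELE, X_ALLELE)] * 3
        assert assign_sex(reps, X_ALLELE, Y_ALLELE) == "F"


def _individuals(n_m, n_f, sessions=None):
    out = []
    for i in range(n_m + n_f):
        sex = "M" if i < n_m else "F"
        sess = sessions[i] if sessions else {f"s{i}": "2020"}
        out.append(Individual(f"I{i}", sex, {}, samples=list(sess), sessions=sess))
    return out


class TestDemography:
    def test_sex_ratio_two_to_one(self):
        d = demography_summary(_individuals(6, 3))
        assert d["sex_ratio"] == 2.0 and d["sex_ratio_label"] == "2:1"

    def test_density(self):
        d = demography_summary(_individuals(6, 3), area_ha=3013.0)
        assert d["density_per_km2"] == pytest.approx(0.2987, abs=1e-4)
        assert round(d["density_per_km2"], 2) == 0.30

    def test_identical_rosters_full_recapture(self):
        sess = [{f"a{i}": "2019", f"b{i}": "2020"} for i in range(4)]
        d = demography_summary(_individuals(2, 2, sess), sessions=["2019", "2020"])
        assert d["recapture_rates"]["2019->2020"] == 1.0

    def test_zero_females_label(self):
        d = demography_summary(_individuals(4, 0))
        assert d["sex_ratio_label"] == "4:0" and math.isinf(d["sex_ratio"])

    def test_genotyping_success(self):
        d = demography_summary(_individuals(1, 1), n_collected=142, n_genotyped=68)
        assert round(d["genotyping_success_pct"]) == 48

    def test_capture_event_required(self):
        bad = [Individual("x", "M", {}, samples=[], sessions={})]
        with pytest.raises(ValueError):
            demography_summary(bad)


class TestAlleleFrequencies:
    def test_from_genotypes(self):
        genos = {"a": {"L": (1, 2)}, "b": {"L": (2, 2)}, "c": {"L": None}}
        fr = AlleleFrequencies.from_genotypes(genos)
        assert fr.freqs["L"] == {1: 0.25, 2: 0.75}
        assert fr.n_genes["L"] == 4 and fr.counts["L"] == {1: 1, 2: 3}

    def test_validation(self):
        with pytest.raises(ValueError):
            AlleleFrequencies(freqs={"L": {1: 0.7, 2: 0.7}}, n_genes={"L": 4})
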