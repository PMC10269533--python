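"""Genome summaries, taxon aggregation, correlations, stratified test."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ttrcensus.classify import TTRRecord, pass_class
from ttrcensus.genome_stats import (
    GenomeSummary,
    adjusted_correlation,
    domain_composition_tally,
    genome_summary,
    raft_stratified_sensory_test,
    taxon_aggregate,
)
from ttrcensus.io_annotation import DomainHit, GenomeMeta, parse_gtdb_taxonomy, registry_from_dict
from ttrcensus.tm_features import TMProfile

BACT_TAX = parse_gtdb_taxonomy("d__Bacteria;p__Testota;c__Testia;o__;f__;g__;s__")


def record(pid, gid="g1", is_ttr=False, is_hybrid=False, is_st=False,
           has_dna=False, n_tm=0, sa=None, raft=None, n_sensory=0, models=()):
    profile = TMProfile(n_tm, (), 21.0 if n_tm else None, sa, raft)
    return TTRRecord(
        protein_id=pid, genome_id=gid, is_ttr=is_ttr, is_hybrid=is_hybrid,
        is_st=is_st or is_ttr, has_dna_binding=has_dna or is_ttr,
        pass_class=pass_class(n_tm), n_sensory_domains=n_sensory,
        dna_binding_models=frozenset(models), tm_profile=profile,
    )


def toy_records(gid="g1"):
    return [
        record(f"{gid}_p1", gid, is_ttr=True, n_tm=1, sa=160.0, raft=True),
        record(f"{gid}_p2", gid, is_ttr=True, is_hybrid=True, n_tm=2, sa=180.0,
               raft=False, n_sensory=1),
        record(f"{gid}_p3", gid, is_st=True),
    ] + [record(f"{gid}_p{i}", gid) for i in range(4, 11)]


def summary_fixture(gid, n_ttr, n_st, cds, n_hybrid=0, tax=BACT_TAX, sk="bacteria"):
    return GenomeSummary(
        genome_id=gid, taxonomy=tax, superkingdom=sk, cds_total=cds,
        n_proteins=n_st, n_st=n_st, n_ttr=n_ttr, n_hybrid=n_hybrid,
        n_dna_binding_total=n_ttr, tm_count_histogram={}, mean_tm_per_ttr=None,
    )


class TestGenomeSummary:
    def test_hand_tallied_toy_genome(self):
        meta = GenomeMeta("g1", BACT_TAX, 10)
        s = genome_summary(toy_records(), meta)
        assert (s.n_st, s.n_ttr, s.n_hybrid) == (3, 2, 1)
        assert s.ratio_ttr_cds == pytest.approx(0.2)
        assert s.ratio_ttr_st == pytest.approx(2 / 3)
        assert s.ratio_st_cds == pytest.approx(0.3)
        assert s.n_dna_binding_total == 2
        assert s.tm_count_histogram == {1: 1, 2: 1}

    def test_no_st_proteins_leaves_ratio_absent(self):
        meta = GenomeMeta("g1", BACT_TAX, 5)
        s = genome_summary([record("p1")], meta)
        assert s.n_st == 0 and s.ratio_ttr_st is None

    def test_saturated_genome_has_unit_ratios(self):
        meta = GenomeMeta("g1", BACT_TAX, 2)
        recs = [record("p1", is_ttr=True, n_tm=1, sa=150.0, raft=True),
                record("p2", is_ttr=True, n_tm=1, sa=150.0, raft=True)]
        s = genome_summary(recs, meta)
        assert (s.ratio_ttr_cds, s.ratio_ttr_st, s.ratio_st_cds) == (1.0, 1.0, 1.0)

    def test_genome_id_mismatch_rejected(self):
        meta = GenomeMeta("g2", BACT_TAX, 10)
        with pytest.raises(ValueError, match="g2"):
            genome_summary(toy_records("g1"), meta)

    def test_count_conservation_partition(self):
        meta = GenomeMeta("g1", BACT_TAX, 10)
        s = genome_summary(toy_records(), meta)
        assert s.n_ttr + (s.n_st - s.n_ttr) + (s.cds_total - s.n_st) == s.cds_total


class TestTaxonAggregate:
    def test_two_genome_taxon_statistics(self):
        taxa = taxon_aggregate(
            [summary_fixture("g1", 4, 10, 100), summary_fixture("g2", 6, 10, 100)],
            min_genomes=2,
        )
        (t,) = taxa
        assert t.taxon_key == "Testota;Testia"
        assert t.mean_n_ttr == pytest.approx(5.0)
        assert t.sd_n_ttr == pytest.approx(math.sqrt(2))
        assert t.included

    def test_minimum_genome_rule_excludes_but_reports(self):
        taxa = taxon_aggregate(
            [summary_fixture(f"g{i}", 1, 5, 50) for i in range(9)], min_genomes=10
        )
        (t,) = taxa
        assert not t.included and t.n_genomes == 9

    def test_taxa_partition_their_genomes(self):
        other = parse_gtdb_taxonomy("d__Bacteria;p__Otherota;c__Otheria;o__;f__;g__;s__")
        taxa = taxon_aggregate(
            [summary_fixture("g1", 2, 5, 50),
             summary_fixture("g2", 8, 10, 50, tax=other),
             summary_fixture("g3", 4, 5, 50)],
            min_genomes=1,
        )
        assert {t.taxon_key: t.n_genomes for t in taxa} == {
            "Testota;Testia": 2, "Otherota;Otheria": 1}
        by_key = {t.taxon_key: t for t in taxa}
        assert by_key["Testota;Testia"].mean_n_ttr == pytest.approx(3.0)
        assert by_key["Otherota;Otheria"].mean_n_ttr == pytest.approx(8.0)

    def test_empty_phylum_routed_to_unclassified(self):
        tax = parse_gtdb_taxonomy("d__Bacteria;p__;c__;o__;f__;g__;s__")
        taxa = taxon_aggregate([summary_fixture("g1", 1, 2, 50, tax=tax)], min_genomes=1)
        assert taxa[0].taxon_key == "unclassified"

    def test_hybrid_fraction_pools_counts(self):
        taxa = taxon_aggregate(
            [summary_fixture("g1", 4, 10, 100, n_hybrid=1),
             summary_fixture("g2", 6, 10, 100, n_hybrid=0)],
            min_genomes=1,
        )
        assert taxa[0].hybrid_fraction == pytest.approx(0.1)


class TestAdjustedCorrelation:
    def test_monotone_fixture_has_perfect_rank_correlation(self):
        summaries = [summary_fixture(f"g{i}", i, 3 * i, 10 * i) for i in range(1, 11)]
        rep = adjusted_correlation(summaries)
        for pair in (rep.ttr_vs_st_minus_ttr, rep.ttr_vs_cds_minus_st):
            assert pair.spearman_rho == pytest.approx(1.0)
            assert pair.kendall_tau == pytest.approx(1.0)

    def test_identical_genomes_flag_undefined(self):
        summaries = [summary_fixture(f"g{i}", 2, 6, 60) for i in range(5)]
        rep = adjusted_correlation(summaries)
        assert rep.ttr_vs_st_minus_ttr.undefined
        assert rep.ttr_vs_cds_minus_st.undefined

    def test_fewer_than_three_genomes_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            adjusted_correlation([summary_fixture("g1", 1, 2, 10)] * 2)

    def test_independent_counts_fall_inside_permutation_null(self):
        # x and y independent by construction; the 95% null band is the
        # permutation distribution of |rho| and |tau| under reshuffling y
        rng = np.random.default_rng(42)
        n = 200
        x = rng.poisson(5, n)
        y = rng.permutation(rng.poisson(200, n))
        z = rng.poisson(2000, n)
        summaries = [
            summary_fixture(f"g{i}", int(x[i]), int(x[i] + y[i]),
                            int(x[i] + y[i] + z[i]))
            for i in range(n)
        ]
        rep = adjusted_correlation(summaries)
        null_rho, null_tau = [], []
        perm_rng = np.random.default_rng(4242)
        for _ in range(499):
            yp = perm_rng.permutation(y)
            null_rho.append(abs(sps.spearmanr(x, yp)[0]))
            null_tau.append(abs(sps.kendalltau(x, yp)[0]))
        pair = rep.ttr_vs_st_minus_ttr
        assert abs(pair.spearman_rho) < np.quantile(null_rho, 0.95)
        assert abs(pair.kendall_tau) < np.quantile(null_tau, 0.95)

    def test_rank_statistics_invariant_to_cds_scale(self):
        summaries = [
            summary_fixture(f"g{i}", i % 7, 3 * (i % 7) + i % 3, 40 + 11 * i)
            for i in range(20)
        ]
        scaled = [
            summary_fixture(s.genome_id, s.n_ttr, s.n_st, s.cds_total * 10)
            for s in summaries
        ]
        a = adjusted_correlation(summaries).ttr_vs_st_minus_ttr
        b = adjusted_correlation(scaled).ttr_vs_st_minus_ttr
        assert a.spearman_rho == pytest.approx(b.spearman_rho)
        assert a.kendall_tau == pytest.approx(b.kendall_tau)


class TestRaftStratifiedTest:
    @staticmethod
    def make_cohort(low_values, high_values):
        recs = []
        for i, v in enumerate(low_values):
            recs.append(record(f"l{i}", is_ttr=True, n_tm=1, sa=160.0, raft=True,
                               n_sensory=int(v)))
        for i, v in enumerate(high_values):
            recs.append(record(f"h{i}", is_ttr=True, n_tm=1, sa=190.0, raft=False,
                               n_sensory=int(v)))
        return recs

    def test_identical_strata_give_null_result(self):
        res = raft_stratified_sensory_test(self.make_cohort([1, 1, 1], [1, 1, 1]))
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_means_are_detected(self):
        rng = np.random.default_rng(7)
        low = np.clip(np.rint(rng.normal(0.5, 0.5, 200)), 0, None)
        high = np.clip(np.rint(rng.normal(2.0, 0.5, 200)), 0, None)
        res = raft_stratified_sensory_test(self.make_cohort(low, high))
        assert res.p_value < 1e-4
        assert res.mean_low < res.mean_high

    def test_singleton_stratum_rejected(self):
        with pytest.raises(ValueError, match="above-threshold"):
            raft_stratified_sensory_test(self.make_cohort([1, 2, 3], [1]))

    def test_pooled_t_matches_scipy_reference(self):
        low, high = [0, 1, 0, 2, 1], [2, 3, 1, 2, 4]
        res = raft_stratified_sensory_test(self.make_cohort(low, high))
        t, p = sps.ttest_ind(low, high, equal_var=True)
        assert res.t_statistic == pytest.approx(float(t))
        assert res.p_value == pytest.approx(float(p))


class TestDomainTally:
    REG = registry_from_dict(
        {"dna_binding": ["HTH_1", "GerE"], "st_membership": ["PAS"]}
    )

    @staticmethod
    def hit(pid, model):
        return DomainHit(pid, model, "", 1, 60, 50.0, 1e-10)

    def test_fraction_of_ttrs_carrying_model(self):
        recs = [record(f"p{i}", is_ttr=True, n_tm=1, sa=160.0, raft=True) for i in range(4)]
        hits = {f"p{i}": [self.hit(f"p{i}", "HTH_1")] for i in range(3)}
        hits["p3"] = [self.hit("p3", "GerE")]
        tally = domain_composition_tally(recs, hits, self.REG)
        assert tally["dna_binding"][0] == ("HTH_1", 3, 0.75, 0.75)
        assert tally["dna_binding"][1] == ("GerE", 1, 0.25, 1.0)

    def test_model_carried_twice_counts_once_per_ttr(self):
        recs = [record("p0", is_ttr=True, n_tm=1, sa=160.0, raft=True)]
        hits = {"p0": [self.hit("p0", "PAS"), self.hit("p0", "PAS")]}
        tally = domain_composition_tally(recs, hits, self.REG)
        assert tally["sensory"] == [("PAS", 1, 1.0, 1.0)]

    def test_empty_ttr_set_gives_empty_tables(self):
        tally = domain_composition_tally([record("p0")], {}, self.REG)
        assert tally == {"dna_binding": [], "sensory": []}
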