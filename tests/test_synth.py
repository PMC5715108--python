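"""Synthetic-data generators: determinism, ground truth, count model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from butycore.catalogue import hamming_identity
from butycore.synth import (
    CommunitySpec,
    SimulationConfig,
    SynthError,
    TaxonSpec,
    default_genes,
    make_case_control,
    make_community,
    make_correlated_taxa,
    make_gene_sequences,
    make_longitudinal,
    make_reference_genomes,
    reference_catalogue,
    simulate_counts,
    simulate_reads,
)


class TestCommunitySpec:
    def test_abundances_must_sum_to_one(self):
        t = TaxonSpec("t0", "others", 0.5, ("Ac",), default_genes(["Ac"]))
        with pytest.raises(SynthError):
            CommunitySpec([t], background_fraction=0.4)

    def test_short_gene_length_rejected(self):
        t = TaxonSpec("t0", "others", 0.3, ("Ac",), default_genes(["Ac"]),
                      gene_lengths={g: 100 for g in default_genes(["Ac"]) | {"rplB", "recA", "pyrG"}})
        with pytest.raises(SynthError):
            CommunitySpec([t], background_fraction=0.7)

    def test_true_pathway_abundance(self):
        com = make_community(10, seed=0, background_fraction=0.6)
        assert com.true_pathway_abundance("Ac") == pytest.approx(40.0)
        total = sum(t.abundance for t in com.taxa) + com.background_fraction
        assert total == pytest.approx(1.0, abs=1e-9)


class TestReferenceGenomes:
    def test_all_prevalences_one_carries_everything(self):
        hits, truth = make_reference_genomes(1, seed=0)
        genes = set(hits.gene_symbol)
        assert default_genes(["Ac", "Gl", "4A", "Ly"], "both") <= genes
        assert truth.present.all()

    def test_zero_prevalence_removes_pathway_genes(self):
        hits, truth = make_reference_genomes(1, {"Ac": 0.0}, seed=0)
        assert not (set(hits.gene_symbol) & {"thl", "bhbd", "cro", "but", "buk"})
        assert not truth[truth.pathway == "Ac"].present.any()

    def test_prevalence_approximately_respected(self):
        _, truth = make_reference_genomes(100, {"Ac": 0.8}, seed=7)
        frac = truth[truth.pathway == "Ac"].present.mean()
        assert 0.68 <= frac <= 0.92  # binomial(100, .8), +-3 SD

    def test_invalid_prevalence(self):
        with pytest.raises(SynthError):
            make_reference_genomes(5, {"Ac": 1.5})

    def test_seed_reproducibility(self):
        h1, t1 = make_reference_genomes(10, {"Gl": 0.5}, seed=3, noise_rate=0.2)
        h2, t2 = make_reference_genomes(10, {"Gl": 0.5}, seed=3, noise_rate=0.2)
        pd.testing.assert_frame_equal(h1, h2)
        pd.testing.assert_frame_equal(t1, t2)


class TestGeneSequences:
    def test_zero_within_divergence_members_identical(self):
        table, _ = make_reference_genomes(3, seed=1)
        seqs, meta = make_gene_sequences(table, 0.0, 0.10, seed=2)
        for (gene, taxon), sub in meta.groupby(["gene_symbol", "taxon_bin"]):
            unique = {seqs[s] for s in sub.seq_id}
            assert len(unique) == 1

    def test_pairwise_identity_bound(self):
        table = pd.concat([make_reference_genomes(1, seed=i)[0].assign(
            genome_id=f"g{i}", taxon_bin="t0") for i in range(5)])
        seqs, meta = make_gene_sequences(table, 0.03, 0.10, seed=3)
        thl_ids = meta[meta.gene_symbol == "thl"].seq_id.tolist()
        for i, a in enumerate(thl_ids):
            for b in thl_ids[i + 1:]:
                assert hamming_identity(seqs[a], seqs[b]) >= 0.94

    def test_between_taxon_divergence_bound(self):
        table, _ = make_reference_genomes(4, seed=4)
        seqs, meta = make_gene_sequences(table, 0.03, 0.12, seed=5)
        thl = meta[meta.gene_symbol == "thl"]
        by_taxon = {t: seqs[s.seq_id.iloc[0]] for t, s in thl.groupby("taxon_bin")}
        taxa = sorted(by_taxon)
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                assert hamming_identity(by_taxon[a], by_taxon[b]) <= 1 - (0.12 - 0.03)

    def test_truncated_variant_emitted(self):
        table, _ = make_reference_genomes(2, seed=6)
        seqs, meta = make_gene_sequences(table, 0.01, 0.1, seed=7,
                                         truncated=[("thl", "t000", 0.5)])
        trunc = meta[meta.truncated]
        assert len(trunc) == 1
        full_len = len(seqs[meta[~meta.truncated & (meta.gene_symbol == "thl")].seq_id.iloc[0]])
        assert len(seqs[trunc.seq_id.iloc[0]]) < 0.7 * full_len

    def test_divergence_order_enforced(self):
        table, _ = make_reference_genomes(2, seed=0)
        with pytest.raises(SynthError):
            make_gene_sequences(table, 0.1, 0.05)


class TestSimulateCounts:
    def test_expected_count_ratio_follows_length(self):
        genes = default_genes(["Ac"], "but")
        lengths = {g: 300 for g in genes | {"rplB", "recA", "pyrG"}}
        lengths["thl"], lengths["bhbd"] = 400, 800
        t = TaxonSpec("t0", "others", 1.0, ("Ac",), genes, gene_lengths=lengths)
        com = CommunitySpec([t])
        cat = reference_catalogue(com, seed=1)
        counts = simulate_counts(com, cat, SimulationConfig(depth=200_000, seed=2))[0]
        ratio = counts.counts["bhbd|t0"] / counts.counts["thl|t0"]
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_seed_determinism(self, community, catalogue):
        cfg = SimulationConfig(depth=10_000, seed=5, n_samples=2)
        c1 = simulate_counts(community, catalogue, cfg)
        c2 = simulate_counts(community, catalogue, cfg)
        assert [c.counts for c in c1] == [c.counts for c in c2]

    def test_unresolvable_gene_raises(self, community):
        small = reference_catalogue(community, seed=1)
        del small.entries[next(iter(small.entries))]
        with pytest.raises(SynthError):
            simulate_counts(community, small, SimulationConfig(depth=100, seed=0))

    def test_total_depth_conserved(self, community, catalogue):
        counts = simulate_counts(community, catalogue,
                                 SimulationConfig(depth=33_333, seed=9))[0]
        assert counts.total() == 33_333


class TestSimulateReads:
    def test_zero_depth_empty(self, community, catalogue):
        reads, prov = simulate_reads(catalogue, community, 80, depth=0, seed=0)
        assert reads == {} and prov.empty

    def test_reads_are_substrings(self, community, catalogue):
        reads, prov = simulate_reads(catalogue, community, 60, depth=50, seed=1)
        for rid, sid, start in prov.itertuples(index=False):
            assert catalogue[sid].sequence[start:start + 60] == reads[rid]

    def test_read_length_validation(self, community, catalogue):
        with pytest.raises(SynthError):
            simulate_reads(catalogue, community, read_length=10**6, depth=1)


class TestLongitudinal:
    def test_full_concordance_all_decrease(self, community):
        series, truth = make_longitudinal(community, 3, concordance=1.0,
                                          magnitude=0.2, seed=1)
        assert truth.decreased.all()
        assert len(series) == 3

    def test_zero_magnitude_identical(self, community):
        series, truth = make_longitudinal(community, 2, concordance=0.5,
                                          magnitude=0.0, seed=2)
        a0 = [t.abundance for t in series[0].taxa]
        a1 = [t.abundance for t in series[1].taxa]
        assert a0 == pytest.approx(a1)

    def test_half_concordance_half_decrease(self):
        com = make_community(200, seed=3)
        _, truth = make_longitudinal(com, 2, concordance=0.5, magnitude=0.3, seed=4)
        assert truth.decreased.mean() == pytest.approx(0.5, abs=0.12)

    def test_abundances_stay_normalized(self, community):
        series, _ = make_longitudinal(community, 4, 0.7, 0.5, seed=5)
        for com in series:
            total = sum(t.abundance for t in com.taxa) + com.background_fraction
            assert total == pytest.approx(1.0, abs=1e-9)


class TestCaseControl:
    def test_truth_records_intended_effect(self, community):
        ctrl, case, truth = make_case_control(community, -0.3, 5, seed=1)
        assert truth["intended_relative_difference_pct"] == pytest.approx(-30.0)
        assert len(ctrl) == len(case) == 5

    def test_zero_effect_groups_exchangeable(self, community):
        ctrl, case, _ = make_case_control(community, 0.0, 200, seed=2)
        mc = np.mean([c.true_pathway_abundance("Ac") for c in ctrl])
        mk = np.mean([c.true_pathway_abundance("Ac") for c in case])
        assert mk == pytest.approx(mc, rel=0.05)

    def test_parameter_validation(self, community):
        with pytest.raises(SynthError):
            make_case_control(community, -1.5, 5)
        with pytest.raises(SynthError):
            make_case_control(community, -0.3, 1)

    def test_seed_reproducibility(self, community):
        a = make_case_control(community, -0.2, 3, seed=9)
        b = make_case_control(community, -0.2, 3, seed=9)
        for ca, cb in zip(a[0] + a[1], b[0] + b[1]):
            assert [t.abundance for t in ca.taxa] == [t.abundance for t in cb.taxa]


class TestCorrelatedTaxa:
    def test_planted_rho_recovered(self):
        tables = make_correlated_taxa(1, 100, [(0, 1)], rho=0.7, seed=1)[0]
        rho = spearmanr(tables["t000"], tables["t001"]).statistic
        assert abs(rho - 0.7) <= 0.15

    def test_independent_taxa_near_zero(self):
        t = make_correlated_taxa(1, 200, [], seed=2)[0]
        rho = spearmanr(t["t000"], t["t001"]).statistic
        assert abs(rho) < 0.2

    def test_pair_planted_in_every_dataset(self):
        tables = make_correlated_taxa(4, 150, [(2, 3)], rho=0.8, seed=3)
        for t in tables:
            assert spearmanr(t["t002"], t["t003"]).statistic > 0.5

    def test_rho_bound(self):
        with pytest.raises(SynthError):
            make_correlated_taxa(2, 10, [(0, 1)], rho=1.0)
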