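"""Quantification chain: length correction, housekeeping normalization,
pathway/taxon abundances, enzyme/family groups, conservation."""

import numpy as np
import pandas as pd
import pytest

from butycore.catalogue import CatalogueEntry, GeneCatalogue
from butycore.pipeline import _community_profiles
from butycore.quantify import (
    QuantifyError,
    SampleCounts,
    enzyme_groups,
    family_groups,
    filter_decoys,
    housekeeping_denominator,
    length_correct,
    map_reads_naive,
    pathway_abundance,
    pool_counts,
    profile_sample,
    taxon_abundance,
    taxon_linkage,
    taxon_presence,
)
from butycore.screen import TaxonProfileSet
from butycore.synth import (
    SimulationConfig,
    make_community,
    reference_catalogue,
    simulate_counts,
    simulate_reads,
)


def _corrected(rows):
    df = pd.DataFrame(rows, columns=["taxon_bin", "gene_symbol", "raw"])
    df["corrected"] = df.pop("raw_corr") if "raw_corr" in df else np.nan
    return df


def _frame(records):
    return pd.DataFrame(records, columns=["taxon_bin", "gene_symbol", "raw", "corrected"])


class TestLengthCorrection:
    def test_division_by_median_length(self):
        cat = GeneCatalogue([CatalogueEntry("e1", "A" * 1000, "thl", "t0")])
        pooled = pd.DataFrame({"taxon_bin": ["t0"], "gene_symbol": ["thl"], "raw": [100]})
        out = length_correct(pooled, cat)
        assert out["corrected"].item() == pytest.approx(0.1)

    def test_same_bin_entries_summed_before_correction(self):
        cat = GeneCatalogue([
            CatalogueEntry("e1", "A" * 900, "thl", "t0"),
            CatalogueEntry("e2", "A" * 1100, "thl", "t0"),
        ])
        counts = SampleCounts("s", {"e1": 30, "e2": 70})
        pooled = pool_counts(counts, cat)
        assert pooled["raw"].item() == 100
        out = length_correct(pooled, cat)
        assert out["corrected"].item() == pytest.approx(100 / 1000)


class TestHousekeepingDenominator:
    def test_mean_of_three(self):
        df = _frame([("t", g, 1, 2.0) for g in ("rplB", "recA", "pyrG")])
        assert housekeeping_denominator(df) == pytest.approx(2.0)

    def test_missing_gene_contributes_zero_with_warning(self):
        df = _frame([("t", "rplB", 1, 3.0), ("t", "pyrG", 1, 3.0)])
        with pytest.warns(UserWarning, match="recA"):
            assert housekeeping_denominator(df) == pytest.approx(2.0)

    def test_all_zero_unquantifiable(self):
        with pytest.raises(QuantifyError):
            housekeeping_denominator(_frame([]))


class TestPathwayAbundance:
    def test_ac_mean_rule(self):
        df = _frame([("t", g, 1, 0.2) for g in ("thl", "bhbd", "cro")])
        assert pathway_abundance(df, "Ac", 1.0) == pytest.approx(20.0)

    def test_gcdb_counts_change_nothing(self):
        rows = [("t", g, 1, 0.3) for g in
                ("gctA", "gctB", "hgCoAdA", "hgCoAdB", "hgCoAdC", "gcdA")]
        without = pathway_abundance(_frame(rows), "Gl", 1.0)
        with_gcdb = pathway_abundance(
            _frame(rows + [("t", "gcdB", 1, 9.9)]), "Gl", 1.0
        )
        assert without == pytest.approx(with_gcdb) == pytest.approx(30.0)

    def test_4a_median_rule(self):
        df = _frame([("t", "abfH", 1, 0.1), ("t", "abfD", 1, 0.5)])
        assert pathway_abundance(df, "4A", 1.0) == pytest.approx(30.0)

    def test_terminal_genes_never_quantified(self):
        df = _frame([("t", "but", 1, 5.0), ("t", "buk", 1, 5.0)])
        assert pathway_abundance(df, "Ac", 1.0) == 0.0

    def test_scale_invariance(self):
        rows = [("t", g, 10, 0.2) for g in ("thl", "bhbd", "cro")]
        a1 = pathway_abundance(_frame(rows), "Ac", 0.5)
        rows10 = [(t, g, r * 10, c * 10) for t, g, r, c in rows]
        a2 = pathway_abundance(_frame(rows10), "Ac", 5.0)
        assert a1 == pytest.approx(a2)


class TestTaxonPresence:
    REQUIRED = ("kamA", "kamD", "kamE", "kdd", "kce", "kal")

    def test_all_required_detected(self):
        raw = {g: 2 for g in self.REQUIRED}
        assert taxon_presence(raw, self.REQUIRED)

    def test_kal_not_required(self):
        raw = {g: 2 for g in self.REQUIRED if g != "kal"}
        assert taxon_presence(raw, self.REQUIRED)

    def test_missing_non_exempt_gene_absent(self):
        raw = {g: 2 for g in self.REQUIRED if g not in ("kdd",)}
        assert not taxon_presence(raw, self.REQUIRED)

    def test_lowdepth_mode_tolerates_one_missing(self):
        raw = {g: 2 for g in self.REQUIRED if g not in ("kdd",)}
        assert taxon_presence(raw, self.REQUIRED,
                              data_mode="metatranscriptome_lowdepth")
        raw2 = {g: 2 for g in self.REQUIRED if g not in ("kdd", "kce")}
        assert not taxon_presence(raw2, self.REQUIRED,
                                  data_mode="metatranscriptome_lowdepth")


class TestTaxonAbundance:
    def test_median_over_genes(self):
        vals = {"thl": 0.1, "bhbd": 0.2, "cro": 0.3}
        assert taxon_abundance(vals, ("thl", "bhbd", "cro"), 1.0) == pytest.approx(20.0)

    def test_single_gene(self):
        assert taxon_abundance({"thl": 0.4}, ("thl",), 2.0) == pytest.approx(20.0)


class TestEnzymeAndFamilyGroups:
    def test_proportional_split_of_both_taxa(self):
        groups = enzyme_groups(
            {"tb": 10.0}, {"tb": "both"}, {"tb": {"but": 3.0, "buk": 1.0}}
        )
        assert groups["but"] == pytest.approx(7.5)
        assert groups["buk"] == pytest.approx(2.5)

    def test_zero_terminal_counts_split_half_half(self):
        with pytest.warns(UserWarning, match="50/50"):
            groups = enzyme_groups({"tb": 4.0}, {"tb": "both"},
                                   {"tb": {"but": 0.0, "buk": 0.0}})
        assert groups["but"] == groups["buk"] == pytest.approx(2.0)

    def test_group_sums_conserve_taxon_total(self):
        ab = {"a": 5.0, "b": 2.0, "c": 1.0}
        cls = {"a": "but", "b": "both", "c": "alternative"}
        groups = enzyme_groups(ab, cls, {"b": {"but": 1.0, "buk": 2.0}})
        assert sum(groups.values()) == pytest.approx(sum(ab.values()))
        fams = family_groups(ab, {"a": "Lachnospiraceae", "b": "NovelFam"})
        assert sum(fams.values()) == pytest.approx(sum(ab.values()))
        assert fams["others"] == pytest.approx(2.0 + 1.0)


class TestDecoyAndLinkage:
    def test_decoy_counts_removed_and_audited(self):
        cat = GeneCatalogue([
            CatalogueEntry("e1", "A" * 200, "thl", "t0"),
            CatalogueEntry("d1", "C" * 200, "thl", "x", is_decoy=True),
        ])
        counts = SampleCounts("s", {"e1": 10, "d1": 7})
        out, removed = filter_decoys(counts, cat)
        assert removed == 7 and out.counts == {"e1": 10}

    def test_linkage_percentage(self):
        df = _frame([
            ("t0", "thl", 30, 0.3), ("t1", "thl", 10, 0.1),
            ("t0", "bhbd", 30, 0.3), ("t1", "bhbd", 10, 0.1),
            ("t0", "cro", 40, 0.4), ("t1", "cro", 10, 0.1),
        ])
        assert taxon_linkage(df, "Ac", ["t0"]) == pytest.approx(100 * 100 / 130)

    def test_linkage_excludes_abfd_for_4a(self):
        df = _frame([("t0", "abfH", 10, 0.1), ("t0", "abfD", 90, 0.9)])
        assert taxon_linkage(df, "4A", ["t0"]) == pytest.approx(100.0)
        assert taxon_linkage(df, "4A", []) == pytest.approx(0.0)


class TestNaiveMapper:
    def test_assignments_match_provenance(self, community, catalogue):
        reads, prov = simulate_reads(catalogue, community, read_length=80,
                                     depth=300, seed=4)
        counts, unassigned = map_reads_naive(reads, catalogue, k=31)
        assert unassigned == 0
        expected = prov.groupby("seq_id").size()
        # identical housekeeping genes across taxa can tie; compare per gene
        got = {}
        for sid, n in counts.counts.items():
            gene = catalogue[sid].gene_symbol
            got[gene] = got.get(gene, 0) + n
        want = {}
        for sid, n in expected.items():
            gene = catalogue[sid].gene_symbol
            want[gene] = want.get(gene, 0) + n
        assert got == want

    def test_unmatched_read_unassigned(self, catalogue):
        counts, unassigned = map_reads_naive({"r": "N" * 50}, catalogue)
        assert unassigned == 1 and counts.counts == {}


class TestFullProfile:
    def test_conservation_identities(self, community, catalogue, taxon_profiles,
                                     sample_counts):
        for counts in sample_counts:
            prof = profile_sample(counts, catalogue, taxon_profiles,
                                  taxonomy=community.taxonomy())
            ac_total = sum(prof.taxon_abundances("Ac").values())
            assert sum(prof.enzyme_groups.values()) == pytest.approx(ac_total, abs=1e-9)
            assert sum(prof.family_groups.values()) == pytest.approx(ac_total, abs=1e-9)
            assert prof.richness["Ac"] == len(prof.taxon_abundances("Ac"))

    def test_scale_invariance_of_full_profile(self, community, catalogue,
                                              taxon_profiles):
        counts = simulate_counts(community, catalogue,
                                 SimulationConfig(depth=50_000, seed=8))[0]
        scaled = SampleCounts("s2", {k: v * 7 for k, v in counts.counts.items()})
        p1 = profile_sample(counts, catalogue, taxon_profiles)
        p2 = profile_sample(scaled, catalogue, taxon_profiles)
        for pid in p1.pathway_abundance:
            assert p1.pathway_abundance[pid] == pytest.approx(
                p2.pathway_abundance[pid]
            )

    def test_deep_sample_recovers_truth(self, community, catalogue, taxon_profiles):
        from butycore.synth import expected_pathway_se

        counts = simulate_counts(community, catalogue,
                                 SimulationConfig(depth=1_000_000, seed=21))[0]
        prof = profile_sample(counts, catalogue, taxon_profiles,
                              taxonomy=community.taxonomy())
        truth = community.true_pathway_abundance("Ac")
        se = expected_pathway_se(community, catalogue, "Ac", 1_000_000)
        assert abs(prof.pathway_abundance["Ac"] - truth) <= 3 * se
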