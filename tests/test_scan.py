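import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccs import alphabet
from ccs.engine import AncestralStates, marginal_ancestral_states
from ccs.io import AminoAlignment, TraitMap, ValidationError
from ccs.scan import (
    CLASS_CCS,
    CLASS_RELAXED,
    NOISE_FALSE,
    NOISE_RANDOM,
    ScanConfig,
    background_ancestor_node,
    classify_noise,
    classify_site,
    noise_report,
    scan_orthogroups,
)
from ccs.simulate import (
    PlantSpec,
    SimulationConfig,
    generate_orthogroup_set,
    plant_convergence,
    simulate_null,
)
from ccs.tree import Phylogeny


def oracle_classify(column, traits, m, gap_policy="exclude_site"):
    """Independent brute-force implementation of the site rules."""
    fg = sorted(traits.foreground)
    bg = sorted(traits.background)
    missing = {t for t, r in column.items() if r not in alphabet.AMINO_ACIDS}
    if gap_policy == "exclude_site" and missing:
        return []
    bg_residues = {column[t] for t in bg if t not in missing}
    bg_clean = [t for t in bg if t not in missing]
    bg_unanimous = (len(bg_clean) == len(bg)) and len(bg_residues) == 1
    calls = []
    for a in sorted(set(column[t] for t in fg if t not in missing)):
        carriers = [t for t in fg if t not in missing and column[t] == a]
        if len(carriers) >= m and a not in bg_residues:
            strict = bg_unanimous and len(carriers) == len(fg)
            calls.append((a, bg_unanimous, strict))
    return calls


class TestClassifySite:
    def test_majority_foreground_with_unanimous_background(self, fish_traits):
        fg = sorted(fish_traits.foreground)
        bg = sorted(fish_traits.background)
        column = {t: "S" for t in fg[:3]} | {t: "T" for t in fg[3:]}
        column |= {t: "T" for t in bg}
        calls = classify_site(column, fish_traits)
        assert len(calls) == 1
        call = calls[0]
        assert call.klass == CLASS_CCS
        assert call.residue_a == "S" and call.residue_b == "T"
        assert not call.strict_parallel

    def test_invariant_site_is_no_call(self, fish_traits):
        column = {t: "A" for t in fish_traits.all_taxa}
        assert classify_site(column, fish_traits) == []

    def test_all_foreground_vs_all_background_is_strict_parallel(
        self, fish_traits
    ):
        column = {t: "S" for t in fish_traits.foreground}
        column |= {t: "T" for t in fish_traits.background}
        (call,) = classify_site(column, fish_traits)
        assert call.strict_parallel
        assert call.klass == CLASS_CCS

    def test_relaxed_without_conservative_background(self, fish_traits):
        bg = sorted(fish_traits.background)
        column = {t: "S" for t in fish_traits.foreground}
        column |= {t: "T" for t in bg}
        column[bg[0]] = "A"  # background no longer unanimous
        (call,) = classify_site(column, fish_traits)
        assert call.klass == CLASS_RELAXED
        assert call.residue_b is None
        assert not call.strict_parallel

    def test_two_qualifying_residues_reported_separately(
        self, five_taxon_traits
    ):
        traits = TraitMap.create(
            ["F1", "F2", "F3", "F4"], ["B1", "B2"], "B2"
        )
        column = {"F1": "S", "F2": "S", "F3": "W", "F4": "W",
                  "B1": "T", "B2": "T"}
        calls = classify_site(column, traits,
                              ScanConfig(min_foreground_share=2))
        assert sorted(c.residue_a for c in calls) == ["S", "W"]

    def test_gap_policy_excludes_site(self, fish_traits):
        column = {t: "S" for t in fish_traits.foreground}
        column |= {t: "T" for t in fish_traits.background}
        column[sorted(fish_traits.background)[0]] = "-"
        assert classify_site(column, fish_traits) == []
        calls = classify_site(
            column, fish_traits, ScanConfig(gap_policy="treat_as_mismatch")
        )
        # gap breaks background unanimity but not the relaxed rule
        assert len(calls) == 1 and calls[0].klass == CLASS_RELAXED

    def test_matches_oracle_on_random_columns(self, fish_traits):
        rng = np.random.default_rng(19)
        taxa = sorted(fish_traits.all_taxa)
        residues = list("ST-WA")
        config = ScanConfig()
        for _ in range(2000):
            column = {t: residues[rng.integers(len(residues))] for t in taxa}
            expected = oracle_classify(column, fish_traits, 3)
            got = classify_site(column, fish_traits, config)
            assert sorted(c.residue_a for c in got) == [a for a, _, _ in expected]
            for call, (_, unanimous, strict) in zip(
                sorted(got, key=lambda c: c.residue_a), expected
            ):
                assert (call.klass == CLASS_CCS) == unanimous
                assert call.strict_parallel == strict

    def test_matches_oracle_exhaustively_small_alphabet(
        self, five_taxon_traits
    ):
        """All 3^5 columns over a reduced alphabet, m = 2."""
        taxa = ["F1", "F2", "F3", "B1", "B2"]
        config = ScanConfig(min_foreground_share=2)
        for combo in itertools.product("ARN", repeat=5):
            column = dict(zip(taxa, combo))
            expected = oracle_classify(column, five_taxon_traits, 2)
            got = classify_site(column, five_taxon_traits, config)
            assert sorted(c.residue_a for c in got) == [a for a, _, _ in expected]
            for call, (_, unanimous, strict) in zip(
                sorted(got, key=lambda c: c.residue_a), expected
            ):
                assert (call.klass == CLASS_CCS) == unanimous
                assert call.strict_parallel == strict

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.lists(st.sampled_from("STWA-X"), min_size=14, max_size=14))
    def test_property_ccs_subset_of_relaxed(self, residues):
        traits = TraitMap.create(
            [f"F{i}" for i in range(6)], [f"B{i}" for i in range(8)], "B7"
        )
        taxa = sorted(traits.all_taxa)
        column = dict(zip(taxa, residues))
        calls = classify_site(column, traits)
        for c in calls:
            if c.klass == CLASS_CCS:
                assert c.residue_b is not None
            if c.strict_parallel:
                assert c.klass == CLASS_CCS
                assert len(c.carriers) == 6

    def test_strict_sites_invariant_under_within_class_permutation(
        self, fish_traits
    ):
        rng = np.random.default_rng(23)
        fg = sorted(fish_traits.foreground)
        bg = sorted(fish_traits.background)
        column = {t: "S" for t in fg} | {t: "T" for t in bg}
        base = classify_site(column, fish_traits)
        for _ in range(5):
            pf = rng.permutation(fg)
            pb = rng.permutation(bg)
            permuted = {pf[i]: column[fg[i]] for i in range(len(fg))}
            permuted |= {pb[i]: column[bg[i]] for i in range(len(bg))}
            calls = classify_site(permuted, fish_traits)
            assert [c.strict_parallel for c in calls] == [
                c.strict_parallel for c in base
            ]


class TestClassifyNoise:
    def _fake_asr(self, node, n_sites, residue):
        code = alphabet.AMINO_ACIDS.index(residue)
        post = np.zeros((n_sites, 20))
        post[:, code] = 1.0
        return AncestralStates(
            node_names=[node], n_sites=n_sites,
            posterior={node: post},
            map_codes={node: np.full(n_sites, code, dtype=np.int8)},
        )

    def test_ancestor_matching_outgroup_is_random(
        self, fish_tree, fish_traits
    ):
        column = {t: "S" for t in fish_traits.foreground}
        column |= {t: "T" for t in fish_traits.background}
        (call,) = classify_site(column, fish_traits)
        node = background_ancestor_node(fish_tree, fish_traits)
        asr = self._fake_asr(node, 1, "T")
        assert classify_noise(call, asr, fish_traits, fish_tree).noise_class \
            == NOISE_RANDOM

    def test_ancestor_differing_from_outgroup_is_false(
        self, fish_tree, fish_traits
    ):
        column = {t: "S" for t in fish_traits.foreground}
        column |= {t: "T" for t in fish_traits.background}
        (call,) = classify_site(column, fish_traits)
        node = background_ancestor_node(fish_tree, fish_traits)
        asr = self._fake_asr(node, 1, "W")
        assert classify_noise(call, asr, fish_traits, fish_tree).noise_class \
            == NOISE_FALSE

    def test_non_detection_rejected(self, fish_tree, fish_traits):
        column = {t: "A" for t in fish_traits.all_taxa}
        aln = AminoAlignment.from_sequences(column)
        from ccs.scan import SiteCall, CLASS_NONE

        call = SiteCall(site=0, klass=CLASS_NONE, residue_a="A",
                        residue_b=None, carriers=(), strict_parallel=False,
                        outgroup_residue="A",
                        n_foreground_matching_background=0)
        node = background_ancestor_node(fish_tree, fish_traits)
        with pytest.raises(ValidationError):
            classify_noise(call, self._fake_asr(node, 1, "A"),
                           fish_traits, fish_tree)


class TestScanOrthogroups:
    def test_planted_genes_recovered_exactly(
        self, fish_tree, fish_traits, jtt
    ):
        alignments, truth, _ = generate_orthogroup_set(
            20, 60, 0.25, seed=31, tree=fish_tree, traits=fish_traits,
            model=jtt,
        )
        cegs, sites, errors = scan_orthogroups(
            alignments, fish_tree, fish_traits
        )
        assert not errors
        assert {c.orthogroup_id for c in cegs} >= set(truth["gene"])
        planted = truth.set_index(["gene", "site"])
        for c in cegs:
            if c.orthogroup_id in set(truth["gene"]):
                for s, (a, b) in zip(c.sites, c.residues):
                    if (c.orthogroup_id, s) in planted.index:
                        row = planted.loc[(c.orthogroup_id, s)]
                        assert (row["a"], row["b"]) == (a, b)

    def test_relaxed_only_gene_is_not_a_ceg(self, fish_tree, fish_traits):
        fg = sorted(fish_traits.foreground)
        bg = sorted(fish_traits.background)
        seqs = {t: ("S" if t in fg[:3] else "T") + "A" for t in fg}
        seqs |= {t: "TA" for t in bg}
        aln = AminoAlignment.from_sequences(seqs, orthogroup_id="g1")
        cegs, sites, _ = scan_orthogroups([aln], fish_tree, fish_traits)
        assert cegs == []
        assert len(sites) == 1 and not sites.iloc[0]["strict_parallel"]

    def test_empty_gene_list(self, fish_tree, fish_traits):
        cegs, sites, errors = scan_orthogroups([], fish_tree, fish_traits)
        assert cegs == [] and sites.empty and errors == {}

    def test_leaf_mismatch_recorded_and_scan_continues(
        self, fish_tree, fish_traits, jtt
    ):
        good = simulate_null(
            SimulationConfig(n_sites=30, seed=1, model=jtt, tree=fish_tree)
        )
        good.orthogroup_id = "good"
        bad = AminoAlignment.from_sequences(
            {"A": "AR", "B": "AR"}, orthogroup_id="bad"
        )
        cegs, _, errors = scan_orthogroups(
            {"good": good, "bad": bad}, fish_tree, fish_traits
        )
        assert "bad" in errors and "good" not in errors


class TestNoiseReport:
    def test_zero_length_tree_has_no_detections(self, fish_traits, jtt):
        newick = Phylogeny.from_newick(
            "(Lepisosteus_oculatus:0.0,(Danio_rerio:0.0,"
            "((Oryzias_latipes:0.0,Xiphophorus_maculatus:0.0):0.0,"
            "((Takifugu_rubripes:0.0,Gasterosteus_aculeatus:0.0):0.0,"
            "(Cheilinus_undulatus:0.0,((Labroides_dimidiatus:0.0,"
            "(Thalassoma_bifasciatum:0.0,Notolabrus_celidotus:0.0):0.0):0.0,"
            "((Symphodus_melops:0.0,Labrus_bergylta:0.0):0.0,"
            "(Semicossyphus_pulcher:0.0,Tautogolabrus_adspersus:0.0):0.0)"
            ":0.0):0.0):0.0):0.0):0.0):0.0);"
        )
        aln = simulate_null(
            SimulationConfig(n_sites=2000, seed=3, model=jtt, tree=newick)
        )
        report, calls = noise_report(aln, newick, fish_traits, jtt)
        assert report.n_relaxed == 0 and report.n_ccs == 0
        assert calls == []

    def test_ccs_counts_bounded_by_relaxed_counts(
        self, fish_tree, fish_traits, jtt
    ):
        aln = simulate_null(
            SimulationConfig(n_sites=20000, seed=5, model=jtt, tree=fish_tree)
        )
        report, _ = noise_report(aln, fish_tree, fish_traits, jtt)
        assert report.n_relaxed > 0
        for k in (NOISE_RANDOM, NOISE_FALSE):
            assert report.ccs[k] <= report.relaxed[k]
        for v in report.reduction_percent.values():
            assert v is None or 0.0 <= v <= 100.0

    def test_reduction_na_when_no_detections(self, fish_traits, jtt):
        # a conservative-only alignment: all taxa identical everywhere
        aln = AminoAlignment.from_sequences(
            {t: "A" * 50 for t in fish_traits.all_taxa}
        )
        from ccs.datasets import cleaner_fish_tree

        tree = cleaner_fish_tree()
        report, _ = noise_report(aln, tree, fish_traits, jtt)
        assert report.to_dict()["reduction_percent"] == {
            NOISE_RANDOM: "n/a", NOISE_FALSE: "n/a"
        }
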