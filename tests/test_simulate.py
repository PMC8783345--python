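"""Synthetic generators: determinism, planted-margin construction, topology."""

import numpy as np
import pytest

from vesiclink.simulate import (DEFAULT_MOTIF_CLASSES, UnrealizableRegexError,
                                gen_expression, gen_go, gen_pathway,
                                gen_proteomes, generate_fixture, witness)

from conftest import tree_hash


class TestWitness:
    @pytest.mark.parametrize("regex", ["[ST].[ACVILF]$", "P..P[AL]",
                                       "K[RK].LL", "PP.Y", "A{3}", "[^P]KK"])
    def test_witness_matches_its_regex(self, regex):
        import re
        w, anchored = witness(regex)
        m = re.compile(regex).match(w)
        assert m and m.end() == len(w)
        assert anchored == regex.endswith("$")

    @pytest.mark.parametrize("regex", ["(AB)+", "A|B", "A*", "A+?", "[]X"])
    def test_unsupported_constructs_raise_naming_class(self, regex):
        with pytest.raises(UnrealizableRegexError, match="CLSNAME"):
            witness(regex, class_name="CLSNAME")


class TestProteomes:
    def test_seeded_regeneration_identical(self):
        a = gen_proteomes(seed=21)
        b = gen_proteomes(seed=21)
        assert a.bact == b.bact and a.hosts == b.hosts
        assert a.profiles == b.profiles
        assert a.truth_matches == b.truth_matches

    def test_planted_spans_exceed_cutoffs_by_margin(self):
        sim = gen_proteomes(n_planted=5, margin=0.1, seed=2)
        assert len(sim.planted_sites) == 5
        for hid, _, start, end in sim.planted_sites:
            prof = sim.profiles[hid]
            assert np.mean(prof.iupred[start - 1:end]) >= 0.6
            assert np.mean(prof.anchor[start - 1:end]) >= 0.5

    def test_decoys_are_motif_matches_failing_disorder(self):
        sim = gen_proteomes(n_decoys=3, margin=0.1, seed=2)
        assert len(sim.decoy_sites) == 3
        classes = {c.identifier: c for c in DEFAULT_MOTIF_CLASSES}
        for hid, cls_id, start, end in sim.decoy_sites:
            seq = next(h.sequence for h in sim.hosts if h.id == hid)
            assert classes[cls_id].pattern.match(seq, start - 1)
            prof = sim.profiles[hid]
            assert np.mean(prof.iupred[start - 1:end]) <= 0.4

    def test_truth_is_oracle_output_not_planting_intent(self):
        # decoy spans never appear in the truth table
        sim = gen_proteomes(seed=2)
        decoy_keys = {(h, c, s, e) for h, c, s, e in sim.decoy_sites}
        truth_keys = {(h, c, s, e) for _, h, c, _, s, e in sim.truth_matches}
        assert decoy_keys.isdisjoint(truth_keys)

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(Exception, match="margin"):
            gen_proteomes(margin=0.0)


class TestExpressionGen:
    def test_off_set_has_exact_size_and_zero_counts(self):
        sim = gen_expression(["mono"], ["h", "d"], n_genes=100,
                             off_fraction=0.1, seed=4)
        for group, off in sim.truth_off.items():
            assert len(off) == 10
            cells = sim.labels.index[
                (sim.labels["cell_type"] == group[0]) &
                (sim.labels["condition"] == group[1])]
            assert (sim.values.loc[sorted(off), cells] == 0).all().all()

    def test_seeded_regeneration_identical(self):
        a = gen_expression(["mono"], ["h"], seed=9)
        b = gen_expression(["mono"], ["h"], seed=9)
        assert a.values.equals(b.values)

    def test_condition_specific_gene_on_only_in_listed_groups(self):
        cs = {"TLR4": {("mono", "d")}}
        sim = gen_expression(["mono"], ["h", "d"], gene_names=None,
                             n_genes=60, condition_specific=None, seed=1)
        genes = list(sim.values.index)
        genes[0] = "TLR4"
        sim = gen_expression(["mono"], ["h", "d"], gene_names=genes,
                             n_genes=60, condition_specific=cs, seed=1)
        assert "TLR4" not in sim.truth_expressed[("mono", "h")]
        assert "TLR4" in sim.truth_expressed[("mono", "d")]

    def test_constant_genes_identical_across_conditions(self):
        sim = gen_expression(["mono"], ["h", "d"], n_genes=60, seed=2,
                             constant_across_conditions=("G0001",))
        h_cells = sim.labels.index[sim.labels["condition"] == "h"]
        d_cells = sim.labels.index[sim.labels["condition"] == "d"]
        assert (sim.values.loc["G0001", h_cells].to_numpy() ==
                sim.values.loc["G0001", d_cells].to_numpy()).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(Exception, match="n_genes"):
            gen_expression(["mono"], ["h"], n_genes=10)


class TestGoGen:
    def test_depth_bound_and_acyclicity(self):
        for seed in range(3):
            sim = gen_go([f"g{i}" for i in range(50)], n_terms=30, depth=3,
                         seed=seed)
            for t in sim.dag.terms:
                assert sim.dag.depth(t) <= 3  # GoDag construction asserts acyclicity

    def test_planted_term_annotates_its_block(self):
        sim = gen_go([f"g{i}" for i in range(50)], planted_block=20, seed=1)
        annotated = {g for g, t in sim.annotations if t == sim.planted_term}
        assert sim.planted_genes <= annotated
        assert len(sim.planted_genes) == 20


class TestPathwayGen:
    def test_layer_counts(self):
        pw = gen_pathway(2, 1, 2, 1, seed=0)
        by_layer = {}
        for m, l in pw.layer.items():
            by_layer.setdefault(l, []).append(m)
        assert (len(by_layer["receptor"]), len(by_layer["adaptor"]),
                len(by_layer["kinase"]), len(by_layer["tf"])) == (2, 1, 2, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_edges_only_layer_forward(self, seed):
        pw = gen_pathway(seed=seed)
        order = {"receptor": 0, "adaptor": 1, "kinase": 2, "tf": 3}
        for s, t, _ in pw.edges:
            assert order[pw.layer[t]] == order[pw.layer[s]] + 1


class TestFixtureTree:
    def test_regenerated_fixture_is_byte_identical(self, tmp_path):
        generate_fixture(tmp_path / "a", seed=33)
        generate_fixture(tmp_path / "b", seed=33)
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")

    def test_fixture_contains_all_inputs_and_truth(self, fixture_dir):
        root = fixture_dir.root
        for name in ["bact.fasta", "host.fasta", "bact_domains.tsv",
                     "motif_classes.tsv", "motif_interactions.tsv",
                     "expression.mtx", "expression.labels.tsv", "go.obo",
                     "annotations.gaf", "pathway_members.tsv",
                     "pathway_edges.tsv", "config.yaml",
                     "truth/planted_interactions.tsv", "truth/expressed.tsv",
                     "truth/enriched_term.txt",
                     "truth/condition_specific_nodes.tsv"]:
            assert (root / name).exists(), name
        assert any((root / "disorder").iterdir())
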