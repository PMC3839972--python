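import math

import pytest

from genenorm.collective import (Assignment, GroundAtom, GroundNetwork,
                                 WeightConfig, extract_evidence,
                                 ground_formulae, infer_map, learn_weights,
                                 normalize_document)
from genenorm.errors import ConfigError, TrainingError
from genenorm.lexicon import GeneKB, Lexicon, LexiconEntry
from genenorm.mapping import map_mentions

from conftest import make_doc


def assert_hard_constraints(assignment: Assignment, cands) -> None:
    """At-most-one link per mention; every linked mention is human; links
    come from the mention's candidate set."""
    for x, gid in assignment.links.items():
        if gid is not None:
            assert gid in cands.ids(x)
            assert x in assignment.human


def small_lexicon(*entries):
    lex = Lexicon([LexiconEntry(g, t, set(names))
                   for g, t, names in entries])
    kb = GeneKB(taxon_of={e.gene_id: e.taxon for e in lex})
    return lex, kb


def run_both_solvers(doc, mentions, cands, kb, weights):
    a_enum = normalize_document(doc, mentions, cands, kb, weights,
                                solver="enumerate")
    a_ls = normalize_document(doc, mentions, cands, kb, weights,
                              solver="local_search", seed=5)
    assert a_enum.score == pytest.approx(a_ls.score, abs=1e-9)
    assert_hard_constraints(a_enum, cands)
    assert_hard_constraints(a_ls, cands)
    return a_enum


class TestSalience:
    def _fixture(self):
        lex, kb = small_lexicon(
            ("100", "9606", {"AF1", "common name"}),
            ("200", "9606", {"BG2", "common name"}),
        )
        doc = make_doc("sal", [("abstract",
                                "AF1 rises early. Later the common name "
                                "falls again.",
                                [("AF1", "100"), ("common name", "100")])])
        cands = map_mentions(doc, doc.mentions, lex)
        return doc, cands, kb

    def test_second_mention_inherits_first_id(self):
        """The repeated (salient) entity pulls the ambiguous mention to the
        ID already linked earlier in the section."""
        doc, cands, kb = self._fixture()
        a = run_both_solvers(doc, doc.mentions, cands, kb, WeightConfig())
        assert a.links[1] == "100"
        assert a.links[2] == "100"

    def test_monotone_in_salience_weight(self):
        """Raising the salience weight never flips the second mention away
        from the first mention's ID (here the tie-break alone would pick the
        competing smaller ID without salience)."""
        lex, kb = small_lexicon(
            ("500", "9606", {"ZF5", "common name"}),
            ("200", "9606", {"BG2", "common name"}),
        )
        doc = make_doc("sal2", [("abstract",
                                 "ZF5 rises. Then the common name falls.",
                                 [("ZF5", "500"),
                                  ("common name", "500")])])
        cands = map_mentions(doc, doc.mentions, lex)
        linked_to_500 = False
        for w in [0.0, 0.1, 0.5, 1.0, 2.0, 4.0]:
            cfg = WeightConfig()
            cfg.weights["salience"] = w
            a = normalize_document(doc, doc.mentions, cands, kb, cfg,
                                   solver="enumerate")
            assert_hard_constraints(a, cands)
            if linked_to_500:
                assert a.links[2] == "500"
            linked_to_500 = a.links[2] == "500"
        assert linked_to_500


class TestTransitivity:
    def test_coref_partner_inherits_id(self):
        """Full-name/abbreviation pair: the ambiguous abbreviation follows
        its co-referent full name (salience switched off to isolate the
        transitivity dependency)."""
        lex, kb = small_lexicon(
            ("100", "9606", {"alpha common factor", "ACF"}),
            ("900", "9606", {"ACF", "XY9"}),
        )
        doc = make_doc("tr", [("abstract",
                               "The alpha common factor (ACF) is key.",
                               [("alpha common factor", "100"),
                                ("ACF", "100")])])
        cands = map_mentions(doc, doc.mentions, lex)
        cfg = WeightConfig()
        cfg.weights["salience"] = 0.0
        cfg.weights["coref_shared_id"] = 0.0
        a = run_both_solvers(doc, doc.mentions, cands, kb, cfg)
        assert a.links[1] == "100"
        assert a.links[2] == "100"
        assert (1, 2) in a.coref


class TestPPI:
    def test_interactor_pair_selected(self):
        """A known interaction between candidate IDs beats the smaller-ID
        tie-break for the ambiguous partner mention."""
        lex, kb = small_lexicon(
            ("100", "9606", {"AF1"}),
            ("200", "9606", {"shared partner"}),
            ("300", "9606", {"shared partner"}),
        )
        kb.add_ppi("100", "300")
        doc = make_doc("ppi", [("abstract",
                                "AF1 binds the shared partner in vitro.",
                                [("AF1", "100"),
                                 ("shared partner", "300")])])
        cands = map_mentions(doc, doc.mentions, lex)
        cfg = WeightConfig()
        cfg.weights["salience"] = 0.0
        cfg.weights["coref_shared_id"] = 0.0
        a = run_both_solvers(doc, doc.mentions, cands, kb, cfg)
        assert a.links[1] == "100"
        assert a.links[2] == "300"


class TestHumanFilter:
    def test_nonhuman_mention_stays_unlinked(self):
        lex, kb = small_lexicon(("99", "10090", {"Mlgn3"}))
        doc = make_doc("nh", [("abstract",
                               "In mouse tissue, Mlgn3 was elevated.",
                               [("Mlgn3", None)])])
        cands = map_mentions(doc, doc.mentions, lex)
        a = run_both_solvers(doc, doc.mentions, cands, kb, WeightConfig())
        assert a.links[1] is None

    def test_species_ambiguity_resolved_to_human(self, toy_lexicon, toy_kb):
        doc = make_doc("sp", [("abstract",
                               "In human subjects the shared name rose.",
                               [("shared name", "1234")])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        a = run_both_solvers(doc, doc.mentions, cands, toy_kb,
                             WeightConfig())
        assert a.links[1] == "1234"  # not the mouse gene 99


class TestEvidence:
    def test_species_cue_nearest_in_sentence(self, toy_lexicon, toy_kb):
        doc = make_doc("ev", [("abstract",
                               "The rat urocortin rose. A human cohort was "
                               "recruited separately.",
                               [("urocortin", None)])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, toy_kb)
        assert GroundAtom("SpeciesCue", (1, "10116")) in atoms
        assert GroundAtom("SpeciesCue", (1, "9606")) not in atoms

    def test_abbrev_pair_feature(self, toy_lexicon, toy_kb):
        doc = make_doc("ab", [("abstract",
                               "The urocortin (UCN) peptide is secreted.",
                               [("urocortin", "7349"), ("UCN", "7349")])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, toy_kb)
        assert GroundAtom("CorefAbbrev", (1, 2)) in atoms

    def test_no_go_names_no_mostgoterms(self, toy_lexicon):
        kb = GeneKB(taxon_of={e.gene_id: e.taxon for e in toy_lexicon})
        doc = make_doc("go0", [("abstract", "The p53 level rose.",
                                [("p53", "7157")])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, kb)
        assert not [a for a in atoms if a.predicate == "MostGOTerms"]

    def test_mostgoterms_marks_argmax_id(self, toy_lexicon, toy_kb):
        doc = make_doc("go1", [("abstract",
                                "Urocortin alters corticotropin secretion "
                                "in stress. The urocortin level rose.",
                                [("urocortin", "7349")])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, toy_kb)
        assert GroundAtom("MostGOTerms", ("7349", "s0")) in atoms
        assert GroundAtom("MostGOTerms", ("29151", "s0")) not in atoms

    def test_info_rich_sections(self, toy_lexicon, toy_kb):
        doc = make_doc("ir", [
            ("title", "The p53 study", [("p53", "7157")]),
            ("abstract", "We study p53 here.", [("p53", "7157")]),
            ("results", "Again p53 rose.", [("p53", "7157")])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, toy_kb)
        rich = {a.args[0] for a in atoms
                if a.predicate == "InfoRichSection"}
        assert rich == {"s1"}


class TestGrounding:
    def test_single_unambiguous_mention_has_no_collectives(
            self, toy_lexicon, toy_kb):
        doc = make_doc("g1", [("abstract", "The p53 level rose.",
                               [("p53", "7157")])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, toy_kb)
        net = ground_formulae(atoms, WeightConfig(), cands=cands)
        collective_ids = {"salience", "transitivity", "ppi",
                          "salience_cross", "transitivity_cross",
                          "ppi_cross"}
        assert not [c for c in net.clauses
                    if c.formula_id in collective_ids]

    def test_cross_disabled_equals_filtered_grounding(self, toy_lexicon,
                                                      toy_kb):
        doc = make_doc("g2", [
            ("abstract", "The urocortin (UCN) peptide acts here.",
             [("urocortin", "7349"), ("UCN", "7349")]),
            ("results", "Then urocortin acted again.",
             [("urocortin", "7349")])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, toy_kb)
        full = ground_formulae(atoms, WeightConfig(), cands=cands)
        no_cross = ground_formulae(
            atoms, WeightConfig(enable_cross=False), cands=cands)
        cross_ids = {"salience_cross", "transitivity_cross", "ppi_cross"}
        assert [c for c in full.clauses if c.formula_id in cross_ids]
        expected = [(c.formula_id, c.literals, c.weight)
                    for c in full.clauses if c.formula_id not in cross_ids]
        got = [(c.formula_id, c.literals, c.weight)
               for c in no_cross.clauses]
        assert got == expected

    def test_unknown_formula_id_rejected(self):
        with pytest.raises(ConfigError):
            WeightConfig(weights={"not_a_formula": 1.0})
        with pytest.raises(ConfigError):
            WeightConfig(weights={"unique": 1.0})


class TestInference:
    def test_empty_network(self):
        a = infer_map(GroundNetwork())
        assert a.links == {} and a.score == 0.0

    def test_individual_only_equals_unit_clause_argmax(
            self, synthetic_bundle):
        """With all collective groups off the MAP decomposes into an
        independent per-mention argmax over the unit-clause weights
        (closed-form oracle)."""
        _, bundle, docs, _ = synthetic_bundle
        lexicon, kb = bundle.build()
        cfg = WeightConfig(enable_intra=False, enable_cross=False)
        for doc in docs[:3]:
            cands = map_mentions(doc, doc.mentions, lexicon)
            atoms = extract_evidence(doc, doc.mentions, cands, kb)
            net = ground_formulae(atoms, cfg, cands=cands)
            a = infer_map(net, solver="local_search", seed=0)
            assert_hard_constraints(a, cands)
            # oracle: unit-clause utilities per atom
            unit = {}
            for c in net.clauses:
                if not c.hard and len(c.literals) == 1:
                    i, pos = c.literals[0]
                    unit[i] = unit.get(i, 0.0) + (c.weight if pos
                                                  else -c.weight)
            n_by_mention = {}
            h_util = {}
            for i, atom in enumerate(net.atoms):
                if atom.predicate == "NormalizeTo":
                    n_by_mention.setdefault(atom.args[0], []).append(
                        (atom.args[1], unit.get(i, 0.0)))
                elif atom.predicate == "HumanGene":
                    h_util[atom.args[0]] = unit.get(i, 0.0)
            for x, options in n_by_mention.items():
                h = h_util.get(x, 0.0)
                best_gain = 0.0
                for gid, u in options:
                    gain = u + (0.0 if h >= 0 else h)
                    best_gain = max(best_gain, gain)
                linked_gain = 0.0
                if a.links[x] is not None:
                    u = dict(options)[a.links[x]]
                    linked_gain = u + (0.0 if h >= 0 else h)
                assert linked_gain == pytest.approx(best_gain, abs=1e-9)

    def test_every_seed_satisfies_hard_constraints(self, synthetic_bundle):
        _, bundle, docs, _ = synthetic_bundle
        lexicon, kb = bundle.build()
        doc = docs[0]
        cands = map_mentions(doc, doc.mentions, lexicon)
        for seed in range(8):
            a = normalize_document(doc, doc.mentions, cands, kb,
                                   seed=seed, restarts=2)
            assert_hard_constraints(a, cands)


class TestLearnWeights:
    def _toy_training(self, n_docs=6):
        """Corpus where only salience separates gold from the smaller-ID
        tie-break: gold is always the larger of two tied candidates."""
        lex, kb = small_lexicon(
            ("555", "9606", {"ZF5", "common name"}),
            ("111", "9606", {"AB1", "common name"}),
        )
        docs = []
        for i in range(n_docs):
            docs.append(make_doc(f"t{i}", [
                ("abstract",
                 "ZF5 is measured. Then the common name is measured.",
                 [("ZF5", "555"), ("common name", "555")])]))
        return docs, lex, kb

    def test_salience_weight_becomes_positive(self):
        docs, lex, kb = self._toy_training()
        init = WeightConfig()
        init.weights["salience"] = 0.0
        init.weights["salience_cross"] = 0.0
        init.weights["coref_shared_id"] = 0.0
        init.weights["transitivity"] = 0.0
        trained = learn_weights(docs, lex, kb, epochs=3, seed=0, init=init)
        assert trained.weights["salience"] > 0.0

    def test_zero_epochs_returns_init(self):
        docs, lex, kb = self._toy_training(2)
        init = WeightConfig()
        out = learn_weights(docs, lex, kb, epochs=0, seed=0, init=init)
        assert out.weights == init.weights

    def test_duplicated_corpus_equals_doubled_epochs(self):
        docs, lex, kb = self._toy_training(3)
        w1 = learn_weights(docs + docs, lex, kb, epochs=2, seed=0)
        w2 = learn_weights(docs, lex, kb, epochs=4, seed=0)
        for k in w1.weights:
            assert w1.weights[k] == pytest.approx(w2.weights[k], abs=1e-9)

    def test_no_gold_raises(self):
        docs, lex, kb = self._toy_training(1)
        for m in docs[0].mentions:
            m.gold_gene_id = None
        with pytest.raises(TrainingError):
            learn_weights(docs, lex, kb, epochs=1, seed=0)


class TestWeightConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = WeightConfig(enable_cross=False)
        cfg.weights["salience"] = 1.25
        path = tmp_path / "w.yaml"
        cfg.to_yaml(path)
        back = WeightConfig.from_yaml(path)
        assert back.weights == cfg.weights
        assert back.enable_cross is False

    def test_infinite_hard_weight_flagged(self, toy_lexicon, toy_kb):
        doc = make_doc("h", [("abstract", "The p53 level rose.",
                              [("p53", "7157")])])
        cands = map_mentions(doc, doc.mentions, toy_lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, toy_kb)
        net = ground_formulae(atoms, WeightConfig(), cands=cands)
        for c in net.clauses:
            if c.hard:
                assert math.isinf(c.weight)
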