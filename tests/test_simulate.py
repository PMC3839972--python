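import statistics

import pytest

from genenorm.corpus import write_collection
from genenorm.errors import ConfigError
from genenorm.simulate import (GeneratorConfig, degrade_recognition,
                               generate_corpus, generate_lexicon,
                               write_gold_pairs)


class TestGeneratorConfig:
    def test_rates_validated(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(seed=1, ambiguity_rate=1.5)
        with pytest.raises(ConfigError):
            GeneratorConfig(seed=1, nonhuman_rate=-0.1)

    def test_contradictory_ambiguity(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(seed=1, n_genes=1, ambiguity_rate=0.5)


class TestGenerateLexicon:
    def test_no_ambiguity_means_unique_surfaces(self):
        cfg = GeneratorConfig(seed=3, n_genes=40, ambiguity_rate=0.0)
        bundle = generate_lexicon(cfg)
        owners = {}
        for g in bundle.genes:
            for name in g.names:
                owners.setdefault(name, set()).add(g.gene_id)
        assert all(len(v) == 1 for v in owners.values())

    def test_mean_ids_per_ambiguous_name(self):
        """Planted shared surfaces average the configured IDs-per-name."""
        means = []
        for seed in (1, 2, 3):
            cfg = GeneratorConfig(seed=seed, n_genes=500,
                                  mean_ids_per_ambiguous_name=2.93)
            bundle = generate_lexicon(cfg)
            owners = {}
            for g in bundle.genes:
                for name in g.ambiguous:
                    owners.setdefault(name, set()).add(g.gene_id)
            means.append(statistics.mean(len(v) for v in owners.values()))
        assert abs(statistics.mean(means) - 2.93) <= 0.3

    def test_two_taxa_present(self):
        cfg = GeneratorConfig(seed=5, n_genes=30)
        bundle = generate_lexicon(cfg)
        assert len({g.taxon for g in bundle.genes}) >= 2

    def test_deterministic_tables(self, tmp_path):
        cfg = GeneratorConfig(seed=9, n_genes=50)
        for run in ("a", "b"):
            d = tmp_path / run
            d.mkdir()
            generate_lexicon(cfg).write(d / "g.tsv", d / "go.tsv",
                                        d / "p.tsv")
        for name in ("g.tsv", "go.tsv", "p.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()


class TestGenerateCorpus:
    def test_every_gold_id_exists_in_lexicon(self, synthetic_bundle):
        _, bundle, docs, _ = synthetic_bundle
        ids = {g.gene_id for g in bundle.genes}
        for d in docs:
            for m in d.mentions:
                if m.gold_gene_id is not None:
                    assert m.gold_gene_id in ids

    def test_coreference_chains_group_same_gene(self, synthetic_bundle):
        _, _, docs, _ = synthetic_bundle
        chained = 0
        for d in docs:
            by_chain = {}
            for m in d.mentions:
                if m.gold_chain:
                    by_chain.setdefault(m.gold_chain, []).append(m)
            for chain in by_chain.values():
                ids = {m.gold_gene_id for m in chain}
                assert len(ids) == 1
                if len(chain) >= 3:
                    chained += 1
        assert chained > 0

    def test_nonhuman_rate_one_removes_all_entrez_ids(self):
        cfg = GeneratorConfig(seed=4, n_docs=3, n_genes=40,
                              nonhuman_rate=1.0)
        bundle = generate_lexicon(cfg)
        docs, _ = generate_corpus(cfg, bundle)
        # human PPI couples still introduce genes; the nonhuman slots
        # themselves never carry an entrez id
        nonhuman = [m for d in docs for m in d.mentions
                    if m.gold_taxon != "9606"]
        assert nonhuman
        assert all(m.gold_gene_id is None for m in nonhuman)

    def test_gold_pairs_reference_sentences_with_both_ids(
            self, synthetic_bundle):
        _, _, docs, pairs = synthetic_bundle
        by_id = {d.doc_id: d for d in docs}
        for doc_id, si, pair in pairs:
            doc = by_id[doc_id]
            sentences = sorted(s for sec in doc.sections
                               for s in sec.sentences)
            a, b = sentences[si]
            ids_in_sentence = {m.gold_gene_id for m in doc.mentions
                               if a <= m.span[0] < b}
            assert pair <= ids_in_sentence

    def test_byte_identical_corpus(self, tmp_path):
        cfg = GeneratorConfig(seed=12, n_docs=4, n_genes=60)
        blobs = []
        for run in range(2):
            bundle = generate_lexicon(cfg)
            docs, pairs = generate_corpus(cfg, bundle)
            xml = tmp_path / f"c{run}.xml"
            tsv = tmp_path / f"p{run}.tsv"
            write_collection(docs, xml)
            write_gold_pairs(pairs, tsv)
            blobs.append((xml.read_bytes(), tsv.read_bytes()))
        assert blobs[0] == blobs[1]


class TestDegradeRecognition:
    def test_all_drops_zero_is_identity(self, synthetic_bundle):
        _, _, docs, _ = synthetic_bundle
        cfg0 = GeneratorConfig(seed=42, sentence_initial_drop=0.0,
                               lowercase_drop=0.0)
        for d in docs:
            assert degrade_recognition(d, cfg0) == d.mentions

    def test_full_drop_removes_every_sentence_initial_duplicate(
            self, synthetic_bundle):
        _, _, docs, _ = synthetic_bundle
        cfg1 = GeneratorConfig(seed=42, sentence_initial_drop=1.0,
                               lowercase_drop=0.0)
        for d in docs:
            kept = degrade_recognition(d, cfg1)
            starts = {s[0] for sec in d.sections for s in sec.sentences}
            kept_spans = {m.span for m in kept}
            seen = set()
            for m in d.mentions:
                dup = m.surface in seen
                seen.add(m.surface)
                if dup and m.span[0] in starts:
                    assert m.span not in kept_spans

    def test_first_occurrence_never_removed(self, synthetic_bundle):
        _, _, docs, _ = synthetic_bundle
        cfg1 = GeneratorConfig(seed=42, sentence_initial_drop=1.0,
                               lowercase_drop=1.0)
        for d in docs:
            kept_surfaces = {m.surface for m in degrade_recognition(d, cfg1)}
            assert kept_surfaces == {m.surface for m in d.mentions}

    def test_drop_composition_matches_configured_rates(self):
        """Across 50 documents the realized drop fractions stay within
        five points of the configured 29.7% / 12.1%."""
        cfg = GeneratorConfig(seed=77, n_docs=50, n_genes=150)
        bundle = generate_lexicon(cfg)
        docs, _ = generate_corpus(cfg, bundle)
        eligible = {"initial": 0, "lower": 0}
        dropped = {"initial": 0, "lower": 0}
        for d in docs:
            kept_spans = {m.span for m in degrade_recognition(d, cfg)}
            starts = {s[0] for sec in d.sections for s in sec.sentences}
            seen = set()
            for m in d.mentions:
                dup = m.surface in seen
                seen.add(m.surface)
                if not dup:
                    continue
                if m.span[0] in starts:
                    kind = "initial"
                elif m.surface.isalpha() and m.surface.islower():
                    kind = "lower"
                else:
                    continue
                eligible[kind] += 1
                if m.span not in kept_spans:
                    dropped[kind] += 1
        assert eligible["initial"] > 30 and eligible["lower"] > 30
        assert abs(dropped["initial"] / eligible["initial"] - 0.297) <= 0.05
        assert abs(dropped["lower"] / eligible["lower"] - 0.121) <= 0.05
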