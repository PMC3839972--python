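import pytest

from genenorm.corpus import Document, Mention, Section, segment_sentences
from genenorm.lexicon import GeneKB, Lexicon, LexiconEntry
from genenorm.simulate import GeneratorConfig, generate_corpus, generate_lexicon


@pytest.fixture(scope="session")
def toy_lexicon():
    """Small hand-built lexicon: the classic two-species 'urocortin' case
    plus ambiguous and multi-token names."""
    entries = [
        LexiconEntry("7349", "9606", {"UCN", "urocortin"}),
        LexiconEntry("29151", "10116", {"Ucn", "urocortin"}),
        LexiconEntry("7157", "9606",
                     {"TP53", "p53", "tumor protein p53 binding"}),
        LexiconEntry("405", "9606", {"ARNT", "Arnt"}),
        LexiconEntry("3558", "9606", {"IL2", "IL-2", "interleukin 2"}),
        LexiconEntry("7124", "9606", {"TNF", "TNF-alpha"}),
        LexiconEntry("1234", "9606", {"shared name", "AAA1"}),
        LexiconEntry("99", "10090", {"shared name", "BBB2"}),
    ]
    return Lexicon(entries)


@pytest.fixture(scope="session")
def toy_kb(toy_lexicon):
    kb = GeneKB(taxon_of={e.gene_id: e.taxon for e in toy_lexicon})
    kb.go_terms["7349"] = {"corticotropin secretion"}
    kb.go_terms["7157"] = {"dna damage response"}
    kb.add_ppi("7349", "7157")
    return kb


def make_doc(doc_id: str, section_specs):
    """Build a Document from [(section_type, text, [(surface, gold_id)])].

    Mentions are located by first non-overlapping occurrence of the surface
    inside the section, in the order given.
    """
    text_parts, sections, mentions = [], [], []
    pos = 0
    for i, (stype, stext, ments) in enumerate(section_specs):
        start = pos
        text_parts.append(stext)
        pos += len(stext)
        sentences = [(a + start, b + start)
                     for a, b in segment_sentences(stext)]
        sections.append(Section(section_id=f"s{i}", section_type=stype,
                                span=(start, pos), sentences=sentences))
        cursor = 0
        for surface, gold in ments:
            at = stext.index(surface, cursor)
            cursor = at + len(surface)
            mentions.append(Mention(
                order_index=0, span=(start + at, start + at + len(surface)),
                surface=surface, section_ref=f"s{i}",
                gold_gene_id=gold))
        text_parts.append("\n")
        pos += 1
    text = "".join(text_parts)
    mentions.sort(key=lambda m: m.span)
    for k, m in enumerate(mentions, start=1):
        m.order_index = k
    doc = Document(doc_id=doc_id, text=text, sections=sections,
                   mentions=mentions)
    doc.validate()
    return doc


@pytest.fixture(scope="session")
def synthetic_bundle():
    cfg = GeneratorConfig(seed=42, n_docs=6, n_genes=80)
    bundle = generate_lexicon(cfg)
    docs, pairs = generate_corpus(cfg, bundle)
    return cfg, bundle, docs, pairs
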