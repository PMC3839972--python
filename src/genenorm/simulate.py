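"""Synthetic lexicons and corpora with controlled instance-level structure.

The generator plants every signal the pipeline is supposed to exploit, with
exact gold control: per-mention gold IDs and species, full-name/abbreviation
pairs forming co-reference chains, shared (ambiguous) surface names whose
mean IDs-per-name is configurable, GO-term phrases embedded in section text,
templated protein-interaction sentences consistent with the knowledge base,
section structure with information-rich abstract/introduction sections, and
sentence-initial / lowercase-only duplicate mentions that a degradable oracle
recognizer can hide from the pipeline.

Text is template-generated; realism is deliberately sacrificed for exact gold
control: filler vocabulary, gene surfaces and GO phrases are constructed to
be mutually non-colliding at token boundaries, so an exact-match scan over
the article finds gene surfaces exactly where mentions were planted.
"""

from __future__ import annotations

import math
import random
import zlib
from dataclasses import dataclass, field

from genenorm.corpus import Document, Mention, Section, reindex_mentions
from genenorm.errors import ConfigError
from genenorm.lexicon import GeneKB, Lexicon, LexiconEntry

_SYLLABLES = ("ba", "ce", "di", "fo", "gu", "hy", "ka", "lo", "mi", "nu",
              "pe", "qi", "ro", "sa", "te", "vu", "wa", "xi", "yo", "zu")

_TAXA_NONHUMAN = ("10116", "10090")  # rat, mouse
_SPECIES_WORD = {"10116": "rat", "10090": "mouse"}


def _enc(i: int, prefix: str = "") -> str:
    """Unique lowercase pseudo-word for index i (three base-20 syllables)."""
    s = []
    for _ in range(3):
        s.append(_SYLLABLES[i % 20])
        i //= 20
    return prefix + "".join(s)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    ``mean_ids_per_ambiguous_name``, ``sentence_initial_drop`` and
    ``lowercase_drop`` default to the corpus statistics reported for the
    real annotation effort (2.93 IDs per ambiguous name; 29.7% of missed
    duplicate mentions sentence-initial, 12.1% lowercase-only).
    """

    seed: int
    n_docs: int = 50
    n_genes: int = 200
    synonyms_per_gene: int = 2
    ambiguity_rate: float = 0.3
    nonhuman_rate: float = 0.1
    mean_ids_per_ambiguous_name: float = 2.93
    sentence_initial_drop: float = 0.297
    lowercase_drop: float = 0.121
    sections_per_doc: int = 4
    ppi_density: float = 0.02

    def __post_init__(self):
        for name in ("ambiguity_rate", "nonhuman_rate",
                     "sentence_initial_drop", "lowercase_drop",
                     "ppi_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.ambiguity_rate > 0 and self.n_genes < 2:
            raise ConfigError("ambiguity_rate > 0 requires n_genes >= 2")
        if self.ambiguity_rate > 0 and self.mean_ids_per_ambiguous_name < 2:
            raise ConfigError("mean_ids_per_ambiguous_name must be >= 2")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not 2 <= self.sections_per_doc <= 4:
            raise ConfigError("sections_per_doc must be in 2..4")


@dataclass
class GeneRecord:
    gene_id: str
    taxon: str
    symbol: str
    full_name: str
    synonyms: list[str]
    ambiguous: list[str] = field(default_factory=list)
    go_terms: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [self.symbol, self.full_name, *self.synonyms, *self.ambiguous]


@dataclass
class LexiconBundle:
    """Generated lexicon plus knowledge tables, writable as module TSVs."""

    genes: list[GeneRecord]
    ppi_pairs: list[tuple[str, str]]

    def build(self) -> tuple[Lexicon, GeneKB]:
        entries = [LexiconEntry(g.gene_id, g.taxon, set(g.names))
                   for g in self.genes]
        kb = GeneKB(taxon_of={g.gene_id: g.taxon for g in self.genes})
        for g in self.genes:
            kb.go_terms[g.gene_id] = set(g.go_terms)
        for a, b in self.ppi_pairs:
            kb.add_ppi(a, b)
        return Lexicon(entries), kb

    def write(self, gene_table, go_table, ppi_table) -> None:
        with open(gene_table, "w", encoding="utf-8") as fh:
            fh.write("tax_id\tgene_id\tsymbol\tsynonyms\n")
            for g in self.genes:
                syns = "|".join([g.full_name, *g.synonyms, *g.ambiguous])
                fh.write(f"{g.taxon}\t{g.gene_id}\t{g.symbol}\t{syns}\n")
        with open(go_table, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tgo_term_name\n")
            for g in self.genes:
                for term in g.go_terms:
                    fh.write(f"{g.gene_id}\t{term}\n")
        with open(ppi_table, "w", encoding="utf-8") as fh:
            fh.write("gene_id_a\tgene_id_b\n")
            for a, b in self.ppi_pairs:
                fh.write(f"{a}\t{b}\n")


def generate_lexicon(cfg: GeneratorConfig) -> LexiconBundle:
    """Generate genes across two or more taxa with planted shared surfaces.

    A fraction ``ambiguity_rate`` of all surfaces is shared by >= 2 genes;
    the number of genes per shared surface is 2 + Poisson(mean - 2), giving
    the configured mean IDs per ambiguous name.
    """
    rng = random.Random(cfg.seed)
    n_nonhuman = max(1, round(cfg.n_genes * 0.2)) if cfg.n_genes > 1 else 0
    genes: list[GeneRecord] = []
    for i in range(cfg.n_genes):
        gid = str(1000 + i)
        taxon = ("9606" if i < cfg.n_genes - n_nonhuman
                 else _TAXA_NONHUMAN[i % 2])
        word = _enc(i)
        symbol = word[:4].upper() + str(i)
        full_name = f"{word} associated factor {i}"
        synonyms = [word + "in"]  # lowercase-only alias
        for j in range(1, cfg.synonyms_per_gene):
            synonyms.append(f"{symbol}-{j}")
        go_terms = [f"regulation of {word}ase signaling",
                    f"{word}ase complex assembly"]
        genes.append(GeneRecord(gid, taxon, symbol, full_name, synonyms,
                                go_terms=go_terms))

    if cfg.ambiguity_rate > 0:
        n_unique = sum(len(g.names) for g in genes)
        n_shared = round(cfg.ambiguity_rate / (1 - cfg.ambiguity_rate)
                         * n_unique) if cfg.ambiguity_rate < 1 else n_unique
        lam = cfg.mean_ids_per_ambiguous_name - 2
        for k in range(n_shared):
            surface = _enc(k, prefix="x")
            m = 2 + _poisson(rng, lam)
            m = min(m, cfg.n_genes)
            for gi in rng.sample(range(cfg.n_genes), m):
                genes[gi].ambiguous.append(surface)

    human_ids = [g.gene_id for g in genes if g.taxon == "9606"]
    ppi: list[tuple[str, str]] = []
    seen = set()
    # guaranteed couples so every document can host interaction sentences
    for i in range(0, len(human_ids) - 1, 2):
        ppi.append((human_ids[i], human_ids[i + 1]))
        seen.add(frozenset(ppi[-1]))
    n_random = round(cfg.ppi_density * cfg.n_genes * (cfg.n_genes - 1) / 2)
    for _ in range(n_random):
        a, b = rng.sample(human_ids, 2) if len(human_ids) >= 2 else (None,) * 2
        if a is None or frozenset((a, b)) in seen:
            continue
        seen.add(frozenset((a, b)))
        ppi.append((a, b))
    return LexiconBundle(genes=genes, ppi_pairs=ppi)


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    limit, k, p = math.exp(-lam), 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.chunks: list[str] = []
        self.pos = 0
        self.sections: list[Section] = []
        self.mentions: list[tuple] = []  # (start, end, surface, rec)
        self._cur_sentences: list[tuple[int, int]] = []
        self._sec_start = 0
        self.sentence_count = 0
        self.initial_flags: list[bool] = []

    def start_section(self):
        self._sec_start = self.pos
        self._cur_sentences = []

    def end_section(self, section_id: str, section_type: str):
        self.sections.append(Section(
            section_id=section_id, section_type=section_type,
            span=(self._sec_start, self.pos),
            sentences=list(self._cur_sentences)))
        self._append("\n")

    def _append(self, text: str):
        self.chunks.append(text)
        self.pos += len(text)

    def sentence(self, parts: list, sentence_index_out: list | None = None):
        """parts: strings and (surface, record) mention tuples."""
        start = self.pos
        first = True
        for part in parts:
            if isinstance(part, str):
                self._append(part)
            else:
                surface, rec = part
                a = self.pos
                self._append(surface)
                self.mentions.append((a, self.pos, surface, rec))
                self.initial_flags.append(first and a == start)
            first = False
        self._cur_sentences.append((start, self.pos))
        if sentence_index_out is not None:
            sentence_index_out.append(self.sentence_count)
        self.sentence_count += 1
        self._append(" ")

    def finish(self) -> Document:
        text = "".join(self.chunks)
        if text.endswith("\n"):  # separator after the last section
            text = text[:-1]
        mentions = []
        chains: dict[str, str] = {}
        for (a, b, surface, rec) in sorted(self.mentions):
            gid, taxon, chain = rec
            mentions.append(Mention(
                order_index=0, span=(a, b), surface=surface,
                section_ref="", gold_gene_id=gid, gold_taxon=taxon,
                gold_chain=chain))
        doc = Document(doc_id=self.doc_id, text=text, sections=self.sections)
        for m in mentions:
            sec = doc.section_of(m.span[0])
            m.section_ref = sec.section_id
        doc.mentions = reindex_mentions(mentions)
        doc.validate()
        return doc


def generate_corpus(cfg: GeneratorConfig, bundle: LexiconBundle
                    ) -> tuple[list[Document], list[tuple[str, int, frozenset]]]:
    """Generate documents plus the gold sentence-level interaction pairs.

    Each document introduces its focus genes in the abstract as
    "full name (SYMBOL)" (a gold abbreviation co-reference pair), re-mentions
    them later — with probability ``ambiguity_rate`` under a shared surface —
    plants each focus gene's GO phrase in sections where it appears, and
    describes knowledge-base interactions in single sentences. Non-human
    mention slots carry a species word and taxonomy_id only. Deterministic:
    same config and seed give byte-identical output.
    """
    rng = random.Random(cfg.seed + 1)
    human = [g for g in bundle.genes if g.taxon == "9606"]
    nonhuman = [g for g in bundle.genes if g.taxon != "9606"]
    couples = list(bundle.ppi_pairs)
    by_id = {g.gene_id: g for g in bundle.genes}
    if not couples or not human:
        raise ConfigError("corpus generation needs at least one human "
                          "PPI pair in the lexicon bundle")

    docs: list[Document] = []
    gold_pairs: list[tuple[str, int, frozenset]] = []
    section_plan = ["title", "abstract", "introduction", "results"]
    section_plan = section_plan[:max(2, cfg.sections_per_doc)]

    for d in range(cfg.n_docs):
        doc_id = f"SYN{cfg.seed}-{d:04d}"
        b = _DocBuilder(doc_id)
        n_couples = 2 if len(couples) >= 2 else 1
        picked = rng.sample(couples, n_couples)
        focus, seen_focus = [], set()
        for pair in picked:
            for g in pair:
                if g not in seen_focus:
                    seen_focus.add(g)
                    focus.append(by_id[g])

        def rec(gene: GeneRecord):
            if gene.taxon == "9606":
                return (gene.gene_id, "9606", f"g{gene.gene_id}")
            return (None, gene.taxon, f"g{gene.gene_id}")

        def later_surface(gene: GeneRecord) -> str:
            if gene.ambiguous and rng.random() < cfg.ambiguity_rate:
                return rng.choice(gene.ambiguous)
            if rng.random() < 0.25:
                return gene.synonyms[0]  # lowercase alias
            return gene.symbol

        def maybe_nonhuman_sentence():
            if nonhuman and rng.random() < cfg.nonhuman_rate:
                g = rng.choice(nonhuman)
                word = _SPECIES_WORD.get(g.taxon, "mouse")
                b.sentence([f"In the {word} model, ", (g.symbol, rec(g)),
                            " expression was reduced after treatment."])

        g0 = focus[0]
        # title: information-poor section; duplicate of an abstract gene
        b.start_section()
        b.sentence([(later_surface(g0), rec(g0)),
                    " activity in primary cells"])
        b.end_section("s0", "title")

        # abstract: rich; introduces every focus gene as full name (SYMBOL)
        b.start_section()
        for k, g in enumerate(focus):
            lead = "In human patients, the " if k == 0 else "The "
            b.sentence([lead, (g.full_name, rec(g)), " (",
                        (g.symbol, rec(g)),
                        ") is a regulator of cell growth."])
        for a, c in picked:
            ga, gc = by_id[a], by_id[c]
            out: list[int] = []
            b.sentence([(ga.symbol, rec(ga)), " interacts with ",
                        (gc.symbol, rec(gc)), " in these cells."],
                       sentence_index_out=out)
            if ga.taxon == "9606" and gc.taxon == "9606":
                gold_pairs.append((doc_id, out[0],
                                   frozenset((ga.gene_id, gc.gene_id))))
        for g in focus[:2]:
            surf = later_surface(g)
            if rng.random() < 0.5:
                b.sentence([(surf, rec(g)),
                            " was strongly expressed in all samples."])
            else:
                b.sentence(["We observed that ", (surf, rec(g)),
                            " levels increased during differentiation."])
        # lowercase alias mentioned twice: the second occurrence is the
        # lowercase-only duplicate a case-sensitive recognizer tends to miss
        for g in focus[:2]:
            lc = g.synonyms[0]
            b.sentence(["We measured ", (lc, rec(g)),
                        " in cultured cells."])
            b.sentence(["Analysis showed that ", (lc, rec(g)),
                        " remained elevated."])
        maybe_nonhuman_sentence()
        b.end_section("s1", "abstract")

        if "introduction" in section_plan:
            b.start_section()
            b.sentence(["Prior studies examined this regulatory module "
                        "in detail."])
            for g in focus[:2]:
                b.sentence(["This process contributes to ",
                            g.go_terms[0], "."])
                b.sentence([(later_surface(g), rec(g)),
                            " has been implicated in the same pathway."])
            b.end_section("s2", "introduction")

        if "results" in section_plan:
            b.start_section()
            for g in focus[2:] or focus[:1]:
                surf = later_surface(g)
                if rng.random() < 0.5:
                    b.sentence([(surf, rec(g)),
                                " signal was measured in treated cells."])
                else:
                    b.sentence(["Knockdown of ", (surf, rec(g)),
                                " reduced the reporter signal."])
            ga, gc = by_id[picked[-1][0]], by_id[picked[-1][1]]
            out = []
            b.sentence(["Binding of ", (ga.symbol, rec(ga)), " to ",
                        (gc.symbol, rec(gc)),
                        " was confirmed by the assay."],
                       sentence_index_out=out)
            if ga.taxon == "9606" and gc.taxon == "9606":
                gold_pairs.append((doc_id, out[0],
                                   frozenset((ga.gene_id, gc.gene_id))))
            maybe_nonhuman_sentence()
            b.end_section("s3", "results")
        docs.append(b.finish())
    return docs, gold_pairs


def _doc_rng(cfg: GeneratorConfig, doc_id: str) -> random.Random:
    return random.Random((cfg.seed * 2654435761 + zlib.crc32(doc_id.encode()))
                         % (1 << 31))


def degrade_recognition(doc: Document, cfg: GeneratorConfig
                        ) -> list[Mention]:
    """Oracle recognizer with configurable blind spots.

    Removes ``sentence_initial_drop`` of sentence-initial duplicate-surface
    mentions and ``lowercase_drop`` of lowercase-only duplicate-surface
    mentions; the first occurrence of a surface is never removed, so the
    refinement dictionary can always be seeded. Deterministic per document.
    """
    rng = _doc_rng(cfg, doc.doc_id)
    starts = {s[0] for sec in doc.sections for s in sec.sentences}
    seen: set[str] = set()
    kept = []
    for m in doc.mentions:
        duplicate = m.surface in seen
        seen.add(m.surface)
        if not duplicate:
            kept.append(m)
            continue
        if m.span[0] in starts:
            drop = rng.random() < cfg.sentence_initial_drop
        elif m.surface.isalpha() and m.surface.islower():
            drop = rng.random() < cfg.lowercase_drop
        else:
            drop = False
        if not drop:
            kept.append(m)
    return reindex_mentions(kept)


def write_gold_pairs(pairs, path) -> None:
    """Gold interaction pairs as TSV: doc_id, sentence_index, id_a, id_b."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tsentence_index\tid_a\tid_b\n")
        for doc_id, si, pair in pairs:
            a, b = sorted(pair, key=lambda s: (len(s), s))
            fh.write(f"{doc_id}\t{si}\t{a}\t{b}\n")


def read_gold_pairs(path) -> list[tuple[str, int, frozenset]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        assert header.startswith("doc_id")
        for line in fh:
            doc_id, si, a, b = line.rstrip("\n").split("\t")
            out.append((doc_id, int(si), frozenset((a, b))))
    return out
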