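"""Data model and BioC XML I/O for instance-level gene-normalization corpora.

A :class:`Document` is the unit over which disambiguation networks are built.
All character coordinates are 0-based half-open intervals over the full
document text; BioC passage/annotation offsets are converted at the I/O
boundary. Every gene annotation becomes a :class:`Mention` with a
document-global ``order_index`` assigned by start offset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from lxml import etree

from genenorm.errors import CorpusParseError, ValidationError

logger = logging.getLogger(__name__)

SECTION_TYPES = (
    "title", "abstract", "introduction", "methods",
    "results", "discussion", "caption", "other",
)

#: Default infon-key schema for the IGN-style BioC dialect. Other dialects can
#: remap these keys via the ``schema`` argument of :func:`read_collection`.
DEFAULT_SCHEMA: dict[str, object] = {
    "gene_types": frozenset({"gene", "protein", "gene_or_protein"}),
    "sentence_type": "sentence",
    "entrez_id": "entrez_id",
    "taxonomy_id": "taxonomy_id",
    "coreference_chain": "coreference_chain",
    "predicted_entrez_id": "predicted_entrez_id",
    "section_type": "type",
    "section_id": "section_id",
}

_HEADING_MAP = (
    ("introduction", "introduction"), ("background", "introduction"),
    ("abstract", "abstract"), ("title", "title"),
    ("method", "methods"), ("materials", "methods"),
    ("result", "results"),
    ("discussion", "discussion"), ("conclusion", "discussion"),
    ("caption", "caption"), ("figure", "caption"), ("table", "caption"),
)


def classify_section_type(label: str) -> str:
    """Map a BioC passage type / heading string onto the section-type enum."""
    low = label.strip().lower()
    if low in SECTION_TYPES:
        return low
    for key, stype in _HEADING_MAP:
        if key in low:
            return stype
    return "other"


@dataclass
class Section:
    section_id: str
    section_type: str
    span: tuple[int, int]
    sentences: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Mention:
    """One gene-mention occurrence.

    ``order_index`` is 1-based and document-global, strictly increasing with
    start offset. ``gold_gene_id`` is set for human mentions only; non-human
    mentions carry ``gold_taxon`` instead, mirroring the corpus convention
    that only human genes are identity-linked.
    """

    order_index: int
    span: tuple[int, int]
    surface: str
    section_ref: str
    gold_gene_id: str | None = None
    gold_taxon: str | None = None
    gold_chain: str | None = None
    #: predicted IDs read back from a predictions file (comma-joined infon)
    pred_ids: tuple[str, ...] | None = None


@dataclass
class Document:
    doc_id: str
    text: str
    sections: list[Section] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)

    def section_of(self, pos: int) -> Section | None:
        for sec in self.sections:
            if sec.span[0] <= pos < sec.span[1]:
                return sec
        return None

    def section_by_id(self, section_id: str) -> Section:
        for sec in self.sections:
            if sec.section_id == section_id:
                return sec
        raise KeyError(section_id)

    def sentence_of(self, pos: int) -> tuple[int, int] | None:
        for sec in self.sections:
            for s in sec.sentences:
                if s[0] <= pos < s[1]:
                    return s
        return None

    def validate(self) -> None:
        n = len(self.text)
        prev_end = -1
        for sec in self.sections:
            a, b = sec.span
            if not (0 <= a <= b <= n):
                raise ValidationError(
                    f"{self.doc_id}: section {sec.section_id} span {sec.span} "
                    f"outside text of length {n}")
            if a < prev_end:
                raise ValidationError(
                    f"{self.doc_id}: section {sec.section_id} overlaps "
                    "previous section")
            prev_end = b
            last = a
            for s in sec.sentences:
                if not (a <= s[0] <= s[1] <= b) or s[0] < last:
                    raise ValidationError(
                        f"{self.doc_id}: sentence {s} not contained/sorted "
                        f"in section {sec.section_id}")
                last = s[1]
        prev_start = -1
        seen_spans: set[tuple[int, int]] = set()
        for i, m in enumerate(self.mentions, start=1):
            if m.order_index != i:
                raise ValidationError(
                    f"{self.doc_id}: order_index not 1..n at mention {i}")
            if m.span[0] < prev_start:
                raise ValidationError(
                    f"{self.doc_id}: mention {i} not sorted by start offset")
            if m.span in seen_spans:
                raise ValidationError(
                    f"{self.doc_id}: duplicate mention span {m.span}")
            seen_spans.add(m.span)
            prev_start = m.span[0]
            if self.text[m.span[0]:m.span[1]] != m.surface:
                raise ValidationError(
                    f"{self.doc_id}: mention {i} surface {m.surface!r} != "
                    f"text slice {self.text[m.span[0]:m.span[1]]!r}")


def reindex_mentions(mentions: list[Mention]) -> list[Mention]:
    """Sort by span and reassign order_index 1..n."""
    out = []
    for i, m in enumerate(sorted(mentions, key=lambda m: m.span), start=1):
        out.append(replace(m, order_index=i))
    return out


# --- sentence segmentation ---------------------------------------------------

# tokens (lowercased, final period stripped) after which a period never ends a
# sentence; tokens containing an internal period (e.g, i.e, et.al) are treated
# as abbreviations as well
_ABBREVIATIONS = frozenset({
    "fig", "figs", "dr", "prof", "e.g", "i.e", "etc", "vs", "al", "no",
    "cf", "ca", "approx", "st", "mr", "mrs", "ms", "inc", "ltd", "spp",
})

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)|\n")


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence splitter.

    A run of ``.!?`` followed by whitespace ends a sentence when the next
    non-space character is an uppercase letter or a digit and the preceding
    token is not on the abbreviation stop-list; newlines always split.
    Returned intervals are whitespace-trimmed and cover all non-whitespace
    text. Deterministic.
    """
    bounds = [0]
    for match in _BOUNDARY_RE.finditer(text):
        end = match.end()
        if match.group() != "\n":
            tok = re.search(r"[A-Za-z.]*$", text[:match.start()]).group()
            if tok.rstrip(".").lower() in _ABBREVIATIONS or "." in tok.rstrip("."):
                continue
            nxt = text[end:].lstrip()
            if nxt and not (nxt[0].isupper() or nxt[0].isdigit()):
                continue
        bounds.append(end)
    bounds.append(len(text))
    out = []
    for a, b in zip(bounds, bounds[1:]):
        chunk = text[a:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if a + lead < b - trail:
            out.append((a + lead, b - trail))
    return out


# --- BioC XML I/O ------------------------------------------------------------

def _infons(elem) -> dict[str, str]:
    return {i.get("key"): (i.text or "") for i in elem.findall("infon")}


def read_collection(path, schema: dict | None = None) -> list[Document]:
    """Read a BioC XML collection into :class:`Document` objects.

    Every annotation whose ``type`` infon is one of ``schema['gene_types']``
    becomes a Mention; IGN infons (entrez_id, taxonomy_id, coreference_chain)
    map onto the gold fields. Annotations of the sentence type provide
    sentence boundaries; passages without them are segmented by
    :func:`segment_sentences`. Overlapping gene annotations keep the longest
    span (discards logged); gaps between passages are reconstructed as
    newlines.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(
            f"malformed BioC XML in {path}: {exc.msg} "
            f"(line {exc.lineno}, column {exc.position[1]})") from exc
    docs = []
    for delem in tree.getroot().findall("document"):
        doc_id = (delem.findtext("id") or "").strip()
        passages = []
        for pelem in delem.findall("passage"):
            offset = int(pelem.findtext("offset") or 0)
            passages.append((offset, pelem))
        passages.sort(key=lambda t: t[0])
        # rebuild the document text; inter-passage gaps become newlines
        pieces, cursor = [], 0
        sections, raw_mentions = [], []
        for i, (offset, pelem) in enumerate(passages):
            ptext = pelem.findtext("text") or ""
            if offset < cursor:
                raise ValidationError(
                    f"{doc_id}: passage offset {offset} overlaps previous "
                    "passage")
            pieces.append("\n" * (offset - cursor))
            pieces.append(ptext)
            cursor = offset + len(ptext)
            inf = _infons(pelem)
            stype = classify_section_type(
                inf.get(sch["section_type"], "") or ptext.split("\n", 1)[0])
            sec = Section(
                section_id=inf.get(sch["section_id"]) or f"s{i}",
                section_type=stype,
                span=(offset, cursor),
            )
            sentences = []
            for aelem in pelem.findall("annotation"):
                ainf = _infons(aelem)
                loc = aelem.find("location")
                if loc is None:
                    continue
                a = int(loc.get("offset"))
                b = a + int(loc.get("length"))
                atype = ainf.get("type", "")
                if not (offset <= a <= b <= cursor):
                    raise ValidationError(
                        f"{doc_id}: annotation {aelem.get('id')!r} span "
                        f"[{a},{b}) outside passage [{offset},{cursor})")
                if atype == sch["sentence_type"]:
                    sentences.append((a, b))
                elif atype in sch["gene_types"]:
                    raw_mentions.append((
                        (a, b), aelem.findtext("text") or ptext[a - offset:b - offset],
                        sec.section_id, ainf, aelem.get("id")))
            sec.sentences = sorted(sentences)
            if not sec.sentences:
                sec.sentences = [
                    (a + offset, b + offset)
                    for a, b in segment_sentences(ptext)]
            sections.append(sec)
        text = "".join(pieces)
        mentions = _resolve_mentions(doc_id, raw_mentions, sch)
        doc = Document(doc_id=doc_id, text=text, sections=sections,
                       mentions=mentions)
        doc.validate()
        docs.append(doc)
    return docs


def _resolve_mentions(doc_id, raw, sch) -> list[Mention]:
    # longest-first at equal start, then greedy left-to-right non-overlap
    raw = sorted(raw, key=lambda r: (r[0][0], -(r[0][1] - r[0][0])))
    kept, last_end = [], -1
    for span, surface, sec_id, ainf, aid in raw:
        if span[0] < last_end:
            logger.info("%s: discarding annotation %r at %s overlapping the "
                        "kept mention ending at %d", doc_id, aid, span,
                        last_end)
            continue
        kept.append((span, surface, sec_id, ainf))
        last_end = span[1]
    out = []
    for i, (span, surface, sec_id, ainf) in enumerate(kept, start=1):
        out.append(Mention(
            order_index=i, span=span, surface=surface, section_ref=sec_id,
            gold_gene_id=ainf.get(sch["entrez_id"]) or None,
            gold_taxon=ainf.get(sch["taxonomy_id"]) or None,
            gold_chain=ainf.get(sch["coreference_chain"]) or None,
            pred_ids=(tuple(ainf[sch["predicted_entrez_id"]].split(","))
                      if ainf.get(sch["predicted_entrez_id"]) else None),
        ))
    return out


def write_collection(docs: list[Document], path,
                     predictions: dict | None = None,
                     schema: dict | None = None) -> None:
    """Write documents as BioC XML.

    ``predictions`` maps doc_id to either an Assignment-like object with a
    ``links`` mapping (order_index -> gene_id or None) or a plain mapping of
    order_index to gene_id / set of gene_ids. Predicted IDs are written under
    the ``predicted_entrez_id`` infon so gold and predicted coexist.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    predictions = predictions or {}
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "genenorm"
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = "genenorm.key"
    for doc in docs:
        doc.validate()
        links = predictions.get(doc.doc_id)
        if links is not None and hasattr(links, "links"):
            links = links.links
        chains: dict[str, list[int]] = {}
        for m in doc.mentions:
            if m.gold_chain:
                chains.setdefault(m.gold_chain, []).append(m.order_index)
        delem = etree.SubElement(root, "document")
        etree.SubElement(delem, "id").text = doc.doc_id
        for sec in doc.sections:
            pelem = etree.SubElement(delem, "passage")
            _infon(pelem, sch["section_type"], sec.section_type)
            _infon(pelem, sch["section_id"], sec.section_id)
            etree.SubElement(pelem, "offset").text = str(sec.span[0])
            etree.SubElement(pelem, "text").text = \
                doc.text[sec.span[0]:sec.span[1]]
            for j, (a, b) in enumerate(sec.sentences):
                aelem = etree.SubElement(
                    pelem, "annotation", id=f"{sec.section_id}.sent{j}")
                _infon(aelem, "type", sch["sentence_type"])
                etree.SubElement(aelem, "location",
                                 offset=str(a), length=str(b - a))
                etree.SubElement(aelem, "text").text = doc.text[a:b]
            for m in doc.mentions:
                if not (sec.span[0] <= m.span[0] < sec.span[1]):
                    continue
                aelem = etree.SubElement(
                    pelem, "annotation", id=f"m{m.order_index}")
                _infon(aelem, "type", "gene")
                if m.gold_gene_id is not None:
                    _infon(aelem, sch["entrez_id"], m.gold_gene_id)
                if m.gold_taxon is not None:
                    _infon(aelem, sch["taxonomy_id"], m.gold_taxon)
                if m.gold_chain is not None:
                    _infon(aelem, sch["coreference_chain"], m.gold_chain)
                    _infon(aelem, "coreference_members",
                           ",".join(str(i) for i in chains[m.gold_chain]))
                pred = (links.get(m.order_index) if links is not None
                        else m.pred_ids)
                if pred:
                    if isinstance(pred, (set, frozenset, list, tuple)):
                        pred = ",".join(sorted(pred, key=_id_sort_key))
                    _infon(aelem, sch["predicted_entrez_id"], str(pred))
                etree.SubElement(aelem, "location", offset=str(m.span[0]),
                                 length=str(m.span[1] - m.span[0]))
                etree.SubElement(aelem, "text").text = m.surface
    Path(path).write_bytes(etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True))


def _id_sort_key(gid: str):
    s = str(gid)
    return (0, int(s)) if s.isdigit() else (1, s)


def _infon(parent, key: str, value: str) -> None:
    el = etree.SubElement(parent, "infon", key=str(key))
    el.text = str(value)
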