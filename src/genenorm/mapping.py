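"""Candidate mapping and recognition refinement.

Mapping assigns each recognized mention its candidate gene IDs: exact
dictionary matching (with orthographic variants) first, partial token-Jaccard
matching only when exact matching finds nothing. Refinement then collects the
surfaces of successfully mapped mentions into a refinement dictionary and
re-scans the whole article for unrecognized occurrences of those surfaces —
the classic failure mode being a surface that the recognizer catches
mid-sentence but misses at a sentence start, where orthographic and context
cues vanish.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from genenorm.corpus import Document, Mention, reindex_mentions
from genenorm.lexicon import Lexicon, id_sort_key

EXACT, PARTIAL, REFINED = "exact", "partial", "refined"


@dataclass(frozen=True)
class Candidate:
    gene_id: str
    method: str  # exact | partial | refined
    score: float


@dataclass
class CandidateSet:
    """Per-mention candidate lists, keyed by mention order_index."""

    by_mention: dict[int, list[Candidate]] = field(default_factory=dict)

    def get(self, order_index: int) -> list[Candidate]:
        return self.by_mention.get(order_index, [])

    def ids(self, order_index: int) -> list[str]:
        return [c.gene_id for c in self.get(order_index)]

    def set(self, order_index: int, cands: list[Candidate]) -> None:
        seen, out = set(), []
        for c in sorted(cands, key=lambda c: (-c.score,
                                              id_sort_key(c.gene_id))):
            if c.gene_id not in seen:
                seen.add(c.gene_id)
                out.append(c)
        self.by_mention[order_index] = out


def map_mentions(doc: Document, mentions: list[Mention], lexicon: Lexicon,
                 tau: float = 0.85, k: int = 5,
                 variants: bool = True) -> CandidateSet:
    """Assign candidate gene IDs to every mention.

    Exact matches short-circuit partial lookup; mentions with no candidates
    keep an empty list so evaluation still sees them.
    """
    cands = CandidateSet()
    for m in mentions:
        exact = lexicon.lookup_exact(m.surface, variants=variants)
        if exact:
            cands.set(m.order_index,
                      [Candidate(g, EXACT, 1.0) for g in exact])
        else:
            cands.set(m.order_index,
                      [Candidate(g, PARTIAL, s)
                       for g, s in lexicon.lookup_partial(m.surface, tau, k)])
    return cands


def build_refinement_dictionary(cands: CandidateSet,
                                mentions: list[Mention]
                                ) -> dict[str, set[str]]:
    """Surfaces of successfully mapped mentions -> union of candidate IDs."""
    out: dict[str, set[str]] = {}
    for m in mentions:
        ids = set(cands.ids(m.order_index))
        if ids:
            out.setdefault(m.surface, set()).update(ids)
    return out


def _sentence_case_variant(key: str) -> str | None:
    if key and key[0].isalpha():
        flipped = (key[0].lower() if key[0].isupper() else key[0].upper())
        if flipped != key[0]:
            return flipped + key[1:]
    return None


def refine_article(doc: Document, mentions: list[Mention],
                   refinement_dict: dict[str, set[str]],
                   cands: CandidateSet | None = None
                   ) -> tuple[list[Mention], CandidateSet]:
    """Add mentions for unrecognized occurrences of refinement-dictionary keys.

    Matching is exact and case-sensitive at token boundaries, with one
    extension: at a sentence start a key also matches when only the case of
    its first character differs (the sentence-initial failure mode).
    Longest match wins on ties at the same start; occurrences overlapping
    existing mentions are skipped. Existing mentions are never removed or
    altered; order_index is reassigned by offset and the candidate set is
    remapped accordingly.
    """
    cands = cands or CandidateSet()
    old_by_span = {m.span: m for m in mentions}
    old_cands_by_span = {m.span: cands.get(m.order_index) for m in mentions}

    occupied = sorted(m.span for m in mentions)
    sentence_starts = {s[0] for sec in doc.sections for s in sec.sentences}

    hits: list[tuple[int, int, str]] = []  # (start, -len, key)
    for key, ids in refinement_dict.items():
        if not ids or not key:
            continue
        patterns = [key]
        alt = _sentence_case_variant(key)
        for pat in patterns:
            rx = re.compile(r"(?<![0-9A-Za-z])" + re.escape(pat) +
                            r"(?![0-9A-Za-z])")
            for mt in rx.finditer(doc.text):
                hits.append((mt.start(), -(mt.end() - mt.start()), key))
        if alt is not None:
            rx = re.compile(r"(?<![0-9A-Za-z])" + re.escape(alt) +
                            r"(?![0-9A-Za-z])")
            for mt in rx.finditer(doc.text):
                if mt.start() in sentence_starts:
                    hits.append((mt.start(), -(mt.end() - mt.start()), key))

    def overlaps(a: int, b: int) -> bool:
        for s, e in occupied:
            if s < b and a < e:
                return True
        return False

    new_mentions = list(mentions)
    new_spans: dict[tuple[int, int], str] = {}
    for start, neglen, key in sorted(hits):
        end = start - neglen
        if overlaps(start, end):
            continue
        sec = doc.section_of(start)
        if sec is None:
            continue
        occupied.append((start, end))
        occupied.sort()
        new_spans[(start, end)] = key
        new_mentions.append(Mention(
            order_index=0, span=(start, end),
            surface=doc.text[start:end], section_ref=sec.section_id))

    new_mentions = reindex_mentions(new_mentions)
    out_cands = CandidateSet()
    for m in new_mentions:
        if m.span in old_by_span:
            out_cands.set(m.order_index, old_cands_by_span[m.span])
        else:
            key = new_spans[m.span]
            out_cands.set(m.order_index,
                          [Candidate(g, REFINED, 1.0)
                           for g in sorted(refinement_dict[key],
                                           key=id_sort_key)])
    return new_mentions, out_cands
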