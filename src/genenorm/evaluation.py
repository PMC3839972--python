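"""Instance-level scoring of recognition and normalization.

Scores are computed over mention instances, not document-level ID lists:
every (span, ID) prediction is compared against the gold mention it matches.
Span matching is either ``exact`` (identical boundaries) or ``approximate``
(at least one overlapping character, one-to-one greedy matching by overlap
length). Mentions without a gold ID are the corpus' non-human placeholders:
linking them to any ID is a false positive, leaving them unlinked costs
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from genenorm.corpus import Document, Mention
from genenorm.errors import ValidationError

APPROXIMATE, EXACT = "approximate", "exact"


@dataclass
class EvalReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def zero_denominator(self) -> bool:
        return (self.tp + self.fp == 0) or (self.tp + self.fn == 0)

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "EvalReport") -> "EvalReport":
        return EvalReport(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "zero_denominator": self.zero_denominator}


def _as_doc_map(x) -> dict:
    return x if isinstance(x, dict) else {"": x}


def _check_docs(gold: dict, pred: dict) -> None:
    extra = set(pred) - set(gold)
    if extra:
        raise ValidationError(
            "predictions for documents absent from gold: "
            + ", ".join(sorted(map(str, extra))))


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def match_spans(gold_spans: list[tuple[int, int]],
                pred_spans: list[tuple[int, int]],
                criterion: str = APPROXIMATE
                ) -> list[tuple[int, int]]:
    """One-to-one span matching; returns (gold_idx, pred_idx) pairs.

    Approximate: any overlap counts, matched greedily by overlap length
    (ties to the earlier gold, then earlier pred span). Exact: identical
    spans only.
    """
    if criterion not in (APPROXIMATE, EXACT):
        raise ValidationError(f"unknown criterion {criterion!r}")
    pairs = []
    for gi, g in enumerate(gold_spans):
        for pi, p in enumerate(pred_spans):
            if criterion == EXACT:
                if g == p:
                    pairs.append((0, gi, pi))
            else:
                ov = _overlap(g, p)
                if ov > 0:
                    pairs.append((-ov, gi, pi))
    pairs.sort()
    used_g, used_p, out = set(), set(), []
    for _key, gi, pi in pairs:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        out.append((gi, pi))
    return out


def score_recognition(gold, pred, criterion: str = APPROXIMATE) -> EvalReport:
    """Mention-boundary PRF; ``gold``/``pred`` map doc_id -> list of Mention
    (bare lists are treated as a single document)."""
    gold, pred = _as_doc_map(gold), _as_doc_map(pred)
    _check_docs(gold, pred)
    rep = EvalReport()
    for doc_id, gms in gold.items():
        pms = pred.get(doc_id, [])
        matched = match_spans([m.span for m in gms], [m.span for m in pms],
                              criterion)
        rep.tp += len(matched)
        rep.fn += len(gms) - len(matched)
        rep.fp += len(pms) - len(matched)
    return rep


def _pred_ids(link) -> set[str]:
    if link is None:
        return set()
    if isinstance(link, (set, frozenset, list, tuple)):
        return {str(g) for g in link}
    return {str(link)}


def score_normalization(gold, pred_mentions, pred_links,
                        criterion: str = APPROXIMATE) -> EvalReport:
    """Instance-level normalization PRF.

    ``pred_links`` maps doc_id -> {order_index: gene_id | set | None}
    (aggregated document-level predictions carry ID sets; each predicted ID
    counts as one prediction). A prediction is a true positive iff its span
    matches a gold mention under ``criterion`` and the ID equals the gold ID.
    """
    gold = _as_doc_map(gold)
    pred_mentions = _as_doc_map(pred_mentions)
    if "" in pred_mentions:  # bare-list form: links are one flat mapping
        pred_links = {"": pred_links}
    _check_docs(gold, pred_mentions)
    rep = EvalReport()
    for doc_id, gms in gold.items():
        pms = pred_mentions.get(doc_id, [])
        links = pred_links.get(doc_id, {})
        matched = match_spans([m.span for m in gms], [m.span for m in pms],
                              criterion)
        matched_g = {gi for gi, _ in matched}
        matched_p = {pi for _, pi in matched}
        for gi, pi in matched:
            gold_id = gms[gi].gold_gene_id
            ids = _pred_ids(links.get(pms[pi].order_index))
            if gold_id is not None and str(gold_id) in ids:
                rep.tp += 1
                rep.fp += len(ids) - 1
            else:
                rep.fp += len(ids)
                if gold_id is not None:
                    rep.fn += 1
        for gi, m in enumerate(gms):
            if gi not in matched_g and m.gold_gene_id is not None:
                rep.fn += 1
        for pi, m in enumerate(pms):
            if pi not in matched_p:
                rep.fp += len(_pred_ids(links.get(m.order_index)))
    return rep


def aggregate_document_level(mentions: list[Mention],
                             links: dict[int, object]
                             ) -> dict[int, set[str]]:
    """Document-level aggregation of instance links.

    Collects the union of linked IDs per surface name and assigns that full
    set back to every mention of the surface (mentions of surfaces never
    linked anywhere get an empty set).
    """
    by_surface: dict[str, set[str]] = {}
    for m in mentions:
        by_surface.setdefault(m.surface, set()).update(
            _pred_ids(links.get(m.order_index)))
    return {m.order_index: set(by_surface[m.surface]) for m in mentions}


def _doc_sentences(doc: Document) -> list[tuple[int, int]]:
    out = []
    for sec in doc.sections:
        out.extend(sec.sentences)
    return sorted(out)


def predicted_pairs(doc: Document, mentions: list[Mention],
                    links: dict[int, object]
                    ) -> set[tuple[int, frozenset]]:
    """Unordered ID pairs of linked mentions co-occurring in one sentence,
    keyed by document-global sentence index."""
    sentences = _doc_sentences(doc)
    by_sent: dict[int, list[set[str]]] = {}
    for m in mentions:
        ids = _pred_ids(links.get(m.order_index))
        if not ids:
            continue
        for si, (a, b) in enumerate(sentences):
            if a <= m.span[0] < b:
                by_sent.setdefault(si, []).append(ids)
                break
    pairs: set[tuple[int, frozenset]] = set()
    for si, id_sets in by_sent.items():
        for i in range(len(id_sets)):
            for j in range(i + 1, len(id_sets)):
                for a in id_sets[i]:
                    for b in id_sets[j]:
                        if a != b:
                            pairs.add((si, frozenset((a, b))))
    return pairs


def score_pairs(docs: list[Document], gold_pairs, mentions_by_doc,
                links_by_doc) -> EvalReport:
    """PRF of sentence-level interaction-pair extraction.

    ``gold_pairs`` is a set of (doc_id, sentence_index, frozenset{id_a,
    id_b}); predicted pairs come from linked mentions co-occurring in a
    sentence (ID-set links from aggregation expand combinatorially).
    """
    gold = {(d, s, frozenset(map(str, p))) for d, s, p in gold_pairs}
    pred: set[tuple[str, int, frozenset]] = set()
    for doc in docs:
        links = links_by_doc.get(doc.doc_id, {})
        mentions = mentions_by_doc.get(doc.doc_id, doc.mentions)
        for si, pair in predicted_pairs(doc, mentions, links):
            pred.add((doc.doc_id, si, pair))
    return EvalReport(tp=len(gold & pred), fp=len(pred - gold),
                      fn=len(gold - pred))
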