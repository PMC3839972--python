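"""End-to-end wiring: recognize -> map -> refine -> disambiguate."""

from __future__ import annotations

import logging

from genenorm.collective import WeightConfig, normalize_document
from genenorm.corpus import Document, Mention
from genenorm.lexicon import GeneKB, Lexicon
from genenorm.mapping import (build_refinement_dictionary, map_mentions,
                              refine_article)

logger = logging.getLogger(__name__)


def run_pipeline(docs: list[Document], lexicon: Lexicon, kb: GeneKB,
                 weights: WeightConfig | None = None,
                 mentions_by_doc: dict[str, list[Mention]] | None = None,
                 refinement: bool = True, tau: float = 0.85, k: int = 5,
                 solver: str = "local_search", seed: int = 0,
                 restarts: int = 3
                 ) -> tuple[dict[str, list[Mention]], dict[str, dict]]:
    """Normalize every document; returns (mentions, links) keyed by doc_id.

    ``mentions_by_doc`` is the recognizer output (defaults to the documents'
    own mention annotations, i.e. an oracle recognizer). Unresolvable
    mentions keep a None link so evaluation sees them as recognition-only.
    """
    weights = weights or WeightConfig()
    out_mentions: dict[str, list[Mention]] = {}
    out_links: dict[str, dict] = {}
    for i, doc in enumerate(docs):
        mentions = (mentions_by_doc[doc.doc_id]
                    if mentions_by_doc is not None else doc.mentions)
        cands = map_mentions(doc, mentions, lexicon, tau=tau, k=k)
        if refinement:
            refdict = build_refinement_dictionary(cands, mentions)
            mentions, cands = refine_article(doc, mentions, refdict, cands)
        assignment = normalize_document(
            doc, mentions, cands, kb, weights=weights, solver=solver,
            seed=seed + i, restarts=restarts)
        out_mentions[doc.doc_id] = mentions
        out_links[doc.doc_id] = dict(assignment.links)
        logger.info("%s: %d mentions, %d linked, score %.3f", doc.doc_id,
                    len(mentions),
                    sum(1 for v in assignment.links.values() if v),
                    assignment.score)
    return out_mentions, out_links
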