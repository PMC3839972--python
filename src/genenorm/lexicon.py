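"""Gene-name lexicon, orthographic variants, and the partial-match index.

The lexicon maps surface names (symbols plus synonyms) to gene-database IDs
and species. Exact lookup may be widened by a deterministic orthographic
variant closure (case, hyphen/space, Greek letters, Roman numerals, plurals,
flanking head nouns). Partial lookup scores token-set Jaccard between the
query and every lexicon name through an inverted token index.

Tabular layouts follow the NCBI ``gene_info`` column style:

* gene table (TSV): ``tax_id  gene_id  symbol  synonyms`` (pipe-separated)
* GO table (TSV): ``gene_id  go_term_name``
* PPI table (TSV): ``gene_id_a  gene_id_b``
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from genenorm.errors import ParameterError, SchemaError

logger = logging.getLogger(__name__)

_GREEK = {
    "alpha": ("α", "a"), "beta": ("β", "b"), "gamma": ("γ", "g"),
    "delta": ("δ", "d"), "epsilon": ("ε", "e"), "zeta": ("ζ", "z"),
    "eta": ("η", "e"), "theta": ("θ", "t"), "iota": ("ι", "i"),
    "kappa": ("κ", "k"), "lambda": ("λ", "l"), "mu": ("μ", "m"),
    "nu": ("ν", "n"), "xi": ("ξ", "x"), "omicron": ("ο", "o"),
    "pi": ("π", "p"), "rho": ("ρ", "r"), "sigma": ("σ", "s"),
    "tau": ("τ", "t"), "upsilon": ("υ", "u"), "phi": ("φ", "f"),
    "chi": ("χ", "c"), "psi": ("ψ", "p"), "omega": ("ω", "w"),
}
_GREEK_SYMBOL = {sym: (name, latin) for name, (sym, latin) in _GREEK.items()}

_ROMAN = {"i": "1", "ii": "2", "iii": "3", "iv": "4", "v": "5",
          "vi": "6", "vii": "7", "viii": "8", "ix": "9", "x": "10"}
_ARABIC = {v: k.upper() for k, v in _ROMAN.items()}

_FLANK = frozenset({"protein", "gene", "antigen"})

_SEP_SPLIT = re.compile(r"([-\s]+)")
_WORD_TOKEN = re.compile(r"[0-9A-Za-zα-ωΑ-Ω]+")
_ALNUM_SPLIT = re.compile(r"(?<=[^\W\d_])(?=\d)|(?<=\d)(?=[^\W\d_])")


def _token_substitutions(tok: str, trailing: bool) -> set[str]:
    """Alternative spellings of a single hyphen/space-delimited token."""
    out = set()
    low = tok.lower()
    if low in _GREEK:
        sym, latin = _GREEK[low]
        out.update({sym, latin})
    elif tok in _GREEK_SYMBOL:
        name, latin = _GREEK_SYMBOL[tok]
        out.update({name, latin})
    if trailing:
        if low in _ROMAN:
            out.add(_ROMAN[low])
        elif tok in _ARABIC:
            out.add(_ARABIC[tok])
    if len(tok) > 3 and low.endswith("s") and not low.endswith("ss"):
        out.add(tok[:-1])
    return out - {tok}


def generate_variants(name: str) -> set[str]:
    """Deterministic one-pass orthographic variant closure of ``name``.

    Always contains the input and its case-folded form; never the empty
    string. Rules are applied once over the accumulated set (no recursive
    re-expansion), which keeps the closure finite and idempotent on its own
    case-folded outputs.
    """
    if not name:
        raise ParameterError("generate_variants: empty name")
    variants = {name}

    # strip flanking head-noun tokens (protein/gene/antigen)
    parts = [p for p in _SEP_SPLIT.split(name)]
    words = [p for p in parts if p and not p.isspace() and p != "-"]
    if len(words) > 1:
        if words[0].lower() in _FLANK:
            variants.add(name[len(words[0]):].lstrip(" -"))
        if words[-1].lower() in _FLANK:
            variants.add(name[: len(name) - len(words[-1])].rstrip(" -"))

    # per-token substitutions (Greek, Roman/Arabic on trailing token, plural)
    for base in list(variants):
        parts = _SEP_SPLIT.split(base)
        word_idx = [i for i, p in enumerate(parts)
                    if p and not re.fullmatch(r"[-\s]+", p)]
        for i in word_idx:
            trailing = i == word_idx[-1]
            for sub in _token_substitutions(parts[i], trailing):
                variants.add("".join(parts[:i] + [sub] + parts[i + 1:]))

    # hyphen <-> space <-> deletion
    for base in list(variants):
        if "-" in base:
            variants.add(base.replace("-", " "))
            variants.add(base.replace("-", ""))
        if " " in base:
            variants.add(base.replace(" ", "-"))
            variants.add(base.replace(" ", ""))

    variants |= {v.lower() for v in variants} | {v.upper() for v in variants}
    variants.discard("")
    return variants


def tokenize(name: str, split_alnum: bool = False) -> list[str]:
    """Word tokens of a name (split on non-alphanumeric).

    With ``split_alnum`` each token is additionally split at letter-digit
    transitions ("p53" -> "p", "53"); used for index postings only.
    """
    toks = _WORD_TOKEN.findall(name)
    if split_alnum:
        out = []
        for t in toks:
            out.extend(p for p in _ALNUM_SPLIT.split(t) if p)
        return out
    return toks


def _normalize_token(tok: str) -> str:
    low = tok.lower()
    if low in _GREEK:
        return _GREEK[low][1]
    if tok in _GREEK_SYMBOL:
        return _GREEK_SYMBOL[tok][1]
    if low in _ROMAN:
        return _ROMAN[low]
    if len(low) > 3 and low.endswith("s") and not low.endswith("ss"):
        return low[:-1]
    return low


def token_set(name: str) -> frozenset[str]:
    """Variant-normalized word-token set used for Jaccard scoring."""
    return frozenset(_normalize_token(t) for t in tokenize(name))


def id_sort_key(gid: str):
    s = str(gid)
    return (0, int(s)) if s.isdigit() else (1, s)


@dataclass
class LexiconEntry:
    gene_id: str
    taxon: str
    names: set[str]

    def __post_init__(self):
        if not self.names:
            raise ParameterError(f"entry {self.gene_id}: names must be "
                                 "non-empty")


@dataclass
class GeneKB:
    """Per-gene knowledge: GO term names, PPI partners, species."""

    go_terms: dict[str, set[str]] = field(default_factory=dict)
    ppi: set[tuple[str, str]] = field(default_factory=set)
    taxon_of: dict[str, str] = field(default_factory=dict)

    def add_ppi(self, a: str, b: str) -> None:
        a, b = str(a), str(b)
        if a != b:
            self.ppi.add((a, b))
            self.ppi.add((b, a))

    def interacts(self, a: str, b: str) -> bool:
        return (str(a), str(b)) in self.ppi


class TokenIndex:
    """Inverted token index over lexicon names for partial matching.

    Postings map each (letter/digit-split) token and each whole surface to
    the set of (gene_id, name) pairs containing it; rebuilding from the same
    lexicon reproduces identical postings.
    """

    def __init__(self, pairs: list[tuple[str, str]]):
        self.postings: dict[str, set[tuple[str, str]]] = {}
        self.name_tokens: dict[tuple[str, str], frozenset[str]] = {}
        for gid, name in pairs:
            key = (gid, name)
            self.name_tokens[key] = token_set(name)
            for tok in set(tokenize(name.lower(), split_alnum=True)) | {name.lower()}:
                self.postings.setdefault(tok, set()).add(key)


class Lexicon:
    """Queryable gene-name lexicon with variant and partial matching."""

    def __init__(self, entries: list[LexiconEntry]):
        self.entries = list(entries)
        self.by_id = {e.gene_id: e for e in self.entries}
        self._exact: dict[str, set[str]] = {}
        self._variant_index: dict[str, set[str]] = {}
        pairs = []
        for e in self.entries:
            for name in e.names:
                pairs.append((e.gene_id, name))
                self._exact.setdefault(name, set()).add(e.gene_id)
                for v in generate_variants(name):
                    self._variant_index.setdefault(v, set()).add(e.gene_id)
        self.token_index = TokenIndex(pairs)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def taxon_of(self, gene_id: str) -> str | None:
        e = self.by_id.get(str(gene_id))
        return e.taxon if e else None

    def lookup_exact(self, surface: str, variants: bool = True) -> set[str]:
        """Gene IDs owning ``surface`` (or, with variants, any variant)."""
        if not variants:
            return set(self._exact.get(surface, ()))
        hits: set[str] = set()
        for v in generate_variants(surface):
            hits |= self._variant_index.get(v, set())
        return hits

    def lookup_partial(self, surface: str, tau: float = 0.85,
                       k: int = 5) -> list[tuple[str, float]]:
        """Token-set Jaccard partial matches.

        Returns the best-scoring name per gene with score >= ``tau``,
        sorted by (score desc, gene_id asc), truncated to ``k``.
        """
        if not 0.0 <= tau <= 1.0:
            raise ParameterError(f"tau={tau} outside [0, 1]")
        q_tokens = token_set(surface)
        if not q_tokens:
            return []
        cand: set[tuple[str, str]] = set()
        idx = self.token_index
        for tok in set(tokenize(surface.lower(), split_alnum=True)) | {surface.lower()}:
            cand |= idx.postings.get(tok, set())
        best: dict[str, float] = {}
        for key in cand:
            n_tokens = idx.name_tokens[key]
            union = len(q_tokens | n_tokens)
            score = len(q_tokens & n_tokens) / union if union else 0.0
            gid = key[0]
            if score > best.get(gid, -1.0):
                best[gid] = score
        out = [(gid, s) for gid, s in best.items() if s >= tau]
        out.sort(key=lambda t: (-t[1], id_sort_key(t[0])))
        return out[:k] if k is not None else out


def _read_tsv(path, required: tuple[str, ...]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = [c.lstrip("#") for c in (reader.fieldnames or [])]
        missing = [c for c in required if c not in cols]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {', '.join(missing)}")
        rows = []
        for row in reader:
            rows.append({k.lstrip("#"): (v or "").strip()
                         for k, v in row.items() if k is not None})
        return rows


def load_lexicon(gene_table, go_table=None, ppi_table=None
                 ) -> tuple[Lexicon, GeneKB]:
    """Load lexicon and gene knowledge from TSV tables.

    Duplicate gene_id rows are merged (warning logged); PPI pairs are
    symmetrized; missing GO/PPI tables yield empty knowledge.
    """
    merged: dict[str, LexiconEntry] = {}
    for row in _read_tsv(gene_table, ("tax_id", "gene_id", "symbol",
                                      "synonyms")):
        gid = row["gene_id"]
        names = {row["symbol"]} | {
            s for s in row["synonyms"].split("|") if s and s != "-"}
        names.discard("")
        if gid in merged:
            logger.warning("duplicate gene_id %s in %s: merging synonym "
                           "sets", gid, gene_table)
            merged[gid].names |= names
        else:
            merged[gid] = LexiconEntry(gene_id=gid, taxon=row["tax_id"],
                                       names=names)
    entries = sorted(merged.values(), key=lambda e: id_sort_key(e.gene_id))
    kb = GeneKB(taxon_of={e.gene_id: e.taxon for e in entries})
    if go_table is not None and Path(go_table).exists():
        for row in _read_tsv(go_table, ("gene_id", "go_term_name")):
            kb.go_terms.setdefault(row["gene_id"], set()).add(
                row["go_term_name"])
    if ppi_table is not None and Path(ppi_table).exists():
        for row in _read_tsv(ppi_table, ("gene_id_a", "gene_id_b")):
            kb.add_ppi(row["gene_id_a"], row["gene_id_b"])
    return Lexicon(entries), kb
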