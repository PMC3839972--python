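"""Collective disambiguation: grounding weighted formulae and MAP inference.

All candidate IDs of all mentions in one article form a network. Observed
atoms (Candidate, MostGOTerms, InfoRichSection, Interacts, SpeciesCue,
co-reference features) are extracted from the document; hidden atoms are
NormalizeTo(x, id), Coreference(x, y) and HumanGene(x). A fixed, code-
registered family of weighted first-order formulae is grounded into weighted
clauses over the hidden atoms:

individual
    ``candidate_prior`` / ``partial_prior`` / ``refined_prior`` — a candidate
    may be linked (weight scaled by the mapping score);
    ``most_go_terms`` — prefer the candidate with the most GO term names
    found in the section; ``nonhuman_candidate`` — penalize linking a
    candidate whose species is not human.
human-gene evidence
    ``species_cue_human`` / ``species_cue_nonhuman`` — nearest species word
    in the mention's sentence; ``default_human`` — weak prior for mentions
    with no species cue.
co-reference evidence
    ``coref_surface`` / ``coref_case`` / ``coref_abbrev`` /
    ``coref_shared_id`` — each observed feature softly implies
    Coreference(x, y).
intra-section collectives
    ``salience`` — a later mention inherits an ID already linked earlier in
    the same section; ``transitivity`` — co-referent mentions share one ID;
    ``ppi`` — prefer candidate pairs with a known protein-protein
    interaction in the same section.
cross-section collectives
    ``salience_cross`` / ``transitivity_cross`` / ``ppi_cross`` — the same
    dependencies seeded from information-rich sections (abstract,
    introduction) into other sections.
hard constraints
    at most one NormalizeTo per mention; NormalizeTo(x, _) implies
    HumanGene(x) (linking is optional, but only human mentions may link).

MAP inference returns the assignment maximizing the summed weight of
satisfied soft clauses subject to the hard ones, by exhaustive enumeration
(exact, small networks) or seeded greedy hill-climbing with random restarts
and at-most-one swap moves.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace

import yaml

from genenorm.corpus import Document, Mention
from genenorm.errors import (ConfigError, InfeasibleError, ParameterError,
                             TrainingError)
from genenorm.lexicon import GeneKB, Lexicon, id_sort_key
from genenorm.mapping import (EXACT, PARTIAL, REFINED, CandidateSet,
                              map_mentions)

HUMAN_TAXON = "9606"

#: species keyword -> NCBI taxonomy ID, for the sentence-level species cue
SPECIES_WORDS = {
    "human": "9606", "humans": "9606", "patient": "9606", "patients": "9606",
    "mouse": "10090", "mice": "10090", "murine": "10090",
    "rat": "10116", "rats": "10116",
    "bovine": "9913", "cattle": "9913",
    "yeast": "559292", "zebrafish": "7955",
    "drosophila": "7227", "fly": "7227",
    "chicken": "9031", "rabbit": "9986",
}

HIDDEN_PREDICATES = ("NormalizeTo", "Coreference", "HumanGene")

SOFT_FORMULAE = (
    "candidate_prior", "partial_prior", "refined_prior", "most_go_terms",
    "nonhuman_candidate", "species_cue_human", "species_cue_nonhuman",
    "default_human", "coref_surface", "coref_case", "coref_abbrev",
    "coref_shared_id", "salience", "transitivity", "ppi",
    "salience_cross", "transitivity_cross", "ppi_cross",
)
HARD_FORMULAE = ("unique", "human_filter")

_INDIVIDUAL = frozenset({
    "candidate_prior", "partial_prior", "refined_prior", "most_go_terms",
    "nonhuman_candidate", "species_cue_human", "species_cue_nonhuman",
    "default_human", "coref_surface", "coref_case", "coref_abbrev",
    "coref_shared_id"})
_INTRA = frozenset({"salience", "transitivity", "ppi"})
_CROSS = frozenset({"salience_cross", "transitivity_cross", "ppi_cross"})

DEFAULT_WEIGHTS = {
    "candidate_prior": 1.0,
    "partial_prior": 0.8,
    "refined_prior": 0.7,
    "most_go_terms": 0.8,
    "nonhuman_candidate": 1.5,
    "species_cue_human": 1.0,
    "species_cue_nonhuman": 2.5,
    "default_human": 0.2,
    "coref_surface": 0.6,
    "coref_case": 0.3,
    "coref_abbrev": 0.8,
    "coref_shared_id": 0.2,
    "salience": 0.6,
    "transitivity": 0.8,
    "ppi": 0.5,
    "salience_cross": 0.4,
    "transitivity_cross": 0.4,
    "ppi_cross": 0.3,
}


@dataclass(frozen=True, order=False)
class GroundAtom:
    predicate: str
    args: tuple

    def __repr__(self):
        return f"{self.predicate}({', '.join(map(str, self.args))})"


def _arg_key(a):
    if isinstance(a, int):
        return (0, a, "")
    s = str(a)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def atom_sort_key(atom: GroundAtom):
    try:
        rank = HIDDEN_PREDICATES.index(atom.predicate)
    except ValueError:
        rank = len(HIDDEN_PREDICATES)
    return (rank, atom.predicate, tuple(_arg_key(a) for a in atom.args))


@dataclass
class GroundFormula:
    """One grounding: a weighted disjunction of literals over hidden atoms.

    ``literals`` are (atom_index, positive) pairs; ``multiplier`` is the
    evidence-dependent scale (e.g. a partial-match score) so that the
    effective weight is ``weight(formula_id) * multiplier``. Hard formulae
    must always be satisfied.
    """

    formula_id: str
    literals: tuple[tuple[int, bool], ...]
    weight: float
    hard: bool = False
    multiplier: float = 1.0


@dataclass
class GroundNetwork:
    atoms: list[GroundAtom] = field(default_factory=list)
    clauses: list[GroundFormula] = field(default_factory=list)
    #: at-most-one groups (lists of atom indices), for solver swap moves
    groups: list[list[int]] = field(default_factory=list)

    @property
    def n_hidden(self) -> int:
        return len(self.atoms)

    def dump(self) -> str:
        lines = []
        for c in self.clauses:
            lits = " v ".join(
                ("" if pos else "!") + repr(self.atoms[i])
                for i, pos in c.literals)
            tag = "HARD" if c.hard else f"{c.weight:+.4f}"
            lines.append(f"[{c.formula_id}] {tag}: {lits}")
        return "\n".join(lines)


@dataclass
class WeightConfig:
    """Soft-formula weights plus group-enable flags.

    Hard formulae (uniqueness, human filtering) are structural and carry no
    weight. Disabling a group removes its groundings entirely.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))
    enable_individual: bool = True
    enable_intra: bool = True
    enable_cross: bool = True

    def __post_init__(self):
        unknown = set(self.weights) - set(SOFT_FORMULAE)
        if unknown:
            raise ConfigError(
                f"unknown formula_id(s) in weights: {sorted(unknown)}")
        bad = set(self.weights) & set(HARD_FORMULAE)
        if bad:
            raise ConfigError(f"hard formulae are not reweightable: {bad}")

    def weight(self, formula_id: str) -> float:
        return self.weights.get(formula_id, 0.0)

    def enabled(self, formula_id: str) -> bool:
        if formula_id in _INDIVIDUAL:
            return self.enable_individual
        if formula_id in _INTRA:
            return self.enable_intra
        if formula_id in _CROSS:
            return self.enable_cross
        return True

    def to_yaml(self, path) -> None:
        data = {"weights": {k: float(v) for k, v in sorted(
                    self.weights.items())},
                "enable_individual": self.enable_individual,
                "enable_intra": self.enable_intra,
                "enable_cross": self.enable_cross}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "WeightConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(weights=data.get("weights", dict(DEFAULT_WEIGHTS)),
                   enable_individual=data.get("enable_individual", True),
                   enable_intra=data.get("enable_intra", True),
                   enable_cross=data.get("enable_cross", True))


@dataclass
class Assignment:
    """MAP solution: per-mention link, co-reference pairs, human flags."""

    links: dict[int, str | None] = field(default_factory=dict)
    coref: set[tuple[int, int]] = field(default_factory=set)
    human: set[int] = field(default_factory=set)
    score: float = 0.0
    atom_values: dict[GroundAtom, bool] = field(default_factory=dict)

    @classmethod
    def from_atoms(cls, atoms: list[GroundAtom], values: list[bool],
                   score: float) -> "Assignment":
        a = cls(score=score)
        for atom, v in zip(atoms, values):
            a.atom_values[atom] = v
            if atom.predicate == "NormalizeTo":
                x, gid = atom.args
                a.links.setdefault(x, None)
                if v:
                    a.links[x] = str(gid)
            elif atom.predicate == "HumanGene":
                if v:
                    a.human.add(atom.args[0])
            elif atom.predicate == "Coreference" and v:
                x, y = atom.args
                a.coref.add((min(x, y), max(x, y)))
        return a


# --- evidence extraction ------------------------------------------------------

_WORD_RE = re.compile(r"[0-9A-Za-z]+")


def extract_evidence(doc: Document, mentions: list[Mention],
                     cands: CandidateSet, kb: GeneKB) -> set[GroundAtom]:
    """Build the observed ground atoms for one document."""
    atoms: set[GroundAtom] = set()
    sec_of: dict[int, str] = {}
    cand_ids_by_sec: dict[str, set[str]] = {}
    all_cand_ids: set[str] = set()
    by_index = {m.order_index: m for m in mentions}

    for m in mentions:
        sec_of[m.order_index] = m.section_ref
        for c in cands.get(m.order_index):
            atoms.add(GroundAtom("Candidate",
                                 (m.order_index, c.gene_id, m.section_ref)))
            if c.method == PARTIAL:
                atoms.add(GroundAtom("PartialCandidate",
                                     (m.order_index, c.gene_id)))
            elif c.method == REFINED:
                atoms.add(GroundAtom("RefinedCandidate",
                                     (m.order_index, c.gene_id)))
            cand_ids_by_sec.setdefault(m.section_ref, set()).add(c.gene_id)
            all_cand_ids.add(c.gene_id)

    # species / section / interaction evidence
    for gid in sorted(all_cand_ids, key=id_sort_key):
        taxon = kb.taxon_of.get(gid)
        if taxon is not None and taxon != HUMAN_TAXON:
            atoms.add(GroundAtom("NonHumanId", (gid,)))
    for sec in doc.sections:
        if sec.section_type in ("abstract", "introduction"):
            atoms.add(GroundAtom("InfoRichSection", (sec.section_id,)))
    for a, b in kb.ppi:
        if a in all_cand_ids and b in all_cand_ids:
            atoms.add(GroundAtom("Interacts", (a, b)))

    # MostGOTerms: per section, the argmax candidate IDs by GO-name hits
    for sec in doc.sections:
        ids = cand_ids_by_sec.get(sec.section_id)
        if not ids:
            continue
        sec_text = doc.text[sec.span[0]:sec.span[1]].lower()
        counts = {}
        for gid in ids:
            hits = sum(1 for term in kb.go_terms.get(gid, ())
                       if term.lower() in sec_text)
            if hits:
                counts[gid] = hits
        if counts:
            top = max(counts.values())
            for gid, c in counts.items():
                if c == top:  # ties are real: all argmax IDs are true
                    atoms.add(GroundAtom("MostGOTerms",
                                         (gid, sec.section_id)))

    # species cue: nearest species keyword in the mention's sentence
    for m in mentions:
        if not cands.get(m.order_index):
            continue
        sent = doc.sentence_of(m.span[0])
        if sent is None:
            continue
        stext = doc.text[sent[0]:sent[1]]
        best = None
        for w in _WORD_RE.finditer(stext):
            # whole alphabetic tokens only: "MICE28" is a symbol, not a cue
            if not w.group().isalpha():
                continue
            taxon = SPECIES_WORDS.get(w.group().lower())
            if taxon is None:
                continue
            pos = sent[0] + w.start()
            dist = min(abs(pos - m.span[0]), abs(pos - m.span[1]))
            if best is None or dist < best[0]:
                best = (dist, taxon)
        if best is not None:
            atoms.add(GroundAtom("SpeciesCue", (m.order_index, best[1])))

    # co-reference features over mention pairs
    order = sorted(by_index)
    for i, x in enumerate(order):
        mx = by_index[x]
        ids_x = set(cands.ids(x))
        for y in order[i + 1:]:
            my = by_index[y]
            ids_y = set(cands.ids(y))
            shared = bool(ids_x & ids_y)
            if mx.surface == my.surface:
                atoms.add(GroundAtom("CorefSurface", (x, y)))
            elif mx.surface.lower() == my.surface.lower():
                atoms.add(GroundAtom("CorefCase", (x, y)))
            if shared and mx.section_ref == my.section_ref:
                atoms.add(GroundAtom("CorefSharedId", (x, y)))
            if y == x + 1 and _is_abbrev_pair(doc, mx, my):
                atoms.add(GroundAtom("CorefAbbrev", (x, y)))
    return atoms


def _is_abbrev_pair(doc: Document, full: Mention, abbr: Mention) -> bool:
    """full-name mention immediately followed by "(ABBR)" with matching
    initial letter."""
    between = doc.text[full.span[1]:abbr.span[0]]
    if between.strip() != "(":
        return False
    if abbr.span[1] >= len(doc.text) or doc.text[abbr.span[1]] != ")":
        return False
    fa = next((ch for ch in full.surface if ch.isalpha()), "")
    aa = next((ch for ch in abbr.surface if ch.isalpha()), "")
    return bool(fa) and fa.lower() == aa.lower()


# --- grounding ----------------------------------------------------------------

def ground_formulae(atoms: set[GroundAtom], weights: WeightConfig,
                    cands: CandidateSet | None = None) -> GroundNetwork:
    """Ground the formula family into a weighted clause network.

    Groundings vacuously satisfied by the evidence are never created (all
    observed literals are folded in here). ``cands`` supplies partial-match
    scores for the ``partial_prior`` multiplier.
    """
    net = GroundNetwork()
    atom_index: dict[GroundAtom, int] = {}

    def hidden(pred, *args) -> int:
        atom = GroundAtom(pred, tuple(args))
        if atom not in atom_index:
            atom_index[atom] = len(net.atoms)
            net.atoms.append(atom)
        return atom_index[atom]

    by_pred: dict[str, list[GroundAtom]] = {}
    for a in sorted(atoms, key=atom_sort_key):
        by_pred.setdefault(a.predicate, []).append(a)

    cand_atoms = by_pred.get("Candidate", [])
    partial = {(a.args[0], a.args[1])
               for a in by_pred.get("PartialCandidate", [])}
    refined = {(a.args[0], a.args[1])
               for a in by_pred.get("RefinedCandidate", [])}
    nonhuman_ids = {a.args[0] for a in by_pred.get("NonHumanId", [])}
    most_go = {(a.args[0], a.args[1])
               for a in by_pred.get("MostGOTerms", [])}
    rich = {a.args[0] for a in by_pred.get("InfoRichSection", [])}
    interacts = {(a.args[0], a.args[1])
                 for a in by_pred.get("Interacts", [])}
    cues: dict[int, str] = {a.args[0]: a.args[1]
                            for a in by_pred.get("SpeciesCue", [])}

    cand_of: dict[int, list[tuple[str, str]]] = {}  # x -> [(id, sec)]
    for a in cand_atoms:
        x, gid, sec = a.args
        cand_of.setdefault(x, []).append((gid, sec))

    n_atoms: dict[tuple[int, str], int] = {}
    h_atoms: dict[int, int] = {}
    for x in sorted(cand_of):
        for gid, _sec in cand_of[x]:
            n_atoms[(x, gid)] = hidden("NormalizeTo", x, gid)
        h_atoms[x] = hidden("HumanGene", x)

    coref_feats: dict[tuple[int, int], list[str]] = {}
    for pred, fid in (("CorefSurface", "coref_surface"),
                      ("CorefCase", "coref_case"),
                      ("CorefAbbrev", "coref_abbrev"),
                      ("CorefSharedId", "coref_shared_id")):
        for a in by_pred.get(pred, []):
            x, y = a.args
            if x in cand_of and y in cand_of:
                coref_feats.setdefault((x, y), []).append(fid)
    c_atoms: dict[tuple[int, int], int] = {
        pair: hidden("Coreference", *pair) for pair in sorted(coref_feats)}

    def add(fid, lits, multiplier=1.0, hard=False):
        if not hard and not weights.enabled(fid):
            return
        w = float("inf") if hard else weights.weight(fid) * multiplier
        net.clauses.append(GroundFormula(
            formula_id=fid, literals=tuple(lits),
            weight=w, hard=hard, multiplier=multiplier))

    score_of = {}
    if cands is not None:
        for x in cand_of:
            for c in cands.get(x):
                score_of[(x, c.gene_id)] = c.score

    # hard: at-most-one ID per mention; linking implies HumanGene
    for x in sorted(cand_of):
        idxs = [n_atoms[(x, gid)] for gid, _ in cand_of[x]]
        net.groups.append(idxs)
        for i in range(len(idxs)):
            for j in range(i + 1, len(idxs)):
                add("unique", [(idxs[i], False), (idxs[j], False)],
                    hard=True)
        for gid, _sec in cand_of[x]:
            add("human_filter",
                [(n_atoms[(x, gid)], False), (h_atoms[x], True)], hard=True)

    # individual formulae
    for x in sorted(cand_of):
        for gid, sec in cand_of[x]:
            ni = n_atoms[(x, gid)]
            if (x, gid) in refined:
                add("refined_prior", [(ni, True)])
            elif (x, gid) in partial:
                add("partial_prior", [(ni, True)],
                    multiplier=score_of.get((x, gid), 1.0))
            else:
                add("candidate_prior", [(ni, True)],
                    multiplier=score_of.get((x, gid), 1.0))
            if (gid, sec) in most_go:
                add("most_go_terms", [(ni, True)])
            if gid in nonhuman_ids:
                add("nonhuman_candidate", [(ni, False)])
        cue = cues.get(x)
        if cue is None:
            add("default_human", [(h_atoms[x], True)])
        elif cue == HUMAN_TAXON:
            add("species_cue_human", [(h_atoms[x], True)])
        else:
            add("species_cue_nonhuman", [(h_atoms[x], False)])

    # co-reference feature formulae
    for pair, feats in sorted(coref_feats.items()):
        ci = c_atoms[pair]
        for fid in feats:
            add(fid, [(ci, True)])

    # collectives
    xs = sorted(cand_of)
    for i, x in enumerate(xs):
        ids_x = dict(cand_of[x])  # id -> sec
        for y in xs[i + 1:]:
            ids_y = dict(cand_of[y])
            sec_x = next(iter(ids_x.values()), None)
            sec_y = next(iter(ids_y.values()), None)
            same = sec_x == sec_y
            cross_xy = sec_x in rich and sec_x != sec_y
            cross_yx = sec_y in rich and sec_x != sec_y
            shared = sorted(set(ids_x) & set(ids_y), key=id_sort_key)
            for gid in shared:
                nx, ny = n_atoms[(x, gid)], n_atoms[(y, gid)]
                if same:
                    add("salience", [(nx, False), (ny, True)])
                if cross_xy:
                    add("salience_cross", [(nx, False), (ny, True)])
                if cross_yx:
                    add("salience_cross", [(ny, False), (nx, True)])
            ci = c_atoms.get((x, y))
            if ci is not None:
                for gid in shared:
                    nx, ny = n_atoms[(x, gid)], n_atoms[(y, gid)]
                    if same:
                        add("transitivity",
                            [(ci, False), (nx, False), (ny, True)])
                        add("transitivity",
                            [(ci, False), (ny, False), (nx, True)])
                    if cross_xy:
                        add("transitivity_cross",
                            [(ci, False), (nx, False), (ny, True)])
                    if cross_yx:
                        add("transitivity_cross",
                            [(ci, False), (ny, False), (nx, True)])
            for gi in ids_x:
                for gj in ids_y:
                    if gi == gj or (gi, gj) not in interacts:
                        continue
                    nx, ny = n_atoms[(x, gi)], n_atoms[(y, gj)]
                    if same:
                        add("ppi", [(nx, False), (ny, True)])
                        add("ppi", [(ny, False), (nx, True)])
                    if cross_xy:
                        add("ppi_cross", [(nx, False), (ny, True)])
                    if cross_yx:
                        add("ppi_cross", [(ny, False), (nx, True)])
    return net


# --- MAP inference ------------------------------------------------------------

def _tie_key(net: GroundNetwork, values: list[bool]):
    """Deterministic preference among equal-score assignments: smaller gene
    IDs, then the canonical bit pattern (fewer flipped-on atoms first)."""
    links = []
    for atom, v in zip(net.atoms, values):
        if atom.predicate == "NormalizeTo" and v:
            links.append((atom.args[0], _arg_key(atom.args[1])))
    return (sorted(links), sum(values), tuple(values))


def _score_all(net: GroundNetwork, values: list[bool]) -> float | None:
    """Soft score, or None if a hard clause is violated."""
    score = 0.0
    for c in net.clauses:
        sat = any(values[i] == pos for i, pos in c.literals)
        if not sat:
            if c.hard:
                return None
            continue
        if not c.hard:
            score += c.weight
    return score


def _solve_enumerate(net: GroundNetwork) -> tuple[list[bool], float]:
    n = net.n_hidden
    if n > 20:
        raise ParameterError(
            f"enumerate solver limited to 20 hidden atoms, got {n}")
    soft, hard = [], []
    for c in net.clauses:
        pos = neg = 0
        for i, p in c.literals:
            if p:
                pos |= 1 << i
            else:
                neg |= 1 << i
        (hard if c.hard else soft).append((pos, neg, c.weight, c))
    full = (1 << n) - 1
    best_bits, best_score, best_key = None, None, None
    for bits in range(1 << n):
        violated = False
        for pos, neg, _w, _c in hard:
            if not ((bits & pos) or (~bits & full & neg)):
                violated = True
                break
        if violated:
            continue
        score = 0.0
        for pos, neg, w, _c in soft:
            if (bits & pos) or (~bits & full & neg):
                score += w
        if best_score is None or score > best_score + 1e-12:
            best_bits, best_score = bits, score
            best_key = None
        elif best_score is not None and abs(score - best_score) <= 1e-12:
            values = [bool(bits >> i & 1) for i in range(n)]
            key = _tie_key(net, values)
            if best_key is None:
                best_key = _tie_key(net, [bool(best_bits >> i & 1)
                                          for i in range(n)])
            if key < best_key:
                best_bits, best_key = bits, key
    if best_bits is None:
        name = hard[0][3].formula_id if hard else "hard constraints"
        raise InfeasibleError(
            f"no assignment satisfies hard constraint set ({name})")
    return [bool(best_bits >> i & 1) for i in range(n)], best_score


class _State:
    """Incremental clause-satisfaction bookkeeping for local search."""

    def __init__(self, net: GroundNetwork, values: list[bool]):
        self.net = net
        self.values = list(values)
        seen: list[set[int]] = [set() for _ in net.atoms]
        self.incident: list[list[int]] = [[] for _ in net.atoms]
        for ci, c in enumerate(net.clauses):
            for i, _pos in c.literals:
                if ci not in seen[i]:
                    seen[i].add(ci)
                    self.incident[i].append(ci)
        self.true_lits = [
            sum(1 for i, pos in c.literals if self.values[i] == pos)
            for c in net.clauses]
        self.score = sum(
            c.weight for c, t in zip(net.clauses, self.true_lits)
            if t > 0 and not c.hard)

    def feasible(self) -> bool:
        return all(t > 0 for c, t in zip(self.net.clauses, self.true_lits)
                   if c.hard)

    def delta(self, flips: tuple[int, ...]) -> tuple[float, bool]:
        """(soft score delta, hard-feasibility after flipping ``flips``)."""
        touched: dict[int, int] = {}
        flipset = set(flips)
        for i in flipset:
            for ci in self.incident[i]:
                touched.setdefault(ci, self.true_lits[ci])
        d, ok = 0.0, True
        for ci, t0 in touched.items():
            c = self.net.clauses[ci]
            t1 = t0
            for i, pos in c.literals:
                if i in flipset:
                    t1 += 1 if (not self.values[i]) == pos else -1
            if c.hard:
                if t1 == 0:
                    ok = False
            else:
                if (t0 > 0) != (t1 > 0):
                    d += c.weight if t1 > 0 else -c.weight
        return d, ok

    def apply(self, flips: tuple[int, ...]) -> None:
        flipset = set(flips)
        touched: set[int] = set()
        for i in flipset:
            touched.update(self.incident[i])
        d = 0.0
        for ci in touched:
            c = self.net.clauses[ci]
            t0 = self.true_lits[ci]
            t1 = t0
            for i, pos in c.literals:
                if i in flipset:
                    t1 += 1 if (not self.values[i]) == pos else -1
            self.true_lits[ci] = t1
            if not c.hard and (t0 > 0) != (t1 > 0):
                d += c.weight if t1 > 0 else -c.weight
        for i in flipset:
            self.values[i] = not self.values[i]
        self.score += d


def _informed_init(net: GroundNetwork) -> list[bool]:
    """Per-mention greedy start: all HumanGene atoms on unless unit evidence
    says otherwise, each mention linked to its best unit-clause candidate."""
    values = [False] * net.n_hidden
    unit: dict[int, float] = {}
    for c in net.clauses:
        if c.hard or len(c.literals) != 1:
            continue
        i, pos = c.literals[0]
        unit[i] = unit.get(i, 0.0) + (c.weight if pos else -c.weight)
    for i, atom in enumerate(net.atoms):
        if atom.predicate != "NormalizeTo":
            values[i] = unit.get(i, 0.0) >= 0.0
    for group in net.groups:
        best = min(group, key=lambda i: (-unit.get(i, 0.0),
                                         atom_sort_key(net.atoms[i])))
        if unit.get(best, 0.0) > 0.0:
            values[best] = True
    return values


def _solve_local_search(net: GroundNetwork, seed: int,
                        restarts: int = 20) -> tuple[list[bool], float]:
    rng = random.Random(seed)
    n = net.n_hidden
    group_of = {}
    for g in net.groups:
        for i in g:
            group_of[i] = g
    best_values, best_score = None, None
    for r in range(max(1, restarts)):
        if r == 0:
            init = _informed_init(net)
        else:
            init = [False] * n
        state = _State(net, init)
        if not state.feasible():
            state = _State(net, [False] * n)
        if not state.feasible():
            raise InfeasibleError(
                "hard constraints unsatisfiable from the empty assignment")
        if r > 0:
            for i in rng.sample(range(n), n) if n else []:
                if rng.random() < 0.5:
                    d, ok = state.delta((i,))
                    if ok:
                        state.apply((i,))
        improved = True
        max_steps = 100 * n + 1000  # safety: bounded even with degenerate weights
        steps = 0
        while improved and steps < max_steps:
            steps += 1
            improved = False
            best_move, best_delta = None, 1e-9
            for i in range(n):
                d, ok = state.delta((i,))
                if ok and d > best_delta:
                    best_move, best_delta = (i,), d
            for g in net.groups:
                on = [i for i in g if state.values[i]]
                if len(on) == 1:
                    for j in g:
                        if j == on[0]:
                            continue
                        d, ok = state.delta((on[0], j))
                        if ok and d > best_delta:
                            best_move, best_delta = (on[0], j), d
            if best_move is None:
                # plateau escape: coordinated pair flips, then group swaps
                # combined with one extra flip
                for i in range(n):
                    for j in range(i + 1, n):
                        d, ok = state.delta((i, j))
                        if ok and d > best_delta:
                            best_move, best_delta = (i, j), d
            if best_move is None:
                for g in net.groups:
                    on = [i for i in g if state.values[i]]
                    if len(on) != 1:
                        continue
                    for j in g:
                        if j == on[0]:
                            continue
                        for k in range(n):
                            if k == on[0] or k == j:
                                continue
                            d, ok = state.delta((on[0], j, k))
                            if ok and d > best_delta:
                                best_move, best_delta = (on[0], j, k), d
            if best_move is not None:
                state.apply(best_move)
                improved = True
        if best_score is None or state.score > best_score + 1e-12:
            best_values, best_score = list(state.values), state.score
        elif abs(state.score - best_score) <= 1e-12:
            if _tie_key(net, state.values) < _tie_key(net, best_values):
                best_values = list(state.values)
    return best_values, best_score


def infer_map(net: GroundNetwork, solver: str = "local_search",
              seed: int = 0, restarts: int = 20) -> Assignment:
    """MAP assignment of the hidden atoms.

    ``enumerate`` is exact for networks of at most 20 hidden atoms;
    ``local_search`` is greedy hill-climbing with seeded random restarts and
    at-most-one swap moves, deterministic given the seed. Equal-score
    solutions prefer smaller gene IDs, then fewer true atoms.
    """
    if net.n_hidden == 0:
        return Assignment(score=0.0)
    if solver == "enumerate":
        values, score = _solve_enumerate(net)
    elif solver == "local_search":
        values, score = _solve_local_search(net, seed, restarts)
    else:
        raise ParameterError(f"unknown solver {solver!r}")
    return Assignment.from_atoms(net.atoms, values, score)


def normalize_document(doc: Document, mentions: list[Mention],
                       cands: CandidateSet, kb: GeneKB,
                       weights: WeightConfig | None = None,
                       solver: str = "local_search", seed: int = 0,
                       restarts: int = 20) -> Assignment:
    """Evidence -> grounding -> MAP, for one document."""
    weights = weights or WeightConfig()
    atoms = extract_evidence(doc, mentions, cands, kb)
    net = ground_formulae(atoms, weights, cands=cands)
    return infer_map(net, solver=solver, seed=seed, restarts=restarts)


def random_ground_network(rng: random.Random, max_atoms: int = 12
                          ) -> GroundNetwork:
    """Random small network for solver stress-testing.

    Mixes at-most-one groups (with their hard pairwise clauses) and random
    soft clauses of 1-3 literals with weights in [-2, 2]; the empty
    assignment is always feasible, so both solvers apply.
    """
    n = rng.randint(2, max_atoms)
    net = GroundNetwork(atoms=[GroundAtom("P", (i,)) for i in range(n)])
    idx = list(range(n))
    rng.shuffle(idx)
    while idx:
        g = idx[:rng.randint(1, 3)]
        idx = idx[len(g):]
        if len(g) > 1 and rng.random() < 0.6:
            net.groups.append(sorted(g))
            for i in range(len(g)):
                for j in range(i + 1, len(g)):
                    net.clauses.append(GroundFormula(
                        "unique", ((g[i], False), (g[j], False)),
                        float("inf"), hard=True))
    for _ in range(rng.randint(3, 4 * n)):
        k = rng.randint(1, 3)
        lits = tuple((rng.randrange(n), rng.random() < 0.5)
                     for _ in range(k))
        net.clauses.append(GroundFormula("rand", lits,
                                         rng.uniform(-2.0, 2.0)))
    return net


# --- weight learning ----------------------------------------------------------

def _gold_values(net: GroundNetwork, doc: Document) -> list[bool]:
    gold_id = {m.order_index: m.gold_gene_id for m in doc.mentions}
    gold_chain = {m.order_index: m.gold_chain for m in doc.mentions}
    gold_taxon = {m.order_index: m.gold_taxon for m in doc.mentions}
    values = []
    for atom in net.atoms:
        if atom.predicate == "NormalizeTo":
            x, gid = atom.args
            values.append(gold_id.get(x) is not None
                          and str(gold_id[x]) == str(gid))
        elif atom.predicate == "HumanGene":
            x = atom.args[0]
            values.append(gold_id.get(x) is not None
                          or gold_taxon.get(x) == HUMAN_TAXON)
        elif atom.predicate == "Coreference":
            x, y = atom.args
            cx, cy = gold_chain.get(x), gold_chain.get(y)
            if cx is not None and cy is not None:
                values.append(cx == cy)
            else:
                values.append(gold_id.get(x) is not None
                              and gold_id.get(x) == gold_id.get(y))
        else:
            values.append(False)
    return values


def _formula_counts(net: GroundNetwork, values: list[bool]
                    ) -> dict[str, float]:
    counts: dict[str, float] = {}
    for c in net.clauses:
        if c.hard:
            continue
        if any(values[i] == pos for i, pos in c.literals):
            counts[c.formula_id] = counts.get(c.formula_id, 0.0) \
                + c.multiplier
    return counts


def _reweight(net: GroundNetwork, weights: WeightConfig) -> None:
    for c in net.clauses:
        if not c.hard:
            c.weight = weights.weight(c.formula_id) * c.multiplier


def learn_weights(train_docs: list[Document], lexicon: Lexicon, kb: GeneKB,
                  epochs: int = 5, seed: int = 0,
                  init: WeightConfig | None = None,
                  solver: str = "local_search", restarts: int = 3,
                  learning_rate: float = 0.1) -> WeightConfig:
    """Averaged structured perceptron over MAP inference.

    Gold mentions (with IDs, species and chains) provide the target
    assignment; after each document the weight of every soft formula moves by
    ``learning_rate * (gold satisfied count - predicted satisfied count)``.
    The returned weights are the average over all per-document updates, which
    makes training on a duplicated corpus identical to doubling the epochs.
    Deterministic given the seed and document order.
    """
    if epochs < 0:
        raise ParameterError("epochs must be >= 0")
    init = init or WeightConfig()
    if epochs == 0:
        return replace(init, weights=dict(init.weights))
    if not any(m.gold_gene_id is not None
               for d in train_docs for m in d.mentions):
        raise TrainingError("no gold gene IDs in the training documents")

    grounded = []
    for doc in train_docs:
        cands = map_mentions(doc, doc.mentions, lexicon)
        atoms = extract_evidence(doc, doc.mentions, cands, kb)
        net = ground_formulae(atoms, init, cands=cands)
        gold = _gold_values(net, doc)
        grounded.append((doc, net, gold, _formula_counts(net, gold)))

    w = dict(init.weights)
    totals = {k: 0.0 for k in w}
    n_updates = 0
    t = 0
    for _epoch in range(epochs):
        for doc, net, gold, gold_counts in grounded:
            cfg = replace(init, weights=w)
            _reweight(net, cfg)
            pred = infer_map(net, solver=solver, seed=seed + t,
                             restarts=restarts)
            pred_counts = _formula_counts(
                net, [pred.atom_values[a] for a in net.atoms])
            for fid in set(gold_counts) | set(pred_counts):
                upd = learning_rate * (gold_counts.get(fid, 0.0)
                                       - pred_counts.get(fid, 0.0))
                w[fid] = w.get(fid, 0.0) + upd
            for k in totals:
                totals[k] += w.get(k, 0.0)
            n_updates += 1
            t += 1
    avg = {k: totals[k] / n_updates for k in totals}
    return replace(init, weights=avg)
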