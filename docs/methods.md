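# Methods

## Problem setting and model

Instance-level gene normalization assigns a gene-database ID (or no ID) to
every gene-mention occurrence in an article. The package treats one article
as one joint inference problem: the hidden variables are
`NormalizeTo(x, id)` for every candidate ID of every mention,
`Coreference(x, y)` for mention pairs with at least one co-reference cue,
and `HumanGene(x)` for every mention with candidates. Observed evidence
(candidate sets, GO-term hits, section types, interaction pairs, species
cues, co-reference features) is folded into weighted ground clauses, and the
prediction is the MAP assignment: the hidden-atom truth assignment
maximizing the summed weight of satisfied soft clauses subject to two hard
constraints — at most one ID per mention, and linking implies being a human
gene. Linking is deliberately *optional* (at-most-one rather than
exactly-one): a mention whose best candidate is implausible simply stays
unlinked instead of forcing a false positive, and the human-gene filter
prunes non-human candidates the same way.

The formula family is fixed and code-registered (no generic first-order
parser): individual formulae (candidate priors split by mapping method, the
most-GO-terms preference, a non-human-candidate penalty, species-cue and
default-human evidence for `HumanGene`, four co-reference feature formulae),
three intra-section collectives (salience, transitivity, interaction) and
their three cross-section variants seeded from information-rich sections.
Sections count as information-rich when typed `abstract` or `introduction`;
titles do not, since they are exactly the sections that benefit from
propagation.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `tau` | 0.85 | token-set Jaccard threshold for partial matching ([0, 1]); high values keep partial matching conservative |
| `k` | 5 | maximum partial-match candidates per mention |
| formula weights | hand-set config in `WeightConfig` | relative strengths of the soft formulae; only ratios matter. The shipped defaults make one collective cue (≈0.4–0.8) outweigh a bare tie but never a strong individual signal (1.0 prior, 2.5 species cue) |
| `restarts` | 20 (inference), 3 (training/pipeline) | random restarts of the hill-climbing solver |
| `epochs`, `learning_rate` | 5, 0.1 | averaged-perceptron passes; the average over per-document updates makes duplicated corpora equivalent to doubled epochs |
| generator rates | ambiguity 0.3, 2.93 IDs/ambiguous name, 10% non-human mentions, drops 29.7%/12.1% | the synthetic study conditions (see below) |

## Inference

`enumerate` is exact and used for networks of ≤ 20 hidden atoms (fixtures,
oracle tests). `local_search` is greedy steepest-ascent hill-climbing over
single-atom flips plus swap moves inside each at-most-one group, with seeded
random restarts; restart 0 starts from an informed assignment (per-mention
argmax of unit-clause utilities, human flags from unit evidence), later
restarts from random feasible points. At a plateau the search widens to
coordinated pair flips and, failing that, to group swaps combined with one
extra flip — the escapes that matter in practice are "switch a mention's
candidate while flipping a related human/co-reference atom". These wider
scans run only when no cheaper move improves, keeping the common path
linear in the incidence lists. Moves that would violate a hard clause
are rejected, so every returned assignment satisfies the hard constraints by
construction. Equal-score solutions are resolved deterministically: smaller
gene IDs first, then fewer true atoms, then the canonical bit pattern —
applied identically in both solvers so they agree on ties. Clause
satisfaction is tracked incrementally (per-clause true-literal counts);
weights may be negative (the perceptron can drive them there), which the
move evaluation handles symmetrically. A step cap of `100·n + 1000` bounds
the climb even under degenerate weight settings.

## Weight learning

Averaged structured perceptron over MAP inference: ground each training
document once, compute per-formula satisfied-grounding counts under the gold
assignment (gold links restricted to each mention's candidate set; gold
`HumanGene` from the gold ID or species annotation; gold `Coreference` from
annotated chains), and after each document move every soft weight by
`learning_rate · (gold count − predicted count)`. The returned weights are
the mean over all per-document updates. Hard formulae carry no weight and
are never updated. Training is deterministic given the seed and document
order; the per-document solver seed advances with the update counter so that
a duplicated corpus reproduces doubled epochs exactly.

## Synthetic data: what it emulates, and what it does not

The generator plants, with exact gold control: full-name + "(ABBR)"
introductions in the abstract (gold abbreviation pairs and co-reference
chains), later mentions under symbols, lowercase aliases or shared
(ambiguous) surfaces, GO-term phrases in the introduction, interaction
sentences consistent with the knowledge base (the gold pair file records
their sentence indices), non-human mention slots with a species word and
taxonomy ID only, and a four-section structure (title/abstract/
introduction/results). Ambiguity is planted so that a configurable fraction
of all surfaces is shared by ≥ 2 genes, with 2 + Poisson(0.93) genes per
shared surface (mean 2.93). The degradable oracle recognizer hides
configured fractions of sentence-initial and lowercase-only duplicate
mentions — the two error classes a supervised recognizer is most prone to —
but never a surface's first occurrence.

Deliberate non-realism: text is template-generated; filler vocabulary, gene
surfaces and GO phrases are constructed to be mutually non-colliding at
token boundaries, and surfaces are emitted verbatim (no sentence-initial
recapitalization). Consequently exact-match refinement is exactly
recall-complete on this corpus, and mapping is near-noiseless. Passing tests
therefore demonstrate the *mechanics* — candidate generation, refinement
recovery, collective resolution of planted ambiguity, species filtering,
aggregation directions — not robustness to real orthographic noise, nested
mentions, or recognizer false positives, all of which are harder in real
articles. The end-to-end F on this corpus (≈0.99) is a property of the
controlled conditions and should not be read as an expected real-corpus
score.

## Numerical and design choices

- **Character coordinates** are 0-based half-open over the whole document
  text; BioC offsets are converted at the I/O boundary. Inter-passage gaps
  are reconstructed as newlines on read, so round-trips are exact for
  documents whose sections tile the text up to newline separators (all
  generated corpora do).
- **Sentence splitting** is rule-based (terminator + following
  capital/digit + abbreviation stop-list; newlines always split) — the
  corpus format carries gold boundaries, raw inputs will not.
- **Variant closure** is one-pass (no recursive re-expansion) to stay
  finite; it always contains the input, its case-folded and upper-cased
  forms, and never the empty string.
- **Partial-match scoring** is token-set Jaccard on variant-normalized word
  tokens; letter/digit-split tokens and whole surfaces are indexed for
  retrieval only. Jaccard was chosen over an opaque retrieval score because
  it is transparent and brute-force testable.
- **Refinement matching** is exact and case-sensitive at token boundaries,
  with one extension: at sentence starts a key also matches when only the
  case of its first character differs. Pure case-insensitive matching was
  rejected because it floods false positives on common words ("WAS",
  "MICE").
- **Overlapping input annotations**: keep the longest (greedy
  left-to-right), log the discard.
- **Species cues** are whole alphabetic tokens only (a symbol such as
  "MICE28" is not a cue); the nearest cue within the mention's sentence
  wins. Mentions with no cue receive a weak default-human prior
  (per-mention, which is slightly finer-grained than a document-level
  default).
- **MostGOTerms ties**: all argmax IDs with at least one GO-name hit are
  true; ties are real and forcing uniqueness would drop evidence.
- **Evaluation**: approximate boundary matching means ≥ 1 overlapping
  character with one-to-one greedy matching by overlap length; zero
  denominators score 0 and set a `zero_denominator` flag. A link on a
  mention without a gold ID (the non-human placeholders) counts as a false
  positive; leaving it unlinked costs nothing.
- **Problem sizes** used by the test suite and the acceptance script — 50
  held-out + 50 training documents, 200 genes, 200 random solver-check
  networks, 5 perceptron epochs — were chosen as the smallest sizes at which
  every planted phenomenon (ambiguity, chains, species mixing, drops)
  occurs hundreds of times per run; the whole study completes in well under
  a minute.

## Known limitations

- The co-reference cues are four shallow features (exact/case-insensitive
  surface match, "(ABBR)" pattern with initial-letter check, shared
  candidate in-section); pronominal and appositive co-reference are out of
  scope.
- The human-gene filter is rule-evidence + learned weights; it has no
  trained classifier over contextual features beyond species words and
  candidate taxa.
- `enumerate` is exponential and capped at 20 hidden atoms; `local_search`
  has no optimality guarantee (it matches enumeration on all tested small
  networks, which is evidence, not proof).
- Real lexicon ingestion (Entrez Gene / UniProtKB dumps) is out of scope;
  the TSV layouts mirror the `gene_info` column style so a converter is
  straightforward.
- Only one gold ID per mention is representable; narrations that normalize
  one mention to several species' IDs at once are not modelled.
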