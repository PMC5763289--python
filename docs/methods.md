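# Methods

This note documents the models and procedures implemented in `symptomkb`,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical/design choices made where the design was open.

## Knowledge-base store (`symptomkb.schema`)

Entities carry a stable id, a non-empty Unicode name, a set of concept
types, per-source provenance, and a multimap of attribute values. The type
system is a two-level hierarchy: `TCMSymptom`/`WesternSymptom` imply
`Symptom`, `TCMMedicine`/`WesternMedicine` imply `Medicine`, and an entity
may carry both subtypes of a level at once. Facts are
(subject, predicate, object, source) with entity-valued or literal
objects. Two store rules are enforced at add time rather than checked
later: referential integrity (both ends of an entity-valued fact must
resolve) and a closed predicate vocabulary — an undeclared relation is an
error, not a silent row. The rationale is that the KB's value over a raw
terminology dump is that every relation has declared syntax and semantics.

*Statistics* count multi-type entities once per carried type, so per-type
tables may sum to more than the distinct total, which is reported
separately. *Sampling* for correctness evaluation is simple random
sampling without replacement over a deterministically ordered fact list,
so a (contents, n, seed) triple is reproducible byte for byte. *Vote
aggregation* takes the strictly most frequent of the per-judge labels;
even panels can tie, and ties resolve to "incorrect" — the conservative
direction for a correctness-ratio estimate (a seven-judge panel never
ties).

*RDF export.* Chinese names are not safe IRI local parts everywhere, so
entity IRIs are `<base>/entity/<id>` with a deterministic id (SHA-1 of
source + name, 16 hex chars) and the name attached as an `rdfs:label`
with language tag `zh`. Types become class assertions in the package
ontology namespace; attributes become datatype properties with
percent-encoded local names. Per-fact provenance survives serialization
through standard RDF reification (one statement node per fact carrying
`dcterms:source`), which is what makes `parse(serialize(kb)) == kb` hold
exactly on the triple set for both Turtle and N-Triples.

## Wrapper extraction (`symptomkb.web`)

Detail pages of one site share a layout, so extraction is configuration,
not code: per-site XPath locators for the property box, its rows and
key/value cells, plus a manual attribute-name → schema-property map, all
in YAML. Unmapped attribute rows are skipped (logged), values are
whitespace-normalized, and a page without a property box yields an empty
result with a warning so one malformed page cannot halt a batch.

Subtype heuristics: a symptom related to a department whose name contains
a TCM marker (default set: 中医, TCM, Traditional Chinese — configurable,
because translated department names occur) is a TCM symptom; departments
without a marker vote for the Western subtype; both can co-occur.
Medicine descriptions are scanned against TCM keywords (中成药, 中草药,
"Chinese patent medicine", "herbal medicine") and Western keywords
(化学药品, "pharmaceuticals", "chemicals"); no keyword evidence leaves the
entity a plain `Medicine`.

Synonym harvesting applies two-slot lexico-syntactic templates
("[entity1]又称[entity2]", 俗称, 也叫, "is known as") per sentence. The
slot fillers are the text before and after the first connector occurrence
in the sentence, trimmed of punctuation; self-pairs are suppressed and
each pair is added as a symmetric `sameAs` relation. The template
inventory is configuration; the packaged set seeds the common Chinese
aliasing connectors plus the English form.

## Encyclopedia bootstrapping and classification (`symptomkb.encyclopedia`)

Bootstrapping is a single pass (no re-seeding): healthcare-site entities
are seeds; the categories of their encyclopedia pages form the candidate
set; each category's confidence is the seed ratio |members ∩ seeds| /
|members|, split high/low at a threshold (default 0.1, exposed in config —
the threshold is a design choice, and the test suite sweeps it to confirm
that raising it never grows the high-confidence set). A page carrying any
low-confidence category is removed as noise. Pages without categories are
retained: the rule removes on positive evidence only.

The seven-label classifier (department, tcm, western medicine, symptom,
disease, examination, other) is a decision tree over a fixed
26-dimensional feature vector drawn from the five page fields: six
name-suffix tests (科/病/炎/瘤/综合征/检查), four abstract cue-word tests,
two content cue-word count thresholds (fires at more than three distinct
hits) plus the two raw counts, two full-text TCM cues, six category
cue-word tests, and four per-field total hit counts. The keyword lists
are configurable; the packaged defaults are the Chinese surface forms.
Word-distribution information beyond these lists is deliberately reduced
to the per-field hit counts to keep the dimensionality fixed and
documented. Tree hyperparameters are scikit-learn defaults with a fixed
random state; evaluation uses stratified ten-fold cross-validation with
macro-averaged F1. A page classified as a symptom is refined into
TCM/Western subtypes by harvesting department mentions (…科 tokens) from
its text and reusing the department-marker heuristic; with no evidence
the Western subtype is the default, since TCM labels should only arise
from positive marker evidence.

## EMR symptom recognition (`symptomkb.ner` + `symptomkb.crf`)

Field selection is class-specific: Western symptoms read "physical
examination" and "Western differential" (antidiastole), TCM symptoms read
"disease analysis" and "TCM differential". Because EMR narratives are
heavily copy-pasted, sentences (split on 。！？；) that repeat verbatim
within one record are removed, keeping the first occurrence — the
information-preserving reading of "remove repeated sentences".

Tokens come from a pluggable segmenter. The default is greedy forward
maximum matching over a packaged medical word list (clinical segmenters
vary; the matcher is deterministic and adequate for the templated
synthetic text); a character-level fallback mode exists and the mode used
is recorded in the model metadata. POS tags come from a small rule/lexicon
tagger (noun/verb/modifier/function/punctuation classes, unknown → `x`).

Feature templates per position, constant at 37 via `<PAD>` boundary
tokens: literal unigrams X(i−3..i+3), bigrams (6), trigrams (5), the
position index, and the same 18 n-gram templates over POS tags. The
window of ±3 follows the feature design the templates are modeled on.

The CRF itself (`symptomkb.crf.LinearChainCRF`) is implemented in-package:
indicator features conjoined with labels, label-pair transitions and
start/end weights, trained by maximizing the L2-penalized conditional
log-likelihood (prior strength 0.1, L-BFGS, max 150–200 iterations).
Forward/backward passes are vectorized across all sequences (padded and
masked), which trains a corpus of ~2,600 sentences in a few seconds on
one CPU. Parameters initialize at zero, so training is deterministic for
a fixed data order. Two independent models (Western / TCM) mirror the
separate field selection rather than one four-label model. Decoding is
exact Viterbi; BIO violations in decoded or loaded label sequences are
repaired by promoting an orphan I to B, the least destructive standard
repair. Evaluation is entity-level exact span match; a zero denominator
reports precision/recall as undefined (`None`), not 0.

## Fusion (`symptomkb.fusion`)

Type conflicts across sources are resolved by voting: the most-voted type
wins; tied top types resolve by the priority of their backing sources
(priority is an ordered source list, standing in for a site-traffic
ranking); a residual tie (same source, two types) breaks on type name for
determinism.

Name commonness is |LCS| / max(length) over Unicode code points.
Character level was chosen because Chinese medical names are short and
unsegmented; a word-level LCS would smuggle a segmenter into a similarity
primitive. Both-empty input is an error (0/0), consistent with the
non-empty-name invariant. Relatedness is the fraction of attributes
present on both entities whose value sets contain a pair with commonness
≥ 0.85 (the "similar fact" criterion reuses the same string measure;
0.85 keeps one-character variants of short values similar while separating
genuinely different values). Entities sharing no attributes get
relatedness 0 and a review flag: name evidence alone never merges.

Pairs with product > 0.5 link; clusters are the transitive closure (needed
to merge more than two sources coherently); each cluster keeps the id and
name of its highest-priority member and unions types, sources and
attributes. Merging is order-independent (pairs are enumerated over a
sorted entity list and the union-find root is the smallest id), and a
sweep utility verifies merged-pair counts are non-increasing in the
threshold. Both thresholds are config keys; 0.5 and 0.85 are the package
defaults, chosen as round midpoints of their meaningful ranges and
documented rather than fitted.

Attribute mapping onto the schema is rule-based: a rule matches a source
attribute name with optional subject-type and value-type constraints
(typed rules sort before untyped; first match wins), e.g. the generic
attribute 症状 between two symptom entities maps to
`symptom_related_symptom`. Attributes with no rule are quarantined on the
entity rather than dropped.

## Cross-lingual linking (`symptomkb.linking`)

The translator is an injected callable; the packaged implementation is a
deterministic bilingual lexicon loaded from TSV (a live translation
service would be neither reproducible nor desk-testable, so it is out of
scope by design). Both the translated phrase and every concept term are
normalized identically — lowercase, punctuation stripped, whitespace
split, set semantics — and a link is made exactly when the Jaccard
similarity of the two bags is 1. Because the rule is exact-set equality,
the normalization is consequential and therefore frozen in one place; no
stemming is applied by default ("fevers" ≠ "fever") to keep the rule as
strict as stated. A symptom links to every concept sharing its bag; no
disambiguation step is imposed. Stored links are re-verifiable by a
self-audit that recomputes the Jaccard value from scratch, and links
export as `exact_match` facts (CUI literals) through the KB store. The
concept table is a three-column TSV (cui, term, semantic type) — the
shape of an MRCONSO/MRSTY projection — and semantic-type distributions
over links are reported as counts and fractions.

## Synthetic study conditions (`symptomkb.synth`)

The generators define the conditions everything is measured under; they
are pure functions of (config, seed) and byte-identical on re-run.
Defaults, chosen once as the study conditions:

- **Healthcare sites**: two pseudo-sites with different HTML layouts
  (table-based and dl-based property boxes), 200 entities (80 symptoms,
  50 diseases, 40 medicines, 16 departments, 14 examinations), three
  attributes per entity, duplication rate 0.5 → 100 planted cross-site
  duplicate pairs, 25% of symptoms TCM-related, synonym sentences on 25%
  of symptom abstracts, 2% of pages lacking a property box.
- **Duplicate perturbation**: the twin's name receives 0/1/2 affix-
  character insertions with weights 0.55/0.35/0.10 (real cross-site
  listings differ mostly by added affixes such as 症/性/感), capped at
  (len−1)//3 insertions so the planted pair's commonness stays above 3/4
  — with exactly one of the three shared facts perturbed, relatedness is
  2/3 and the pair is recoverable at the default product threshold
  precisely when commonness exceeds 3/4; planted duplicates are meant to
  be confirmable by an oracle, so edits beyond that budget would plant
  unrecoverable "duplicates".
- **Encyclopedia**: 40 clean pages per label (280), noise pages at 20% of
  the total (70), planted per-label field signals with 5% independent
  signal noise (abstract blanked, content blanked, a category dropped or
  a spurious one added), lifestyle categories (养生/美容/心理) on noise
  pages only, up to 10 seed pages per label so every medical category's
  seed ratio clears the 0.1 threshold.
- **EMR corpus**: 1,000 records, 660/340 train/test protocol split by
  seeded shuffle, ~3 symptom sentences per record and class from templated
  clinical phrasings with distractor sentences, 40% two-token symptom
  mentions (so I-labels are trained), within-record sentence duplication
  at floor(0.3 × sentences), and 5% training-annotation noise (gold spans
  dropped) applied only to the training split.
- **Linking**: 50 exact pairs (bag-equal concept variants via case, word
  order or punctuation changes), 50 near misses (one word added or the
  modifier dropped), 10 distractor concepts; modifier+base English combos
  are unique per pair so near-miss bags cannot collide with any
  translation bag.

What the generators do *not* emulate: real lexical diversity and
ambiguity of clinical Chinese, segmentation errors, infobox schema drift
across sites, translation noise, or annotator disagreement beyond
uniform span dropping. Passing recovery tests therefore demonstrates the
pipeline's correctness and its behavior under controlled noise, not
field performance on hospital data; the original corpus-scale figures
depend on proprietary inputs and are out of scope.

## Problem sizes and runtime

The default conditions keep the whole test suite under a minute of
compute apart from CRF training: six CRF fits (two targets × {50, 200,
660} training records) dominate at a few seconds each thanks to the
vectorized forward–backward pass. The unit-test fixtures run the same
code at roughly a quarter of these sizes. `scripts/acceptance.py`
re-runs everything at the full default sizes in well under a minute.

## Known limitations

- The maximum-matching segmenter is lexicon-bound; out-of-lexicon
  multi-character words fragment into characters (the POS tagger tags
  them `x`), which the CRF tolerates on synthetic text but which would
  hurt on real narratives without a proper segmenter plugged in.
- Synonym extraction takes the first connector occurrence per sentence;
  multiple aliasing constructions in one sentence yield only the first.
- Fusion is O(n²) within each type group; adequate at KB-construction
  batch sizes here, but large sources would need blocking.
- Attribute-value conflicts after merging are kept as multi-values with
  provenance rather than reconciled; reconciliation policy is left to
  consumers.
- The RDF vocabulary is package-local (no OWL axioms); `sameAs` is a
  declared schema property, not `owl:sameAs`, to keep round-trip
  semantics closed.
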