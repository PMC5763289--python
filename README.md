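# symptomkb

Construction of a symptom-centric medical knowledge base in Chinese, end to
end: wrapper-based extraction of entities and attribute–value facts from
healthcare-site detail pages, seed-bootstrapped harvesting and
classification of encyclopedia entities, CRF recognition of symptom
mentions in electronic medical record (EMR) narratives, duplicate-entity
fusion across sources, cross-lingual linking of symptoms to an English
terminology, and export of the result as Linked Data (Turtle /
N-Triples).

The package is aimed at biomedical text-mining practitioners who need a
reproducible, testable implementation of this pipeline. Because the
original inputs of such pipelines (live website snapshots, hospital EMR
corpora, licensed terminologies, commercial translation APIs) cannot be
redistributed, every input is emulated by deterministic synthetic
generators with planted ground truth (`symptomkb.synth`), so the whole
system runs, and is evaluated, offline.

## The core methods

**Schema.** `Symptom` is the hub concept, linked to `Disease`, `Medicine`,
`Department` and `Examination` through a closed property vocabulary
(`relevant_disease`, `relevant_department`, …, `sameAs`). Symptoms and
medicines subdivide into TCM (traditional Chinese medicine) and
Western-medicine subtypes; an entity may carry both.

**Entity fusion.** Duplicate detection scores a pair of identically typed
entities by the product of two signals:

```
commonness(E_A, E_B)  = |LCS(E_A, E_B)| / max(|E_A|, |E_B|)      (names)
relatedness(E_A, E_B) = #(shared attributes with similar values)
                        / #(shared attributes)                    (facts)
```

where LCS is the character-level longest common subsequence and a shared
attribute counts as *similar* when its values reach a commonness of 0.85.
Pairs with `commonness × relatedness > 0.5` are linked; clusters are the
transitive closure, and each cluster merges into one entity named by its
highest-priority source.

**Clinical NER.** One linear-chain CRF per symptom class (Western / TCM),
trained on BIO-tagged (`B-SYM`/`I-SYM`/`O`) segmented sentences with 37
feature templates per token: literal and part-of-speech uni-, bi- and
trigrams over a ±3 context window, plus the position index. Field
selection is class-specific (physical examination + Western differential
for Western symptoms; disease analysis + TCM differential for TCM), and
sentences duplicated within a record are removed first.

**Terminology linking.** Symptom names are translated by a pluggable
deterministic lexicon, reduced to bags of words (lowercase, punctuation
stripped), and linked to every concept row whose term has Jaccard
similarity exactly 1 with the translation — strict exact-set matching.

## Worked example

```python
from symptomkb import synth, web, linking
from symptomkb.schema import KnowledgeBase
from symptomkb.fusion import fuse_kb, SourcePriority

cfg = synth.GeneratorConfig(seed=7)
hc = synth.generate_healthcare_site(cfg)          # two pseudo-sites
kb = KnowledgeBase()
for site in cfg.sites:
    web.extract_site(hc.pages[site], site, hc.wrappers[site], kb=kb)
print("extracted:", len(kb.entities), "entities,", len(kb.facts), "facts")

fused, audit = fuse_kb(kb, SourcePriority(cfg.sites))
print("after fusion:", len(fused.entities), "entities")

lfix = synth.generate_linking_fixture(cfg)
links = linking.link_symptoms(lfix.symptom_entities(), lfix.translator(),
                              lfix.concepts)
print("terminology links:", len(links))
```

prints

```
extracted: 404 entities, 951 facts
after fusion: 304 entities
terminology links: 50
```

404 entities come out of the two generated sites (detail-page subjects
plus the stub entities their property boxes reference); fusion collapses
the 100 planted cross-site duplicates, leaving 304 distinct entities; and
exactly the 50 planted exact-match translation pairs are linked (the 50
planted near-misses, which differ by one word, are rejected by the
Jaccard = 1 rule).

The same pipeline is scriptable from the shell:

```bash
symptomkb fixtures make --seed 7 --out fx
symptomkb extract web --site kangfu --pages fx/healthcare/kangfu \
    --wrappers fx/healthcare/wrappers.yaml --kb kb.json
symptomkb fuse --kb kb.json --out fused.json --priority kangfu,yixun
symptomkb kb stats --kb fused.json
symptomkb kb export --kb fused.json --format turtle --out kb.ttl
```

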