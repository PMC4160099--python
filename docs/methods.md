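# Methods

## Model

`gofinder` predicts which Gene Ontology concept a sentence attributes to
a gene, using only distributional similarity between the sentence and the
ontology's own term names — an open information-extraction approach with
no supervised training step, and therefore no dependence on an annotated
corpus.

Three assumptions carry the method:

1. **A concept's name is a usable document.** Each GO term is embedded
   from its name (optionally definition/synonyms), so a sentence stating
   a function tends to share stemmed tokens with the right concept.
2. **Function statements cluster in specific sections.** Article titles
   (`front`), abstracts and subsection headings (`title_2`) — the FAT
   sections — plus the first sentence of each paragraph carry most
   gene-function statements; other paragraph sentences mostly add noise.
3. **The abstract summarizes the article's functional content.** A
   concept predicted from one sentence should also rank highly against
   the whole abstract; intersecting sentence candidates (G) with abstract
   candidates (D) trades recall for precision.

## Random-indexing space

Token *t* receives a ternary index vector with `nonzeros` (default 10)
±1 entries in `dimension` coordinates, half positive, half negative. The
coordinates are drawn by a PCG64 generator seeded with the first 8 bytes
of SHA-256(seed ‖ NUL ‖ token) — a stable, platform-independent keying;
language-default string hashing is never used, so rebuilding a space
with the same configuration is bit-identical everywhere. Concept and
query vectors are unit-normalized sums of token index vectors with
multiplicity; both go through one shared normalization path (lowercase
tokenization on non-alphanumeric boundaries, stop-word removal, original
Porter 1980 stemming), so a query equal to a concept's exact name attains
cosine 1. Degenerate concepts (name all stop words) get the zero vector;
cosine against a zero vector is defined as 0, which keeps them out of
every top-k list. Concept vectors use raw token counts; term weighting
(e.g. log-entropy) is a possible config extension, not implemented.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `dimension` | 200 | vector length |
| `nonzeros` | 10 | ±1 entries per token index vector (must be even) |
| `seed` | `"1234"` | string mixed into every token hash |
| `content_mode` | `name_only` | concept document source (`name_def`, `name_syn`, `name_def_syn`) |
| `m_fat`, `n_fat` | 9, 75 | sentence / abstract top-k in FAT sections |
| `m_paragraph`, `n_paragraph` | 2, 15 | same for paragraph-first sentences |
| `scope_mode` | `first+fat` | which sentences are searched |

The m/n defaults are the operating point at which the intersection
configuration maximizes F on development data in the original study of
this method; `first+fat` is its best-precision scope. `name_only` is the
default because added definitions/synonyms make concept vectors less
discriminative — nearby concepts share description vocabulary.

Dimension 200 with 10 nonzeros mirrors the historical defaults of the
random-indexing package this design follows. At that size the cosine of
two *unrelated* token index vectors has sd ≈ √(nonzeros²/dimension) /
nonzeros ≈ 0.07 — acceptable for ranking a large ontology, but a
non-negligible noise floor. Where analyses here need chance similarity
to be effectively zero (the planted-signal recovery runs and the
acceptance script), the space is built at `dimension=1000` (noise sd
≈ 0.03), which cleanly separates planted names from collision noise in a
100-concept vocabulary. Both sizes are ordinary configuration values.

## Numerical choices

- **Tie-breaking.** Rankings order by descending cosine, then ascending
  accession. Because cosines are ratios of integer dot products over
  shared norms, exact mathematical ties are common; the sort key
  quantizes similarity to 12 decimals so that such ties remain ties (and
  break by accession) irrespective of floating-point summation order.
  Returned scores are unquantized. Quantization makes top-k(k₁) a true
  prefix of top-k(k₂) and the ranking reproducible across BLAS
  implementations.
- **Degenerate inputs.** Empty query text embeds to the zero vector
  (similarity 0 to everything); a passage with no sentence markup is
  split heuristically with a warning; a document without an abstract
  falls back to its front passage for D, with a warning.
- **Gene matching.** Two tiers: exact token match (case-insensitive), or
  equality of letters-only generalized forms (`Ask-1 → ask`). Generalized
  matching requires ≥ 2 letters, so residues like `p` from `p38` do not
  match everywhere; exact tokens are never suppressed.
- **Evaluation conventions.** Empty predicted and gold sets count as
  P = R = 1; genes compare case-insensitively (collisions logged);
  hierarchical precision sums are over pairs with a non-empty predicted
  expansion. Micro-averaging is the default; macro is available. An
  audit variant (`denominator="printed"`) scores hierarchical precision
  over the gold-side expansion instead of the standard predicted-side
  denominator.
- **Ontology semantics.** Only is_a edges define ancestry; closures are
  reflexive, so hierarchical evaluation reduces to exact evaluation on a
  flat ontology. Obsolete terms are parsed but excluded from retrieval
  and expansion.

## Synthetic data

`fixtures` generates the study conditions under which every stage is
testable offline: 100 concepts, 20 documents, 3 sentences per paragraph,
plant rate 1.0, generator seed 7 (all overridable).

- **Ontology.** Names of 2–4 tokens from a consonant-vowel lexicon,
  pairwise token-disjoint after stemming (asserted at generation), with
  definitions and synonyms; a random DAG with ≤ 2 parents per term and
  one root.
- **Corpus.** Per document: 1 front sentence, 3 abstract sentences plus
  one echo sentence, 1 title_2 sentence, 3 paragraphs. Each eligible
  sentence (FAT or paragraph-first) is planted, with probability
  `plant_rate`, with one concept name verbatim plus one of the document's
  two gene symbols; the echo sentence repeats body-planted names so D can
  contain them. Distractor text uses lexicon words appearing in no
  concept name, so lexical chance similarity is zero and the only noise
  is index-vector collision noise.

What passing planted-signal tests shows: the retrieval, gating,
intersection and selection machinery is correct, deterministic, and
recovers a clean signal perfectly. What it does not show: performance on
real biomedical prose, where concept names are paraphrased rather than
verbatim, names share vocabulary, and gene-bearing sentences discuss
functions not annotated in the gold standard. In particular, the
synthetic corpus cannot reproduce the precision/recall trade-off that
motivates the intersection: its distractor sentences carry no gene
mentions, so the no-intersection baseline has nothing to over-predict
and matches the intersection configuration exactly — the acceptance
report includes both numbers, and their equality is a property of the
fixture, not of real corpora.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 100-concept
/ 20-document corpus (160 planted annotations), a size at which oracle
cross-checks (exhaustive cosine ranking, DFS closures) stay exact and
the whole suite completes in seconds.

## Known limitations

- Hierarchical evaluation ignores non-is_a relationships (`part_of`,
  `regulates`).
- The gene matcher is purely lexical: no identifier normalization,
  species disambiguation, or coreference; generalized matching can
  conflate paralogs (`MAPK8`/`MAPK9 → mapk`).
- Whether substring (non-token) gene matches should count is an open
  interpretation; this implementation requires whole-token matches.
- Concept vectors are one-pass sums (basic random indexing); no
  reflective retraining, no term–term similarity expansion of queries.
- BioC support covers collection/document/passage/sentence/annotation
  with infons and offsets — not relations or arbitrary annotation
  schemas.
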