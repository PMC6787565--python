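# Methods

## Model and assumptions

The package rests on one working hypothesis: a microbial secondary
metabolite that resembles a drug — in structure and in the transcriptional
perturbation it induces — likely shares the drug's function in the human
body.  Resemblance is quantified per metabolite–drug pair and everything
downstream (benchmarking, biclustering, network analysis, annotation
propagation) consumes the resulting ranked pair table.

**Structural half.**  Structures are canonicalized with RDKit; records whose
SMILES fail to parse are excluded from the pair universe (not scored zero)
and counted in the run summary.  Similarity is the Tanimoto coefficient on
binary Morgan (circular) fingerprints, radius 2, 2048 bits — the de facto
standard for drug-likeness comparison.  Fingerprint kind (`morgan`/`rdkit`),
radius and length are configuration knobs.  Structure *identity* is decided
by canonical-SMILES string equality, never by fingerprint equality, because
folded fingerprints can collide; two empty fingerprints score 0.0 (a
structureless entity is dissimilar to everything, including itself).

**Expression half.**  Each compound may carry a gene-level z-score profile.
The default statistic is the Spearman rank correlation over the shared genes
(average ranks on ties; at least 3 shared genes required, otherwise the pair
falls back to structure-only scoring).  Spearman is the default because it
is symmetric and parameter-free.  A connectivity-map-style alternative is
selectable: the query's `top_n` (default 50) most up- and down-regulated
genes are scored against the reference's z-ranked list with the two-sided KS
enrichment statistic, ES = a if a > b else −b with
a = maxⱼ(j/t − V(j)/n) and b = maxⱼ(V(j)/n − (j−1)/t), and the pair value is
(ES_up − ES_down)/2.  This statistic is directional, so the scorer averages
the two directions; ranked-list ties break by gene id for determinism.
Either statistic is mapped from [−1, 1] to [0, 1] by (s+1)/2 before fusion.

**Fusion.**  `score = α·s_struct + (1−α)·s_expr` with α = 0.5 by default —
with no published weighting to inherit, equal weighting is the neutral
choice, and α is exposed as a config/CLI knob.  Two overrides precede the
blend: canonical-equal pairs score exactly 1.0 (score 1.0 is *reserved* for
exact compounds, so "the microbe makes this very drug" is decidable from the
score alone), and pairs without a usable expression similarity score
`s_struct`.  The pair table is sorted by score descending, ties broken by
(metabolite_id, drug_id), and carries a 1-based rank column.

## Benchmark

A metabolite and a drug sharing at least one disease-related pathway are
treated as functionally similar (positive); pairs where both entities are
annotated but share no disease-related pathway are negative; pairs with an
unannotated entity are *unlabeled* and excluded from precision — a negative
claim presupposes annotation.  The disease-related flag is an input column,
not inferred.  Precision above threshold t is positives/(positives+negatives)
over labeled pairs with score > t, reported with its counts; "above" is
strict by default (an `inclusive` flag flips it), and the curve is computed
over a descending threshold ladder (default 0.9/0.8/0.7/0.6) together with
1−t to match the usual precision-vs-(1−score) plotting convention.

## Biclustering

The pair table is aggregated to a microbe × drug matrix (cell = best score
among the microbe's metabolites against the drug, zeroed below the 0.6
cutoff) and binarized — presence/absence of a qualifying link is the
qualitative signal.  The miner is a qualitative, seed-and-expand algorithm:

1. discretize each row to integer symbols in {−r…+r}: the ⌊q·n_cols⌋ largest
   values get positive ranks by equal sub-quantiles (most extreme = +r), the
   smallest the mirrored negatives, the rest 0; a {0,1} matrix passes
   through unchanged; constant rows and rows with q·n_cols < 1 come out
   all-zero (the latter with a warning);
2. connect rows by edges weighted by the number of columns where both carry
   the same nonzero symbol; process edges in decreasing weight (ties:
   lexicographic row-id pairs) as block seeds;
3. expand each seed greedily to a fixpoint: add the row with maximal
   agreement to the block's dominant column symbols, requiring both that the
   row agrees on ≥ c of the block's columns and that the block's minimum
   column consistency stays ≥ c, then add every column whose dominant
   nonzero symbol is shared by ≥ c of member rows.  The per-row agreement
   requirement matters on noisy matrices: without it, near-empty rows can
   join a block on consistency slack alone and dilute it;
4. a block's *consistency* is the minimum over its columns of the largest
   same-nonzero-symbol fraction among member rows; blocks need ≥ 2 rows,
   ≥ 2 columns and consistency ≥ c;
5. deduplicate, sort by size (ties by ids), and report greedily, rejecting
   any block whose cell overlap with an already-reported block exceeds f of
   its own cells (exact duplicates always rejected); keep at most o.

Defaults r=1, q=0.06, c=0.95, o=100, f=1 follow the published defaults of
the qualitative biclustering method this implements.  The overlap rule is
"overlap ≤ f·size admits" so that f=0 permits disjoint blocks and f=1
filters only duplicates.

## Network and propagation

Above the 0.6 cutoff, microbes and drugs form a bipartite graph; edge weight
counts metabolite-level interactions, so total edge weight equals the number
of qualifying metabolite–drug pairs owned by some microbe (a conservation
property the tests assert).  A microbe's "drug type" count is the number of
distinct ATC level-1 letters among its neighbours — *hubs* are the argmax
set, *islands* the argmin set among connected microbes, full tied sets
reported (class-level counting is the default; raw degree is behind a flag).
Drugs carrying several ATC letters contribute to each class in the
phylum × ATC contingency table, which is noted in output metadata since it
inflates marginals.

Annotation propagation uses the stricter `linkage_cutoff = 0.9`,
*inclusive* (score ≥ 0.9), distinct from the strict benchmark tiers; linked
drugs are classified identical (score = 1.0) versus analog.  Indications,
side effects and immune transitions are unioned over a microbe's linked
drugs, every term keeping (drug, score) provenance, and habitat (gut vs
environmental) is carried through so outputs can be split by where the
producer lives.

## Synthetic universe

The generator emulates the database extracts the pipeline would normally
consume — compound structures, perturbation signatures, pathway memberships,
drug annotations, microbe records — with planted ground truth:

- **Chemistry**: an embedded library of 20 ring scaffolds, each with one
  substituent slot, and two disjoint substituent sets.  Drugs are
  scaffold × drug-set combinations; *identical* metabolites copy a drug's
  SMILES; *analogs* reuse the partner's scaffold with an analog-set
  substituent (never canonical-equal to any drug); *unrelated* metabolites
  are acyclic molecules and cannot coincide with the ring-bearing drugs.
  Default fractions: 15% identical, 35% analog.
- **Signatures**: each drug owns a latent N(0,1) gene-effect vector
  (200 genes by default); related metabolites share their partner's latent;
  observed profiles add independent N(0, noise_sd²) noise, noise_sd = 0.5 —
  enough to blur but not destroy rank correlation, which is what matters for
  a rank-based statistic.  Per-gene variance structure is not modeled.
- **Pathways**: each planted related pair gets, with probability 0.9, its
  own private disease-related pathway, so related pairs label positive at
  that rate and unrelated pairs never do; background non-disease pathways
  keep every entity annotated.
- **Microbes/annotations**: metabolites are partitioned among 20 microbes
  over nine phylum labels; habitat is gut with probability 0.2; drugs draw
  1–2 ATC level-1 letters from the 14-letter alphabet plus small
  indication/side-effect/immune-term sets.  An optional planted bicluster
  pins a (phylum, ATC class) block of identical-copy metabolites.

All randomness derives from one master seed through independent per-stage
streams, so outputs are byte-reproducible and adding a stage does not shift
the others.  The default sizes (40 drugs × 60 metabolites) keep a full
pipeline run under a few seconds; they are deliberately desk-scale.

**What passing tests do and do not show.**  The universe has clean planted
structure: relatedness is binary, pathway sharing is private-by-pair, and
signatures share a single gene space.  Success here demonstrates the
machinery is correct (oracles, conservation laws, planted-structure
recovery, parameter recovery), not that the score's precision tiers would
hold on real compound databases, whose chemistry, annotation sparsity and
signature noise are far messier.

## Numerical choices and degenerate inputs

- Ties: average ranks in Spearman; gene-id order in connectivity ranking;
  lexicographic ids everywhere a deterministic order is needed (pair-table
  ties, seed edges, hub/island sets, block membership).
- Missing data: invalid SMILES exclude the record; absent or constant
  signatures and <3 shared genes yield a missing expression value and
  structure-only scoring; unannotated entities are unlabeled in the
  benchmark and empty-ATC in the network.
- Precision over an empty slice is an explicit undefined marker (NA in
  output), never a silent 0 or 1.
- Tabular floats are written with round-trip precision and read back with
  pandas' `float_precision="round_trip"` so writer→reader→writer is
  byte-stable.

## Known limitations

- The fusion rule is a fixed convex blend; no calibration to probabilities
  and no significance estimates on scores or blocks.
- The connectivity statistic uses a single ranked list per compound —
  replicate structure, cell lines and doses are out of scope.
- Biclustering implements the qualitative core only (no negative-correlation
  block pairing beyond the symbol scheme, no per-row rank selection by
  information content, no block p-values).
- Hub/island status is a count statistic on the thresholded network; it
  inherits all sensitivity to the 0.6 cutoff.
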