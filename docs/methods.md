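# Methods

## Problem and scope

`plantdti` models the interaction between a plant transcription factor's
DNA-binding domain (DBD) and a candidate transcription-factor binding site
(TFBS) as a supervised binary classification over (protein sequence, DNA
sequence) pairs. The package covers the full desk-scale pipeline: catalogue
ingestion and filtering, feature construction, negative-pair generation,
per-length model training, evaluation, and promoter scanning. It deliberately
does not talk to external motif databases, run third-party motif-comparison
tools, or handle ChIP-seq/DAP-seq data; the catalogue exchange format is a
plain 7-column TSV that database exports can be flattened into.

## Catalogue filtering

Three filters are applied on load, in order:

1. **link de-duplication** — exact duplicate (tf_id, motif_id) rows are
   dropped, first occurrence wins;
2. **monotypic-DBD restriction** — a TF listed with more than one DBD type is
   removed entirely, because features and profiles are keyed by a single DBD
   type per protein;
3. **length restriction** — motifs shorter than 7 or longer than 15 bp are
   removed; the models are trained per length on that range only.

Filtering is idempotent, and every dropped row is counted in a filter report.
By default a non-standard amino-acid letter (B, J, O, U, X, Z) aborts the
load; lenient mode drops the offending record instead. The strict default
exists because the binding-mode classes below are defined only for the 20
standard residues.

IUPAC degenerate motifs are expanded to their complete set of concrete
A/C/G/T sequences (the Cartesian product over per-position degeneracies)
before any training; duplicate (TF, sequence) pairs from overlapping
expansions are kept once. A configurable cap (default 65,536 expansions per
motif) turns pathological all-N motifs into an explicit error instead of an
out-of-memory condition.

## Features

**DBD block (3 features).** Residues are partitioned into three DNA-contact
modes: hydrogen-bonding (R, K, H, S, N, Q, D, E), van der Waals (F, P, T, G,
A, V, L, I, Y) and weakly binding (C, M, W). The features are the three
class fractions n_k / l over the domain length l; they always sum to 1, are
permutation-invariant (composition only), and need no scaling.

**TFBS block (4·L features).** Position-major, four slots per position in
base order A, T, C, G.

* *binary*: one-hot (A→1000, T→0100, C→0010, G→0001), so a length-L site
  occupies 4·L slots of which exactly L are 1 (28 features at L=7, 60 at
  L=15).
* *base-preference*: the slot of the observed base at position j carries
  P_j(X), the empirical probability of that base at that position among the
  positive sites of the pair's DBD type and length; the other three slots are
  zero. A base never seen at a position (P=0) zeroes the whole position.

The base-preference profile is the column-wise mean of one-hot indicators
over the N positive interactions of a (DBD type, length) group:
P_j(X) = (1/N) Σ_i 1[site_i has X at j]. Each profile column sums to 1. No
pseudocount is added by default — a structural zero is information the
encoder uses — but an optional α can be added to every count cell before
normalisation. Profiles are estimated from positive *training* records only,
never from negatives or held-out data, to avoid label leakage; they are
frozen into the trained model and serialisable as minimal MEME motif text.

Design note: several readings of "encode the site by positional
probabilities" are possible (the full 4·L profile regardless of the query
sequence; a length-L vector of observed-base probabilities; one-hot masked by
the observed-base probability). The package uses the one-hot-masked variant:
it is sequence-discriminative, keeps the advertised 4·L feature count, and
degenerates exactly to the binary code when every profile column is one-hot.
A uniform profile reproduces 0.25 × binary.

An unknown DBD type at prediction time is a hard error in base-preference
mode, not a silent fallback to the binary code: the model's advertised scope
is the DBD types it has profiles for.

## Negative pairs

Two schemes generate one negative per positive (ratio configurable):

* **RP (random pairs)** — the positive's DBD is re-paired with a site drawn
  uniformly from the positive site pool of the same length group. Probes
  whether the model knows *which partner belongs to which*.
* **RW (random within)** — the positive's own site with its bases uniformly
  permuted (every negative is an anagram of its source). Probes whether the
  model knows *the sequence pattern itself*.

A candidate is rejected when any TF of the same DBD type positively binds
that exact sequence (type-level exclusion — the strictest reading, which also
prevents contradictory labels in the synthetic benchmark), when it equals the
source site, or when it duplicates an already-generated negative of the same
TF. A site whose quota cannot be filled within 1,000 draws per needed
negative is excluded and reported (homopolymers under RW have no distinct
permutation; a site positive for every DBD type has no admissible RP
partner). Negatives are generated before the train/test split and split
together with the positives; generation is per length group, since models
are per length, and byte-reproducible for a fixed seed.

## Models and training

Records of each length are split 70:30, stratified by label (each (length,
label) stratum contributes round(0.7·n) records to training), and one
classifier is fitted per (length, scheme) cell:

* **RF (default)**: 100-tree random forest, seeded; 100 trees because F1
  performance is flat beyond that point, and the predicted probability is
  then a rational number with denominator 100.
* **NB**: Gaussian naive Bayes — appropriate since all features are
  real-valued fractions/probabilities in [0, 1].
* **kNN**: Euclidean distance on the raw features (no scaling needed, all
  features already lie in [0, 1]); k selected over odd values 3–103 by
  10-fold cross-validated F1, ties broken toward smaller k.

Prediction thresholds use the convention prob ≥ t. The default operating
threshold is 0.7; model-comparison F1 (the encoding ablation) is evaluated
at 0.5, the symmetric classification threshold, because a degenerate model
that never predicts a positive has an undefined F1 at high thresholds — an
undefined F1 from zero positive predictions ranks as 0 in comparisons, and
is reported as NA everywhere else, never silently as 0.

Persistence is a directory holding a plain-JSON manifest (every model's
seed, classifier, hyperparameters, profiles and hold-out metrics) plus one
joblib file per estimator. Reloaded models reproduce probabilities
bit-identically within one scikit-learn version.

## Evaluation

Confusion counts at a threshold give accuracy, sensitivity, precision,
specificity and F1 by their closed forms; AUROC is the rank-based area under
the ROC curve (ties counted half), computed via scikit-learn and
cross-checked in the tests against an O(n²) pairwise Mann–Whitney oracle.

## Promoter scanning

All windows of 7–15 bp are enumerated on both strands of the promoter
(coordinates 0-based half-open on the forward strand; a minus-strand window
carries the reverse complement of the forward slice). Windows containing
non-ACGT characters are skipped and counted. A 2,000-bp promoter yields
2 · Σ_{L=7..15} (2001 − L) = 35,820 windows. Every (window, TF) pair of a
matching length is scored by that length's RP and RW models; a **consensus
hit** requires both probabilities ≥ τ. The strictest setting τ = 1 keeps
only pairs scored with probability exactly 1 by both models. Predictions are
made once per unique (TF, window sequence) and mapped back to positions;
hits are deduplicated on (tf_id, promoter, start, end, strand), so the same
sequence at two positions yields two hits. Defining the promoter (e.g.
2,000 bp upstream of the translation start) is the caller's responsibility —
the scanner processes whatever FASTA it is given.

## Synthetic benchmark

The generator plants exactly the structure the method assumes, so the whole
pipeline is testable offline:

* each (DBD type, length) gets a profile whose columns are
  s·(random one-hot) + (1−s)·0.25; the planting strength s interpolates
  between no type signal (s=0) and deterministic consensus sites (s=1);
* binding sites are drawn column-wise from the planted profile; optionally a
  per-position rate widens positions to 2-base IUPAC codes (the drawn base
  merged with the profile's strongest alternative — only 2-base codes, to
  keep expansions bounded);
* DBD sequences are random with a type-specific residue-class bias
  (probability 0.6 of drawing from the favoured binding-mode class), so the
  composition features also carry type signal. Random biased strings suffice
  because the DBD features see composition only;
* promoters are uniform-background sequences with planted sites embedded at
  known coordinates (reverse-complemented for minus-strand spikes) and a
  ground-truth record per spike.

Reference benchmark conditions (the package defaults): 2 DBD types, 50 TFs
per type, one motif per TF per length over all nine lengths (`motifs_per_type`
counts motifs per (type, length) cell, assigned round-robin, which guarantees
every cell of the model grid is trainable), s = 1, degeneracy 0, DBD lengths
40–80, one negative per positive. Each per-length model then trains on about
100 positive and 100 negative pairs — large enough that averaged chance-level
checks are statistically meaningful, small enough to run in seconds.

What passing on this benchmark does and does not show: the synthetic classes
are separable by construction at s = 1, so near-perfect hold-out metrics
demonstrate that the pipeline recovers planted signal, not that real plant
catalogues are this clean. Real data have correlated positions within motifs,
phylogenetically related domain sequences, heterogeneous motif counts per
type, and experimental noise — none of which the generator emulates. The
chance-level control (s = 0 → AUROC ≈ 0.5) guards against information
leaking through the pipeline itself (e.g. profiles estimated on test data),
which is the failure mode synthetic data can detect.

## Numerical conventions and edge cases

* Base order within a position is fixed to A, T, C, G everywhere.
* Coordinates are BED-style 0-based half-open; minus-strand hits are
  reported on forward coordinates with strand "−".
* Profile rows must sum to 1 within 1e-9; metric identities hold to 1e-12.
* Undefined metrics (zero denominators) are NA, never 0 — except that an
  undefined F1 from zero positive predictions ranks as 0 in model
  comparisons (see above).
* Ties in kNN selection break toward smaller k; ties in profile-column
  ordering (for IUPAC widening) break by stable sort on base order.
* All generators, splits and estimators take explicit integer seeds; equal
  seeds give byte-identical catalogues, negative sets, models and
  probabilities on one machine and library version.

## Known limitations

* Only monotypic-DBD TFs are modelled; multi-domain TFs are filtered out.
* The base-preference encoding requires the query's DBD type to appear in
  the training catalogue; there is deliberately no fallback.
* Independent per-position profiles ignore within-motif dependencies.
* The RW scheme cannot produce negatives for homopolymeric sites, and very
  low-complexity sites yield few distinct permutations; these are excluded
  and reported rather than silently kept.
* Model persistence relies on joblib; bit-exact reload is only promised
  within a single scikit-learn version.
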