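# plantdti

Machine-learning prediction of interactions between plant transcription-factor
**DNA-binding domains (DBDs)** and **transcription-factor binding sites
(TFBSs)** of 7–15 bp. Given a catalogue of experimentally supported DBD–TFBS
pairs, `plantdti` builds numeric features for each (protein, DNA) pair, trains
one random-forest classifier per binding-site length under two complementary
negative-sampling schemes, and scans promoter sequences for candidate
regulators of a gene of interest.

## Who this is for

Regulatory-genomics researchers working on plant species for which
experimentally measured TF–TFBS data are sparse: the classifier generalises
across transcription factors that share a DBD type, so it can nominate binding
sites — and hence candidate upstream regulators — for TFs that have never been
assayed directly.

## The model

A labelled example is a pair (DBD amino-acid sequence *d*, concrete binding
site *t* of length *L*). Its feature vector concatenates:

* **DBD binding-mode composition** — the fractions *n<sub>k</sub>/l* of
  residues in three DNA-contact classes over the domain length *l*:
  hydrogen-bonding *hb* = {R,K,H,S,N,Q,D,E}, van-der-Waals *dw* =
  {F,P,T,G,A,V,L,I,Y}, and weak-binding *wb* = {C,M,W} (3 features);
* **TFBS encoding** (4·*L* features, position-major, base order A,T,C,G):
  either the classic one-hot *binary* code (A→1000, T→0100, C→0010, G→0001 —
  e.g. `CAGCCG` → `001010000001001000100001`), or the *base-preference* code,
  in which the observed base's slot carries

  P<sub>j</sub>(X) = (1/N) Σ<sub>i=1..N</sub> 1[site *i* has base X at position *j*],

  the positional base probability estimated per (DBD type, *L*) from the
  positive training interactions. The base-preference encoding injects
  DBD-type specificity into the DNA features and is the package default.

Negative (non-interacting) pairs are generated two ways: **RP** re-pairs each
DBD with a binding site from another interaction of the same length group, and
**RW** permutes the bases within each positive's own site; both exclude
anything positive for the same DBD type. One 100-tree random forest is trained
per (length, scheme) cell — up to 9 × 2 = 18 models — on a stratified 70:30
split. A promoter scan slides windows of 7–15 bp over both strands and calls a
(TF, window) pair a **consensus hit** when the RP-trained and RW-trained
models both score it at or above the probability threshold (default 0.7).

IUPAC degenerate motifs (R, Y, N, …) are expanded to their full set of
concrete sequences before training; catalogues are filtered to monotypic-DBD
TFs (exactly one DBD type) and site lengths 7–15.

## Worked example

A fully synthetic catalogue (two DBD types with planted base preferences)
stands in for a real database export:

```python
from plantdti import benchmark_config, sample_catalogue, train_suite, predict_proba

config = benchmark_config(seed=0, tfs_per_type=10, motifs_per_type=10, lengths=(7, 8))
positives = sample_catalogue(config).positives()
registry = train_suite(positives, seed=0)
for (L, scheme), m in sorted(registry.metrics.items()):
    print(f"L={L} {scheme}: accuracy={m.accuracy:.3f}  F1={m.f1:.3f}  AUROC={m.auroc:.3f}")
```

prints the hold-out metrics of the four trained models:

```
L=7 RP: accuracy=1.000  F1=1.000  AUROC=1.000
L=7 RW: accuracy=1.000  F1=1.000  AUROC=1.000
L=8 RP: accuracy=1.000  F1=1.000  AUROC=1.000
L=8 RW: accuracy=1.000  F1=1.000  AUROC=1.000
```

(at full planting strength the synthetic classes are separable by
construction, so held-out metrics of 1.0 are the expected outcome). Scoring a
single pair:

```python
model = registry.get(7, "RP")
pair = next(p for p in positives if p.length == 7)
result = predict_proba(model, [pair])[0]
print(f"{result.tf_id} x {result.tfbs_sequence}: p(interacting) = {result.prob:.2f}")
```

```
DBD00_TF000 x GCCTTAA: p(interacting) = 0.91
```

The probability is the fraction of forest trees voting "interacting"; 0.91 is
above the 0.7 operating threshold, so this pair would be called an
interaction (as it should be — it is a training positive).

The same pipeline is available from the shell:

```bash
plantdti synth --seed 5 --out bundle                     # synthetic benchmark bundle
plantdti train --catalogue bundle/catalogue.tsv --seed 1 --out models
plantdti scan  --promoter bundle/promoter.fa --tfs tfs.tsv \
               --models models --threshold 0.7 --out hits.bed
```

`hits.bed` is BED6: promoter id, 0-based half-open interval, TF id,
round(1000·min(p_RP, p_RW)), strand.

## Documentation

`docs/methods.md` describes the model, the synthetic data generator, the
parameter defaults and the numerical conventions in detail.
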