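# ksp

Kinase–substrate prediction for protein phosphorylation sites.

Given a phosphosite (a 15-mer window: the phosphorylated S/T/Y residue
plus ±7 flanking residues), `ksp` ranks candidate catalyzing kinases by
combining three scorers:

* **Network affinity (KSPScore)** — an integrated undirected graph is
  built from known kinase–substrate pairs and protein–protein
  interactions. The affinity between a kinase and a substrate protein is
  a weighted sum of edge-weight products over connecting paths of length
  1–4 (terms KS0–KS3, combined with a beta vector, default
  `0.25, 0.225, 0.1875, 0.1875`), damped by a degree-dependent punitive
  factor in `[0.8, 1]` that counteracts the bias toward heavily studied
  kinases. Two walk semantics are available: `simple` (default;
  intermediate nodes distinct and excluding the endpoints) and `literal`
  (the nested neighbor sums evaluated verbatim).
* **PWM score** — per-kinase 20×15 position weight matrices of log2
  likelihoods against a background composition.
* **CBS score** — a BLOSUM62 k-nearest-neighbor classifier over training
  peptides (default neighborhood: 7.5 % of the training set); peptides
  with fewer than 7 real residues on either flank have similarity 0.

Per query site, each scorer's scores over the candidate kinases are
min–max normalized; `SequenceScore = normPWM + normCBS` and
`OverallScore = normKSP + SequenceScore`.

The package also ships the full evaluation protocol (k-fold
cross-validated top-k accuracy, per-kinase 7:3 splits with 1:1 negative
sampling, confusion-matrix metrics, ROC/PR curves) and a synthetic data
generator that plants kinase–substrate links in a heavy-tailed network
and per-kinase sequence motifs, so everything is testable without any
external downloads.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact
reproduction of published per-kinase evaluation tables from their
confusion counts, exact equivalence of the KS terms against brute-force
path enumeration on 500 random graphs, the punitive-function and
PWM/CBS contracts, AUROC equality with a pair-counting oracle, and
end-to-end recovery of planted kinases on synthetic data.

## Command line

```bash
# generate a synthetic dataset with planted structure
ksp simulate --spec spec.yaml --out data/

# build and persist the integrated network
ksp build-net --pairs data/pairs.tsv --ppi data/ppi.tsv --out net/

# train per-kinase PWMs (kinases with > 15 distinct site peptides)
ksp train-seq --pairs data/pairs.tsv --min-sites 15 --alpha 0.5 --out models/

# rank kinases for query sites
ksp score-net --net net/ --sites sites.tsv --top-k 10
ksp score-seq --models models/ --corpus data/pairs.tsv --sites sites.tsv
ksp score-all --net net/ --models models/ --corpus data/pairs.tsv \
              --sites sites.tsv --mode overall --top-k 10 --out scores.tsv

# cross-validated top-k accuracy of the network scorer
ksp evaluate --pairs data/pairs.tsv --ppi data/ppi.tsv --folds 10 --seed 17
```

Query sites are TSV rows `substrate<TAB>position<TAB>peptide`.
Kinase–substrate tables are accepted in two dialects: `plain`
(`kinase substrate position peptide`) and `psp`
(`KINASE SUB_ACC_ID MOD_RSD SITE_+/-7_AA`, lowercase modified residue
allowed). All readers accept gzip-compressed input.

## Layout

```
src/ksp/io_formats.py          tables, FASTA, 15-mer windows, filters
src/ksp/network_scoring.py     integrated network, KS terms, affinity graph
src/ksp/sequence_scoring.py    PWMs, BLOSUM62 KNN (CBS)
src/ksp/combined_scoring.py    normalization, SequenceScore/OverallScore
src/ksp/evaluation.py          CV, splits, confusion metrics, ROC/PR
src/ksp/synthetic_fixtures.py  planted-structure data generator
src/ksp/cli.py                 `ksp` command line
```

## Notes

* The default beta vector is used exactly as published even though its
  components sum to 0.85 rather than 1; `BetaVector.normalized()` is
  available if a unit-sum vector is preferred.
* Peptide deduplication is exact-identity per kinase (a pluggable
  similarity-threshold hook is provided via
  `filter_trainable_kinases(dedup=...)`).
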