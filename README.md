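# crossfluid

Robust correlation analysis of matched blood-plasma and cerebrospinal-fluid
(CSF) metabolite profiles from targeted MRM peak-area tables.

Given a long-format table of integrated peak areas (subject, group, fluid,
replicate, metabolite, peak_area), the package:

1. averages replicate measurements per (subject, fluid), ln-transforms, and
   filters metabolites by per-fluid detection fraction (`crossfluid.core_io`);
2. fits, per metabolite, a Huber M-estimate regression (IRLS, MAD/0.6745
   scale) of ln CSF on ln plasma across subjects, and reports the
   Huber-weight-based weighted Pearson correlation with a robust sandwich
   significance test, alongside the plain OLS/Pearson comparison
   (`crossfluid.robust`);
3. classifies metabolites whose plasma–CSF correlation is present in only one
   clinical group ("lost in patients" / "lost in controls"), counts per-scope
   significant sets and their intersection (`crossfluid.groups`);
4. builds a pairwise metabolite correlation graph on pooled profiles,
   partitions it with a flat degree-corrected stochastic block model by
   description-length minimisation, and extracts 95th-percentile subgraphs
   and connected components (`crossfluid.network`);
5. runs hypergeometric overrepresentation with Benjamini–Hochberg FDR against
   user-supplied GMT pathway collections (`crossfluid.enrichment`);
6. embeds profiles with PCA or UMAP and fits OPLS-DA for group discrimination
   (`crossfluid.projection`).

A simulator (`crossfluid.synthetic`) generates replicate-level two-fluid,
two-group cohorts with planted per-group plasma–CSF correlations, metabolite
correlation blocks, outlier contamination and detection structure, so the
whole chain is testable without any external data.

## Command line

```sh
crossfluid simulate --out sim/ --seed 1
crossfluid correlate --input sim/peak_table.csv --out corr.csv
crossfluid compare-groups --corr corr.csv --out comparison/
crossfluid network --input sim/peak_table.csv --q 0.95 --blocks 2 --seed 1 --out net/
crossfluid enrich --query query.txt --gmt sim/fixture.gmt --out enrichment.csv
crossfluid project --input sim/peak_table.csv --method pca --out coords.csv
crossfluid run-all --config pipeline.yaml
```

`run-all` takes a schema-validated YAML config (see `crossfluid.cli.PipelineConfig`
for all keys; unknown keys are rejected):

```yaml
input_table: sim/peak_table.csv
gmt: sim/fixture.gmt
out_dir: results/
alpha: 0.05
min_abs_r: 0.7
percentile_q: 0.95
seed: 1
```

Every run writes a `manifest.json` with the config hash and a SHA-256 per
output file; reruns with the same seed are byte-identical.

## Notes on statistical choices

- Replicates are averaged on the raw area scale before the natural-log
  transform; the detection filter defaults to an 80% per-fluid presence
  fraction and is exposed as a flag.
- Huber tuning constant 1.345, tolerance 1e-8, at most 50 IRLS iterations.
- `p_huber` comes from the M-estimator sandwich slope test with Huber's
  small-sample correction; applying the Pearson t formula to the weighted
  correlation is anticonservative under the null (the adaptive weights
  inflate |r|), which the test suite demonstrates.  The plain t-based
  `correlation_pvalue` is kept for the OLS columns.
- The block model is a flat two-block DC-SBM on the binarised significant
  edge graph, fitted by greedy description-length minimisation with seeded
  restarts (20 by default).
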