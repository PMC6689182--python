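# cisrate

Quantitative modeling of the general mRNA sequence features that control
translation rates in eukaryotes. The package computes five families of
features from per-gene mRNA sequences —

1. **RNA folding** in the 5' region: sliding-window minimum free energies
   (builtin simplified Zuker-style folder, or ViennaRNA as an optional
   backend), turned into 21 per-length feature families (location-anchored
   windows, energy-rank windows, threshold percentages/sums, whole-region
   fold) plus dot-bracket stem statistics;
2. **5' sequence motifs**: position weight matrices anchored at the
   initiating AUG or the 5' cap, an APE (AUG-proximal element) boundary scan,
   and di-/tri-nucleotide frequencies per mRNA region;
3. **uAUG** counts in the 5'UTR;
4. **CDS length** (log10 number of encoded amino acids);
5. **codon usage**: codon / amino-acid / synonymous-codon-preference
   frequencies, including N-/C-terminal half splits

— then regresses log10 translation rate on them with (possibly multipart)
OLS, selects features by BIC forward selection, bootstraps confidence
intervals, and quantifies the collinearity ("overlap") of control between
feature sets and between mRNA segments. A fully seeded synthetic-data
generator plants each effect with known ground truth so the entire pipeline
is testable offline.

## CLI

```bash
# 1. make a synthetic dataset (FASTA + annotation TSV + ground-truth TSV)
cisrate generate --n-genes 1000 --seed 7 --target-r2 0.6 --out-prefix out/syn

# 2. compute fold + simple feature matrices
cisrate features --fasta out/syn.fasta --annotation out/syn.tsv \
    --lengths 25,35 --out out/features.tsv

# 3. BIC forward selection over a feature matrix
cisrate select --fasta out/syn.fasta --annotation out/syn.tsv \
    --matrix out/features.tsv

# 4. full pipeline (features -> selection -> combined model -> overlaps)
cisrate run --config run.yaml
```

A minimal `run.yaml`:

```yaml
synthetic: {n_genes: 1000, target_r2: 0.6}
window_lengths: [25, 35]
ape_bounds: [-6, 13]      # omit to run the APE boundary scan instead
bootstrap: 1000
seed: 7
output_dir: out/run
```

Real data go in as `seq_source`/`annotation` (FASTA + TSV with columns
`gene_id, utr5_len, cds_len, tr, rpkm`, or a single combined table with
`gene_id, utr5_seq, cds_seq, tr, rpkm`), with `species_scheme` one of
`one_part`, `two_part_arabidopsis` (5'UTR threshold 65 nt) or
`three_part_cerevisiae` (thresholds 20/35 nt). All stage outputs are plain
TSV/JSON in `output_dir`.

## Layout

```
src/cisrate/
  data_model.py      records, iAUG coordinates, loading, cohorts, regions, parts
  folding/           NN duplex energies, simplified Zuker MFE DP, stem stats
  fold_features.py   window-energy feature families + FeatureMatrix container
  motif_features.py  PWMs, APE scan, k-mer features, high/low-TR ratio tables
  simple_features.py uAUG, CDS length, codon/AA/syn.codon profiles
  modeling.py        multipart OLS, BIC forward selection, bootstrap, overlap
  synthetic_data.py  seeded generator with planted, ground-truthed effects
  pipeline.py        end-to-end orchestration and TSV reports
  cli.py             click CLI (generate / features / select / run)
```
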