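# oncoamp

Amplicon-to-candidate-oncogene analysis pipeline for tumour cohorts:

1. **qPCR screen** (`oncoamp.qpcr`) — relative-quantification gene dosage
   from Ct values (efficiency-corrected ΔΔCt; ratio 1 ≡ two copies), with
   amplification called at copy number strictly above 3.5 and cohort
   selection on a marker-gene panel.
2. **Copy-number calling** (`oncoamp.cncall`) — absolute integer copy
   number from SNP-array LRR/BAF: greedy binary segmentation of LRR,
   integer (CN, minor-allele) grid fit against LRR + mirrored-BAF
   expectations, probe-weighted modal ploidy for aneuploidy correction,
   and gained/lost/normal segment labels.
3. **Significant regions** (`oncoamp.regions`) — per-marker G-score (mean
   amplification amplitude above ploidy across samples), a cyclic-shift
   permutation null pooled across markers, Benjamini–Hochberg q-values,
   and maximal q < 0.25 runs reported as regions with one peak each.
4. **Integration and ranking** (`oncoamp.integrate`) — per gene/tumour
   copy number from the probes within or nearest to the gene body, fold
   change versus an osteoblast reference (overexpressed at ≥ 2),
   overexpressed-given-amplified (O/A) ranking with a ≥ 50% filter, and a
   Pearson copy-number/expression filter (R > 0, two-sided P ≤ 0.05).
5. **Synthetic cohorts** (`oncoamp.simulate`) — seeded LRR/BAF, qPCR and
   expression data with planted amplicons and known truth, so every stage
   is testable end to end without external data.

## CLI

```sh
oncoamp simulate --seed 0 --n-tumours 20 --out-dir simdata
oncoamp screen simdata/ct_dosage.tsv --out calls.tsv
oncoamp callcn --probes simdata/probes.tsv --lrr simdata/lrr.tsv \
    --baf simdata/baf.tsv --out-dir results
oncoamp regions --probes simdata/probes.tsv --cn-matrix results/cn_matrix.tsv \
    --ploidy results/ploidy.tsv --out-dir results --n-perm 1000 --seed 0
oncoamp integrate --probes simdata/probes.tsv --cn-matrix results/cn_matrix.tsv \
    --genes simdata/genes.bed --expression simdata/expression.tsv \
    --reference simdata/reference.tsv --out-dir results
```

or run everything from a flat YAML config (keys mirror
`oncoamp.config.PipelineConfig`):

```sh
oncoamp -v run --config config.yaml --seed 0 --out-dir results
```

`run` writes a `manifest.json` listing every artifact with its SHA-256
checksum; identical seeds give identical checksums.

All tabular I/O is single-header TSV, genomic intervals are 0-based
half-open (BED on disk), and results go to stdout/files only — logging is
on stderr.

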