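# dualrepress

Identify genes under **dual repression** — transcriptionally silenced by a
chromatin regulator in one cell state and post-transcriptionally targeted by
a microRNA — from three evidence streams:

1. **Differential expression** between two conditions (A = stem-like
   reference, B = differentiated): detection filtering (2-of-3 / all-of-2
   rule for a 3-vs-2 design), quantile normalization, log2 transform, a
   moderated difference statistic `d = (mean_B − mean_A)/(s + s0)` with an
   exhaustive label-permutation FDR, and DEG calling at `FDR < 0.001`,
   `|log2FC| ≥ 1`.
2. **Regulator enrichment** against a scored regulator→gene binding network:
   one-sided Fisher exact test on target/DEG overlap (Bonferroni-corrected
   across regulators) plus a weighted z-score that compares the sum of
   association scores over `targets ∩ DEGs` against resampled equal-size
   subsets of the regulator's full target set (1000 draws by default).
3. **miRNA seed-match scanning** of per-gene 3′UTR and ORF sequences for
   6-mer (miRNA positions 2–7) and 7-mer (positions 2–8, m8-anchored)
   matches; a 7-mer site is never double-counted as its internal 6-mer.

The integration stage intersects regulator binding, derepression calls, an
annotation gene set (GMT) and seed-match flags into a per-gene
dual-regulation table. A synthetic-data module generates all inputs with
planted, recorded ground truth (planted DEGs, an enriched regulator with
score concordance, planted seed sites), so recovery can be scored exactly.

## CLI

```sh
# synthetic end-to-end run (writes every input and output + manifest.yaml)
dualrepress run --seed 42 --out runs/demo

# individual stages on your own files
dualrepress de --expr X.tsv --detect D.tsv --conditions cond.yaml \
    --fdr 0.001 --lfc 1 --s0 median --out de.tsv
dualrepress enrich --network net.tsv --degs up_in_B.txt \
    --universe universe.txt --resamples 1000 --alpha 0.05 --seed 42 --out enrich.tsv
dualrepress seedscan --regions regions.fa --mirna mir.fa --out seeds.tsv
dualrepress synth --config config.yaml --seed 1 --out synth/
```

File formats: expression/detection matrices are TSV (genes × samples, the
detection companion is 0/1); networks are TSV with columns
`regulator, gene, score` (scores in (0,1]); annotations are standard GMT;
sequences are FASTA with record ids `<gene>|<region>`, region ∈
{`3UTR`, `ORF`}; conditions and configs are YAML. Runs are fully
deterministic under a fixed seed — `manifest.yaml` records config, seed,
versions and output checksums, and re-running reproduces every file
byte-for-byte.

## Package layout

| module | contents |
| --- | --- |
| `dualrepress.expression` | `ExpressionMatrix`, filtering, normalization, `sam_statistic`, `sam_fdr`, `call_degs` |
| `dualrepress.enrichment` | `RegulatoryNetwork`, `fisher_overrepresentation`, `bonferroni_adjust`, `weighted_zscore`, `enrich_all` |
| `dualrepress.seeds` | `MirnaRecord`, `seed_motifs`, `scan_region`, `scan_all` |
| `dualrepress.integrate` | `bound_upregulated`, `dual_regulated`, `write_report` |
| `dualrepress.synthetic` | `SynthConfig`, `TruthRecord`, planted-truth generators |
| `dualrepress.pipeline` | `run_synthetic_pipeline`, artifact writing |
| `dualrepress.io` | TSV/GMT/FASTA/YAML readers and writers |
| `dualrepress.cli` | `dualrepress` console entry point |
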