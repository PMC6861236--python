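# polyscan

Mixed-ploidy population-genomic scans for adaptation after whole-genome
duplication: windowed divergence statistics between diploid and
autotetraploid population groups, empirical outlier calling with
permutation tests for outlier-set overlap, heuristic LD-based phasing of
diploid and tetraploid genotypes, per-window BIONJ genealogies, and
exact/Monte-Carlo topology weighting over five taxa to localise
interspecific introgression. A structured-coalescent synthetic-data
generator with full ground truth makes the whole pipeline testable offline.

## Modules

| module                  | what it does |
|-------------------------|--------------|
| `polyscan.io_popgen`    | VCF 4.x read/write with per-sample ploidy inferred from GT arity (`0/1` vs `0/1/1/1`), popmap TSV, GFF3 gene windows, SNP-count windows, BED export |
| `polyscan.divergence`   | per-window AFD, dXY, Hudson-style Fst, Rho (intraclass correlation on dosage/ploidy — ploidy-independent), fixed differences; group means over population pairs |
| `polyscan.outliers`     | empirical quantile outliers per metric, union/intersection combination, scan overlap, label-subset permutation test |
| `polyscan.phasing`      | window phasing by iterative LD (mean r²) maximisation over diploid and tetraploid allele configurations, with phase randomisation and concordance scoring |
| `polyscan.trees`        | haplotype p-distances and a deterministic BIONJ implementation |
| `polyscan.weighting`    | enumeration of the 15 rooted 5-taxon topologies, species/introgression/ILS classification, tree simplification, exact (rational) and sampled (Wilson-CI stopping) weightings, peak calling |
| `polyscan.simulate`     | minimal structured coalescent: species split, two WGDs as daughter-population foundings, tetraploid migration / introgression pulses, infinite-sites mutations, sweep spiking; emits VCF + popmap + BED + truth tables |

## CLI

The stages communicate through plain-text files (VCF, TSV, BED, newick):

```sh
# make a synthetic dataset with a sweep and an introgressed window
polyscan simulate --n-windows 20 --seed 42 \
    --sweep 3:lyrata4x:1.0 --introgress 12:arenosa4x:lyrata4x:5000:0.75 \
    --out-dir sim/

# filter + validate
polyscan ingest --vcf sim/synthetic.vcf --popmap sim/popmap.tsv \
    --max-missing 0.10 --min-dp 5 --out clean.vcf

# windowed divergence scan between taxon groups
polyscan scan --vcf sim/synthetic.vcf --popmap sim/popmap.tsv \
    --windows sim/windows.bed --contrast lyrata2x:lyrata4x --out scan.tsv

# 1% empirical outliers and overlap of two scans
polyscan outliers --scan scan.tsv --quantile 0.99 --out outliers.txt
polyscan overlap --genes-a a.txt --genes-b b.txt --universe universe.txt \
    --nperm 9999 --seed 7 --out overlap.json

# phase -> window trees -> topology weighting
polyscan phase --vcf sim/synthetic.vcf --window-snps 50 --out phased.vcf
polyscan trees --phased-vcf phased.vcf --popmap sim/popmap.tsv \
    --window-snps 50 --out trees.nwk
polyscan twisst --trees trees.nwk --taxa trees.nwk.taxa.tsv \
    --exact-threshold 2000 --ci 0.05 --seed 1 --out weights.tsv
```

## Conventions

* Coordinates are 1-based inclusive internally (VCF/GFF); BED output is
  0-based half-open.
* Missing genotypes are a distinct state, never coerced to dosage 0; all
  frequency denominators count called alleles only.
* All stochastic steps take explicit seeds; identical seeds reproduce
  identical outputs byte for byte.
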