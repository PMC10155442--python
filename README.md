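# promscreen

Mining **endogenous strong constitutive promoters** from bacterial
RNA-seq read counts, with quantitation of the downstream
characterisation assays.

Diazotrophic bacteria such as *Pseudomonas stutzeri* fix atmospheric N₂,
and engineering their nitrogen-fixation (*nif*) pathway — for example
overexpressing the pathway regulator NifA — needs promoters that are
strong in every growth condition. A simple, effective way to find them
is transcriptomic: a gene that sits in the top expression percentile of
*every* sampled condition is driven by a strong constitutive promoter,
and that promoter is, operationally, the intergenic region directly
upstream of the gene. This package implements that screen, end to end,
for people engineering bacterial expression systems from RNA-seq data.

## The screen

Given a per-gene read-count table over *S* samples (conditions) and a
genome annotation:

1. **Rank** the *n* genes of each sample by raw read counts, descending
   (rank 1 = highest; ties broken by gene id).
2. **Top fraction**: keep the first *k* = ⌈*f·n*⌉ genes per sample
   (default *f* = 0.03, the "top 3%"). A tie-inclusive boundary mode is
   available.
3. **Intersect** the per-sample top sets: genes qualifying in all *S*
   samples (configurable to ≥ *m* of *S*) are the constitutive
   candidates.
4. **Extract** each candidate's upstream intergenic region: the span
   between the gene's 5′ boundary and the nearest annotated feature
   boundary on its 5′ side (strand-aware, wrapping across the origin of
   circular replicons; overlapping neighbours give length 0).
5. **Filter**: regions shorter than 100 bp are excluded (a 100 bp region
   is retained); survivors are exported as BED, gene-oriented FASTA and a
   summary TSV.

## Assay quantitation

The companion `assays` module implements the standard formulas used to
characterise the cloned promoters and the engineered strains:

- **Relative promoter strength** (firefly luciferase):
  `100 · (L̄_p − L̄_blank) / (L̄_ref − L̄_blank)` with a promoterless-vector
  blank and a reference promoter at 100%.
- **Nitrogenase activity** (acetylene reduction, GC peak areas):
  `(A_exp/A_1nmol · V_headspace) / (m_protein · t)` in
  nmol ethylene · h⁻¹ · (mg protein)⁻¹, defaulting to a 100 mL bottle and
  4 h incubation.
- **Ammonium concentration**: OLS standard-curve fit
  (absorbance = a·c + b) and inversion, with extrapolation flagging.
- **Relative expression**: the 2^(−ΔΔCt) method against an internal
  control gene (e.g. *gapdh*).
- **One-way ANOVA + Tukey HSD** with the usual `*`/`**`/`***`
  significance stars, plus fold-change ratios rounded half away from
  zero.

## Worked example

Simulate a study bundle (annotated 250 kb circular genome, 200 genes,
4 conditions, 5 planted constitutive genes + 5 condition-specific
decoys), then screen it:

```
$ promscreen simulate --out-dir demo --seed 7 --assay-noise 0
$ promscreen screen --annotation demo/genome.gff3 \
    --annotation-fasta demo/genome.fa --counts demo/counts.tsv \
    --out-dir demo_screen
{
 "n_genes": 200,
 "n_samples": 4,
 "cutoff_size_per_sample": 6,
 "intersection": 5,
 "n_excluded_short": 1,
 "n_retained": 4
}
```

The five genes in the top 3% (k = 6) of all four samples are exactly the
planted constitutive genes; one of them sits behind an upstream gap
shorter than 100 bp and is excluded, leaving four cloneable promoters:

```
$ head -3 demo_screen/promoters_retained.tsv
promoter_id  gene_id    upstream_feature  start  end    strand  length  passed_filter
P00180       SYN_00036  SYN_00037         37980  38307  -       327     True
P00325       SYN_00065  SYN_00066         67358  67739  -       381     True
```

Quantifying the zero-noise assay tables returns the known truth, e.g.
promoter `P_A` at 250.0% of the reference promoter:

```
$ promscreen assays --assay-dir demo/assays --out-dir demo_assays
$ head -2 demo_assays/promoter_strengths.tsv
promoter_id  percent_of_reference  sd_percent  n
P_A          250.0                 0.0         3
```

On real data, point `--annotation` at a GenBank flat file (or GFF3 +
FASTA) and `--counts` at a gene × sample read-count TSV.

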