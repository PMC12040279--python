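# netqtl

Map genetic loci whose genotype classes differ in their gene co-expression
*networks* (rather than in single-gene expression levels).

At each biallelic marker, samples are grouped by genotype (A / H / B), a
Pearson correlation network over genes is built per group (optionally with
within-chromosome entries masked to zero to focus on trans effects), and the
three pairwise network differences are stacked into a `p x p x 3`
differential tensor.  The tensor is summarized by sparse spectral statistics:

* **tensor** — the sparse leading tensor eigenvalue Λ of the rank-1 sparse
  symmetric tensor decomposition `D ≈ Λ·v∘v∘u` (alternating algorithm with a
  penalized-matrix-decomposition v-update);
* **max** / **sum** / **tensor_sq** — variants built from per-slide sparse
  leading matrix eigenvalues `max |v'Dv|` and from Λ².

Statistics are calibrated by permutation (shuffle genotype labels preserving
group sizes, re-run the whole pipeline) with a two-stage scan: `B0 = 100`
screening permutations per marker, `B = 500` confirmation permutations for
markers with screening p < 0.05.  At significant markers the rank-1 fit is
unpacked into per-gene leverages (`v²`, sums to 1), a joint differential
network (`v·v'` edge weights with per-comparison reconstructed changes
`Λ·v_j·v_k·u_l`), and the genotype-comparison loading `u`.

A synthetic F2-intercross generator (one uniform crossover per chromosome
per gamete; Poisson counts whose co-expression depends on genotype at one
planted locus) makes the entire pipeline testable offline, together with a
local baseline (per-pair co-expression F-tests combined by Bonferroni) for
power comparisons.

## CLI

```sh
# synthetic dataset (expression/genotypes/genemap/markermap TSVs + truth.json)
netqtl simulate --n 300 --genes 200 --chroms 20 --effect 1.0 --seed 1 --outdir data/

# two-stage permutation scan -> Manhattan-ready TSV + manifest
netqtl scan --expr data/expression.tsv --geno data/genotypes.tsv \
    --genemap data/genemap.tsv --markermap data/markermap.tsv \
    --stat tensor --b0 100 --b 500 --seed 1 --out results/run

# joint differential network at one marker -> leverage + edge TSVs
netqtl network --expr data/expression.tsv --geno data/genotypes.tsv \
    --genemap data/genemap.tsv --marker M0101 --seed 1 --out results/m0101
```

Inputs are plain TSVs: expression is genes x samples raw counts (header =
sample ids, first column = gene ids); genotypes are markers x samples coded
`A/H/B` or `0/1/2` (`--coding dosage012`); the gene map has columns
`gene_id`, `chrom`, `pos` (chrom 0 = mitochondrial, -1 = unplaced scaffold);
optional covariates (one row per sample) are regressed out during
preprocessing (library-size normalization, `log2(x+1)`, least-squares
residualization, top-k filter by mean expression).  Any flag can be pre-set
from a YAML file via `--config`; every run writes a JSON manifest (resolved
parameters, seed, input checksums).

Sparsity `R` is interpreted as a target support size for the sparse
eigenvector (internally an L1 budget of `sqrt(R)`); `R = p` is exactly
non-sparse.  A BIC-style criterion (`netqtl.spectral.bic_select_R`) picks
`R` from a grid when no prior choice exists.

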