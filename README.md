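# hicmag

Metagenomic Hi-C contig binning: from Hi-C read alignments against a shotgun
assembly to draft genome bins (MAGs).

## The problem

Shotgun metagenome assembly yields thousands of contigs with no record of
which genome each came from. Hi-C proximity ligation adds that record: a
read pair whose mates ligate DNA from the same cell links two contigs of
the same genome, so the inter-contig contact map can be clustered into
genome bins. Two obstacles stand in the way. First, raw contact counts are
dominated by experimental biases — the number of restriction sites on a
contig, its length, and its shotgun coverage — not by genome identity.
Second, a fraction of contacts is *spurious*: cross-species ligation noise,
concentrated between closely related species, that degrades clustering.

`hicmag` addresses both and clusters what remains:

1. **Contact maps** — Hi-C alignments are filtered (mapped, primary,
   non-supplementary, match length ≥ 30, MAPQ ≥ 30), pairs bridging two
   different contigs are counted into a sparse symmetric map `c_ij`, and
   contigs shorter than 1 kbp or with Hi-C signal below 2 are removed.
2. **ZINB normalization** — on contig pairs annotated to the same species
   (a partial taxonomic labeling suffices), contact counts are modeled as
   zero-inflated negative binomial with
   `ln μ_ij = β₀ + β₁ ln(s_i s_j) + β₂ ln(l_i l_j) + β₃ ln(cov_i cov_j)`
   (sites *s*, lengths *l*, coverages *cov*; the site term is dropped in LC
   mode when the restriction enzymes are unknown). The normalized contact
   is the counting-part residual `n_ij = c_ij / μ_ij`.
3. **Spurious-contact removal** — a threshold *t* is calibrated so that at
   most 5% (configurable) of the non-zero intra-species contacts fall below
   it; all normalized contacts `< t` are discarded.
4. **Leiden binning** — the remaining weighted graph is clustered by the
   Leiden algorithm under the Reichardt–Bornholdt Potts modularity
   `Q = Σ_ij (A_ij − γ k_i k_j / 2m) δ(c_i, c_j)`, with the resolution γ
   tuned over {1, 5, 10, 15, 20, 25, 30} by the mean of ARI and NMI on the
   labeled contigs. Clusters above 150 kbp total length become valid bins.
5. **Evaluation & post-processing** — Fowlkes–Mallows / ARI / NMI against a
   ground truth, CheckM-style quality ranks, split-half validation, and
   re-clustering of partially contaminated bins (completeness > 50%,
   contamination > 10%) at γ = 1.

A synthetic-community simulator generates catalogs, labels and ZINB-biased
contact maps with full ground truth, so every stage is testable offline.

## Worked example

Simulate the default 10-species community and run the full pipeline:

```sh
hicmag simulate --seed 0 --out demo
# simulated 400 contigs, 7027 contacts

printf 'inputs:\n  map: demo/contact_map.mtx\n  catalog: demo/contigs.tsv\n  labels: demo/labels.tsv\nseed: 0\n' > demo.yaml
hicmag pipeline --config demo.yaml --out demo_run
# threshold 0.1866; gamma* 1; 10 valid bins covering 100.0% of the assembly

hicmag eval --bins demo_run/bins.tsv --labels demo/truth.tsv
# {
#   "fscore": 1.0,
#   "ari": 1.0,
#   "nmi": 1.0
# }
```

Reading the output: the spurious-contact threshold calibrated on the
labeled intra-species contacts is 0.1866 (normalized-contact units); the
resolution score peaked at γ = 1; the ten clusters exceeding 150 kbp match
the ten simulated species exactly, so all three external metrics against
the withheld full truth equal 1. `demo_run/report.json` records every
stage's bookkeeping (contigs and contacts in/out, fitted β/θ/π, per-γ
scores) plus each convention used.

The same steps are available individually (`hicmag map`, `norm`, `despur`,
`cluster`, `rank`, `postprocess`) and as library functions
(`hicmag.run_pipeline`, `hicmag.fit_hiczin`, `hicmag.leiden_cluster`, …).

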