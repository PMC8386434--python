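# rhizonet

Analysis toolkit linking soil/rhizosphere microbiome composition and local
co-occurrence network structure to treatment effects and crop yield.

The pipeline takes two marker-domain OTU count tables (16S "bacteria",
ITS "fungi") plus sample metadata from a multi-location, four-time-point
field trial and runs:

1. **Compositional transforms** — Bayesian-multiplicative zero replacement
   under a Dirichlet prior, CLR transform, Aitchison distances, PCoA, and a
   joint 70-component PCA of both marker domains.
2. **Diversity statistics** — richness and Shannon H′, Wilcoxon subgroup
   tests, per-location Z-scoring with time-point contrasts, and a sequential
   (Type I) PERMANOVA on Aitchison distances with permutation p-values.
3. **Co-occurrence networks** — exact hypergeometric pair tests for every
   OTU pair (prevalence-filtered, capped), metacommunity co-occurrence and
   co-exclusion networks, and six per-sample local-network statistics
   (modularity, transitivity, edge proportion for each edge type).
4. **Treatment effects** — treatment × time interaction contrasts per
   location on CLR abundances and on network properties, with
   Benjamini–Hochberg control.
5. **Yield model** — KDE-based yield categorisation at density minima, a
   probability forest (averaged terminal-node class frequencies) with Gini
   importances, 3/4-way sensitivity splits, and a block-level
   transitivity–yield regression.

A synthetic-study generator with planted ground truth (co-occurring /
co-excluding OTU blocks, differential OTUs, a transitivity-linked bimodal
yield) makes every stage testable without any data downloads.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(exact pair-test enumeration oracles, known-graph values, compositional
geometry, PERMANOVA oracles and null calibration, planted-structure
recovery, interaction-contrast calibration, yield-model recovery, and
end-to-end determinism).

## CLI

```sh
rhizonet simulate --fixture default --seed 1 --out study/
rhizonet validate --otu study/otu_16s.tsv --meta study/metadata.tsv
rhizonet transform --otu study/otu_16s.tsv --marker 16S --out transformed/
rhizonet diversity --otu study/otu_16s.tsv --meta study/metadata.tsv \
    --terms location,time_point,treatment --n-perm 999 --seed 1 --out div/
rhizonet network --otu study/otu_16s.tsv --marker 16S --min-prev 0.30 \
    --alpha 0.05 --out net_16s.tsv
rhizonet localprops --network net_16s.tsv --otu study/otu_16s.tsv \
    --meta study/metadata.tsv --out props.tsv
rhizonet run --config run.yaml          # full pipeline with manifest
```

A `run.yaml` needs explicit seeds for each stochastic stage:

```yaml
out_dir: results/run1
seeds: {synthetic: 1, permanova: 2, forest: 3}
synthetic: {}            # or otu_16s/otu_its/metadata paths
n_perm: 999
scheme: two              # two | three | four yield categories
```

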