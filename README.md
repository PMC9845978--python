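# phylosyndrome

Phylogenetic association analysis of binary colour, pattern and host-use
traits, with observer-bootstrap consensus support.

## The problem

Do particular caterpillar colours co-evolve with particular pattern
elements (warning "syndromes" such as black-with-yellow bands, or
camouflage such as green with stripes), and do colours and patterns track
host-plant ecology (growth form, tissue consumed, diet breadth)?  Answering
this across a species-level phylogeny requires three ingredients that this
package provides as a tested, reusable toolkit:

1. **Trait coding** — per-observer scores (up to three salient colours from
   an 11-colour vocabulary, five pattern elements, host ecology) become a
   binary species × trait matrix.  Two-colour composites are first-class
   traits (`black/yellow` can signal differently from `black` or `yellow`
   alone); rare colour traits (fewer than 5 occurrences) are excluded;
   three-colour combinations are never expanded.
2. **Phylogenetic logistic regression** — for binary tip traits
   y ~ Bernoulli(μ), logit(μ) = β₀ + β₁x, with residual correlation
   between tips R(α)ᵢⱼ = exp(−α·dᵢⱼ) decaying with patristic distance d on
   the height-normalized tree.  β is estimated by Firth-penalized
   estimating equations (finite under separation), α by residual moment
   matching; inference is by two-sided Wald tests.
3. **Association pipeline** — every coloration ~ pattern/ecology pair is a
   model; p-values are Benjamini–Hochberg adjusted within *a priori*
   (literature-predicted) and exploratory families separately; the whole
   analysis is repeated over B bootstrap datasets drawing one observer's
   scores per species, and a pair is reported only when it is
   FDR-significant with a consistent sign in ≥ 90% of replicates.

A synthetic-data module generates ultrametric trees (Yule/birth–death),
phylogenetically structured binary traits with planted effects, and
two-observer scoring noise, so every stage is testable without any
download.

## Worked example

```python
from phylosyndrome import (
    SimConfig, simulate_dataset, PipelineConfig, run_full_analysis,
    expand_composites,
)

# composite colour coding: a yellow/black/white species carries 6 traits
print(sorted(expand_composites({"yellow", "black", "white"})))
# ['black', 'black/white', 'black/yellow', 'white', 'white/yellow', 'yellow']

# simulate a 300-species study: orange is planted on forb-feeders
# (log-odds effect 2.0), two observers disagree on 10% of trait scores
ds = simulate_dataset(SimConfig(n_tips=300, beta_true=(-1.0, 2.0),
                                disagreement_rate=0.1, seed=0))

pairs = [("orange", "forb"), ("green", "forb"), ("brown", "forb"),
         ("band", "forb"), ("stripe", "forb")]
cfg = PipelineConfig(n_bootstrap=100, seed=1, explicit_pairs=pairs)
results = run_full_analysis(ds.scores, ds.ecology, ds.tree, cfg)
for r in results:
    print(f"{r.spec.response:>6} ~ {r.spec.predictor}: "
          f"beta1={r.full_data_fit.beta[1]:+.2f} support={r.support:.2f} "
          f"supported={r.supported}")
```

prints (exactly, for these seeds):

```
orange ~ forb: beta1=+1.73 support=1.00 supported=True
 green ~ forb: beta1=+0.08 support=0.01 supported=False
 brown ~ forb: beta1=-0.23 support=0.00 supported=False
  band ~ forb: beta1=+0.44 support=0.00 supported=False
stripe ~ forb: beta1=-0.13 support=0.00 supported=False
```

The planted orange–forb association is significant (with the planted
positive sign) in all 100 observer-bootstrap replicates and is the only
supported pair; `support` is the fraction of converged replicates in which
a pair stayed FDR-significant with a consistent sign.

The same analysis runs from the shell:

```bash
phylosyndrome simulate --out sim/ --seed 0
phylosyndrome run --tree sim/tree.nwk --scores sim/scores.csv \
    --ecology sim/ecology.csv --out results/ --bootstrap 1000 --seed 1
```

producing `edges.csv` (the supported-association edge list), `network.json`
(node-link graph, colours as circles / patterns as squares) and
`results.json` (all fits and supports).

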