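# isofactor

Bayesian supervised factor analysis for **protein isoform quantification**
from bottom-up mass-spectrometry peptide data, supervised by transcript
expression.

## The problem

A single gene can encode several protein isoforms through alternative
splicing. Bottom-up proteomics only measures short peptides, and a peptide
frequently maps to more than one isoform, so isoform abundances are not
directly observable: standard practice collapses isoforms into protein
groups or aggregates peptides (average / sum / maximum) regardless of
sharing. `isofactor` instead treats isoform abundances as latent factors and
estimates them jointly from the peptide matrix, an isoform-peptide
detectability mask, and (optionally) matched transcript expression and a
binary condition (e.g. case/control), with full posterior uncertainty and
differential-abundance testing.

## The model

For samples *i*, isoforms *j*, peptides *k*, with transcript matrix **T**
(n×q), peptide matrix **P** (n×r), condition vector **A** and latent
isoform abundances **I**:

```
I = I0 + T W + A Dᵀ + E_I        E_I,ij ~ N(0, 1)
P = I Z + E_P                    E_P,ik ~ N(0, σ²_k)
```

* **W** — diagonal transcript-to-isoform conversion weights, prior N(1, τ_w):
  transcript expression is a priori proportional to isoform abundance.
* **D** — condition effects, prior N(0, τ_d), or a spike-and-slab mixture
  θ·N(0, τ_d) + (1−θ)·δ₀ for sparser, more conservative calls.
* **Z** — detectability coefficients, zero wherever the mask forbids a
  peptide-isoform pairing; on-support entries get a truncated-normal prior
  N̄(1, τ_z) supported on [l̄_j, ū_j], where l̄_j is the ratio of the smallest
  to the largest compatible peptide column mean (and ū_j = 1/l̄_j), keeping
  latent abundances on the observed peptide scale.
* **σ²_k** — heteroskedastic peptide noise, conjugate Inverse-Gamma priors.

All full conditionals are closed-form, so inference is plain Gibbs sampling
(default 3000 iterations, 2000 burn-in, 10 chains). Because **Z** is block
diagonal over connected components of the isoform-peptide graph, every block
is sampled independently on its own random stream — block-parallel execution
is draw-for-draw identical to whole-matrix execution.

Significance uses the **local false sign rate**:
`LFSR_j = min{ P(D_j ≥ 0 | data), P(D_j ≤ 0 | data) }`; isoforms with
LFSR ≤ 0.05 are called differentially abundant, and cross-chain detection
counts measure the stability of each call.

## Worked example

```python
import numpy as np
from isofactor import IsoformAbundanceModel
from isofactor.simulate import ScenarioConfig, simulate_difficult

# 5 isoforms sharing 10 peptides; the first two isoforms carry a unit
# condition effect
sim = simulate_difficult(
    ScenarioConfig(scenario="difficult", n=200, effect=1.0, dact=2, seed=11)
)
model = IsoformAbundanceModel(
    P=sim.data.P, mask=sim.data.mask, T=sim.data.T, A=sim.data.A,
    bounds="data-abs",
)
results = model.fit(n_iter=3000, burn_in=2000, n_chains=4, seed=0)
print(results.summary().round(3).to_string(index=False))
```

prints

```
isoform_id  post_mean_D  post_sd_D  lfsr  pip  detected  detection_count
      iso0        0.938      0.163 0.000  NaN      True                4
      iso1        0.969      0.209 0.000  NaN      True                4
      iso2       -0.064      0.154 0.336  NaN     False                0
      iso3        0.017      0.163 0.458  NaN     False                0
      iso4        0.110      0.212 0.300  NaN     False                0
```

The two truly differential isoforms are recovered close to their simulated
effect of 1 with LFSR 0 in all four chains; the three null isoforms stay
near zero and are never called. `results.isoform_abundance` holds the
posterior-mean latent abundances, `results.pair_correlations()` the
transcript-isoform Pearson correlations with mapping-ambiguity classes and
±0.3 tail flags, and `results.consensus(gamma)` the cross-chain consensus
set at minimum agreement `gamma`.

A command-line interface mirrors the library:

```
isofactor simulate --scenario easy --n 100 --effect 1 --seed 1 --outdir data/
isofactor run --peptides data/peptides.tsv --mask data/mask.tsv \
    --transcripts data/transcripts.tsv --condition data/condition.tsv \
    --seed 0 --outdir out/
isofactor postanalyze --abundance out/isoform_abundance.tsv \
    --transcripts data/transcripts.tsv --mask data/mask.tsv --outdir out/post/
isofactor benchmark --scenario easy --seeds 25 --outdir bench/
```

## Layout

```
src/isofactor/
  data.py         observed-data containers, priors, truncation bounds, validation
  preprocess.py   peptide/transcript normalization, isoform grouping, blocks
  sampler.py      full conditionals, truncated-normal sampling, Gibbs chains
  inference.py    LFSR, detection, consensus, chain-stability filtering
  model.py        IsoformAbundanceModel / IsoformAbundanceResults
  simulate.py     scenario generators, t-test baselines, recovery metrics
  postanalysis.py correlation analysis, analytic null tails, eGene variance
  cli.py          run / simulate / benchmark / postanalyze / config
```

See `docs/methods.md` for the statistical details and design choices.
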