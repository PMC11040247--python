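# noisybc

Agent-based simulation of opinion formation under confirmation bias and
noisy social interaction, built around the bounded-confidence (BC) model
with pairwise assimilation.

## The problem

How does noise shape collective opinion patterns when people attend mainly
to belief-confirming information? `noisybc` is aimed at computational
social scientists studying this question. Agents hold opinions
`x_i ∈ [0, 1]`; when agents `i` and `j` interact, each updates

    x_i ← x_i + μ·(m_j − x_i)   if |m_j − x_i| ≤ ε,

where `ε` is the confidence bound (small `ε` = strong confirmation bias),
`μ` the convergence speed, and `m_j` the message conveying `j`'s opinion.
The package distinguishes four places where noise of level `ν` can enter
this interaction, each a separate operator:

* **ambiguity** — the message itself is noisy: `m_j = x_j + ξ`, truncated
  to the opinion space by resampling;
* **selectivity** — the acceptance bound is perturbed: accept iff
  `|x_j − x_i| ≤ ε + ξ`;
* **adaptation** — the receiver's post-update opinion is perturbed;
* **exogenous** — agents jump spontaneously with probability `ω = ν`,
  independent of interaction.

The headline phenomenon: moderate ambiguity noise combined with moderate
confirmation bias drives a population whose initial opinions are
calibrated to six-segment climate-attitude survey shares toward a
*pro-environmental agreement* (PEA: mean concern ≥ 4/6 and dispersion
≤ 0.1) in roughly three quarters of runs — an effect none of the other
noise types produces. See `docs/methods.md` for the full model
description.

## Worked example

```python
from noisybc import ModelConfig, NoiseSpec, run_simulation, run_ensemble, is_pea

cfg = ModelConfig(
    epsilon=0.175, init="six_americas", seed=42,
    noise=NoiseSpec(noise_type="ambiguity", level=0.13))
res = run_simulation(cfg)
print(res.summary.iloc[[0, -1]].to_string(index=False))
print("PEA reached:", is_pea(res.final))

cell = run_ensemble(cfg, 100)
print(f"PEA frequency over {cell.replicates} replicates: {cell.pea_frequency:.2f}")
```

prints

```
  step     mean  dispersion  kurtosis  n_clusters
     0 0.606591    0.272740 -0.853961           3
100000 0.754346    0.077278 -0.168055           1
PEA reached: True
PEA frequency over 100 replicates: 0.68
```

The survey-calibrated population starts with mean concern 0.61 and
dispersion 0.27 (no agreement, three loose clusters); after 10⁵ pairwise
steps under moderate ambiguity noise it has collapsed into a single
cluster at high concern (mean 0.75, dispersion 0.077), which satisfies
the PEA predicate. Across 100 independently seeded replicates, 68% end
in PEA; larger ensembles put this frequency in the low-to-mid 70s, versus
below ~30% for any (ε, ν) combination of the other three noise types.

A CLI covers the common workflows:

```sh
noisybc run   --config run.toml  --seed 1 --out out/
noisybc sweep --config grid.json --seed 1 --out out/ --plot
noisybc pea   --config grid.json --seed 1 --out out/
```

writing long-format snapshot CSVs, tidy per-cell ensemble tables, and a
JSON manifest (written last, as a completion marker) that suffices to
replay every output byte-for-byte.

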