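# radlesion

Monte Carlo simulation of **clustered DNA-damage induction and
excision-repair outcomes** under radical scavenging (DMSO) and varying
oxygen tension, for radiobiology modelling of low-LET (photon, proton) and
high-LET (helium-ion) exposures.

Ionising radiation deposits correlated groups of elementary lesions —
strand breaks and base damages — within short DNA segments.  Each *cluster*
is scored as one damage site in the standard taxonomy: **BD** (base damage
only), **SSB**, **SSB⁺** (≥2 breaks, one strand), **2SSB** (opposite-strand
breaks >10 bp apart), **DSB** (opposite-strand breaks within 10 bp),
**DSB⁺** (DSB plus an extra break) and **DSB⁺⁺** (≥2 DSBs).  Hydroxyl-radical
scavengers such as DMSO and the oxygen-fixation effect both modify how many
lesions survive to become fixed damage; because complex damage needs several
lesions close together, its yield responds quasi-quadratically to the
per-lesion survival probability while simple damage responds roughly
linearly.  This differential response drives the package's endpoints: DSB
yields, RBE (relative biological effectiveness, the DSB-yield ratio against
a ⁶⁰Co γ-ray reference, Σ_R/Σ_γ), OER (oxygen enhancement ratio, the
21%-O₂ to 0.001%-O₂ DSB-yield ratio), and the mutation frequency of
excision repair.

## Model

* **Induction** — clusters per exposure ~ Poisson(ρ·D·G); lesions per
  cluster 1 + Poisson(ν); positions uniform on a segment of `nseg` bp;
  strand breaks with probability `p`.  (ρ, ν, p, nseg) are calibrated once
  against published MCDS proton class yields (total damage 616.15 /Gy/Gbp,
  total DSB 8.29 /Gy/Gbp).
* **Modifiers** — per-lesion Bernoulli survival,
  `s_DMSO(c) = FNSD + (1−FNSD)·CHMX/(CHMX+c)` with the published
  (FNSD, CHMX) presets, times an Alper–Howard-Flanders oxygen hyperbola
  `h(x) = (m·x+K)/(x+K)` normalised at 21% O₂ and fitted to the DSB-class
  OER anchors.
* **Repair** — non-DSB clusters are processed lesion-by-lesion in random
  order through short-patch BER (1 nt), long-patch BER (2–10 nt) or NER
  (24–32 nt) patches; polymerase bypass of a second base damage inside a
  patch causes a base substitution with probability `q_bypass`; opposing
  strand discontinuities within 10 bp abort as a repair-induced DSB.
  Mutation frequency is reported per Gy per cell (6 Gbp/cell).
* **Spectra & metrics** — dose-weighted spectral averages
  ⟨Y⟩ = ∫Y(E)Φ(E)LET(E)dE / ∫Φ(E)LET(E)dE for photon qualities, plus RBE,
  OER and percent-reduction endpoints with propagated Monte Carlo errors.

## Worked example

```python
import numpy as np
import radlesion as rl

quality = rl.calibrate_baseline(seed=1)          # fit to the proton anchors
quality.oxygen = rl.calibrate_oxygen(quality)    # fit the oxygen hyperbola

config = rl.SimulationConfig(n_clusters_min=1_000_000, fixed_count=True)
pop = rl.generate_clusters(quality, config, np.random.default_rng(2))
uniforms = np.random.default_rng(2).random(pop.n_lesions)

base = rl.tally_yields(pop, config)
env = rl.EnvironmentCondition(dmso_M=0.1, o2_percent=21.0)
s = rl.combined_survival(env, quality)           # 0.7176 per-lesion survival
thinned = rl.tally_yields(rl.thin_lesions(pop, s, uniforms=uniforms), config)

print(base.total_dsb, thinned.total_dsb,
      rl.percent_reduction(base.total_dsb, thinned.total_dsb))
```

prints (seed 2) `8.31 4.33 47.9` — the aerobic proton total-DSB yield of
8.31 per Gy per Gbp falls to 4.33 at 0.1 M DMSO, a 48% reduction, even
though only 28% of lesions were removed: clustering makes double-strand
damage disproportionately sensitive to scavenging.  The runnable scripts in
`examples/` cover the damage table, scavenger/oxygen response, RBE/OER
curves and repair outcomes, each printing the numbers it computes.

A thin CLI wraps the same pipeline:

```bash
radlesion simulate -c run.yaml -o yields.tsv --metadata meta.json --seed 1
radlesion repair   -c run.yaml -o mutation.tsv
radlesion sweep    --kind rbe-dmso -c run.yaml -o curve.tsv
```

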