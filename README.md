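# metakin

Residence-time estimation and structure–kinetics learning from biased
(infrequent-metadynamics-style) ligand unbinding trajectories.

`metakin` is built for the analysis stage of ligand-unbinding studies at
G-protein-coupled receptors — the motivating system is fentanyl and
morphine analogs dissociating from the μ-opioid receptor (mOR) — where
unbinding is far too slow for plain molecular dynamics and is instead
sampled under a slowly growing metadynamics bias. The package takes the
*outputs* of such simulations (per-frame collective-variable/bias time
series, per-frame substituent–residue interaction energies, a ligand
metadata table) and turns them into:

1. **Residence times.** Each biased trajectory's first passage to the
   unbound state (ligand z position > 15 Å) is rescaled to an unbiased
   dissociation time, t = Σᵢ Δtᵢ·exp(Vᵢ/kT). If bias deposition is
   infrequent enough, these times follow a homogeneous Poisson process;
   the residence time τ (= 1/k_off) is fitted by least squares of the
   empirical CDF against 1 − exp(−t/τ), its reliability is checked with a
   two-sample Kolmogorov–Smirnov test against a large Exp(τ̂) reference
   sample (accepted when p > 0.05), and its uncertainty is estimated by
   bootstrap refitting (10,000 resamples of size 15 by default).
2. **Unbiased distributions and free-energy surfaces.** Frames are
   reweighted with w ∝ exp(+V/kT); F(x) = −kT·ln p(x) with basin
   detection and binding-mode classification (D147 salt bridge / H297
   hydrogen bond / loosely bound) from basin minima.
3. **Structure–kinetics relationships.** Residue–substituent interaction
   energies are filtered (magnitude and cross-ligand spread of their
   reweighted means), block-mean-augmented into a regression dataset, and
   used to train four tree ensembles (random forest, extremely randomized
   trees, gradient boosting, XGBoost) predicting log₁₀τ. Kinetic
   modulators are ranked by permutation importance aggregated over
   repeated trials and models, and explained with exact additive
   (tree-path / TreeSHAP) attributions.
4. **Chemistry-level summaries.** Log-scale Pearson correlations between
   calculated τ and experimental τ, K_d and K_i,NLX (with pairwise
   handling of unmeasured values and an R2-analog subset rule), and a
   Tanimoto similarity matrix over the ligand panel.

A synthetic-data module generates all of these inputs from known ground
truth (exponential unbinding times pushed through a deterministic bias
schedule; feature tables with planted kinetic modulators), so the whole
pipeline is testable end to end without any simulation data.

## Worked example

```python
import numpy as np
from metakin import (BiasSchedule, gen_unbinding_trajectories,
                     ResidenceTimeModel)

# synthetic ground truth: tau = 10 s, 15 trajectories, 10 ps stride
trajs, truth = gen_unbinding_trajectories(10.0, BiasSchedule(), n_traj=15,
                                          seed=7, ligand_id="DEMO")
model = ResidenceTimeModel.from_trajectories(trajs)
res = model.fit(ks_n_random=200_000, n_boot=2_000, seed=7)
print(res.summary())
```

```
Residence time fit (homogeneous Poisson)
==============================================
ligand:            DEMO
events:            15
fit method:        ecdf
tau_hat:           9.668 s
KS statistic:      0.1474
KS p-value:        0.8548
reliable (p>0.05): True
bootstrap tau:     9.956 +/- 2.6 s (2000 resamples of size 15)
```

The fitted τ̂ (9.7 s) sits well within one bootstrap standard error of
the true 10 s; the KS p-value of 0.85 says the 15 rescaled times are
statistically indistinguishable from an exponential sample, so the fit
is flagged reliable.

The same pipeline runs from the shell:

```bash
metakin simulate --tau 10 --n-traj 15 --seed 7 --outdir runs/demo
metakin kinetics --colvar runs/demo/LIG_000.colvar ... --outdir runs/demo
metakin all --outdir runs/full-demo     # end-to-end synthetic demo
```

## Layout

| module | contents |
| --- | --- |
| `metakin.kinetics` | event detection, time rescaling, `ResidenceTimeModel`/`Results` |
| `metakin.reweighting` | frame weights, histograms, FES, basins, binding modes |
| `metakin.features` | energy tables, filtering, augmentation, `StructureKineticsModel`, importances |
| `metakin.attribution` | exact additive attributions for tree ensembles |
| `metakin.chem` | log-scale correlations, subset rules, Tanimoto matrix |
| `metakin.synthetic` | ground-truth generators and the 19-ligand panel |
| `metakin.io`, `metakin.config`, `metakin.cli` | COLVAR/CSV formats, config, command line |

See `docs/methods.md` for the underlying models, assumptions and design
choices.
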