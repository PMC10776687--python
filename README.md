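# occlusim

Analysis toolkit for transporter occlusion dynamics. The package builds a
fully synthetic, ground-truth-known counterpart of a two-domain gating
study — ligand-conditioned Langevin ensembles that emit gate distances and
ligand-residue interaction energies, plus patch-clamp current protocols —
and the analysis chain used to characterise it:

- **`occlusim.synthetic`** — discrete Markov chains (estimator oracles),
  2-D overdamped Langevin dynamics on two-basin potentials, observable
  emission, patch-clamp trace generation, and the exact
  Boltzmann-inversion surface oracle.
- **`occlusim.featurize`** — PDB parsing (Å→nm), centre-of-mass gate
  distances, Kabsch superposition, pairwise Coulomb+LJ interaction
  energies (0.9 nm cutoff, Lorentz–Berthelot), occlusion labelling and the
  −20 kJ/mol strong/weak interaction split.
- **`occlusim.modes`** — PCA over pooled frames and functional mode
  analysis (PLS against a scalar query, e.g. an interaction energy), with
  mode-filtered per-residue RMSF profiles.
- **`occlusim.msm`** — tICA → k-means microstates → reversible
  maximum-likelihood MSM → free-energy surface
  (G = −k_B·T·ln Σπ, 310 K), validated by implied timescales, the
  Chapman–Kolmogorov test, and trajectory bootstrap.
- **`occlusim.kinetics`** — mono-exponential peak relaxation (flipping
  rate), saturating dose-rate curves with the closed-form K_on
  (derivative at zero concentration), recovery fits (K_off), the
  unit-Hill-slope logistic (IC50), Michaelis–Menten, and the
  competitive / non-competitive / mixed inhibition classification.
- **`occlusim.pipeline` / CLI** — one command reproduces the full
  six-condition synthetic study deterministically from a master seed.

## CLI

```sh
occlusim all --outdir out --seed 1            # full study
occlusim msm --outdir out --seed 1 --resume   # one stage, cached reruns
occlusim all --config study.yaml              # YAML config (RunConfig keys)
```

Stages: `simulate`, `featurize`, `modes`, `msm`, `kinetics`, `report`.
Outputs are plain text (tab-separated tables, `#`-prefixed metadata, a
Markdown report with per-ligand occluded-basin occupancy, ΔG(OO→OC) and
the fitted kinetic constants).

## Library example

```python
import numpy as np
from occlusim import synthetic, msm

profile = synthetic.default_profile("5HT")
tables = synthetic.make_ligand_ensemble(profile, n_replicas=10,
                                        n_steps=2000, seed=1)
tica = msm.fit_tica(tables, lag_ns=5.0)
disc = msm.discretize([tica.transform(t, dim=2) for t in tables], k=500, seed=1)
model = msm.estimate_msm(disc.dtrajs, lag_ns=25.0, dt_ns=0.5)
surface = msm.free_energy_surface(model, disc, temperature_k=310.0)
```
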