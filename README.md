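# cryometa

Thermodynamic ensembles — structures *and* their populations — from
cryo-EM density maps, by Bayesian metainference.

A cryo-EM reconstruction is an average over many particles. When the
imaged molecule populates several conformations, no single model explains
the map; and parts of the density may come from molecules that are not in
the model at all. `cryometa` addresses both problems at once. The map is
represented as a Gaussian mixture φ_D whose components are the data points
d_i = ovDD_i (each component's overlap with the whole map); a forward
model predicts the same observables from N simultaneously simulated
replicas, f_i(X) = (1/N)Σ_r ov_MD,i^r; and a Gaussian noise model with
per-component uncertainties, marginalized under a Jeffreys prior, scores
the deviation Δ_i = d_i − f_i(X) with the closed-form energy

    E = E_prior − k_BT Σ_i log[ (1/(2Δ_i)) · erf(Δ_i / (√2 α·ovDD_i)) ].

Sampling this posterior with replica-averaged restraints yields an
ensemble whose cluster populations estimate the equilibrium weights of the
underlying conformations, and the posterior of the per-component noise
σ_B,i localizes unexplained density (bound lipids, detergents, artifacts)
as regions of high inferred relative error.

The package provides the full pipeline: MRC/CCP4 and PDB I/O,
divide-and-conquer GMM fitting of maps, the analytic overlap forward model
with electron-scattering-factor parameters, the marginalized score with
exact gradients, multi-replica overdamped Langevin sampling with optional
well-tempered metadynamics, GROMOS clustering / free-energy analysis, and
a fully synthetic two-state benchmark with known ground truth.

Intended users: structural-biology method developers and computational
biophysicists who want a transparent, testable reference implementation of
ensemble map fitting at desk scale.

## Worked example: recovering a 50/50 conformational mixture

```python
from cryometa import BenchmarkSpec, run_two_state_experiment

report = run_two_state_experiment(BenchmarkSpec(w=0.5, seed=11))
print(report["n_major_clusters"])
print(report["recovered_populations"])
print({c["state"]: round(c["center_rmsd_to_state"], 3)
       for c in report["major_clusters"]})
```

This builds a 30-bead hinged chain with two conformations ~0.5 nm apart,
mixes their synthetic maps 1:1, fits a 150-component data-GMM, infers the
replica-to-state assignment of 4 metainference replicas from the map
(state refinement → composition enumeration → unbiased production) and
clusters the pooled ensemble at a 0.35 nm RMSD cutoff. Output:

```
2
{'open': 0.5, 'closed': 0.5}
{'open': 0.078, 'closed': 0.058}
```

i.e. the ensemble resolves exactly two conformational states with equal
populations — the mixing weights used to construct the map — and each
cluster center lies within ~0.15 nm of the true conformer. With
`w=0.7` the recovered populations track 0.7/0.3 within the quantization
allowed by 4 replicas; with 10% spurious density injected into the
data-GMM (`spurious_fraction=0.1, n_spurious=8`) the report's `noise`
section shows the spurious components' inferred relative error exceeding
the clean median several-fold.

Command-line equivalents:

```bash
cryometa benchmark two-state --w 0.5 --seed 11 --out report.json
cryometa fit-gmm --map map.mrc --out data_gmm.txt --ncomp 200 --seed 1
cryometa simulate --config run.yaml --seed 1 --out traj/
cryometa analyze cluster --traj traj/trajectory.npz --cutoff 0.35 --out clusters.json
cryometa noise-map --traj traj/trajectory.npz --gmm data_gmm.txt \
    --map map.mrc --out-map err.mrc --out-tsv noise.tsv
```

See `docs/methods.md` for the model, the sampling protocol, parameter
choices and limitations.

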