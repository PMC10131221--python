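# ctidp — circuit topology of contact dynamics in disordered proteins

Intrinsically disordered proteins (IDPs) have no single native structure:
they exist as heterogeneous, rapidly interconverting conformational
ensembles, which defeats RMSD-style structural comparison.  `ctidp`
characterises such ensembles through **circuit topology (CT)**: the
arrangement of every pair of intrachain residue–residue contacts as
**series** (S — disjoint chain intervals), **parallel** (P — one interval
nested in the other) or **cross** (X — overlap without containment), with
*concerted* subclasses CS/CP when the two contacts share a residue.  This
three-letter grammar turns a noisy 3-D trajectory into a low-dimensional,
comparable description of chain topology.

Given a contact trajectory (from multi-MODEL PDB frames or a plain TSV of
`frame, res_i, res_j`), the toolbox:

1. **Contacts & lifetimes** — detects contacts (4.5 Å heavy-atom cutoff by
   default) and computes each pair's maximum lifetime, the longest
   contiguous run of frames times the frame interval (default 5 ns).
2. **Lifetime regimes** — fits the lifetime density in log–log space by a
   stepwise power law over growing prefixes and reads the short / middle /
   long boundaries off the R² curve (first drop below t₁ = 0.8; first rise
   above t₂ = 0.3 after the global minimum).
3. **Topology landscape** — maps every frame to (nS, nP, nX) counts,
   min–max scales them, segments the cloud into transient topological
   states with a BIC-selected Gaussian mixture, and scores the directional
   interconversion between temporally ordered states with the evolution
   score `E = Σ d_ij / (s_i + s_j)` (centroid distance over combined
   spreads).
4. **Topology strings** — linearizes the N×N relation matrix into a string
   over {S, CS, P, CP, X}, coarse-grains it (S=0 … X=4, windows of five),
   and measures similarity between proteins/conformations by global
   alignment (match 1 / mismatch 0 / gap 0, normalised by 2/(l₁+l₂)) or by
   the longest-contiguous-block ratio.
5. **Annotation** — hydropathy (Kyte–Doolittle sums), opposite-charge
   contact ratios per lifetime regime, pair energies from a pluggable
   20×20 contact-potential table, DPR/OPR sequence content, and
   topological circuits (chain subsections removable without changing the
   topology of the rest).

A `synthetic` module generates trajectories, landscape point clouds and
string families with known ground truth, so the whole pipeline is testable
without downloads.

## Worked example

```python
from ctidp import (LifetimeRegimeModel, PipelineConfig, compute_lifetimes,
                   run_full_pipeline)
from ctidp.synthetic import GeneratorSpec, sample_trajectory

spec = GeneratorSpec(seed=7, charge_coupling=True)   # 120 residues, 200 frames
traj, truth = sample_trajectory(spec)

regimes = LifetimeRegimeModel(compute_lifetimes(traj)).fit()
print(regimes.summary())

config = PipelineConfig(seed=7, k_max=5, n_init=10)
bundle = run_full_pipeline(config, traj, sequence=truth["sequence"])
for regime, res in bundle["landscapes"].items():
    print(f"{regime}: k={res.k} states, evolution score E={res.evolution:.3f}")
print("short vs middle string similarity:", round(bundle["similarity"], 3))
```

prints

```
Lifetime regime segmentation
----------------------------
samples:          68
grid step:        5 ns
KDE bandwidth:    1 ns
R^2 thresholds:   t1=0.8, t2=0.3
short regime:     lifetime <= 60 ns
middle regime:    60 < lifetime <= 985 ns
long regime:      lifetime > 985 ns
power-law slope:  -1.390 (exponent 1.390)

short: k=5 states, evolution score E=5.497
middle: k=5 states, evolution score E=25.105
short vs middle string similarity: 0.5
```

Reading it: the stepwise fit supports a power law up to 60 ns, so contacts
living up to 60 ns are "short", those up to 985 ns "middle", and the
scaffold contacts beyond are "long".  Both regime-filtered trajectories
segment into five topological states, but the middle-life topology moves
through narrower, better-separated states (higher E) — persistent contacts
drive the directional part of the topological evolution, while short-lived
contacts produce a diffuse cloud.  The charged-contact ratio of the
middle/long population (0.80) dwarfs that of the short one (0.02), as this
generator plants charge-stabilised scaffolds.

The same pipeline is available from the shell:

```bash
ctidp synth trajectory --seed 7 -o traj.tsv --truth truth.json
ctidp run --input traj.tsv --seed 7 -o results/
ctidp regimes --contacts traj.tsv -o regimes.json
```

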