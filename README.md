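# nanosite

Trajectory analysis for **Zn(II)–TACN-functionalised gold nanozymes** —
monolayer-protected gold nanoparticles whose ligands end in a
1,4,7-triazacyclononane (TACN) crown chelating one Zn(II) each. Such
particles hydrolyse RNA-model phosphodiesters (HPNP) by transiently forming
**two-metal-ion sites**: two chelated Zn ions drifting within a cutoff
distance of each other, optionally capturing a substrate in a precatalytic
geometry. `nanosite` turns raw MD output (GRO/PDB + XTC/TRR/DCD) into the
quantities that characterise this chemistry, and ships a synthetic-trajectory
generator that *plants* ground-truth events so every detector can be verified
exactly without running MD.

## What it computes

- **Monolayer descriptors** (`nanosite.structure`): radial distribution
  functions and cumulative coordination numbers referenced to the gold-core
  centre of mass, RMSF and P2 rotational autocorrelation after core
  superposition, radius of gyration, inertia eccentricity
  `e = 1 − I_min/I_avg`, geometric hydrogen bonds (D···A ≤ 0.35 nm,
  H–D···A ≤ 30°), close contacts (Zn···O8, Zn···water, Zn···Cl at 0.25 nm),
  and solvent-shell counts.
- **Thiol bundles** (`nanosite.bundles`): connected components (≥3 ligands)
  of the per-frame interligand C=O8···H–N9 hydrogen-bond graph, with a
  size-frequency table.
- **Site and complex events** (`nanosite.events`): bimetallic Zn pairs
  (Zn–Zn ≤ 0.50 nm), mono/bimetallic substrate binding (O4/O5–Zn ≤ 0.25 nm),
  precatalytic complexes of types 1–3 (adding the hydroxyl oxygen O3, with
  solvation `d4 < 0.20 nm` and nucleophile-activation `d5 ≤ 0.25 nm` flags),
  segmented into maximal contiguous **events** whose populations are fitted
  with `N(t) = N₀·e^(−λt)` (λ in ns⁻¹); per-event median distance to the
  core c.o.m. is summarised as boxplot quantiles (5/25/50/75/95).
- **¹³C T1 prediction** (`nanosite.relaxation`): Lipari–Szabo model-free
  approach — internal CH-vector ACF fitted with
  `C_I(t) = S² + a₁e^(−t/τ₁) + a₂e^(−t/τ₂)` (a₁+a₂+S² = 1), overall tumbling
  from Stokes–Einstein `D_rot = k_B T / 8πηr³` with `r = 1.1·⟨R_g⟩`, spectral
  density `J(ω) = (2/5)[S²τ_r/(1+(ωτ_r)²) + Σ aᵢτᵢ′/(1+(ωτᵢ′)²)]`, and the
  dipolar rate `1/T1 = n_H (d²/4)[J(ω_H−ω_C) + 3J(ω_C) + 6J(ω_H+ω_C)]`.
- **Synthetic ground truth** (`nanosite.synthetic`): a ~1.6 nm core with 60
  anchored ligand chains, 60 chelated Zn, diffusing substrates, water and
  Cl⁻; Gaussian-jitter baseline motion plus scheduled events placed to
  satisfy their defining distances exactly; exponential existence-time
  sampling and tumbling CH-vector series with known (D_rot, S², τ_e).

## Worked example

Run the whole pipeline on a seeded synthetic particle:

```bash
nanosite all --out demo --seed 1
```

This builds the fixture (GRO + XTC + ground-truth manifest), then writes
`rdf.csv`, `structure.json`, `bundles.csv`, `events.csv`, `decay.json`,
`transitions.csv` and `t1.csv` under `demo/`. With the default schedule (40
Zn-pair events with existence times drawn at λ = 131 ns⁻¹ plus one complex of
each type) the events summary looks like:

```json
"znpair": {
  "n_events": 43,
  "n_unique_sites": 43,
  "location_nm": {"median": 3.194, "q25": 3.180, "q75": 3.209, ...},
  "decay": {"N0": 42.89, "lambda_ns_inv": 149.5, ...}
}
```

`n_events` counts maximal contiguous intervals ("formed X times"),
`n_unique_sites` distinct Zn pairs; the fitted `lambda_ns_inv` sits within
the sampling noise of the planted 131 ns⁻¹ rate for only 43 events (the
`decay_rate_fit_*` entries of the acceptance script use n = 5000 and land
within a few percent), and the median site distance sits at the Zn shell
radius of the synthetic monolayer. The
same stages run on real data by passing `--topology`, `--traj` and
`--labels` (a YAML map from atom/residue names to semantic roles; presets
`aunp2`/`aunp3` cover the alkyl- and PEG-linker naming of the generator).

Library use mirrors the CLI:

```python
from nanosite import synthetic, events

cfg = synthetic.SyntheticConfig(seed=1)
topo, frame0 = synthetic.build_nanoparticle(cfg)
traj = synthetic.generate_trajectory(topo, frame0, synthetic.EventSchedule([]), cfg)
evs = events.build_events(traj, topo, "znpair")
```

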