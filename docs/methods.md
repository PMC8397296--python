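# Methods

This note documents the models behind `nanosite`, the parameter choices that
matter, what the synthetic fixtures emulate (and what they deliberately do
not), and the numerical conventions.

## System and semantic model

The package analyses monolayer-protected gold nanoparticles (~1.6 nm core)
carrying ~60 thiolate ligands whose terminal TACN crown chelates one Zn(II)
each, in water with chloride counterions and ~10 diffusing
2-hydroxypropyl-4-nitrophenylphosphate (HPNP) substrate molecules. Standard
coordinate formats carry no chemistry, so every analysis runs on a
`LabeledTopology`: a user-supplied YAML label map assigns each atom a role —
gold core, ligand segments (S, alkyl C1–C7, inner amide O8/N9, linker 12/15,
outer amide N18/O19, TACN N/C), chelated Zn, substrate P/O3/O4/O5 (O3 the
hydroxyl/nucleophile oxygen, O4/O5 the phosphoryl oxygens), water and Cl.
Shipped presets cover the two linker chemistries of the generator (alkyl
C12/C15 and PEG O12/O15). Every Zn must find TACN nitrogens in its residue;
loading fails loudly otherwise.

Units: nm, ps, amu throughout; decay rates are reported in ns⁻¹ and T1 in
seconds. PDB coordinates (Å) are converted on load.

## Geometry conventions

All distances use the minimum-image convention (fractional rounding refined
over the 27 neighbour images, so triclinic cells are handled exactly).
Whether the original analyses used wrapped or unwrapped coordinates is not
derivable from the inputs; minimum image is adopted and applied uniformly.
Centres of mass unwrap the selection around its first atom before averaging
so clusters split across the boundary get a sensible centre.

Cutoff conventions: all coordination cutoffs are inclusive (≤) — Zn–Zn
0.50 nm, substrate O–Zn 0.25 nm, water-O–O3 (d5) 0.25 nm — except the
Zn-bound-water criterion d4 < 0.20 nm, which is strict as defined. Hydrogen
bonds use the de-facto standard geometric criterion, donor–acceptor ≤
0.35 nm and H–D···A angle ≤ 30°; both are config-exposed.

## Event machinery

Per-frame classifiers produce a state per Zn pair or per substrate:

- **Bimetallic site**: two Zn within 0.50 nm.
- **Binding**: bimetallic when O4 and O5 contact two *different* Zn;
  monometallic when ≥1 phosphoryl oxygen contacts exactly one Zn and no
  second Zn touches any substrate oxygen.
- **Precatalytic**: type 2 (bimetallic, O4/O5 bridge two Zn and O3 sits on
  one of them), type 3 (pseudo-bimetallic, one Zn on the phosphoryl oxygens,
  a second Zn *only* on O3), type 1 (monometallic, a single Zn holds O3, O4
  and O5 exclusively). When several definitions could fire simultaneously
  the precedence is 2 → 3 → 1: bimetallic evidence outranks
  pseudo-bimetallic outranks monometallic. The precedence is config-exposed;
  the truth-table test pins the behaviour over all qualitative
  configurations, including the subset relations type 1 ⊂ monometallic and
  type 2 ⊂ bimetallic binding.

States are segmented into **events** — maximal runs of consecutive frames
with the same identity (kind + Zn ids + substrate). A single false frame
ends an event; a gap tolerance exists for sensitivity analysis but defaults
to 0. Existence time is run length × frame spacing (5 ps default), so the
shortest observable event is one frame. Each event carries the median
distance of its Zn to the gold-core centre of mass, pooled over both ions
and all event frames, and (for precatalytic kinds) solvation /
nucleophile-ready flags with any-frame semantics: an event counts as
solvated if any of its frames has a Zn-bound water.

Populations `N(t)` count events with existence time **greater than** t,
evaluated at 0 and every observed duration, and are fitted with
`N(t) = N₀·e^(−λt)` by nonlinear least squares seeded from a log-linear
regression on the positive part of the curve. The fit window is
config-exposed (full curve by default). Two count semantics are reported:
total events ("formed X times") and distinct identities ("unique sites").
Bundle frequencies are likewise reported both as fraction-of-frames and raw
counts, since either normalisation of a size-frequency distribution is a
legitimate reading.

## Lipari–Szabo T1

Internal and overall motions are assumed independent. The internal P2 ACF
of CH vectors (averaged over equivalent carbons across ligands *before*
fitting, which is the lower-variance order) is fitted with the constrained
plateau form `C_I(t) = S² + a₁e^(−t/τ₁) + a₂e^(−t/τ₂)`, `a₁+a₂+S² = 1`,
amplitudes parametrised as squared fractions so the constraints hold by
construction and times fitted in log space with a small multi-start. Fit
window default 2 ns (config-exposed). Overall tumbling comes from
Stokes–Einstein, `D_rot = k_B T / 8πηr³`, with hydrodynamic radius
`r = 1.1 ⟨R_g⟩`, viscosity default 8.5×10⁻⁴ Pa·s (water near 300 K,
config-exposed) and `τ_r = 1/(6 D_rot)`.

Relaxation is ¹³C–¹H dipolar only with `r_CH = 0.109 nm`; CSA and
cross-correlated terms are neglected, the standard approximation for
protonated aliphatic carbons at 9.4 T (defaults 400.13 MHz ¹H /
100.61 MHz ¹³C, both config-exposed). With effective times
`1/τᵢ′ = 1/τ_r + 1/τᵢ`,

    J(ω)  = (2/5) [ S² τ_r/(1+(ωτ_r)²) + Σᵢ aᵢ τᵢ′/(1+(ωτᵢ′)²) ]
    1/T1  = n_H (d²/4) [ J(ω_H−ω_C) + 3 J(ω_C) + 6 J(ω_H+ω_C) ],
    d     = (μ0/4π) ħ γ_H γ_C / r_CH³.

The spectral density is cross-checked in the tests against direct cosine
quadrature of the product correlation function (0.1 %), against the
extreme-narrowing closed form `1/T1 → n_H d² τ_c`, and end-to-end against
the analytic T1 for tumbling fixtures with known (D_rot, S², τ_e).

## Synthetic fixtures: what they are and are not

The generator is *jitter, not physics*: no forces, no solvent structure, no
realistic conformational ensembles. This is sufficient because every
analysis in the package is geometric/statistical — a detector cannot tell
thermal motion from seeded Gaussian noise. Specifics:

- Gold beads on concentric shells (core c.o.m. planted exactly at the box
  centre); ligand anchors on a deterministic Fibonacci lattice so fixtures
  are bit-reproducible across platforms; radial bead chains with the full
  role sequence; Zn placed on the crown axis at 0.21 nm from **each** of
  the three chelating TACN nitrogens (the physical Zn–N bond length).
- Substrates, waters and Cl packed uniformly outside the monolayer with a
  0.2 nm overlap floor and a 0.7 nm clearance from the Zn shell, so no
  diffusing oxygen can come within 1.5× any coordination cutoff unless an
  event plants it. Substrates move as rigid bodies on a reflected random
  walk; everything else jitters (σ = 0.02 nm default) about its built
  position.
- Scheduled events overwrite participant coordinates so the defining
  distances hold *exactly* in every event frame (solvation distances d4/d5
  are placed by triangle construction and rejected as infeasible when the
  triangle inequality fails). Planted existence times are therefore
  recovered exactly by construction at zero jitter, and remain exact under
  jitter because baseline separations keep ≥3σ margins from every cutoff.
- Existence times are sampled exponentially and discretised by *ceiling* to
  ≥1 frame. Ceiling keeps the survival counts at the frame grid exactly
  exponential (`P(D > k·dt) = e^(−λk·dt)`), so λ-recovery tests measure the
  fit, not a discretisation bias.
- Tumbling CH vectors: the internal process holds the vector at a fixed
  cone angle θ from a body axis with `P2(cos θ) = √S²` and resamples the
  azimuth at Poisson rate 1/τ_e, which makes the internal P2 ACF *exactly*
  `S² + (1−S²)e^(−t/τ_e)`; the body frame undergoes small-step isotropic
  rotational diffusion, exact in the dt→0 limit (step variance 2·D_rot·dt
  per axis; tests keep 6·D_rot·dt ≪ 1).

Consequently, passing tests demonstrate that the detectors, estimators and
relaxation pipeline are correct *given* their geometric definitions — they
do not validate the definitions against real solvated dynamics, force-field
quality, or sampling adequacy of finite MD.

## Numerical choices

- Event populations at the studied rates decay within tens of frames; decay
  fits in the tests use n = 2000–5000 sampled durations, the trajectory
  fixtures 30–60 frames of a few hundred atoms, and the relaxation fixtures
  2–3 × 10³ frames × 50 vectors — sizes chosen so the whole suite completes
  in well under a minute per stage on one core while keeping stochastic
  tolerances (10 % for λ and T1 recovery) comfortably above sampling noise.
- P2 ACFs are computed via FFT correlation of the nine dyadic components
  (`C(τ) = 3/2⟨(u·u′)²⟩ − 1/2`), normalised per-lag.
- RMSF/RCF superposition fits the gold core only (mass-weighted Kabsch);
  the core is the rigid body of record.
- RDF normalisation uses the ideal-gas density of the target selection with
  self-pairs excluded; the core-centre-referenced variant (one reference
  point) is the default for locating monolayer segments radially.
- The nonlinear fits evaluate their exponentials through a scalar path:
  NumPy's SIMD `exp` can differ by 1 ulp with array alignment, enough to
  flip an ill-conditioned two-exponential fit between near-degenerate
  minima and break byte-level reproducibility of seeded runs.
- Quantiles use NumPy's default linear interpolation.
- λ is reported in ns⁻¹ regardless of the frame spacing; unit conversions
  happen only at reporting boundaries.

## Known limitations

- The two-exponential internal ACF model is weakly identifiable on short
  windows; amplitudes of nearly-degenerate solutions can trade off while T1
  (which depends on an integral of the ACF) stays stable. The fitted
  parameters should be read accordingly.
- Bundles are defined purely by hydrogen-bond connectivity; geometric
  definitions via chain alignment or tilt are out of scope.
- Event statistics assume the no-gap segmentation; a brief detector dropout
  splits one physical event in two. The gap-tolerance flag exists to probe
  this sensitivity.
- Markov-state modelling, free-energy estimates and any quantum-mechanical
  treatment of the catalytic step are out of scope; the package
  characterises geometry and kinetics of site formation only.
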