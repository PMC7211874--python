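# myofibrekit

Myofibre-architecture generation, fibre-dispersion quantification and
dispersed-active-stress cardiac mechanics on tetrahedral ventricular meshes.

Computational models of the heart need a myofibre field — the local
fibre / sheet / sheet-normal triad (**f₀**, **s₀**, **n₀**) — before any
mechanics can be computed.  In practice that field comes either from
diffusion-tensor MRI mapped onto the target geometry, or from a rule-based
method (RBM) that rotates the fibre linearly across the wall.  Measured
fields are *dispersed*: fibres scatter both within the
circumferential–longitudinal plane and out of it, and that scatter carries
real pump-function consequences because contraction then acts partly along
the cross-fibre directions.  This package provides the full chain for
studying that effect on synthetic (and therefore fully reproducible)
geometry:

* **Rule-based fibre generation** on labelled tet meshes: the transmural
  coordinate ē (a Laplace–Dirichlet harmonic field, 0 at endocardium, 1 at
  epicardium), local circumferential–radial–longitudinal frames, AHA17
  segment labels, and fibre angles θ(ē) = θ^endo + ē (θ^epi − θ^endo),
  either one endo/epi pair for the whole ventricle or one per AHA17 segment.
* **Fibre mapping** from a template mesh through a surface displacement
  field (harmonic interior interpolation, push-forward f → F f/|F f| with
  F = I + ∇u, nearest-neighbour transfer).
* **Dispersion quantification**: in-plane and out-of-plane deviation angles
  against a rule-based reference, fitted by maximum likelihood to the
  π-periodic von Mises density ρ(θ; b) = exp(b cos 2θ)/(π I₀(b)).
* **Generalized structural tensor**: H = (1/N)∫∫ ρ_in(Θ; b₁) ρ_op(Φ−π/2; b₂)
  sinΘ · M⊗M dΘ dΦ over the unit sphere, whose diagonal in the
  (s₀, n₀, f₀) axes gives the active-tension proportions (n_s, n_n, n_f).
* **Constitutive laws**: the reduced Holzapfel–Ogden passive energy (with
  tension-only I₄ terms and I₈ shear couplings), a time-varying-elastance
  active tension T_a(t, l), and the dispersed active stress
  σ_a = T_a (n_f f̂⊗f̂ + n_s ŝ⊗ŝ + n_n n̂⊗n̂).
* **A desk-scale pump model**: a lumped (Windkessel-equivalent) circulation
  coupled to thick-walled incompressible spherical ventricles driven by the
  constitutive laws, producing pressure–volume loops and ejection fractions.
* **Synthetic data** for all of the above: truncated thick-walled ellipsoid
  meshes with endo/epi/base labels, dispersed fibre fields with prescribed
  von Mises concentrations, and closed-form diffeomorphic warps.

## Worked example

The dispersion concentrations fitted to a DT-MRI-derived neonatal fibre
field are b₁ = 1.6153 (in-plane) and b₂ = 1.2144 (out-of-plane).  The
structural tensor they imply:

```sh
$ myofibrekit structural-tensor --b-in 1.6153 --b-out 1.2144
{"n_f": 0.645931, "n_s": 0.085469, "n_n": 0.2686}
```

So ~65% of the active tension acts along the mean fibre, ~27% along the
sheet-normal and ~9% along the sheet — a sheet-normal-to-fibre ratio of
about 41%.  Feeding those proportions into the reduced-order closed loop:

```sh
$ myofibrekit simulate --cycles 2 --nf 0.646 --ns 0.086 --nn 0.268
{"lv": {"EDV_ml": 2.87, "ESV_ml": 1.07, "SV_ml": 1.81, "EF": 0.629, ...},
 "rv": {"EDV_ml": 1.96, "ESV_ml": 0.74, "SV_ml": 1.21, "EF": 0.620, ...}}
```

i.e. a left ventricle filling to 2.87 ml at the 8 mmHg end-diastolic
pressure and ejecting 63% of it, with the closed-loop blood volume
conserved to round-off (`volume_conservation_rel ≈ 1e-14`).  Raising the
sheet-normal proportion raises the ejection fraction; raising the sheet
proportion lowers it (transmural contraction thins the wall and opposes
ejection) — run `simulate --nn 0.4` vs `--ns 0.4` to see the split.

The same pipeline runs end to end from Python (see `myofibrekit.io_cli.run_scenario`),
including the mapped-field scenario: sample a dispersed field, warp it
through an analytic diffeomorphism, transfer it to the target mesh by
nearest neighbour, re-fit the concentrations and rebuild the tensor.

## Layout

| module | contents |
| --- | --- |
| `synthetic_data` | ellipsoidal ventricle meshes, dispersed fibre sampling, analytic warps |
| `geometry_frames` | `TetMesh`, transmural Laplace solve, local frames, AHA17 labels |
| `rbm_fibres` | rotation-angle tables, rule-based fibre fields |
| `fibre_mapping` | harmonic displacement interpolation, deformation gradients, push-forward, nearest-neighbour transfer |
| `dispersion` | angle extraction, π-periodic von Mises density / sampling / MLE |
| `structural_tensor` | spherical quadrature of H, Monte-Carlo oracle, active proportions |
| `constitutive` | passive Holzapfel–Ogden-type stress, elastance active tension, dispersed active stress |
| `pump_sim` | lumped circulation, spherical ventricle equilibrium, cycle integration |
| `io_cli` | ASCII .vtu I/O, scenario orchestration, `myofibrekit` CLI |

See `docs/methods.md` for the model assumptions, parameter tables, units
and known limitations.
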