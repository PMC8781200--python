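# Methods

## The model

`renoimp` predicts the tetrapolar (four-electrode) electrical impedance
measured on the posterior skin over a kidney, and how that impedance changes
as the kidney fills with blood over a cardiac cycle.  The model has three
parts.

**Anatomy.** The trunk segment is an elliptic cylinder (cross-section full
axes 2a₁ × 2b₁) with, moving inward from the posterior skin: a subcutaneous
fat layer of thickness h_subc, a muscle layer h_m, then mixed abdominal
contents ("background").  Layer boundaries are concentric ellipses shrunk by
the layer thickness per axis, so thicknesses are exact along the body axes
and the electrode normal.  The kidney is a two-layer ellipsoid — a cortex
shell of uniform thickness h_c around a medulla core, realized by per-axis
semi-axis subtraction — wrapped in a perirenal fat capsule of uniform
margin, its nearest surface `depth` millimetres under the skin, long axis
cranio-caudal.  Skin is not a separate layer: the measured subject table
lists subcutaneous fat as the outermost layer, and the electrodes contact it
directly.  Everything is voxelized on a regular grid at pitch h by sampling
tissue membership at voxel centers; the build refuses h > h_c because the
cortex shell would be unresolvable.

**Electrophysiology.** At 100 kHz tissue in this region is predominantly
resistive, so each tissue carries one scalar resistivity ρ (Ω·m) and the
solve is real-valued.  Kidney parenchyma starts at ρ = 5.84 Ω·m (cortex =
medulla before blood filling).  Pulsatile blood filling follows the
parallel-conductor model: adding blood mass m_b (resistivity ρ_b) to m_k
grams of tissue (ρ_k) lowers the bulk resistivity by

    Δρ = ρ_k · m_b · (ρ_k − ρ_b) / (m_k · ρ_b + m_b · ρ_k).

Healthy renal perfusion (~400 mL·min⁻¹ per 100 g, one 1-s cycle,
ρ_b = 1.5 Ω·m) gives Δρ ≈ 0.89 Ω·m — the "about 1 Ω·m" physiological
order.  Two canonical perfusion cases describe how that blood splits
between the layers: 90–10 (normal, cortex-dominant; cortex 5.84 → 4.99,
medulla 5.84 → 5.75 Ω·m) and 70–30 (cortical hypoperfusion; 5.84 → 5.18 and
5.84 → 5.56).  These after-values are carried as data, not re-derived: the
per-layer mass split behind them is not published, so the Δρ formula is
exposed for user-defined cases instead.

**Forward solve.** The quasi-static conduction equation ∇·(σ∇φ) = 0 is
discretized with a cell-centered 7-point finite-volume stencil; face
conductances use the harmonic mean of the adjacent voxel conductivities
(exact for layered media normal to the face, the dominant structure here).
All outer boundaries are insulating except the current-electrode footprints,
where the drive current ±I (default 3 mA) is spread uniformly over the
footprint faces; measurement electrodes are ideal area-averaged pickups
(no shunting).  The matrix is symmetric positive semi-definite with the
constants as nullspace; the gauge is zero mean potential.  Transfer
impedance is Z = (φ̄(M1) − φ̄(M2))/I, positive for the in-line order
C1-M1-M2-C2.

## Numerics

* **Solvers.**  Heterogeneous, ellipse-masked domains are solved with
  Jacobi-preconditioned conjugate gradients to relative residual 1e-8
  (cap 10⁵ iterations); perfusion after-states warm-start from the
  before-state potential, which roughly halves their iteration count.
  Homogeneous full-box domains (the half-space oracle geometry) are solved
  exactly: the cell-centered Neumann Laplacian is diagonal in the DCT-II
  basis, so the solve is a forward/inverse cosine transform — no matrix is
  ever formed, which is what makes fine-grid convergence studies affordable.
  The two paths solve the same discrete system; a test checks them against
  a dense reference on a small grid.
* **Electrode rasterization.**  A footprint is the set of skin faces whose
  centers fall strictly inside the disk; an empty set falls back to the
  single nearest face.  The homogeneous-block builder additionally shifts
  the grid phase (by < h/2) so the first electrode center lands on a cell
  center: when spacings are multiples of h this pins every electrode to a
  cell center at every resolution, removing rasterization parity jumps from
  h-refinement studies.  The analytic half-space formula
  Z = 2ρb/(π(a² − b²)) assumes point electrodes, so oracle comparisons use
  sub-voxel disks; with the default 3 mm disks the solution converges to a
  disk-electrode limit ≈ 0.4% above the point formula.
* **Degenerate inputs.**  Disconnected conduction domains, electrode
  footprints off the skin, overlapping disks, kidneys that do not fit the
  torso wall, and unresolvable cortex shells all raise typed errors before
  any solve.  An all-zero blood-volume curve yields an all-zero impedance
  waveform rather than an error.
* **Tie-breaks.**  Containment tests use a 1e-6 slack on the normalized
  ellipse/ellipsoid coordinate so surfaces touching a layer boundary (the
  default capsule abuts the muscle wall exactly) are accepted.

## Experiment protocols and problem sizes

* **Spacing sweep.**  Adjacent spacing d runs 7…40 mm in 3 mm steps
  (current electrodes at 3d).  Per row the grid pitch is min(2 mm, d/4)
  unless overridden; each row solves one before-state and one after-state
  per perfusion case on the same grid, so ΔZ = Z_before − Z_after is free
  of rasterization differences between states.  The acceptance suite runs a
  reduced protocol — four spacings 7, 13, 16, 20 mm at h = 2.5 mm
  (~0.85 M unknowns, ≈ 100 s total) — spanning the range of the physical
  electrode systems (measuring distances 10–20 mm).
* **Depth sweep.**  Kidney depth +0/+10/+20 mm at fixed d = 20 mm,
  h = 2.5 mm, models inspiratory kidney displacement.
* **Oracle block.**  360 × 180 × 360 mm homogeneous block (lateral extent
  6× the current-electrode separation) at h = 4, 2, 1 mm; the residual
  error floor (~0.4–0.5%) is set by the insulating far boundaries, and
  shrinks to <0.1% when the block is doubled.
* **Reciprocity.**  Default patient model at h = 4 mm (~210 k unknowns);
  the discrete system is symmetric, so the measured asymmetry (~1e-9)
  reflects solver tolerance only.
* **Impedance waveform.**  The forward problem is solved at n keyframe
  blood-filling levels s ∈ [0, 1]; layer resistivities at level s follow
  the parallel-conductor relation with blood mass s·m̂, where m̂ is the
  closed-form inverse that makes s = 1 reproduce the case's after-state.
  ΔZ(t) is interpolated at s(t) = Q(t)/max Q (clipped to [0, 1]).  Two
  keyframes degenerate to linear scaling; five keyframes change the
  waveform by < 5% of its peak, confirming the perturbation is nearly
  linear.

## Synthetic data

The generators emulate the *structure* of the measured inputs, not any
particular subject.  The arterial cycle is a diastolic floor (15 cm/s) plus
a half-sine systolic peak (to 77.4 cm/s over 35% of a 1 s cycle), chosen so
the per-cycle arterial volume (≈ 8.7 cm³ through S_a = 0.30 cm²) matches
healthy renal perfusion of ~400 mL·min⁻¹ per 100 g scaled to a 130 g
kidney; venous return is near-steady (22.8 cm/s through S_v = 0.38 cm²,
10% pulsatility) so the cycle closes with ≈ zero net volume.  Noise is
additive Gaussian, seeded, specified as a fraction of each signal's own
standard deviation.  Real Doppler traces have spectral broadening, angle
error and baseline wander that these curves do not; passing tests therefore
demonstrate that the pipeline recovers known ground truth with the right
convergence orders and noise attenuation (r → 1/√(1+noise²/signal²)), not
that any clinical waveform is reproduced.

## Design choices where the design was open

* Trunk-wall and blood resistivities (fat 40, muscle 2.8, blood 1.5,
  background 5.0 Ω·m at 100 kHz) are literature-derived defaults, marked as
  such and config-overridable; only the kidney values are subject-specific
  measurements.
* Kidney semi-axes (30, 20, 55 mm), depth (26.28 mm = wall + capsule) and
  capsule margin (10 mm) are typical-adult defaults: the source subject's
  kidney dimensions were never published.  The described trunk-sized
  "fibrous layer" is anatomically implausible as a kidney capsule, so a
  uniform capsule margin replaces it.
* The trunk segment is 400 mm long so the grid boundary stays ≥ 3
  current-electrode spacings from any electrode of the default array.
* One-cycle analysis only; cycle segmentation of multi-beat records is out
  of scope, as are reactive impedance components, contact impedance and
  frequency sweeps.

## Known limitations

* Absolute impedances depend on the unpublished kidney geometry, non-renal
  resistivities and the electrode boundary condition of the original
  simulation; this package reproduces magnitudes and trends (static Z
  falling from ~360 to ~26 Ω over the sweep; ΔZ tens of mΩ rising with
  spacing) but is not expected to match a specific subject's table to the
  millohm.
* The perfusion-case ordering ΔZ(90–10) ≥ ΔZ(70–30) holds up to d = 20 mm
  under the default geometry and inverts by ≤ 2% beyond ~22 mm: at wide
  spacings the sensitivity field reaches deep enough that the medulla's
  share grows.  The crossover spacing moves with kidney size and depth, so
  this ordering should be interpreted within the in-vivo array range
  (measuring distances ≤ 20 mm).
* Per-row grid re-alignment leaves ~1% jitter on ΔZ(d) between sweep rows
  at fixed h; trends across the full 7–40 mm protocol are monotone up to
  this jitter.
* The correlation between the simulated impedance waveform and the
  blood-volume curve is exact by construction with two keyframes; it tests
  the plumbing and near-linearity, not an independent physiological
  prediction.
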