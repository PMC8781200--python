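# renoimp

Patient-specific numerical modelling of renal bio-impedance.

Monitoring renal blood circulation matters for early detection of kidney
allograft rejection and for critically ill patients at risk of acute kidney
injury, but bedside-capable methods are scarce.  A tetrapolar electrode
array on the skin over the kidney — two outer electrodes injecting a small
100 kHz current, two inner ones picking up the voltage — sees a static
impedance set by all tissue between the electrodes and a small pulsatile
component ΔZ driven by cardiac blood filling of the kidney.  Whether that
pulsatile signal really comes from the kidney, and which electrode spacing
makes it usable, depends on the subject's anatomy.  `renoimp` answers those
questions in silico: it builds a voxel model of the perirenal space from a
handful of measured dimensions, solves the quasi-static conduction forward
problem, and checks the predicted impedance waveform against the renal
blood-volume curve derived from Doppler ultrasound.

It is intended for researchers in bioimpedance instrumentation and
physiological modelling who need a transparent, scriptable forward model
rather than a commercial FEM package.

## The model in brief

* **Anatomy** — layered elliptic trunk cross-section (subcutaneous fat
  h_subc, muscle h_m, abdominal background), a two-layer kidney ellipsoid
  (cortex shell h_c around a medulla core) in a perirenal fat capsule,
  voxelized at pitch h; an in-line four-electrode array (adjacent spacing d,
  current pair at 3d) on the posterior skin.
* **Conduction** — ∇·(σ∇φ) = 0, cell-centered finite volumes with
  harmonic-mean face conductances, insulating boundaries, current injected
  over the electrode footprints; Z = (φ̄(M1) − φ̄(M2))/I.  Validated
  against the half-space formula Z = 2ρb/(π(a² − b²)) (a, b = half the
  current/measuring separations), which reduces to ρ/(2πd) for an
  equidistant array.
* **Perfusion** — the parallel-conductor model
  Δρ = ρ_k m_b (ρ_k − ρ_b)/(m_k ρ_b + m_b ρ_k) maps per-cycle blood filling
  to kidney-layer resistivity drops; canonical cases send 90% or 70% of
  renal flow to the cortex.  ΔZ = Z_before − Z_after.
* **Doppler verification** — Q(t) = ∫₀ᵗ V_a S_a dt − ∫₀ᵗ V_v S_v dt, the
  cumulative arterio-venous volume balance over one cardiac cycle, and its
  Pearson correlation with the impedance waveform.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

```python
from renoimp import (paper_default_fixture, spacing_sweep, WaveformParams,
                     synth_velocity_pair, blood_volume_change,
                     synth_impedance_from_volume, pearson_correlation)

torso, kidney, tissues, cases = paper_default_fixture()
sweep = spacing_sweep(torso, kidney, tissues, cases, d_values=[7, 13, 20], h=2.5)
print(sweep.data.round(4).to_string(index=False))

artery, vein = synth_velocity_pair(WaveformParams(noise_sd=0.0))
q = blood_volume_change(artery, vein)
dz = synth_impedance_from_volume(q, gain=20.0, noise_sd=0.2, seed=7)
print(f"peak volume change: {q.Q.max():.2f} cm^3")
print(f"correlation r = {pearson_correlation(q.Q, dz.dz_mohm):.3f}")
```

prints

```
 d_mm  Z_before_ohm  Z_after_90-10_ohm  dZ_90-10_ohm  Z_after_70-30_ohm  dZ_70-30_ohm
  7.0      364.0433           364.0321        0.0113           364.0324        0.0110
 13.0      110.7004           110.6731        0.0272           110.6736        0.0267
 20.0       45.2899            45.2382        0.0517            45.2385        0.0514
peak volume change: 2.57 cm^3
correlation r = 0.983
```

Read: the static impedance falls steeply as the array widens (deeper, more
conductive tissue enters the measurement), while the pulsatile component
rises — at d = 20 mm the 7 mm array's 11 mΩ has grown to 52 mΩ, and normal
cortex-dominant perfusion (90–10) gives a slightly larger signal than
cortical hypoperfusion (70–30).  The synthetic Doppler cycle stores ~2.6 cm³
of blood at systole, and an impedance waveform with 20% noise still
correlates with the volume curve at r ≈ 0.98.

A CLI mirrors the library (`renoimp sweep spacing`, `renoimp sweep depth`,
`renoimp waveform`, `renoimp synth doppler`, `renoimp synth fixture`,
`renoimp volume`); patient models round-trip through YAML
(`renoimp synth fixture --out model.yaml`), and grids/fields export to
legacy VTK for inspection.

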