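# vitriflow

Simulation of large free-surface deformation of a cryoprotective agent
(CPA) vitrifying in a container, with the accompanying cryomacroscopy
data-reduction pipeline.

## The problem

When a CPA such as 7.05M DMSO is cooled rapidly toward its glass
transition (about −132 °C), it contracts thermally while its viscosity
climbs by ~14 orders of magnitude. The interplay of inward-moving thermal
gradients, temperature-dependent density ρ(T) and exponentially growing
viscosity μ(T) makes the free surface collapse into a deep central cavity —
deformations of several millimetres in a 10 mm-wide cuvette. These
deformations matter to cryobiologists because they concentrate
thermo-mechanical stress and hence the risk of structural damage in
preserved tissues and organs.

`vitriflow` implements:

- **TF (thermal-fluids) model** — coupled transient heat transfer

  ρc_p (∂T/∂t + v·∇T) = ∇·(k∇T),  −n̂·k∇T = h (T_c − T_∞)

  and quasi-static creeping flow with variable properties

  0 = ∇·[−pI + μ(∇v + ∇vᵀ) − ⅔μ(∇·v)I] + ρ(T)g,
  ∇·v = −(1/ρ)(dρ/dT)(DT/Dt),

  on a deforming 2D axisymmetric mesh (ALE): the free surface moves with
  the normal fluid velocity, the traction on it is zero (surface tension
  neglected), and walls are no-slip.

- **TM (thermo-mechanics) model** — the TF loop plus a Maxwell-solid
  response (ε̇ = ε̇_elastic + ε̇_creep + ε̇_thermal, with ε̇_creep = S/2μ and
  ε̇_thermal = αṪI) wherever the viscosity passes an arrest threshold,
  yielding stress estimates in the vitrified material.

- **Cryomacroscopy metrics** — reduction of on-screen cavity measurements
  to physical displacement, u_s(t) = H_e(t) − H_e(0) with
  H_e = H_p·L_e/L_p, and the associated uncertainty propagation
  (δL_p = √3·δH_p, first-order partials of H_e, error bars ±2δu_s).

The finite-element core (axisymmetric P1 conduction–advection; stabilized
equal-order P1–P1 Stokes with an implicit free-surface restoring term) is
built directly on numpy/scipy sparse linear algebra.

## Worked example

```bash
vitriflow run --rate 20 --tfinal -125 --elements 4000 --out out_20
```

prints per-step progress and then

```
final u_s = -6.199 mm, max |u_s| = 6.199 mm
outputs: out_20/history.csv
```

meaning the centerline of the free surface ends 6.2 mm below its starting
position after cooling at 20 °C/min from 10 °C to −125 °C (the chamber
ramp lasts 405 s; the CPA centerline lags the chamber by roughly 40 °C at
the end). `history.csv` holds the time series (t, chamber temperature,
centerline displacement, surface volume flux, mesh quality, peak fluid
viscosity, CPA mass — the last is a conservation diagnostic, constant to
&lt;0.1%); `surface_profiles.csv` holds surface-shape snapshots; with
`--snapshots N`, a VTU/PVD series of the full temperature/velocity/pressure
fields is written as well.

Other entry points:

```bash
vitriflow sweep --rates 10,15,20,25 --tfinals -125       # study grid
vitriflow compare-tf-tm --rate 20 --tfinal -125          # TM vs TF
vitriflow metrics --frames frames.csv --out report.csv   # experiment reduction
vitriflow run --config examples/default_run.yaml         # full config file
```

The same functionality is available as a library
(`vitriflow.run_tf_simulation`, `vitriflow.run_tm_simulation`,
`vitriflow.macroscopy`, …); `docs/methods.md` documents the model,
numerics and their limitations.

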