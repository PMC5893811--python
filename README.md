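# laa-stasis

Hemodynamic stasis analysis of left-atrial-appendage (LAA) morphologies
at desk scale.

More than 90% of the atrial thrombi behind stroke in atrial
fibrillation (AF) form in the LAA, a small lobed sac on the left
atrium, and clinical series associate its shape class — *chicken wing*,
*cactus*, *windsock*, *cauliflower* — with different thrombosis risk.
`laa_stasis` builds parametric planar atrium + appendage geometries for
the four classes, solves pulsatile incompressible Newtonian flow
through them under a healthy and an AF mitral-outflow waveform, washes
out a virtual contrast agent, and quantifies stasis: how fast velocity
and shear strain rate (SSR = √(2 D:D)) decay from the appendage ostium
to its tip, how much contrast survives four cardiac cycles, and where
that residue sits. The package is aimed at method development and
teaching in cardiovascular flow analysis: everything runs in minutes on
one CPU and every input is generated in-repo.

The flow model is the laminar incompressible Navier–Stokes system (ρ =
1060 kg/m³, μ = 0.0035 Pa·s; peak mitral Reynolds number ≈ 2400 <
3000), discretized with a projection scheme on unstructured P1
triangles: error-compensated semi-Lagrangian advection, implicit
viscosity, an exact discrete projection (post-projection divergence at
rounding level), and a conservative bounded upwind transport for the
contrast scalar on flux-corrected, divergence-free edge fluxes. The
mitral waveform is biphasic (E- and A-wave, cycle 0.8 s, 37.5% atrial
diastole, peak 0.32 m/s); AF removes the A-wave. Details and all
modelling decisions are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from laa_stasis import (
    DEFAULT_SPECS, generate_anatomy, generate_mesh, extract_centerline,
    assemble_bcs, FluidProperties, SolverConfig, run, summarize,
)

anatomy = generate_anatomy(DEFAULT_SPECS["windsock"])
mesh = generate_mesh(anatomy, h=1.2e-3)          # ~4.1k triangles
centerline = extract_centerline(mesh, n_stations=16)

for condition in ("healthy", "af"):
    bcs = assemble_bcs(mesh, condition)          # walls, 6 PV inlets, mitral plug
    result = run(mesh, bcs, FluidProperties(), SolverConfig())  # 4 cycles, dt=0.5 ms
    s = summarize(result, mesh, centerline, condition, "windsock")
    print(f"{condition:8s} |v|_LAA={s.mean_velocity_LAA:.4f} m/s "
          f"SSR_LAA={s.mean_ssr_LAA:.1f} 1/s "
          f"residual={s.residual_contrast_domain:.2f}% "
          f"dye@s={s.dye_localization:.2f} "
          f"periodicity={s.periodicity_metric:.3f}")
```

```
healthy  |v|_LAA=0.0086 m/s SSR_LAA=6.3 1/s residual=13.49% dye@s=0.57 periodicity=0.049
af       |v|_LAA=0.0047 m/s SSR_LAA=4.9 1/s residual=16.23% dye@s=0.52 periodicity=0.019
```

Reading the output: the cycle-averaged appendage velocity and shear
drop under AF (emptying without the atrial kick is less effective),
the residual contrast after four cycles rises from 13.5% to 16.2% of
the domain, and the surviving dye centres past mid-arclength — in the
distal half, where thrombi form. The periodicity metric (relative
cycle-3 vs cycle-4 velocity difference) of 0.02–0.05 confirms the flow
is settled. Centerline profiles (`s.centerline_velocity`,
`s.centerline_ssr`) decay monotonically from ostium to tip (Spearman ρ
vs arclength ≈ −0.97 here).

The full 4-shape × 2-condition grid, comparison table and VTK
snapshots come from the CLI:

```bash
laa-stasis run --outdir out/           # 8 runs, summaries + comparison.csv
laa-stasis compare out/                # healthy-vs-AF deltas per morphology
laa-stasis mesh-sense --levels 3       # metric drift across mesh resolutions
laa-stasis waveform --condition af     # tabulate the mitral waveform
```

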