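# uncsampler

Analysis chain for badge-type passive aerosol samplers of the UNC design:
an SEM stub with a sticky collection surface under a perforated mesh cap,
on which airborne dust deposits by settling and diffusion.  The package
turns scanning-electron-microscope tile images of such a stub into
blank-corrected PM₂.₅/PM₁₀ air concentrations, computes the gravimetric
impactor and optical-particle-counter references they are judged against,
and ships a synthetic-deposition generator so the whole chain can be
validated by parameter recovery.

It is written for occupational-hygiene and aerosol researchers evaluating
passive sampling against active reference methods.

## The method

Each tile image is thresholded automatically by maximising the two-class
Rényi entropy (orders α = ½, 1, 2 combined by the standard three-estimate
rule), connected components are labelled with 8-connectivity, and
components outside 0.41–10000 µm² are discarded.  A detected particle of
projected area *A* is sized and weighed through

    d_pa = √(4A/π)
    d_ve = (6 f_V/π)^{1/3} · d_pa
    d_ae : d_ae² C_c(d_ae) ρ₀ = d_ve² C_c(d_ve) ρ_p / χ
    m    = ρ_p · f_V · d_pa³

with volume shape factor f_V = 1.6 (convention V = f_V·d_pa³), dynamic
shape factor χ = 1.4, particle density ρ_p = 2.0 g cm⁻³ and the
Cunningham slip correction C_c.  The deposited mass on one stub inverts
to an airborne concentration per PM fraction f:

    C_f = Σ_i m_i · w_f(d_ae,i) / (η(d_ae,i) · V_dep(d_ae,i)) / (A_stub · T)

where w_f is the (sharp, boundary-inclusive) PM-fraction weight, η the
mesh-cap collection efficiency, V_dep the deposition velocity
(gravitational settling plus Brownian diffusion across a 1 mm boundary
layer), A_stub the analyzed area and T the sampling duration.  Field-blank
means are computed per collection surface (polycarbonate vs carbon tab)
and subtracted from every result of that surface; negative corrected
values are retained.  References: impactor concentrations from duplicate
filter weighings and metered flow (C = Δm/Q·t), and optical-counter bin
counts converted to cumulative PM masses at 2.0 g cm⁻³, with
PM₀.₇₅ ≡ (PM₀.₅ + PM₁.₀)/2 as the fine-fraction proxy.

## Worked example

Simulate a stub exposed 24 h to 2 mg m⁻³ of lognormal dust
(CMAD 2.5 µm, GSD 1.6), segment it, and recover the concentration:

```python
from uncsampler import default_config, synth, quantify as q
from uncsampler.segmentation import collect_stub

cfg = default_config()
scen = synth.TruthScenario(true_concentration_mg_m3=2.0, cmad_um=2.5, gsd=1.6,
                           duration_h=24.0, deposition_area_mm2=3.0,
                           pixel_side_um=0.25, d_min_um=1.5, seed=1)
particles = synth.sample_population(scen, cfg)
stub = synth.render_tiles(particles, scen, cfg)
records, area = collect_stub(stub.tiles, cfg.with_(pixel_side_um=0.25))
occ = q.SamplingOccasion("demo", "lab", "PC", duration_h=24.0)
res = q.stub_concentration(q.size_particles(records, cfg), area, occ, cfg)
truth = synth.true_pm_concentrations(scen, cfg)
print(f"PM2.5 {res.pm25_mg_m3:.4f} vs true {truth['pm2.5']:.4f} mg/m3")
print(f"PM10  {res.pm10_mg_m3:.4f} vs true {truth['pm10']:.4f} mg/m3")
```

prints

```
PM2.5 0.1448 vs true 0.1469 mg/m3
PM10  1.8572 vs true 1.9276 mg/m3
```

i.e. ~6100 deposited particles are segmented and inverted back to within
a few percent of the generated truth.  Running the same campaign at the coarser
0.64 µm pixel drops PM2.5 recovery to ~78% while PM10 stays near 98%:
at that scale the measured-area grid has no size point between 2.18 and
2.52 µm, so particles just below the 2.5 µm cut are mis-sized out of the
fine fraction — a concrete mechanism for passive samplers under-reading
PM2.5 relative to impactors at low magnification.

A campaign-scale narrative of the same chain lives in `analysis/`
(`01_simulate_campaign.py` → `04_compare_with_references.py`); it writes
its tables under `results/` and a command-line interface (`uncsampler
simulate|segment|quantify|compare`) wraps the identical library calls for
work on real image directories.

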