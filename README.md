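# curvsense

Membrane curvature-sensing analysis for coarse-grained curved-bilayer
systems.

Peripheral membrane proteins such as the ANTH domain of CALM/AP180 are
believed to localize on membranes through a balance of two opposing
attractions: hydrophobic insertion, which favours convex regions where
lipid tails are more solvent-exposed, and electrostatic binding to PIP2
headgroups, which are themselves enriched at concave curvature.  On a
bilayer draped over a nanoporous substrate the two preferences pull toward
different radii, and whether a protein variant "senses curvature" can be
read off as the position of its radial distribution function (RDF) peak
relative to the membrane's curvature bands.

`curvsense` provides the full analysis chain for that readout, plus a
synthetic generator that stands in for molecular-dynamics output so every
stage is testable end to end:

* **Membrane profile** — the radially averaged headgroup height h(r) is
  fitted with the sigmoid h(r) = a + (c − a)/(1 + exp(b(r − x0)))^d, and
  curvature follows analytically as K = f″/(1 + f′²)^{3/2}, RoC = 1/|K|,
  with symbolically generated derivatives.  Grid points are labelled
  concave (K > 0, toward the solvent), convex, or flat.
* **Localization** — protein centre-of-mass traces are reduced to
  r = √((x − x_c)² + (y − y_c)²), binned into sum-1 histograms (100 bins,
  0–25 nm), 50 × 50 heatmaps of absolute distances, Gaussian KDEs, and
  RDFs normalized by exact box-clipped annulus areas and by the species'
  global area density so uniform occupancy reads RDF = 1.
* **Contacts & orientation** — per-residue contact counts against
  hydrophobic tail beads and PIP2 headgroups (periodic minimum-image,
  cKD-tree accelerated), residue-class annotation, top-k ranking, and a
  principal-axis tilt angle.
* **Synthetic data** — curved-membrane bead frames with curvature-sorted
  PIP2 and Metropolis protein walks under U(r) = −w_hydro·A_convex(r)
  − w_pip2·A_PIP2(r), with a direct-summation Boltzmann occupancy oracle.
* **Pipeline/CLI** — `curvsense run` orchestrates
  generate → profile → localize → contacts into a seeded, manifest-hashed
  run and a verdict matrix over three protein analogues × two membrane
  compositions.

See `docs/methods.md` for the models, defaults, and what the synthetic
generator does and does not emulate.

## Worked example

```python
import numpy as np
import curvsense as cs

cfg = cs.GeneratorConfig(n_frames=5, seed=1)          # PC/PIP2 membrane
frames = cs.generate_membrane_frames(cfg)

hp = cs.radial_height_profile(frames, cfg.pore_center)
fit = cs.fit_sigmoid(hp)
print("fit params (a, b, c, d, x0):", tuple(round(p, 3) for p in fit.params))

curv = cs.curvature_and_roc(fit, np.linspace(0, 25, 512))
bands = cs.classify_regions(curv)
print("most concave r:", round(bands.most_concave_r, 2),
      "nm; most convex r:", round(bands.most_convex_r, 2), "nm")

energy = cs.radial_energy(cfg, frames=frames)         # full-helix preset
traces = cs.generate_protein_traces(cfg, energy, n_steps=10_000)
rdf = cs.rdf_normalize(cs.radial_histogram(traces, cfg.pore_center),
                       cfg.box, cfg.pore_center)
peak = cs.peak_location(rdf, curv, min_count=100)
print("protein RDF peak:", round(peak.r_peak, 2), "nm in the",
      peak.region, "band; enrichment", round(rdf.density.max(), 1))
```

Output:

```
fit params (a, b, c, d, x0): (14.995, 0.551, 11.044, 0.947, 8.407)
most concave r: 5.72 nm; most convex r: 11.3 nm
protein RDF peak: 11.38 nm in the convex band; enrichment 7.1
```

The fitted plateaus (≈ 15 and ≈ 11 nm) and transition radius reproduce the
generating geometry; the curvature bands sit near 6 and 11 nm; and the
full-helix analogue — whose hydrophobic weight outmatches its PIP2
attraction — peaks at ≈ 11 nm inside the convex band at ≈ 7× its bulk
density: a convex-sensing verdict.  Rerunning with the `short` preset
(`cfg = dataclasses.replace(cfg, protein=cs.ProteinSpec.preset("short"))`)
moves the peak into the concave band, the PIP2-driven phenotype.

From a shell, the same pipeline is:

```bash
curvsense run --config run.yaml --seed 1
curvsense localize --traj traces.tsv --center 16,20 --bins 100 --rmax 25 \
          --mode rdf --out rdf.tsv
```

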