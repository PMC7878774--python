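# bzdna

Conformational-dynamics analysis of B–Z junctions at DNA mismatches.

An A…A mismatch embedded in B-form DNA is a conformational chameleon: the
two adenines exchange between several hydrogen-bond schemes
(N1…N6/N6…N1, N3…N6/N6…N3, N7…N6/N6…N7 or none), flip, extrude into the
grooves, or stack, and the surrounding backbone visits Z-like substates —
the signature of a local B–Z junction. `bzdna` provides the analysis
stack used to characterize this behaviour from simulation trajectories,
plus a synthetic-data layer that generates trajectories and biased
samples with known ground truth, so every estimator can be validated
end to end. It is aimed at structural bioinformaticians and simulators
working on non-canonical DNA.

Core components:

- **Backbone substate calling** — per-step rotamer wells of
  (ε, ζ, α, γ) labeled BI (t, g−, g−, g+), BII (g−, t, g−, g+),
  BIII (g−, g−, g−, g+) or ZI (g−, g+, g+, t); glycosyl χ classified
  +syn/anti/−syn; Altona–Sundaralingam sugar pucker.
- **Hydrogen-bond dynamics** — frame-by-frame scheme assignment from the
  six donor…acceptor distances (bonded ≤ 3.5 Å, non-bonded > 4 Å),
  run-length lifetime profiles, occupancies, and non-bonded density maps
  over (χ_a, χ_b).
- **Event metrics** — base-flip pseudo-dihedral, signed groove-ward
  extrusion, stacking, pair opening, minor-groove width
  (P(i)…P(j−3) − 5.8 Å).
- **2D periodic WHAM** — umbrella windows on the glycosyl torsion pair
  with harmonic periodic bias U = ½k[d_p(χ_a−c_a)² + d_p(χ_b−c_b)²],
  self-consistent solution of

      P(x) ∝ Σ_j n_j(x) / Σ_j N_j e^{(F_j − U_j(x))/k_BT},
      e^{−F_j/k_BT} = Σ_x P(x) e^{−U_j(x)/k_BT},

  min-normalized PMF on a periodic 72 × 72 grid, time-block error
  estimation, basin detection and barrier analysis.
- **Synthetic data** — an analytic four-basin free-energy surface with a
  vectorized biased Metropolis sampler, Markov scheme timelines, scripted
  event trajectories, and an idealized B-form fiber duplex builder with a
  posable mismatch.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
from bzdna import (build_fiber_duplex, canonical_check, step_states,
                   generate_windows, wham_2d, find_basins,
                   analytic_surface, sample_windows_batch, WhamConfig)
from bzdna.torsions import compute_torsions_chain

# idealized 15-mer duplex with an A...A mismatch opposite residue 8
frame, topo = build_fiber_duplex("CAACAACAACAACAA", mismatches={8: "A"})
reports = canonical_check(frame, topo)
dists = [d for r in reports for d in r.distances.values()]
print(f"canonical pairs: {len(reports)}, WC distances "
      f"{min(dists):.2f}-{max(dists):.2f} A, broken: {sum(r.broken for r in reports)}")

labels = [s.label for s in step_states(compute_torsions_chain(frame, topo.strand_a))]
print("strand-a step states:", {l: labels.count(l) for l in set(labels)})

# umbrella sampling on the default four-basin glycosyl surface
surf = analytic_surface().normalized()
windows = sample_windows_batch(surf, generate_windows(10.0, 100.0), 500, seed=0)
grid = wham_2d(windows, WhamConfig())
print(f"WHAM converged in {grid.iterations} iterations")
for b in find_basins(grid, threshold=3.0).basins:
    print(f"  basin {b.label}: minimum {b.minimum_energy:.2f} kcal/mol "
          f"at chi = {b.minimum_location} deg")
```

Output:

```
canonical pairs: 14, WC distances 2.87-3.05 A, broken: 0
strand-a step states: {'BI': 14}
WHAM converged in 1365 iterations
  basin B1: minimum 0.00 kcal/mol at chi = (67.5, 237.5) deg
  basin B2: minimum 0.19 kcal/mol at chi = (242.5, 57.5) deg
  basin B3: minimum 0.92 kcal/mol at chi = (242.5, 237.5) deg
  basin B4: minimum 1.39 kcal/mol at chi = (57.5, 52.5) deg
```

The 14 canonical pairs of the mismatched duplex keep their Watson–Crick
donor…acceptor distances inside the accepted 2.5–3.5 Å range and every
base step classifies BI, as a B-form control should. The reconstructed
free-energy surface recovers all four planted glycosyl basins —
+syn…anti (B1), anti…+syn (B2), anti…anti (B3) and +syn…+syn (B4) —
within one 5° bin of their true centers, with basin depths matching the
planted 0 / 0.25 / 0.9 / 1.4 kcal/mol to the sampling noise.

A `bzdna` command-line interface wraps the same pipelines
(`bzdna torsions|hbonds|events|wham|minima|synth ...`); every run echoes
its effective configuration to a provenance file and writes TSV/JSON
outputs with unit-bearing headers.

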