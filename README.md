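# hemelink

Analysis toolkit for crosslinked haem-c (P460-type) active sites: geometric
descriptors and crosslink classification from coordinates, excitation-spectrum
convolution and ferric/ferrous Soret-shift comparison, MD-trajectory
water/H-bond statistics, and constrained electrostatic-potential (ESP) charge
fitting — together with seeded synthetic-data generators so every stage is
testable without any external downloads.

## Modules

| Module | Purpose |
| --- | --- |
| `hemelink.structure_io` | PDB/mmCIF/XYZ reading (via biotite), altloc resolution (max occupancy, then min B-factor), mapping of the named haem-c site atoms (Fe, pyrrole N, meso/beta carbons, proximal His N, crosslinking Lys NZ/CE/CD, distal water O) |
| `hemelink.haem_geometry` | Site descriptor vector (Fe–HisN, Fe–water, Fe–pyrrole N, LysNZ–CHA, LysCD–C2A, C3A–CMA, Fe out-of-plane, ring planarity RMS), crosslink classification (SC/DC/AMBIGUOUS/NONE) and C–C bond-character assignment |
| `hemelink.spectra` | Stick-spectrum I/O, Gaussian convolution (unit-area lines, default sigma 0.15 eV; 30/50-state truncation for ferrous/ferric), Soret assignment (max oscillator strength or convolved peak), nm↔eV conversion and round-then-difference redox shifts |
| `hemelink.trajectory_analysis` | Water residence near Fe (default 3.5 Å cutoff), distance series, histogram mode detection (bimodality), geometric H-bond occupancy |
| `hemelink.esp_charges` | Coulomb grid-potential prediction and exactly-constrained linear least-squares charge fitting (total charge, group sums, equivalence sets via the KKT system), plus group-charge redistribution for transferable charges |
| `hemelink.synthetic_data` | Seeded generators: idealized porphyrin sites with requested descriptors, Gaussian-mixture Fe–water trajectories with exact H-bond frame counts, Soret-dominant stick spectra, shell-grid ESP problems from known charges — each returning machine-checkable ground truth |

## CLI

```bash
hemelink geometry --in site.pdb --chain A            # descriptor report (JSON)
hemelink spectra convolve --in sticks.dat --out curve.csv
hemelink spectra shift --ferric a.dat --ferrous b.dat --rounding 2dp
hemelink traj --traj frames.pdb --cutoff 3.5
hemelink espfit --problem problem.json --out-charges charges.csv
hemelink synth porphyrin|traj|spectrum|esp --out ...  # synthetic inputs
```

Stick-spectrum files are two-column text (energy eV, oscillator strength,
`#` comments); trajectories are multi-model PDB or XYZ frame stacks; ESP
problems are JSON documents (positions, grid, potentials, constraints).

## Conventions

- Coordinates in Å; charges in e; potentials in e/Å (k = 1).
- Fe out-of-plane distance is from Fe to the unweighted centroid of the four
  pyrrole nitrogens; its signed variant is positive on the distal (water)
  side of the N4 plane.
- Crosslink thresholds: a contact ≤ 1.80 Å counts as bonded; CD–C2A ≥ 2.80 Å
  counts as clearly unbonded; in between is AMBIGUOUS. C–C bond character:
  ≤ 1.40 Å double, ≥ 1.48 Å single. All thresholds configurable.
- No periodic-boundary imaging is applied to trajectories; frames are assumed
  whole and site-centred.
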