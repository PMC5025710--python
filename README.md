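# cyclomap

Tools for low-resolution single-particle cryo-EM map analysis of elongated
oligomeric particles:

* **Cylindrical initial models** — turn a single 2D side-view class average
  into a rotationally symmetric 3D starting model by sweeping its 2D
  Fourier transform about the long axis (`symminit`), plus a soft-edged
  reference-cylinder generator.
* **Simulated density & projections** — Gaussian-atom rendering of atomic
  models, volume projection, and exhaustive projection matching
  (`density_model`).
* **Rigid-body docking** — FFT cross-correlation translation search over a
  deterministic orientation grid, with sequential multi-copy fitting and
  steric-clash counting (`docking`).
* **Ring / lock-washer geometry** — total-least-squares reference plane
  through six subunit anchors, opening angle, axial displacements, bending
  curve, cross-section extents and axial-gate state (`conformation`).
* **Resolution machinery** — Fourier shell correlation, threshold-crossing
  resolution (0.143 gold standard), soft masks, Nyquist-fraction
  arithmetic (`fsc_resolution`, `map_core`).
* **Synthetic fixtures** — hexameric head–neck–legs phantoms in planar and
  lock-washer conformations with exact ground truth, noisy projection
  stacks, and SSNR-controlled half-map pairs (`synthetic_data`), so the
  whole pipeline is testable without downloading any data.

Maps are MRC2014 (modes 0/1/2) via `mrcfile`; atomic models are PDB/mmCIF
via `biotite`. Arrays are indexed `(z, y, x)` with `z` the particle long
axis; physical coordinates are Angstrom relative to the box-center voxel.

## CLI

The `cyclomap` entry point groups all operations:

```sh
cyclomap cylinder --length 220 --diameter 140 --box 224 --apix 1.8 --out cyl.mrc
cyclomap init-model classavg.mrc --lowpass 120 --out model.mrc
cyclomap pdb2map model.pdb --apix 2.0 --resolution 15 --box 96 --out sim.mrc
cyclomap fit map.mrc model.pdb --copies 6 --angular-step 10 --resolution 15
cyclomap ringgeom anchors.tsv
cyclomap sections map.mrc --every 5
cyclomap fsc half1.mrc half2.mrc --threshold 0.143 --out fsc.json
cyclomap phantom --conformation lockwasher --opening-angle 81 --rise 20 --out ph.mrc
cyclomap info / filter / fliphand / project / matchproj / bend ...
```

Run `cyclomap COMMAND --help` for options.

## Notes on conventions

* Low-pass filters use a raised-cosine edge (default 3 Fourier pixels);
  the exact window used by upstream processing packages is generally
  unspecified, so filtered outputs record their parameters in metadata.
* The Fourier sweep interpolates the 2D spectrum linearly in radius at
  each axial frequency; the input is mirror-symmetrized about the long
  axis first so the output volume is exactly real.
* Gaussian-atom rendering uses `sigma = resolution / (pi * sqrt(2))` with
  per-atom integral proportional to atomic weight; the constant is
  exposed for other conventions.
* Docking is fully deterministic: fixed orientation grids, lexicographic
  tie-breaking, no randomness.
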