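# epidose

EPID-based 3D dosimetric verification toolkit:

* **epid** — portal-image corrections (arm backscatter, gantry-dependent
  panel displacement), two-exponential scatter-kernel fitting against in-air
  ion-chamber data, FFT deconvolution of portal images into absolute
  fluence maps at the isocenter plane, horn flattening.
* **beam_model** — bundled photon spectra (6/10 MV), NIST water attenuation
  table, analytic two-exponential point energy-deposition kernel tabulated
  on 36 zenith bands, 288-direction collapsed-cone set, and
  cumulative/cumulative-cumulative (CK/CCK) kernel tables.
* **engine** — TERMA by divergent per-voxel ray tracing with exact
  (Siddon-style) radiological depth, collapsed-cone convolution/
  superposition with density-scaled CCK transport, multi-field plan dose
  reconstruction, plus a brute-force point-kernel superposition oracle.
* **gamma** — 3D gamma index with 1 mm trilinear resampling, dose
  threshold, distance-sorted shell search with sub-lattice refinement, and
  an exhaustive-search oracle.
* **metrics** — water override, cumulative DVHs, mean/max dose-difference
  report in percent of prescription.
* **fixtures** — synthetic slab phantoms (adipose/muscle/bone/lung/water),
  square fields with error-function penumbras, forward-simulated EPID
  images; everything is generated programmatically and seeded.
* **nrrd_io / pipeline / cli** — minimal NRRD volume I/O (raw + ascii),
  YAML plan configs, and the `epidose` command line.

## CLI

```sh
epidose fixtures --preset slab30 --out fixtures/        # synthetic phantom
epidose fixtures --preset epid-sim --out fixtures/      # simulated portal TIFF
epidose fit-kernel --data chamber.csv --out kernel.json
epidose fluence --epid image.tif --config plan.yaml --out fluence.csv
epidose dose   --config plan.yaml --out dose.nrrd
epidose gamma  --ref tps.nrrd --eval epid.nrrd --crit 3,3 --threshold 10 \
               --out gamma.nrrd --report gamma.json
epidose run    --config plan.yaml --out results/        # full pipeline
```

Exit codes: 0 ok, 1 user error, 2 internal error.

A plan config is YAML; every key has a default, so the minimal end-to-end
run is fully synthetic:

```yaml
seed: 1
energy: 6MV
kernel: {c: 0.03, mu_S: 1.5, mu_L: 0.5}
fields:
  - {gantry_deg: 0.0, side_cm: 10.0}
gamma_criteria: [[3, 3], [2, 2]]
```

## Conventions

3D grids are `(nx, ny, nz)` arrays with per-axis spacing and the origin at
the center of voxel (0,0,0); the isocenter is the coordinate origin; all
lengths in cm (gamma criteria in mm).  Gantry rotates about +y; at gantry 0
the source sits at `(0, 0, +SAD)` and the beam travels toward −z.
Densities are relative electron densities (water = 1).  Dose units are
Gy-proportional, carried through the absolute calibration scalar `c_ad`.
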