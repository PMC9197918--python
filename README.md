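# aneuflow

Post-processing toolkit for comparing hemodynamic velocity fields acquired
by different modalities (4D-flow-MRI-like, stereo/tomographic-PIV-like,
CFD-like). It estimates wall shear stress (WSS) on a triangulated lumen
surface from gridded 3D velocity data, computes vortex metrics
(vorticity, Q-criterion), handles dynamic-similarity scaling between a
scaled-up phantom and patient-scale flow, and quantifies cross-modality
agreement (profile correlations, Bland–Altman limits of agreement).

A synthetic-phantom generator (parabolic pipe flow and a
tube-plus-spherical-sac geometry with a divergence-free recirculating
vortex) plus modality-degradation emulation make the whole pipeline
testable without any patient data.

## Layout

| module | purpose |
|---|---|
| `aneuflow.io_formats` | STL (binary/ASCII), VTK legacy structured points, CSV grid/table I/O; config |
| `aneuflow.synthetic_data` | analytic flows, sac phantom, modality presets and degradation |
| `aneuflow.tensor_calculus` | velocity-gradient tensor, S/W split, vorticity, Q-criterion |
| `aneuflow.wall_shear` | inward vertex normals, IDW gradient mapping, `tau = 2*mu*symm(grad u).n`, normalization, summaries |
| `aneuflow.similarity_scaling` | Reynolds numbers, Re-matched ratio bundles, WSS/vorticity rescaling |
| `aneuflow.comparison_stats` | V_ref normalization, trilinear down-sampling, profiles, Pearson, Bland–Altman |

All internal units are SI (m, m/s, Pa, Pa·s). Grids are indexed
`(i, j, k) -> (x, y, z)` with voxel centers at `origin + index * spacing`.

## CLI

```sh
# generate a sac phantom, degrade it to MRI-like resolution
aneuflow --seed 1 synth --case sac --spacing 2.5e-4 --modality mri -o mri.vtk
aneuflow synth --case sac --spacing 2.5e-4 -o fine.vtk --surface-out wall.stl

# wall shear stress on the lumen surface
aneuflow wss fine.vtk wall.stl --mu 0.0035 --idw-power 2 --neighbors 8 -o wss.csv

# vortex metrics
aneuflow vortex fine.vtk --q-iso 9000 -o q.vtk

# agreement statistics
aneuflow compare fine.vtk mri.vtk --match-resolution
aneuflow profile fine.vtk --start -0.002,0,0.006 --end 0.002,0,0.006 -n 50
aneuflow ba wss_a.csv wss_b.csv
```

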