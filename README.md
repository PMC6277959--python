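# platescan

Software toolkit for a low-cost automated multi-well plate imager built
from a repurposed CNC engraving stage, a fixed video microscope and a
relay-triggered camera.  The hardware moves the plate under the optics;
everything else — knowing where each well is, driving the scan,
reassembling the image series, and merging each well's z-stack into one
sharp micrograph — is software, and that software is this package.

It covers four jobs:

1. **Calibration** — predict the machine coordinate of every well from
   four manually measured corner wells.  The operator zeroes the stage
   on the top-left drop and notes the coordinates of the other three
   corners; each axis then gets a bilinear surface

   ```
   f(u, v) = k0 + k1·u + k2·v + k3·u·v
   ```

   over normalized grid fractions (u, v), with the closed form
   k0 = c00, k1 = c10 − c00, k2 = c01 − c00, k3 = c11 − c10 − c01 + c00.
   Three corners would define a plane, but inexpensive stages move
   nonlinearly enough to push wells out of focus; the u·v warp term is
   the minimal curved correction exactly determined by the fourth
   corner.

2. **Scan planning** — emit the GRBL G-code program that visits every
   well (serpentine by default), steps through an n-point z-stack
   (default 5 images spaced 0.15 mm, centered on the calibrated focus),
   and pulses the camera relay (`m3` … `m5`) with settle and
   write dwells (`g4 p…`) so the stage stops shaking and the camera
   finishes writing before the next move.  One extra, deliberately
   defocused *sentinel* image closes each well.

3. **Stack segmentation** — partition the camera's sequentially
   numbered JPEGs back into per-well stacks.  JPEG compression makes
   the defocused sentinel markedly smaller on disk than its in-focus
   neighbors, so stack boundaries are found from file sizes alone (no
   decoding), then reconciled with the expected stack period by a
   dynamic program that tolerates occasionally skipped frames.

4. **Focus fusion** — align each stack by integer-pixel translation,
   weight every pixel by local Laplacian contrast, and blend the frames
   in a Laplacian pyramid into one extended-depth-of-field image per
   well.

A seeded synthetic-acquisition generator renders defocus-blurred
droplet scenes with the JPEG size signature of the real instrument, so
the whole pipeline is testable without hardware.

## Worked example

Write a control file with the plate and the measured corners (mm,
absolute machine coordinates, origin at well A1):

```toml
[plate]
name = "96"

[calibration]
c10 = [100.15, -1.34, 0.13]   # top-right corner drop
c01 = [0.22, -62.81, -0.05]   # bottom-left
c11 = [100.40, -64.10, 0.21]  # bottom-right

[scan]
n_z = 5
dz = 0.15
```

Then plan the scan:

```
$ platescan plan --config plate.toml -o scan.gcode
scan.gcode: 3457 commands, 576 images over 96 wells
```

576 images is 96 wells × (5 z-images + 1 sentinel).  The program
starts:

```
g90
g21
g0 x0.000 y0.000 z0.300
g4 p0.1
m3
g4 p0.2
m5
g4 p0.5
```

— absolute mm mode, move to well A1 at the stack top (calibrated focus
z = 0 plus 2 × 0.15 mm), settle 0.1 s, trigger the camera relay with a
0.2 s pulse, then wait 0.5 s for the image to be written.  Any G-code
sender (e.g. bCNC) can stream the file to the stage.

```
$ platescan calibrate --config plate.toml
planar-model residual at far corner (mm): x=+0.030, y=+0.050, z=+0.130
planar model within focus tolerance (curved model still used)
```

The calibrate report shows how much the three-corner planar model would
miss the fourth corner — here 0.13 mm in z, comparable to the 0.15 mm
z-step, which is why the curved model exists.

With no instrument at hand, simulate an acquisition and process it:

```
$ platescan simulate --plate 24 --seed 7 -o simdir
simdir: wrote 144 images for 24 wells
$ platescan segment simdir --plate 24 --nz 5 -o manifest.json
manifest.json: 24 stacks (24 complete with 5 images)
$ platescan fuse manifest.json -o fused/
fused/: wrote 24 fused images
```

`fused/` now holds one extended-depth-of-field PNG per well (`A1.png`,
`A2.png`, …) plus an `index.csv`.

The same functionality is available as a library:

```python
from platescan import (CornerSet, ScanConfig, builtin_plate,
                       fit_corners, plan_scan, count_images)

corners = CornerSet(c10=(100.15, -1.34, 0.13),
                    c01=(0.22, -62.81, -0.05),
                    c11=(100.40, -64.10, 0.21))
program = plan_scan(fit_corners(corners), builtin_plate("96"), ScanConfig())
count_images(program)   # 576
```

## Layout

| module | contents |
| --- | --- |
| `platescan.plate_geometry` | plate layouts, well ↔ grid-fraction mapping, field-of-view arithmetic |
| `platescan.calibration` | four-corner bilinear calibration, planar diagnostics |
| `platescan.scan_planner` | scan protocol, G-code generation and parsing |
| `platescan.stack_segmentation` | sentinel detection, series partitioning, well assignment |
| `platescan.focus_fusion` | alignment, contrast weights, pyramid fusion |
| `platescan.synthetic_acquisition` | seeded synthetic acquisitions with ground truth |
| `platescan.config` / `platescan.cli` | TOML control files, `platescan` command |

See `docs/methods.md` for the models, defaults and their rationale.
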