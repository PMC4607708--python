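# octpath

Shortest-path segmentation of retinal OCT B-scans, thickness
quantification at the fovea, and the paired statistics used to ask
whether two spectral-domain OCT instruments measure the same retina once
a single segmentation algorithm is applied to both.

Different OCT devices report systematically different retinal
thicknesses, mostly because their built-in software disagrees about
where the outer retinal boundary is. `octpath` removes that variable: it
traces the same four boundaries on any calibrated B-scan — the inner
limiting membrane (ILM), the photoreceptor inner/outer segment junction
(IS/OS), the RPE centerline, and the posterior edge of the RPE–Bruch's
membrane complex (RPE_outer) — and computes two thickness outcomes,

* **retinal thickness** = ILM → RPE_outer,
* **RPE+OS complex** = IS/OS → RPE_outer,

at the foveal center point (CPT), on the central 1-mm line
(mean of the −0.5, 0, +0.5 mm points), and at all 13 points of the 6-mm
line. A device-agreement module then runs paired *t* tests, Pearson
correlation, ordinary-least-squares device conversion, Bland–Altman
limits (mean ± 2 SD of the paired differences) and test–retest
repeatability. A synthetic phantom generator with exact ground truth
(layered reflectivity, foveal pit, multiplicative speckle, frame
averaging, per-A-scan jitter, two device geometries) makes the whole
chain testable without clinical data.

## The core algorithm

Each boundary is the minimum-cost left-to-right path through a cost
image: one row per column, per-column row change bounded by `max_jump`,
path length = the sum of pixel values along the path, solved exactly by
dynamic programming. The RPE centerline uses the negated B-scan
(hyper-reflective areas become dark) in a narrow band around the
brightest image row; the IS/OS, RPE_outer and ILM use negated
polarity-matched vertical gradient images in anatomically constrained
bands, traced in that order. User-supplied anchor points force the path
through known-correct pixels, replacing interactive click correction;
each inter-anchor interval is solved as an independent fixed-endpoint
problem. Details, defaults and measured limits: [docs/methods.md](docs/methods.md).

## Worked example

```python
from octpath import segment_all, measure_scan
from octpath.phantom import device_a_spec, generate_phantom

res = generate_phantom(device_a_spec(), seed=0)   # 512 A-scans / 6 mm, speckled
seg = segment_all(res.scan)                        # four traced boundaries
summary = measure_scan(seg, "RETINA")
print(f"CPT        {summary.cpt_um:7.1f} um")
print(f"1-mm line  {summary.line1mm_um:7.1f} um")
print(f"all points {summary.allpoints_um:7.1f} um  ({summary.n_missing} missing)")
```

prints, for this seed:

```
CPT          224.5 um
1-mm line    230.9 um
all points   283.8 um  (1 missing)
```

The phantom's true central thickness for this anatomy is 226.0 μm: the
traced CPT lands within half an axial pixel of it despite single-look
speckle. The all-points mean is higher than the CPT because the retina
thickens away from the pit; one 3-mm grid point fell off the 6-mm scan
after the fovea was localized slightly off-center, and is masked rather
than extrapolated.

The same pipeline drives a two-device comparison end-to-end:

```python
from octpath.phantom import generate_cohort, DEVICE_A, DEVICE_B
from octpath.agreement import per_point_compare

eyes, truth = generate_cohort(n_eyes=37, bias_um=1.85, seed=11)
_, pooled = per_point_compare(truth[truth.layer_pair == "RETINA"],
                              DEVICE_A, DEVICE_B)
print(round(pooled.mean_diff, 3))   # 1.775 — the injected bias, from the truth tables
```

## Command line

```bash
octpath phantom --mode cohort --n 37 --seed 1 --out data/      # synthetic dataset
octpath segment data/eye00_deviceA.tiff data/eye00_deviceA.json --out seg.json
octpath thickness seg.json --layer-pair retina --layer-pair rpeos --out thick.csv
octpath compare data/cohort_truth.csv --out table.csv --ba-out ba.csv
```

`segment` exits nonzero with the offending columns when the traced
boundaries violate their anatomical ordering — the cue to supply an
`--anchors` file.

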