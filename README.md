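# lensuse

Locate the regions of a spectacle lens that a wearer actually looks through,
from wearable eye-tracker recordings, and compare them with the regions a
task's geometry predicts.

The pipeline:

1. **recordings_io** — read/write 50 Hz binocular gaze recordings (native TSV
   or a Tobii-style JSON-lines dialect), load frame/task configuration files,
   and apply the data-loss quality-control rule (recordings with ≥ 10 % loss
   in any analyzed eye are excluded).
2. **fixation_detection** — I-VT velocity-threshold classification of samples
   into fixation events (30 °/s, 60 ms defaults, both configurable).
3. **lens_geometry** — intersect each fixation's sight line (mean pupil
   position + mean gaze direction) with the lens back surface (plane by
   default, sphere optional) and express the pierce point relative to the
   fitting cross, with nasal-positive re-expression per eye.
4. **task_zones** — theoretical regions of use from task geometry: sight
   lines from each eye's rotation center to the target rectangle's corners
   (per-eye convergence included), expanded by half the cohort mean pupil
   diameter.
5. **use_analysis** — region-of-use centers of mass (Cx, Cy), point-in-zone
   containment, and concordance statistics (fixation-pooled percentage,
   subject-averaged percentage, strict all-fixations-inside percentage).
6. **synthetic_gaze** — seeded simulator producing recordings with
   configurable accuracy bias, precision jitter and data loss, including a
   pinhole validity-check scenario with known ground truth.
7. **cli** — `lensuse` command wiring it all together.

## Coordinate convention

Right-handed headset frame: origin at the eye-tracker reference point,
`+z` forward along primary gaze, `+y` up, `+x` toward the wearer's **left**.
Right-eye rotation center at `x = −ipd/2`, left at `+ipd/2`. Nasal is `+x`
for the right eye and `−x` for the left eye; all tables carry both the signed
`x` and the nasal-positive `x_nasal`. Lengths are mm, times seconds, angles
degrees (target distances in metres in config files).

## CLI

```sh
# simulate a 26-subject cohort for the on-axis distance-reading condition
lensuse simulate --out scratch/sim --seed 1 --task distance_on_axis \
    --subjects 26 --duration 30

# project a recording onto the lens (QC + fixation classification included)
lensuse project --recording scratch/sim/S01_distance_on_axis.tsv \
    --frame frame.yaml --out scratch/points.csv --condition distance_on_axis

# theoretical zones for the same condition
lensuse zones --out scratch/zones.csv --task distance_on_axis --frame frame.yaml

# concordance tables and lens-map figures
lensuse concordance --points scratch/points.csv --zones scratch/zones.csv --out scratch/conc
lensuse report --points scratch/points.csv --zones scratch/zones.csv --out scratch/figs
```

Task presets: `distance_on_axis`, `distance_off_10`, `distance_off_15`,
`near_left`, `near_center`, `near_right`, `near_full`; any `--task` argument
may instead be a YAML/JSON file with unit-suffixed keys
(`target_distance_m`, `angular_width_deg`, `mean_pupil_diameter_mm`, ...).
Frame files use `ipd_mm`, `pupil_height_mm`, `bvd_mm`, `cre_to_lens_mm`;
pantoscopic tilt and wrap angle are read but deliberately not applied by the
projection model (a warning notes this).

Every command writes a resolved-configuration snapshot next to its outputs,
and `simulate` refuses to run without `--seed`.

## Notes on defaults

- `cre_to_lens` defaults to 25.5 mm (13.5 mm cornea-to-rotation-center
  + 12 mm back vertex distance).
- The angular-to-mm error conversions use an explicit lever arm
  (`DEFAULT_LEVER_ARM_MM = 32.5`); this exceeds the default CRE-to-lens
  distance and is kept explicit rather than hidden.
- The near-reading screen's elevation is an assumption (−20°, typical
  reading posture), configurable per task.
- Cohort mean pupil diameters: 3.73 mm (distance task), 2.88 mm (near task).
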