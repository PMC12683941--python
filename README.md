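# scaffoldquant

Spatial quantification of 3D scaffold co-culture images: who is where, who
is touching whom, and how well engineered T cells kill their targets.

3D scaffold co-cultures of bone-marrow stromal cells (BMSCs, CD90+),
malignant B cells (CD19+), and autologous CAR or mock-transduced T cells
(CD3+, optionally CAR+) are imaged as multi-channel confocal z-stacks. The
questions a lab asks of such stacks are quantitative: what fraction of
cells in an image is stromal / B / T, how many B cells are *co-localized*
with a T cell (a segmented mask positive for both CD19 and CD3 —
interpreted as a T cell engaging its target), does that differ between
disease groups (e.g. CLL vs ALL) or between the scaffold's periphery and
core, and how much target lysis do the effector cells achieve.

`scaffoldquant` implements that analysis as a tested, reusable Python
library:

- **Synthetic scaffold generator** — seeded 3D phantoms of a stromal
  network with adherent B cells, infiltrating T cells, a configurable
  engaged-contact fraction, per-class log-normal marker intensities,
  channel crosstalk, PSF blur and noise — plus matched "FACS" anchor
  tables and assay tables, so every downstream stage is verifiable
  against known ground truth without patient data.
- **Preprocessing** — grayscale morphology (ball-structured open / close /
  median) and an exact edge-clipped 3D neighborhood variance filter
  (default radius 2).
- **Segmentation** — a classical, deterministic 3D nuclei segmenter
  (Gaussian smoothing, Otsu, distance-transform watershed sized by the
  expected ~10.2-pixel cell diameter, per-mask half-maximum trim), and
  first-class import of label volumes from any external segmenter: the
  downstream math is segmentation-agnostic.
- **Marker quantification** — the core procedure. Per mask *m* and channel
  *c*, the total pixel intensity `I_mc` is min–max normalized and
  log-transformed, pooling all of a patient's stacks:
  `L_mc = ln((I_mc − min)/(max − min) + ε)`. The positivity threshold is
  anchored to flow cytometry: with `f` the mean externally measured
  positive fraction (in %) for the disease group across both experimental
  conditions, the threshold is the `n = 100 − f` th percentile of the
  patient's pooled `L` distribution, and a mask is positive iff `L` is
  strictly above it. Because both steps are rank-based, the called
  fraction matches the anchor by construction. CD19+CD3+ masks are
  classified *co-localized*; CD19+ only → B cell; CD3+ only → T cell;
  double-negative → stromal.
- **Spatial summaries and statistics** — composition fractions per stack /
  patient / region / group, `coloc_of_b` (double-positives over all CD19+
  masks), patient-level means of images, group mean ± SEM, and the
  standard test designs (paired t periphery-vs-core, Mann–Whitney U
  between groups with exact small-sample handling, one-way ANOVA with
  Tukey or Šidák adjustment).
- **Cytotoxicity calculators** —
  `% cytolysis = (live_targets_alone − live_sample) / live_targets_alone × 100`
  with matched baselines and core−periphery contrasts, and kinetic
  live-cell lysis curves: per-object double-positive areas filtered of
  background objects (≤ 10 µm), summed per 30-min frame, corrected by the
  time-matched spontaneous (basal) trace, and normalized to the maximal
  CAR lysis signal of the assay.
- **Pipeline + CLI** — a YAML-configured end-to-end runner
  (simulate → preprocess → segment → classify → quantify → report) with a
  JSON manifest (config hash, seed, output hashes) for bit-reproducible
  runs, and a thin `scaffoldquant` command-line interface over it.

## Worked example

`python examples/cytotoxicity.py` generates synthetic viability and
kinetic tables under the emulated study conditions and runs both
calculators:

```
endpoint cytolysis (% of target-alone viability lost):
group    region condition  cytolysis_pct  flagged_negative
  CLL periphery       car           27.9             False
  CLL      core       car           19.9             False
  ALL periphery       car           50.2             False
  ALL      core       car           45.1             False

core - periphery differences (CAR):
group condition  core_minus_periphery
  CLL       car                  -8.0
  ALL       car                  -5.1

CAR kinetic curve: maximal lysis at 9.0 h (peak 100% of maximal signal)
```

CLL-derived CAR T cells lyse ~28% of targets at the scaffold periphery
and ~20% in the stroma-dense core (an 8-point core deficit), against
~50/45% for ALL; the kinetic trace reaches maximal lysis at 9 h. The
other examples (`simulate_scaffold.py`, `classify_cohort.py`,
`segment_and_score.py`) walk the imaging side: on a simulated cohort with
noise-free anchors the classifier recovers the configured engaged-B
fraction exactly (`coloc_of_b` 0.25 vs configured 0.25) and the baseline
segmenter reaches F1 ≈ 0.8–0.9 against ground-truth masks.

## Command-line interface

```sh
scaffoldquant simulate --config sim.yaml --seed 7 --outdir out/
scaffoldquant segment --in out/stack.tif --channel nuclei --diameter 10.2 --out labels.tif
scaffoldquant classify --stack out/stack.tif --labels labels.tif \
    --anchors anchors.csv --group CLL --patient P1 --out cells.csv
scaffoldquant quantify --cells cells.csv --by patient_id,region --out summary.csv
scaffoldquant cytolysis --viability viability.csv --out lysis.csv
scaffoldquant run --config pipeline.yaml
```

See `docs/methods.md` for the model, its assumptions, parameter defaults,
and known limitations.
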