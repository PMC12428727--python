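# rbcflow

Red blood cell (RBC) deformability analysis for transfusion-unit quality
assessment: from microscopy fields of shear-deformed cells to per-cell
elongation ratios, population deformability profiles, donor-vs-recipient
statistical comparison, and a membrane-proteomics predictor of
deformability.

## The problem

Packed RBC units issued for transfusion are conventionally selected by
storage duration (first-in-first-out), but units of identical age differ
widely in *hemodynamic* quality — above all in how readily their cells
deform under shear. This matters acutely for premature neonates, whose own
cord-blood RBCs are on average more deformable than adult donor cells:
transfusing a rigid unit can impair microcirculation. `rbcflow` implements
the computational side of a cell flow-properties analysis: cells attached
to a slide under controlled shear (3.0 Pa) elongate; each cell's
**elongation ratio** is

    ER = A / B

where `A` and `B` are the cell's major and minor axes (ER = 1 for an
undeformed, rigid cell). A specimen is profiled by the distribution of ER
over ~10,000–15,000 cells imaged across 25–35 fields of 0.1 mm² each:

| Parameter | Definition |
|-----------|------------|
| MER       | median elongation ratio |
| AER       | mean elongation ratio |
| %UDFC     | undeformable cells, ER < 1.1 |
| %LDFC     | low-deformable cells, 1.1 ≤ ER < 1.3 |
| %HDFC     | highly deformable cells, ER ≥ 2.5 |

Beyond imaging, deformability correlates with membrane composition: the
package fits the linear predictor

    MER = a·[Protein] + b·[HBB]

where `[Protein]` is the Ln(LFQ) membrane level of a structural protein
(ezrin, stomatin, band 4.1, flotillin 1/2) and `[HBB]` the Ln(LFQ) level
of membrane-bound hemoglobin β-subunit, enabling unit selection from a
proteomics table alone.

Because suitable raw data are not publicly deposited, the package ships a
first-class synthetic-data generator (ER populations with calibratable
profiles, rendered field images with ground truth, unit cohorts, and
proteomics tables with a known linear response) so every stage is testable
end to end.

## Worked example

Calibrate a population model to a measured cord-blood unit profile
(MER 1.55, %UDFC 1.12, %HDFC 6.14), render 25 microscopy fields of it,
and recover the profile by image analysis:

```python
import rbcflow as rf

model = rf.calibrate_population(1.55, 1.12, 6.14)
sample = rf.simulate_er_population(model, 10_000, seed=1)
fields, truth = rf.render_specimen(sample, rf.ImagingParams(), n_fields=25, seed=2)
tables, profile = rf.analyze_specimen(fields)
print(f"MER = {profile.mer:.3f}, %UDFC = {profile.pct_udfc:.2f}, "
      f"%HDFC = {profile.pct_hdfc:.2f}, n = {profile.n_cells}")
```

This prints

```
MER = 1.547, %UDFC = 0.86, %HDFC = 5.91, n = 9996
```

i.e. the analyzer recovers the generated population's median elongation
(truth MER 1.547 for this finite sample; |error| 0.0002) from the rendered
images alone; four cells with ER above the quality-control ceiling of 6
were flagged rather than measured, hence n = 9996.

Ranking donor units against a recipient works on profiles or on predicted
deformability:

```python
rankings, selected = rf.rank_units(units, recipient_profile, tolerance=0.01)
```

A unit is selected when its (measured or predicted) MER is higher than, or
at least equal to, the recipient's.

The same stages are scriptable from the shell:

```bash
rbcflow simulate fields --seed 1 --out-dir fields/
rbcflow segment fields/*.tif --pixel-size 0.15 --out cells.csv
rbcflow profile cells.csv --out profile.json
rbcflow run --seed 1 --out-dir run/        # full synthetic pipeline
```

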