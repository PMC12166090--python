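# crcimmune

Region-resolved immune scoring and prognosis for colorectal cancer (CRC)
from H&E whole-slide image derivatives.

Deep-learning models can detect and classify every nucleus on an H&E
whole-slide image and segment the slide into tissue types. This package
implements everything that comes *after* those models: it turns per-slide
nuclei detection tables (centroids in μm plus one of seven nucleus
classes) and tissue-type label rasters (nine classes, with a μm-per-pixel
resolution) into quantitative immune scores that are resolved by tumor
region, and evaluates their prognostic value in a time-to-recurrence
survival analysis. The motivating biology: eosinophils and lymphocytes
near the invasive margin of CRCs carry prognostic information, and
quantifying them separately in the tumor front and tumor center makes
that information accessible directly from routine H&E slides.

## What it computes

**Invasive front.** CRCs grow into muscle and adipose tissue. The front
line is estimated as the equidistant midline between the tumor-epithelium
mask and the muscle∪adipose mask of the tissue raster (zero level set of
the difference of the two distance transforms), omitting any stretch that
borders normal mucosa. Tumor cells within 500 μm of the line (a 1000 μm
diameter band) are the **tumor front**; the rest are the **tumor center**.

**Lymphoid structures.** Lymphocytes are single-link clustered at a 20 μm
radius; connected components of >500 cells are lymphoid aggregates and
>50 000 are lymph nodes. Their members (and everything inside a lymph
node's hull) are excluded from all scores, since such structures would
otherwise skew stromal lymphocyte counts.

**Intraepithelial lymphocytes (IELs).** The epithelial region is the
union of 25 μm disks around tumor-epithelial cells minus 12.5 μm disks
around connective-tissue cells; non-excluded lymphocytes inside it are
IELs. The IEL score is the ratio of tumor cells with an adjacent IEL
(≤25 μm) to those without.

**Region scores.** For group *g* ∈ {lymphocyte, eosinophil} and region
*R* ∈ {front, center, all}:

```
score(g, R) = #{unique cells of g within 200 μm of their nearest tumor cell,
               attributed to R} / #{tumor cells in R}
```

An immune cell is attributed to the region of its *nearest* tumor cell,
so it is never counted twice (abbreviations LymF, LymC, LymA, EosF, EosC,
EosA). Descriptive distance profiles bin each immune cell by distance to
its nearest tumor cell (10 μm bins to 500 μm).

**Patients and cohorts.** Slide scores are aggregated per patient by
tumor-cell-weighted averaging, then min-max scaled per cohort using the
5th/95th percentiles of that cohort's stage II patients (values outside
[0, 1] are kept). Prognosis is assessed on time to recurrence (TTR,
censored at 60 months) with Kaplan-Meier quartile curves and Cox
proportional-hazards models (Efron ties, log1p-transformed scores),
compared by AIC.

Because real WSI detections and clinical follow-up cannot be bundled, the
package ships a first-class synthetic-data generator (`crcimmune.simulate`)
producing layered tissue geometries, distance-decaying immune point
patterns, planted lymphoid structures, and survival cohorts under known
proportional-hazards effects — every pipeline stage is testable against
ground truth.

## Worked example

```bash
crcimmune simulate --out demo/study --seed 7 --n-patients 5
crcimmune run-all --slides-dir demo/study --cohort demo/study/cohort.csv --out demo/results
```

`scores_slides.csv` then holds per-slide raw scores (immune cells per
tumor cell) plus the tumor-cell counts used as aggregation weights:

```
    slide_id  LymF  LymC  EosF  EosC   IEL  n_tumor_front  n_tumor_center
SIM-00000-s0 0.463 0.478 0.065 0.089 1.048            882             924
SIM-00000-s1 0.464 0.525 0.086 0.082 1.293            884             863
SIM-00001-s0 0.597 0.494 0.148 0.104 1.203            867             955
...
```

Patient SIM-00000's two slides average ~0.46 lymphocytes per front tumor
cell within 200 μm; its IEL values mean roughly half of tumor cells have
an adjacent intraepithelial lymphocyte. After stage-II percentile
normalization (`scores_patients_normalized.csv`) scores are on a common
per-cohort scale — 0 at the stage II 5th percentile, 1 at the 95th, with
values outside that window passing through:

```
patient_id   LymF   EosF    IEL  n_slides
 SIM-00000  0.445 -0.094  0.872         2
 SIM-00001  1.062  0.846  1.014         1
```

On a simulated survival cohort at a realistic scale, the Cox stage
recovers the generating protective effects:

```bash
crcimmune simulate-cohort --out demo/cohort.csv --seed 3 --n-patients 1122
crcimmune survival --patients demo/cohort.csv --out demo/surv
```

```
LymF: HR=0.62 95%CI=(0.29-1.33) p=0.2208
EosF: HR=0.73 95%CI=(0.34-1.56) p=0.4120
IEL:  HR=0.24 95%CI=(0.08-0.67) p=0.0068
```

(The generator's true hazard ratios are 0.59, 0.70 and 0.34 per unit of
the analysis covariate; each multivariate model adjusts for age, sex,
tumor location, pT, pN, adjuvant chemotherapy and MSI status.)
`model_aic.csv` ranks the score models by AIC with ΔAIC to the best.

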