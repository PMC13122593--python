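# cobbgeo

Deterministic Cobb-angle and coronal-tilt measurement from vertebral
keypoint annotations on standing coronal (PA) spine radiographs.

Adolescent idiopathic scoliosis (AIS) is quantified by the **Cobb angle**:
the angle between the superior endplate line of the most tilted vertebra
bounding a curve from above and the inferior endplate line of the most
tilted vertebra bounding it from below. Keypoint-detection models can
localize vertebral corners on radiographs, but the clinically meaningful
numbers — Cobb angles, end-vertebra choices, vertebral level names,
pelvic obliquity — come from a *geometry* step downstream of detection.
`cobbgeo` is that step, packaged for people building or auditing
screening pipelines: it turns corner/spinous keypoints and bilateral
PSIS (posterior superior iliac spine) landmarks into auditable clinical
measurements, with no learned components and no angle supervision
anywhere.

## The measurement model

All coordinates are image pixels, origin top-left, y increasing
downward. For vertebra *n* with top corners *l<sub>t,n</sub>*,
*r<sub>t,n</sub>* and bottom corners *l<sub>b,n</sub>*, *r<sub>b,n</sub>*:

- superior endplate angle α<sub>n</sub> = atan2(r<sub>t,n,y</sub> − l<sub>t,n,y</sub>, r<sub>t,n,x</sub> − l<sub>t,n,x</sub>)
- inferior endplate angle β<sub>n</sub> = atan2(r<sub>b,n,y</sub> − l<sub>b,n,y</sub>, r<sub>b,n,x</sub> − l<sub>b,n,x</sub>)
- both normalized to [−90°, 90°); vertebral tilt θ<sub>n</sub> = (α<sub>n</sub> + β<sub>n</sub>)/2

Over a visible vertebral sequence, the **end-vertebra search**
exhaustively evaluates C(i, j) = |α<sub>i</sub> − β<sub>j</sub>| (difference wrapped to the
acute range) for every pair with j − i ≥ 3, keeps the argmax if it
reaches 5°, then repeats once on the superior and inferior flanking
intervals — up to three curves per radiograph, each stratified as
mild (<20°), moderate (20–35°) or severe (>35°), with ≤10° below the
scoliosis threshold.

Level names (T1–L5) are anchored on the pelvis: the most caudal
vertebra whose box center lies above the horizontal PSIS line is L5 and
numbering proceeds superiorly; without a pelvis, the most superior
visible vertebra is assumed to be T1. The assignment is verified
(advisory only) by the fact that thoracic vertebrae have a larger
height/width ratio than lumbar ones. Pelvic (and optionally shoulder)
coronal tilt is the inclination of the bilateral landmark line.

The package also ships a **synthetic spine simulator** with analytic
ground truth (sum-of-Gaussian lateral deviation, vertebrae perpendicular
to the centerline, seeded keypoint jitter) and the **reader-agreement
statistics** used to validate such tools clinically: the three-reader
≤3°-spread consensus rule, MAE/MdAE/RMSE, ICC(2,1), Bland–Altman limits
of agreement, and severity-stratified tables.

## Annotation formats

One pose-label text line per object, all values normalized by the image
dimensions; class 0 = vertebra (5 keypoint triplets: lt, rt, lb, rb,
spinous process), class 1 = pelvis (left PSIS, right PSIS):

```
0 0.5 0.5 0.1 0.05 0.45 0.48 2 0.55 0.48 2 0.45 0.52 2 0.55 0.52 2 0.5 0.5 2
1 0.5 0.9 0.2 0.05 0.40 0.90 2 0.60 0.90 2
```

The first line is a vertebra with bounding box center (0.5, 0.5), size
0.1×0.05, and corners at (0.45, 0.48) … (0.55, 0.52); on a 1000×1000
image that means lt = (450, 480) px and so on. The trailing `2` per
keypoint is a visibility flag (0 = absent, which excludes the vertebra
from angle computation). An equivalent JSON schema mirrors the in-memory
`SpineAnnotation` field for field (`cobbgeo.write_json_annotation`).

## Worked example

Simulate three noisy spines and measure one:

```sh
cobbgeo simulate --n 3 --noise 1.5 --seed 42 --out demo
cobbgeo measure --labels demo/case_0000.txt --image-size 927x2020 \
    --out demo/report.json --overlay demo/overlay.png
```

prints

```
case_0000: 3 curve(s), primary 47.16 deg (severe)
```

The ground-truth CSV written by `simulate` records that this case was
generated with a true primary Cobb of 46.02° between sequence indices
4 and 11 and a pelvic tilt of 3.16°. The report JSON shows what the
pipeline recovered from the jittered keypoints (σ = 1.5 px): a primary
curve T5–T12 of 47.16° flagged severe, flanking curves T1–T5 (17.50°)
and T12–L5 (18.12°), pelvic tilt 2.60°, levels anchored on the PSIS
line. The overlay PNG draws the keypoints, the end-vertebra endplates
with extended Cobb measurement lines, level labels, the PSIS line and a
text block of the same numbers, so every value is visually auditable.

Batch mode (`cobbgeo batch IN OUT --manifest sizes.csv`) writes one
report per file plus a summary CSV; `cobbgeo agree` compares a
prediction column against three-reader consensus and emits the
stratified agreement table.

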