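# cystquant

Quantification of cystic disease severity from histological sections of
polycystic kidney and liver.

In polycystic kidney disease (PKD) and polycystic liver disease (PLD) the
parenchyma is progressively replaced by fluid-filled cysts, and the standard
severity biomarker on H&E-stained sections is the **cystic index** (CI): the
percentage of the section area occupied by cyst lumens, complemented by the
cyst count and the distribution of cyst sizes.  Most labs estimate the CI by
global thresholding (e.g. in ImageJ), which systematically over-counts
because tubule, duct and vessel lumens are as bright as cysts.  `cystquant`
is a headless library + CLI for researchers phenotyping PKD/PLD mouse
models: it recognises cysts as objects, lets an expert correct the
recognition through auditable edit operations, and quantifies the result.

## Method

Automatic recognition runs six deterministic steps on the RGB image:

1. extract the green channel `I_G` (strongest lumen/tissue contrast in H&E);
2. compute its global mean grey level `μ_G`;
3. threshold: `I_B = I_G > μ_G` (lumens are bright);
4. refine with two-cluster k-means on the intensities, initialised from
   `I_B`, giving `I_k`;
5. morphological opening with a disk (3 px for liver; ≈`d_min` for kidney)
   to remove sub-cyst noise, giving `I_o`;
6. trace the outer border of every 8-connected component and keep the
   components with equivalent-circle diameter `2√(A/π)` inside the
   user-chosen range `[d_min, d_max]`.

Supervised post-processing mirrors an expert's review: delete, draw,
complete, split, merge, remove cysts inside a manually drawn region, and an
*add smaller cysts* tool that re-segments at fine scale and keeps only the
sub-`d_min` candidates that a texture classifier accepts.  The classifier is
an RBF-kernel SVM on 54 rotation-invariant uniform local-binary-pattern
features (scales `(R,P) = (1,8), (2,16), (3,24)`), grid-searched over
`C = 2^{-5..15}`, `γ = 2^{-13..3}` by 4-fold cross-validated Cohen kappa.

Every edit is logged, and the log doubles as the evaluation ground truth for
the automatic recognition: untouched automatic cysts are true positives,
edited ones false positives, added ones false negatives, giving

    Se = 100·TP/(TP+FN)        Sp = (1 − FP/NA)·100,    NA = TP+FP,  NS = TP+FN

plus the percentage of cysts deleted (PCD = 100·FP/NA) and added
(PCA = 100·FN/NS).

Because real cystic sections are not redistributable, the package ships a
seeded synthetic H&E generator (bright elliptical lumens, textured
tubule/duct distractors, exact ground truth) on which the whole pipeline is
tested end to end.

## Worked example

```sh
cystquant synth --seed 11 --out-dir demo
cystquant recognize --image demo/image.png --organ kidney \
    --dmin 18 --dmax 120 --out demo/auto.xml
cystquant quantify --annotations demo/auto.xml --csv demo/quant.csv
```

prints

```
25 cysts, 0 small cysts, 0 distractors; ground-truth CI=8.26% -> demo
25 cysts -> demo/auto.xml
auto: CI=8.23% n=25 severity=mild_cystic
```

The generator placed 25 elliptical cysts covering 8.26% of the section; the
automatic recognition finds all 25 and measures a cystic index of 8.23%
(within 0.03 points of the truth), which falls in the kidney *mild-cystic*
band (CI < 35%).  `demo/quant.csv` adds the calibration, the image size and
the cyst-size profile (all 25 cysts have equivalent diameters below
100 px):

```
image_id,um_per_px,width_px,height_px,cystic_index_pct,n_cysts,d_0_100,d_100_200,...
auto,1.0,1020,768,8.229421977124183,25,25,0,0,0,0,0
```

The same objects are available as a library:

```python
import cystquant as cq

cyst_set, trace = cq.recognize_cysts(image, "kidney", cq.DiameterRange(18, 120))
session = cq.SupervisionSession(cyst_set)
session.delete_cyst(3)                      # expert removes a false detection
counts = cq.counts_from_log(cyst_set, session.log)
print(cq.cystic_index(session.current), cq.specificity(counts))
```

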