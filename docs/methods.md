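# Methods

## The statistic

The pipeline's central quantity is the melanocyte density (MD): the
number of junctional melanocytes per 0.5 mm of basal epidermal length.
Junctional melanocytes are operationalised as separated nuclear
immunostain signals whose centroid lies within a band of ±10 µm around
the basal (lower) epidermal border. Densities map to three zones —
green < 25, yellow 25–29, red ≥ 30 per 0.5 mm — and a slide's call
(negative / borderline / positive) follows the maximum window density,
mirroring how a manual count selects the most densely affected area.
Zone boundaries are closed on the stated side: a density of exactly 25
is yellow, exactly 30 is red.

## Pipeline model and assumptions

**Epidermis.** A pixel segmenter produces a probability map in [0, 1];
probability ≥ 0.5 is epidermis (the tie sits on the foreground side so
binarisation is deterministic). Before contour extraction the mask is
cleaned — holes filled, objects under 50 µm² removed — because
tangentially cut sections produce pinholes. The basal side of each
fragment is the boundary adjacent to tissue (dermis) rather than to the
bright slide background, determined by voting over boundary-pixel
neighbourhoods against a brightness-thresholded tissue mask; when no
tissue mask is usable an explicit orientation hint (`surface=top` …)
resolves it. The border is traced as one extreme-pixel profile per scan
column along the fragment's dominant axis and smoothed with a σ = 2 px
Gaussian before arc length is measured: integer pixel quantisation
would otherwise inflate the length of oblique or wavy borders by
several percent, while smoothing keeps the polyline within ~1 px of the
true boundary and the measured length within 1 % of the analytic value.
Fragments whose border is shorter than 100 µm are discarded as speck
noise. Adnexal epithelium is the same positive class as epidermis; its
contours carry a flag but contribute to density windows.

**Nuclei.** The nuclear detector's probability map is binarised at 0.5;
the binary mask is split into instances by marker-controlled watershed
in a fixed order: Gaussian-smooth the probability map (σ = 1 µm), find
local maxima at least `min_seed_distance` apart as seeds, run the
watershed on the inverted Euclidean distance transform restricted to the
mask, and drop instances below 8 µm². The seed distance default is
3 µm ≈ one nuclear radius: touching pairs at centre spacing 1.4 r
(≈ 4.2 µm for r = 3 µm) must contribute two seeds, and a larger
suppression radius measurably caps the pair-split rate below the ≥ 95 %
the pipeline commits to. A mask region whose only maximum was
suppressed by a stronger neighbour is adopted whole as one instance, so
instance pixel sets always partition the mask minus dropped specks.

**Junctional filter.** Each instance is assigned its nearest
basal-contour vertex; depth is signed positive into the dermis and
negative into the epidermis (reports state the convention). The default
band is symmetric, |depth| ≤ 10 µm, capturing junctional nuclei bulging
to either side; one-sided variants are configurable. Excluded instances
are kept in the instance table for audit but never counted.

**Density windows.** Windows of 0.5 mm slide at a default stride of
0.1 mm, giving near-continuous traffic-light colouring; stride = window
yields disjoint bins whose counts sum exactly to the junctional count
(the count-conservation test). A window truncated by the contour end —
or a contour shorter than one window — is linearly rescaled to a
per-0.5 mm density and flagged `extrapolated`; truncated windows under
0.1 mm are additionally flagged `insufficient` and skipped when taking
the slide maximum, since a handful of nuclei on a 50 µm stub would
extrapolate to an unstable density. Window intervals are half-open
[start, end) except the final window, which closes on the right so the
last nucleus on a contour is never lost.

**Nests.** A nest is ≥ 3 confluent melanocytes. Confluence is geometric:
two instances are confluent when their pixel masks come within
`confluence_gap_um` (default 1 µm) of each other, i.e. each mask dilated
by half the gap intersects the other. Nests are connected components of
this graph with ≥ 3 members. A trained nest detector could stand behind
the same interface; the geometric definition is deterministic and
directly testable, and is monotone in the gap (enlarging it can only
merge components). Nest members also count toward MD windows.

**Statistics.** Confusion counts come from paired binary slide calls;
borderline (yellow) slides map to negative in binary comparisons unless
`borderline_positive` is set, because the binary statistics use the
single red cutoff. ROC curves put one point per grid cutoff
(15, 20, …, 45; predicted positive ⇔ max density ≥ cutoff), anchored at
(0, 0) and (1, 1) before trapezoidal integration — a seven-point grid
otherwise underestimates the area. Cutoff selection maximises
J = tpr − fpr with ties broken toward the larger (more specific)
cutoff; anchor points never win ties. The ±5-count rule (a deviation of
≥ 5 melanocytes between two counts is inconsistent) is reported as a
separate concordance column rather than being folded into the binary
confusion labels, which keeps the confusion statistics a pure function
of the cutoff. Composition percentages are rounded half-up to two
decimals.

## The synthetic generator

`sox10md.synth` emulates the statistical structure the pipeline assumes,
not histological appearance. A tile holds slide background, a
sinusoidally wavy epidermis band (thickness, waviness amplitude and
period configurable) and dermis below. Junctional melanocytes are a
Poisson process along the basal arc length (`junctional_density_per_mm`)
offset perpendicular within ±5 µm; nests are clusters whose members sit
1.5 radii apart along the border with sub-µm perpendicular zigzag, so
their rendered blobs always overlap; dermal distractors (default
5 / mm²) are placed ≥ 16 µm below the border so the 10 µm filter must
reject them. Nuclei render as dark brown ellipses with ±20 % radius
jitter on a pale counterstain, plus additive Gaussian noise. Every draw
flows from one seed; identical specs give byte-identical tiles.

`min_nucleus_spacing_um` (default 0) optionally thins background nuclei
to a hard-core process. Fixtures for *exact* nest-recovery comparisons
set it to 12 µm: under a pure Poisson process, chance triples of
touching background nuclei are genuinely confluent clusters, so exact
equality between generator nest labels and geometric nest calls is only
a well-posed oracle when background nuclei stay isolated (12 µm clears
two maximally jittered radii plus the confluence gap). Poisson-count
properties are asserted with spacing 0.

What the generator deliberately does **not** model: real stain texture
and intensity distributions, pigment and melanophages, scanner
artefacts, colliding lesions (lentigo solaris, seborrheic keratosis,
actinic keratosis), and oblique sectioning. Passing oracle tests
therefore demonstrates the correctness of the measurement chain
(geometry, counting, filtering, statistics) — not detector performance
on real slides, which requires training on annotated clinical material.

## Trainable backend

The detectors are classical pixel classifiers: multiscale image
features (per-channel intensity and gradient magnitude at σ = 1–8 px)
feed a logistic-regression model fitted by stochastic gradient descent,
one pass per epoch over class-balanced pixel samples from the training
tiles. The training contract matches a neural backend: image-level
80/20 train/validation split driven by the config seed, per-epoch loss
logging, optional flip/rotation/brightness augmentation, 0.5-threshold
binarisation, and single-file checkpoints embedding the config. The
brightness jitter is mild (gain ±3 %, bias ±4 grey levels) because the
synthetic counterstain separates compartments by only ~20 grey levels.
An untrained segmenter predicts 0.5 everywhere — all-foreground after
thresholding — and serves as the baseline that trained checkpoints must
beat on validation IoU (epidermis) or pixel F1 (nuclei).

## Numerical choices and problem sizes

* Default calibration in examples is 1 µm/px (epidermis scale) and
  0.5 µm/px for nuclear-detail simulations.
* Arc-length tolerances: extraction is validated to 1 % against
  analytic lengths; in practice it lands near 0.05 %.
* Floating-point window bounds use a 1 ns (1e-9 mm) epsilon for
  interval membership.
* Validation suites run on 128–512 px tiles, 8-tile training sets,
  5 epochs, 20-fixture oracle sweeps, 200 watershed pairs and
  200-per-class cohort simulations — sizes chosen so the whole suite
  re-runs in well under a minute of compute per module while keeping
  every Monte-Carlo margin wide (observed split rates ~100 % against a
  95 % bound, AUC ~0.99 against 0.95).

## Known limitations

* The evaluation of real whole-slide images is limited to tiles and
  crops with a known µm/px; gigapixel pyramid streaming is out of scope.
* Fixture realism is uncalibrated by design — no published quantitative
  description of stain intensity or nucleus-size distributions backs the
  renderer, so the toy detectors say nothing about clinical accuracy.
* The colour-marker/dirt artefact pre-filter (hue-interval rejection) is
  off by default and untrained on real contamination examples.
* Pagetoid spread and nuclear atypia are not assessed; MD and nest
  presence are the only malignancy criteria computed.
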