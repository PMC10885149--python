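# Methods

`plaquemap` quantifies how the lipid microenvironment changes at individual
amyloid-β (Aβ) plaques in MALDI mass spectrometry imaging (MSI) data: which
sphingolipid and phospholipid species are enriched inside a plaque relative
to its immediate surroundings, which are depleted, and how the species
co-localize at single-pixel resolution. This note describes the models,
parameters and numerical choices; it documents design decisions where the
design was genuinely open.

## Lipid mass chemistry

Shorthand names are parsed into molecular formulas by per-class construction
rules built from residue blocks:

* a dihydroxy sphingoid base `dS:B` is C<sub>S</sub>H<sub>2S+3−2B</sub>NO₂
  (d18:1 → C18H37NO2, sphingosine); a ceramide is base + fatty acid − H₂O,
  so Cer(d18:1/X:Y) = C<sub>18+X</sub>H<sub>35+2X−2Y</sub>NO₃;
* CerP = Cer + HPO₃; PE‑Cer = Cer + C₂H₆NO₃P; HexCer = Cer + C₆H₁₀O₅
  (anhydro hexose); ST (sulfatide) = HexCer + SO₃; GM3 = Cer + 2 Hex +
  NeuAc (C₁₁H₁₇NO₈); GM2 = GM3 + HexNAc (C₈H₁₃NO₅); GM1 = GM2 + Hex;
  the `(2OH)` suffix adds one oxygen (2-hydroxylated N-acyl);
* diacyl PA with total chain C:D is C<sub>C+3</sub>H<sub>2C+5−2D</sub>O₈P;
  lyso (one chain) species use O₇ and two more H; CPA = LPA − H₂O;
  PE = PA + C₂H₅N; PI = PA + hexose; a plasmalogen (P- prefix) removes one
  oxygen (vinyl ether in place of an ester).

Monoisotopic masses use six fixed element constants (C 12 exactly,
H 1.00782503, N 14.00307401, O 15.99491462, P 30.97376151, S 31.97207069).
The deprotonated adduct subtracts the *proton* mass 1.00727646 Da, not the
hydrogen atom mass: the electron's 5.5 × 10⁻⁴ Da is ~0.7 ppm at m/z 800 and
would consume a third of a ±2 ppm budget.

Annotation assigns an observed m/z to a library species when
|observed − theoretical| / theoretical ≤ 2 ppm (configurable); among
multiple candidates the smallest absolute ppm error wins, with a
lexicographic name tie-break for determinism.

The bundled reference panel (`plaquemap.reference`) lists the 38 verified
plaque-associated species with their literature masses and observed m/z
values. Two rows are internally inconsistent in the literature source
(a lyso-PI theoretical mass typo; a PA(16:0/18:1) row whose printed
theoretical mass belongs to a 34:2 species) — they are flagged rather than
silently corrected, and the inconsistent PA row is excluded from the
default library. Single-chain PA/PE/PI names normalise to lyso classes and
the published "LPA(18:0)" row is canonically CPA(18:0) (cyclic
phosphatidic acid), consistent with its printed mass.

## Preprocessing

Pixel spectra are TIC-normalized: each spectrum is scaled so its total ion
current (trapezoidal integral for profile data, stick sum for centroid)
equals the dataset mean raw TIC. Using the mean — rather than 1 — as the
target preserves the native intensity scale for ion images. Consequently
the normalized feature matrix is *equivariant* under a global intensity
rescaling (c·raw → c·features); every downstream ratio statistic is
invariant. Zero-TIC pixels are dropped with a logged warning.

Peaks are detected on the whole-dataset mean spectrum so that a single
global peak-bin set defines one feature space for pixel-level clustering
(a per-ROI binning mode is available). The noise level is
1.4826 · MAD(Δy)/√2 — the robust σ of the first difference of the
spectrum. A local maximum is accepted if its prominence **and** its height
above the baseline (median intensity) both exceed `snr_threshold` × noise
(default 5) and its half-height width spans ≥ `min_fwhm_points` samples
(default 3). Prominence alone is not enough: under pure noise the global
maximum has prominence close to the max-to-min range (~6σ for a few
hundred samples), whereas nothing stands 5σ above the baseline; with the
height criterion a pure-noise spectrum yields no peaks in ≥95% of runs.
FWHM is obtained by linear interpolation at half prominence. Bin borders
sit at the nearest flanking local minima, clipped to ±3 FWHM around the
center; overlapping borders are truncated at the midpoint between adjacent
centers so bins tile the axis and integrals are additive.

Per-pixel features are trapezoidal areas under the curve within each bin,
with interval endpoints included by linear interpolation (this makes
adjacent bins exactly additive); centroid data sum stick intensities.

## Segmentation and ROIs

Bisecting k-means starts from one cluster and repeatedly splits the leaf
with the largest within-cluster sum of squares using 2-means (scikit-learn
K-means, best of 10 seeded restarts) until k leaves exist (default k = 8,
a deliberately small number that keeps a distinct plaque cluster without
fragmenting the background). Features are z-scored per bin before
clustering so high-abundance background lipids do not dominate the
Euclidean distance (`none` is available). Rows are clustered in a
canonical order derived from permutation-symmetric row statistics, making
the result independent of pixel ordering and of bin-column order; the full
bisection tree (per-split SSE before/after) is recorded.

Plaque-like clusters are selected either by a **marker** rule (mean
z-scored intensity in designated marker bins — GM1 by default — above 1.0)
or a **punctate** rule (median 8-connected component area within plaque
bounds). Plaque ROIs are the 8-connected components of the selected
clusters filtered to [min_area, max_area] (default [5, 200] px), with ids
ordered by centroid. Every plaque gets a matched control: the annulus of
pixels 2–6 px (20–60 μm at 10 μm pixels) away from it, excluding all
plaque pixels and off-tissue pixels, with overlap between neighbouring
annuli resolved to the nearer plaque; a plaque whose annulus is empty
(tissue edge) falls back to a random tissue patch of matched area, logged.

## Enrichment, group statistics, SPSC

Per (ROI, bin): enrichment ratio = mean normalized AUC over plaque pixels
÷ mean over that plaque's control pixels (a grand-mean denominator is
available as a config alternative). Group-level inference across subjects
takes each subject's mean log₂ ratio per species and applies a two-sided
one-sample test against 0 — exact Wilcoxon signed-rank by default (chosen
because typical cohorts have ~5 subjects and normality is unverifiable),
Student t optionally. Raw p-values are reported; Benjamini–Hochberg
adjusted values are reported alongside but not used for gating. With five
subjects the smallest attainable exact two-sided p is 2/2⁵ = 0.0625.

Single-pixel signal correlation (SPSC) is the Pearson correlation between
two species' AUC vectors over the union of plaque-ROI pixels (default) or
between per-ROI means. Constant signals get correlation 0 and a flag.
SPSC is invariant to per-species affine transforms with positive slope.

## The synthetic-data generator

No raw tissue data accompany the study conditions, so the generator is the
test bed: it emulates negative-ion-mode MSI of brain tissue at 10 μm pixel
size with focal circular plaque hotspots. Defaults define the study
conditions and are not tuned per experiment:

| parameter | default | meaning |
|---|---|---|
| grid, plaques | 128×128 px, 20 discs of radius 3–6 px | tissue field with ~8% plaque area |
| panel | 38 species + 10 decoys | reference panel; folds by class |
| folds | GM/CerP/PE-Cer 3; HexCer, PI/PE/PA 2; ST 0.5; decoys 1 | planted log₂ folds {1.585, 1, −1, 0} |
| resolution | 120 000 | FWHM = m/z ÷ R; Gaussian profiles |
| axis | FWHM/6 at the panel median m/z, ±5 FWHM windows | sparse windowed profile axis |
| gain | log-normal(0, 0.3²) per pixel | multiplicative ionization/gain field |
| noise | Gamma areas, shape = SNR², SNR 10 | MALDI pixel-to-pixel variability |
| severity | α per plaque, log-normal(0, 0.3²), folds act as fold^α | plaque-to-plaque heterogeneity |
| background | 120 fold-1 peaks, bases 1000–5000 | TIC-dominating unchanged lipids/matrix |

Two of these deserve justification. **Background peaks:** in real tissue
spectra the panel species are a small fraction of the total ion current,
which is why TIC normalization is an (almost) unbiased gain correction
there. A simulation containing only the panel would violate that — plaque
enrichment would inflate the pixel TIC and normalization would suppress
plaque pixels by ~1 log₂ unit. The background population restores the real
situation; the residual TIC coupling is below 0.05 log₂ units at defaults.
**Per-plaque severity:** plaques in tissue differ in how strongly they
remodel their environment (clearly visible in per-plaque bar plots).
Applying planted folds as fold^α with a log-normal α reproduces this and
is what generates the block structure in SPSC heatmaps after TIC
normalization removes the shared gain: co-enriched species rise and fall
together across plaques, depleted species move oppositely. Because the
median of α is 1, median-based fold recovery stays unbiased, and fold-1
(null) species are exactly unaffected by α.

Plaques are hard discs placed without overlap by rejection sampling; an
optional Gaussian rim blur (off by default) emulates diffuse halos.
Determinism: all randomness derives from one seed through spawned
generators; equal seeds give bitwise-identical datasets. Intensities are
stored float32 (the storage convention of the imzML side); normalization
and statistics run in float64.

What the generator does **not** emulate: isotope envelopes, matrix cluster
peaks, mass-calibration drift, chemical baseline, spatially structured
anatomy (white/grey matter), or partial-volume plaque boundaries beyond
the optional rim blur. Passing recovery tests therefore demonstrates the
pipeline's correctness under the stated noise model, not performance on
real tissue.

## Scoring and test problem sizes

`score_recovery` reports Dice/Jaccard of the recovered plaque mask against
truth, recovered plaque count, per-species planted-fold bias (median log₂
ratio across ROIs minus planted log₂ fold, with bins matched to panel
m/z at 2 ppm), annotation precision/recall, and SPSC block scores (mean
within-enriched-block r; mean enriched-vs-depleted r).

The test suite exercises recovery at the default 128×128 / 20-plaque
conditions over 10 seeds. The type-I-error calibration of the group test
uses 200 simulations of 5 subjects each on 32×32 centroid-mode grids with
an all-null panel and ground-truth ROIs — the quantity under test is the
statistic's calibration, for which segmentation (already covered by the
Dice recovery tests) is not re-run, and a fully null panel is the correct H₀
(a panel with enriched species would shift pixel TICs and make "null"
species weakly non-null through normalization — a real effect, not a test
artifact).

## Known limitations

* Only the [M−H]⁻ adduct is implemented; positive-ion modes, isotopologue
  scoring and MS/MS-based isomer resolution are out of scope.
* The peak detector assumes profile spectra with a locally flat baseline;
  there is no baseline subtraction, recalibration or deisotoping.
* k for the segmentation is a config choice, not estimated from data.
* Group tests treat subjects as exchangeable; no covariates (age, mutation)
  are modelled.
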