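# Methods

This note records the models, numerical conventions and design choices
behind `larvamorph`, and what the synthetic validation does and does not
demonstrate about real data.

## Elliptic Fourier analysis

A closed outline traversed at constant speed is two periodic signals
x(t), y(t) with period T = perimeter. Truncating their Fourier series at
N harmonics gives 4N coefficients (aₙ, bₙ, cₙ, dₙ) plus the mean point
(A₀, C₀). For polygonal outlines the coefficient integrals are evaluated
in closed form segment by segment (integration by parts of the
piecewise-linear parametrisation; the boundary terms telescope around
the loop). This is exact for the polygon — there is no FFT and no
sampling-grid error — and is validated in the tests against a
200 000-sample trapezoid quadrature oracle to 1e-6 and against the
analytic circle solution.

**Normalization** follows the first-harmonic-ellipse method used by the
classic SHAPE software family: the starting point is rotated to the
first ellipse's semi-major axis (phase θ from the standard half-angle
formula), the shape is rotated so that axis lies along +x (angle ψ), and
all coefficients are divided by the semi-major axis length E. This
leaves a₁ = 1, b₁ = c₁ = 0 exactly, and the returned
`NormalizationParams` invert the transform to machine precision.

Two conventions had to be decided where the classical method is silent:

* **Starting-point half-period ambiguity.** θ is only defined modulo π;
  the two candidates differ by a sign flip of all even harmonics. A
  coefficient-sign rule is exactly start-invariant but unstable under
  digitisation noise whenever the deciding coefficient is small — which
  is the generic situation for bilaterally symmetric animals, where the
  candidate flip is numerically almost a mirror image. `larvamorph`
  instead orients the outline's asymmetric mass: among the reconstructed
  coordinates, the axis with the larger third central moment must have
  positive skew (the pointier end of the animal faces the positive
  half-axis). This depends on the gross shape, not on any single
  coefficient, and is both exactly invariant to the digitisation
  starting point (including half-perimeter shifts) and stable at the
  noise levels used throughout (multiplicative radial noise, σ = 0.02).
  A largest-differing-coefficient rule is the fallback for skew-free
  shapes such as regular polygons.
* **Reflection.** Ingestion orients every contour counter-clockwise, so
  chirality does not appear in the sign of d₁ (always positive here) but
  in the signs of the b/c coefficients. The optional reflection
  standardization — off by default, so dorsal and ventral views of the
  same head remain distinct shapes unless the user asks otherwise —
  forces the largest-magnitude b/c coefficient over odd harmonics ≥ 3 to
  be positive. Odd harmonics are unaffected by the start-candidate flip,
  which keeps the chirality and orientation conventions independent and
  the canonical representative unique.

**Round trips.** decompose → reconstruct → decompose is exact only for
outlines traversed at near-uniform speed: re-decomposition parametrises
the reconstructed curve by its own arc length, which differs from the
Fourier parameter wherever the traversal speed varies. The tests pin
this down quantitatively (≈3e-7 agreement on a near-circular contour,
a few per cent bias on a strongly irregular star). In the pipeline this
bias is irrelevant — outlines are decomposed once — but users comparing
coefficients across reparametrised curves should know it exists.

**Defaults.** 20 harmonics (configurable 1–64): enough to capture labrum
prongs and stylet lobes, small enough that per-vertex noise does not
dominate the tail coefficients. 128 resampled points per outline.

## Morphospace

PCA is computed on the covariance matrix of the normalized coefficient
rows (constant columns a₁, b₁, c₁ dropped; d₁ kept, since it carries the
first-ellipse aspect and chirality). Covariance, not correlation: after
normalization all coefficients live on one scale, and variance-rescaling
would inflate noise-dominated high harmonics. The decomposition uses the
symmetric eigensolver with eigenvalues clipped at zero and a fixed sign
convention (largest-magnitude loading positive), so results are
bit-stable across runs; scikit-learn's PCA serves as an independent
cross-check in the tests, never as the implementation.

**Effective PCs.** The number of components treated as carrying real
signal defaults to the proportion rule: every PC explaining ≥ 2% of
total variance. Applied to the published per-analysis variance
proportions this reproduces the published counts (six for head+stylets
at 52.5/24.8/7.5/3.9/3.0/2.5%, four for stylets); the Kaiser-style
greater-than-mean rule is available as an alternative. Each of the five
anatomical structure classes is meant to be fitted as its own
morphospace; nothing in the code couples them.

**Shape meaning of axes.** `reconstruct_along_pc` rebuilds the outline
at mean ± k·SD along one PC. Note that size normalization converts any
localized length change into a global radial rescale plus a localized
residual; the tests therefore check *concentration* of the radial-ratio
deviation rather than strict locality.

## Occupation statistics

Occupation is measured in the PC1×PC2 plane only — matching how such
analyses are drawn and interpreted — as the convex-hull area of a
group's scores (SciPy Qhull; area 0 and a `degenerate` flag for groups
with fewer than three or collinear points). Overlaps are convex-polygon
intersections via shapely. The subset ratio area(subset)/area(full) ∈
[0, 1] quantifies how much newly added specimens expanded the previously
occupied area.

**Accumulation and saturation.** For each subset size k, hull areas of
uniform without-replacement subsets are averaged over `n_resamples`
draws (percentile 2.5/97.5 confidence bands; the k = n point is assigned
the full-sample area exactly). The saturation statistic is the
least-squares slope of the mean curve over the last 20% of k values,
divided by the full-sample area: relative area gained per additional
specimen. A reporting label "saturated" is attached below 0.005; the
threshold is purely presentational and configurable. The sample mean at
adjacent k values is noisy at finite resample counts, so monotonicity
holds only up to that noise — the tests allow a 1% tolerance.

All resampling uses a single caller-seeded `numpy` Generator; there is
no global RNG state anywhere in the package.

## Specimen inventory

The packaged TSV carries all 98 specimens: 52 previously studied (their
per-specimen details were published elsewhere, so only epoch and
provenance are stored — no unpublished data is invented) and 46 newly
described fossils with repository numbers, body lengths and labrum
morphotypes. Conventions: lengths printed as ranges are stored as the
midpoint with `length_is_estimate = true`; where a measured length of an
incomplete specimen differs from the estimated complete length, the
estimate is stored and the measurement noted; verbal labrum descriptions
map to the six morphotype labels, with genuinely ambiguous descriptions
("triangular to pentagonal") left `unknown`. Nine of the 46 new records
are flagged as excluded from the final analysis; for the two Baltic-amber
specimens known only from photographs the published account does not
state their analysis status, and the fixture records the assumption made
(the small, partly concealed published photograph excluded; the
high-quality photographs included) in its notes column. A SHA-256
checksum guards the fixture against silent corruption.

## Synthetic cohorts

The generator builds star-convex outlines in polar form around the
centroid: an elliptical head template (aspect = width/length), a labrum
protrusion built from raised-cosine bumps — one apex for triangular /
pentagonal / broad, three prongs for trident, five for pentadent, and a
split middle prong (four local maxima) for the bifid trident — and two
stylet lobes flanking the labrum, skewed by a curvature parameter.
Star-convexity rules out self-intersection by construction; it is a
deliberate simplification, and real larval outlines (overlapping
stylets, concave head rears) are outside what this generator can emulate.
Template defaults make the outlines strongly elongated, as the real
head+stylet outlines are; this also keeps the first-harmonic ellipse
clearly anisotropic, which the stability of EFA orientation
normalization depends on. Per-vertex multiplicative radial noise
(default σ = 0.01–0.02) stands in for digitisation error; it does not
model correlated tracing error or view-angle distortion.

Cohorts draw each specimen from its own counter-derived RNG stream
(`default_rng([seed, counter])`), so output is independent of generation
order. Each epoch has a specimen count, a morphotype mixture, and a
dispersion multiplier scaling the log-normal parameter jitter
(base σ = 0.06). The default cohort mirrors the real study's included
specimens — 64 Cretaceous, 13 Eocene, 12 extant — with trident-family
morphotypes confined to the Cretaceous mixture and dispersion falling
3:2:1, so the documented decline is a *recoverable simulation outcome*:
the end-to-end pipeline recovers the hull-area ordering in ≥95 of 100
seeds, and an equal-dispersion, equal-n null shows no epoch winning more
than 70 of 100 seeds. Passing these checks demonstrates that the
pipeline faithfully transmits dispersion differences into occupation
differences; it does not validate the biological parameter values
themselves, which no deposited coordinates exist to check.

## Problem sizes

The test suite and the acceptance script use: 96–128 outline points and
20 harmonics per specimen; 60–90 specimens per simulated cohort; 100
seeds for the ordering and null studies; accumulation curves over the
full k-grid with 30–200 resamples; and a 10⁶-dart Monte-Carlo oracle for
hull areas. These sizes make the whole suite run in a couple of minutes
while leaving every statistical margin (≥95/100, ≤70/100, slope
thresholds) comfortably clear of its criterion.
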