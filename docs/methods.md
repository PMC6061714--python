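# Methods

## Scope and data model

`rtshift` analyses a runs × compounds matrix of retention times collected
under a full factorial design in mobile-phase pH and column temperature.
The default layout is five coded levels per factor (−2…+2; pH center 3.75,
step 0.25; temperature center 40 °C, step 2.5 °C), giving 25 factorial
runs plus 5 center-point replicates. The design matrix expands each run
into the terms `[1, p, t, p², t², p·t]` on the coded scale; quadratic
columns are raw squares, not orthogonal polynomials, because the
pseudo-inverse solver tolerates the resulting mild collinearity and the
coefficients remain directly interpretable in minutes per coded unit.
Run order is deterministic (first declared factor outermost, replicates
appended last); replicates are flagged rows, never deduplicated, because
they carry the pure-error information.

MLR fitting uses an SVD pseudo-inverse with singular values below
`max(dim) · eps · s_max` truncated. A rank-deficient design raises an
error naming the collinear columns rather than silently returning a
minimum-norm solution.

## Uncertainty

Confidence intervals are pure-error intervals from the center replicates,
not regression-residual intervals: with `n` replicates the retention-time
halfwidth is `t(1−α/2, n−1) · sd / √n` per compound. Because all
replicate rows share one design row, the replicate standard deviation is
statistically independent of the coefficient estimates, so propagating it
through the design leverage, `t · sd_c · √[(DᵀD)⁻¹]_jj`, yields an exact
t-interval per coefficient under i.i.d. run-to-run noise. Both forms are
exposed (`replicate_ci`, `coefficient_ci`); Monte-Carlo coverage of the
propagated intervals is checked in the acceptance suite (200 repeats;
observed ≈ 95% at the 95% level).

## The PCA ↔ design bridge

`X` is column-mean-centered before PCA; an uncentered decomposition would
spend PC1 on mean elution times and obscure the design structure. The
intercept column of `D` is therefore dropped from the conversion
regression `Ĉ = pinv(T) · D_centered` and the intercept is reconstructed
from the centering offsets (`b₀ = x̄ − d̄ᵀ B̂`), making the output
term-for-term comparable with MLR. The sign of each component is fixed so
its largest-magnitude loading entry is positive, which makes scores,
loadings and `Ĉ` reproducible across SVD implementations. The recovery
`B̂ = pinv(Ĉ) Pᵀ` requires at least as many effective components as
non-intercept terms; a singular `ĈᵀĈ` raises. The whole chain is
invariant to any orthogonal rotation applied jointly to scores and
loadings (the rotation cancels between `Ĉ` and `Pᵀ`), which the tests
verify with random rotations.

## ASCA

ASCA partitions the grand-centered matrix into per-factor effect matrices
(each row replaced by its factor-level mean) plus a residual, then
decomposes each part by PCA. With center replicates present the overall
design is unbalanced (coded level 0 is over-represented), so grand and
level means are computed over the balanced factorial core only and
broadcast to all rows; replicate rows receive the level-0 effect, and the
residual is defined as the exact remainder. This "type-I on the factorial
core" choice keeps two properties exact that a naive all-rows mean would
break: the partition always reconstructs the grand-centered input
elementwise, and a factor with no simulated effect yields an identically
zero effect matrix on noiseless data. A genuinely unbalanced core raises
unless `force=True`.

Because five levels are partitioned nonparametrically by level means, a
factor's effect matrix captures its linear *and* quadratic structure; the
pairwise interaction lives in the residual of a main-effects partition.
Coefficient recovery therefore concatenates the per-effect PCA scores
with the residual's leading scores (rank-trimmed at 10⁻⁹ of the largest
singular value) before applying the conversion-factor bridge; on clean
designed data this reproduces MLR exactly, including the interaction
term.

## PCR, PLS and design-level prediction

Per-compound calibration regresses the target's (centered) retention
vector on the leading principal components of the calibrant block — all
other compounds minus any compound whose retention time ever comes within
`rt_window` (default 0.2 min, the width of a typical peak cluster) of the
target in any run. The per-run exclusion criterion is symmetric and
deterministic. Six components are the default model size, configurable.
Cross-validation is leave-one-run-out (30 runs make it cheap, and no fold
structure is implied by the design); the PCA is refit inside each fold.
The PLS1 variant delegates to scikit-learn's NIPALS implementation and
reports the same metric surface. Relative residual variance normalizes
the residual sum of squares by the *centered* total sum of squares
(`uncentered` exposed as an option), so 1.0 means "no better than the
compound's mean".

Design-level prediction reverses direction: each non-intercept design
column is regressed on the first `k` retention-PCA scores for `k` in a
range (default up to 10), reporting RMSEC, leave-one-run-out RMSECV and
auto-prediction explained variance. Score orthogonality makes the RMSEC
path exactly non-increasing in `k`. Terms whose true coefficients are at
or below the noise cannot be predicted: their RMSECV stays at the level
of the term column's own standard deviation for every `k`, while strongly
encoded terms calibrate to a small fraction of theirs.

## Synthetic data generator

The generator realizes `X = D B + S L + E` with known ground truth:

* **Compounds**: 98 by default, base retention times uniform on 2–38 min
  (a 40-min gradient window), columns sorted by elution time.
* **Coefficients** (minutes per coded unit): linear temperature mostly
  negative, magnitude ≈ |N(0.18, 0.06²)| + 0.02, with exactly 10 of 98
  compounds positive; linear pH N(0, 0.15²) (either sign); quadratic pH
  N(0, 0.05²); quadratic temperature N(0, 0.005²) and interaction
  |N(0, 0.004²)| — both deliberately below the noise, i.e. practically
  insignificant. Any per-term scale can be overridden.
* **Latent uncontrolled factors**: rank-one additive terms `s lᵀ` with
  per-run scores N(0, 0.03² min²) and N(0,1) loadings. This is an explicit
  mechanism for run-to-run variation the design does not explain; one
  factor is on by default. Its scale places the latent singular value
  well above the Marchenko–Pastur noise floor of a 30 × 98 matrix, so it
  occupies one additional principal component (the sixth, after the five
  design directions) without dominating the designed effects.
* **Noise**: i.i.d. Gaussian, sd 0.03 min per cell — a realistic
  run-to-run repeatability for a modern LC system and the simplest model
  consistent with replicate-based pure-error intervals.
* **Peak lists**: each compound (charge 1 or 2) contributes its
  monoisotopic peak plus isotopologues at `k · 1.00335/z` Th (intensity
  fractions 0.55, 0.22) and, with probability 0.5 per adduct, sodium /
  ammonium adducts at `Δ/z` (+21.98194, +17.02655 Th for z = 1) at 30% of
  the base intensity, all co-eluting with small m/z (sd 0.0005 Th) and RT
  (sd 0.005 min) jitter. Compound m/z values are drawn with rejection so
  that no two compounds' isotope/adduct ladders approach within 0.012 Th,
  making classification accuracy a property of the rules rather than of a
  lucky draw.

What the generator does *not* emulate: chromatographic peak shapes and
widths, intensity-dependent m/z accuracy, missing peaks, retention-time
drift within a run sequence, heteroscedastic or correlated noise, and
real peptide isotope-pattern intensities (averagine). Tests passing on
this generator therefore demonstrate the correctness of the algebra and
the qualitative phenomenology (latent-factor advantage of PCR,
unpredictability of sub-noise terms), not instrument-level robustness.

## Peak classification

Classification is a single greedy pass in decreasing intensity order: the
most intense unflagged peak claims co-eluting isotopologue partners
(heavier, strictly less intense, spacing `k · 1.00335/z`, `k ≤ 2`) and
adduct partners (standard cation deltas divided by the charge). The
charge comes from the peak record when present; otherwise candidate
charges 1–3 are tried. Greedy intensity ordering resolves chained
relations deterministically, flags are mutually exclusive, and
classify→filter is idempotent. Default tolerances are 0.005 Th and
0.1 min. The real study's in-house filtering rules are not published;
these are the standard mass relations, all configurable.

## Numerical and design choices

* Pseudo-inverses via SVD everywhere; normal equations are never formed.
* Coded-scale fitting is the default (standard DoE practice); real-unit
  design columns are available via `DesignMatrix.real_values()`.
* Effective rank decisions (pipeline component clamping, ASCA score
  trimming) use a relative singular-value floor of 10⁻⁸–10⁻⁹, separating
  genuine variance from SVD dust on noiseless inputs.
* Monte-Carlo sizes in the shipped checks — 200 repeats for coefficient
  recovery, 50 for the PCR-vs-MLR comparison, 1000 replicates for the
  noise-calibration test — were chosen to make the sampling error of each
  checked statistic at least an order of magnitude smaller than its
  tolerance band.
* Degenerate inputs fail loudly: zero-variance compounds in residual
  normalization, zero-variance score columns in the conversion fit,
  rank-deficient designs, unbalanced ASCA cores, component counts beyond
  the rank.

## Known limitations

* ASCA significance (permutation testing) is out of scope; the package
  reports effect sums of squares, not p-values.
* The overlap-exclusion window and the latent-factor model are
  assumptions standing in for undocumented aspects of real studies; both
  are configurable and documented rather than hidden.
* With replicated center points the design is unbalanced for ASCA;
  alternatives to the factorial-core convention (weighted means, mixed
  models) are not implemented.
* Peak filtering enumerates candidate charges but does no isotope-pattern
  fitting or charge deconvolution; heavily overlapping real spectra would
  need a dedicated deisotoping tool upstream.
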