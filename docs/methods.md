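# Methods

## The stochastic assembly model

An AAV capsid is a T=1 icosahedral shell of exactly 60 viral-protein (VP)
subunits drawn from up to three species — VP1, VP2 and VP3 — that share the
VP3 core sequence and differ only in their N-terminal extensions.  `aavsim`
models assembly as 60 independent draws from the bulk pool of expressed
VPs: the probability of a capsid with integer stoichiometry
(n1, n2, n3), n1+n2+n3 = 60, is the multinomial

    P(n1, n2, n3) = 60! / (n1! n2! n3!) · p1^n1 · p2^n2 · p3^n3,

where (p1, p2, p3) are the bulk VP fractions.  For three species there are
C(62, 2) = 1,891 distinct stoichiometries.  Probabilities are computed in
log space via log-gamma and exponentiated at the end (60! overflows naive
arithmetic); a species with p = 0 and count > 0 yields exactly 0.  Marginal
copy-number distributions are binomial, Binom(60, p_s), and the fraction of
capsids lacking VP1 or VP2 follows by inclusion–exclusion:
(1−p1)^60 + (1−p2)^60 − (1−p1−p2)^60.  The number of distinguishable
subunit arrangements of one stoichiometry, 60!/(n1! n2! n3!), is computed
in exact integer arithmetic; icosahedral symmetry can reduce the count of
truly distinct configurations by at most a factor of 60.

Assembly kinetics, chaperone (AAP) preferences, and genome-containing
capsids are outside the model; the bulk fractions subsume any such effects.

## Spectrum simulation

Each capsid mass M (Da; the stoichiometry's mass plus a single per-capsid
+2.8 kDa solvent-adduct term) acquires a charge-state envelope:

* mean charge from the electrospray charging law z = 1.638·(M/kDa)^0.5497 + b,
  with b an instrument/spray offset;
* 37 consecutive integer charges centred on the rounded mean charge
  (truncated below z = 1), Gaussian-weighted about the real-valued mean
  with a constant width of 6 charges, scaled so each envelope's total
  intensity equals the stoichiometry's probability.

The 1,891-mass, 3-species default therefore yields 1,891 × 37 = 69,967 ion
species.  Each ion (M, z) sits at m/z = (M + z·1.00728)/z and is rendered
as a Gaussian with σ = FWHM/2.355, where the FWHM follows the Orbitrap
resolution law

    R(m/z) = R_ref · (t/32 ms) · sqrt(mz_ref / mz),   FWHM = mz / R,

with R_ref = 6,250 at mz_ref = 400 Th for a 32 ms transient, scaled
linearly with transient time t.  These reference values are nominal
instrument settings and are exposed in `InstrumentModel`.  Peaks are
accumulated on a uniform m/z grid within ±3 FWHM of each centroid (the
kernel skips bins only where the contribution is numerically negligible),
in a canonical ion order so the result is bit-reproducible regardless of
input order.  A rolling-minimum baseline (window 250 Th, followed by a
same-width smoothing pass and zero-clipping) mimics the suppression of
unresolved signal by transient averaging.  Final spectra are
max-normalized; only peak positions are used downstream, so absolute scale
is arbitrary.

A structural property worth noting: because charges are integers, the peak
positions of a given mass set form a fixed comb {(M + z·m_p)/z}.  The
offset b does not move peaks — it decides which part of the comb carries
intensity.  Sub-charge accuracy in b is therefore ample for alignment.

## Scoring

Peak centroids are local maxima above 2% of the base peak that also have
at least that much topographic prominence (suppressing ripple left by
baseline correction on composite peaks), with 3-point parabolic apex
refinement.  Experimental and simulated centroid lists are matched
one-to-one, greedily in order of increasing deviation, within half the
average spacing of adjacent experimental centroids.  The average absolute
deviation over matched pairs, plus 1 Th per unmatched peak on either side,
is converted to a score with a Gaussian (µ = 0, σ = 10 Th) normalized to 1
at zero deviation.  Peak heights are deliberately not scored: they are
distorted by transient averaging, baseline correction and the offset
estimate.

The phrase "adding 1 Th to the average deviation" for unmatched peaks
admits a second reading — unmatched peaks entering the average as 1 Th
pseudo-deviations — which is implemented behind
`ScoringConfig(penalty_mode="as_deviation")`.  It is not the default: a
simulation that matches nothing then averages exactly 1 Th and can
outscore a genuinely good match with realistic few-Th deviations.

## Screening

The screen walks integer VP1%/VP2% grid points (VP3% = 100 − VP1% − VP2%;
5,151 points at step 1, 231 at step 5), and per point: builds the
ensemble, drops stoichiometries below 1e−5 of the modal probability (a
pure speed optimization; the retained probability mass exceeds 99.99%),
calibrates b, simulates, baseline-corrects, centroids and scores against
the experimental centroid list, which is extracted once per screen so the
matching tolerance is constant and scores are comparable.  Ties at the
argmax break to the lowest VP1%, then lowest VP2%.

Offset calibration starts from the closed formula
b = M̄/⟨m/z⟩ − 1.638·(M̄/kDa)^0.5497 (M̄ the probability-weighted mean
ensemble mass, ⟨m/z⟩ the intensity-weighted experimental mean) and then
refines b by a secant-accelerated iteration until the baseline-corrected
simulation populates the same mean m/z as the experiment (tolerance 1 Th).
The refinement is necessary because baseline correction removes the
unresolved composite asymmetrically, shifting the intensity-weighted mean
by hundreds of Th relative to what the closed formula assumes; without it
every simulation sits ~2 charges off.  An optional coarse-to-fine mode
(step-5 grid, then step-1 refinement around the optimum) cuts a screen
from 5,151 to roughly 300 simulations.

## Synthetic data

Fixtures bundle VP monomer masses with reference bulk ratios.  The
AAV1-like mass set is constructed from three constraints: a VP3-only
60-mer plus adduct weighs 3,571 kDa (VP3 = 59,470 Da), the VP2 extension
is 6.5 kDa, and the VP1 extension is exactly three VP2 extensions
(19.5 kDa).  The last makes two interferences exact: three VP3→VP2
substitutions nearly coincide with the next charge state, and one VP3→VP1
substitution coincides with three VP3→VP2 substitutions.  The AAV5/8/9
fixtures instead carry approximate real-serotype masses (e.g. AAV9:
81,290 / 66,210 / 59,730 Da) — for real serotypes the VP1 extension is
~2 kDa heavier than three VP2 extensions, and that residual is what makes
the (+1 VP1, −3 VP2) direction of ratio space identifiable at all.  With
the exactly degenerate mass set, that substitution preserves every capsid
mass identically, and no position-based score can distinguish bulk ratios
along the ridge; fixtures are AAV-like, not sequence-exact.

Pseudo-experimental spectra distort a clean simulation with:

* per-peak position jitter — each peak of the baseline-corrected clean
  spectrum receives an independent Gaussian m/z shift (default σ = 2 Th,
  the scale of the centroid residuals seen in practice), applied as a
  displacement field interpolated between apexes so peaks move without
  tearing;
* smooth multiplicative intensity noise (default 5%, correlation 60 Th);
* a broad Gaussian unresolved hump (default 20% of the base peak,
  σ = 1,200 Th) centred on the envelope.

Everything is driven by one seeded generator; a given seed reproduces the
spectrum bit for bit, and zero noise returns the clean simulation exactly.
What the generator does *not* emulate: detector shot noise at the transient
level, adduct-distribution tails beyond the single +2.8 kDa shift, isotope
fine structure, m/z-calibration drift, and mixed empty/full capsid
populations.  Passing the recovery tests therefore shows the inference is
sound when the forward model is correct and peak positions are noisy — not
that every real-world distortion is survivable.

## Recovery experiment conditions

The parameter-recovery tests screen noisy synthetic spectra generated at
the bundled reference ratios and ask the best-scoring point to land within
±2 percentage points on both axes.  The generating fixtures are the ones
with realistic serotype masses: on the exactly degenerate AAV1-like mass
set the (+1 VP1, −3 VP2) direction of ratio space is unidentifiable by
construction (only peak intensities change, and intensities are not
scored), so that fixture demonstrates the interference properties rather
than serving as a recovery benchmark.  The screens run at the 128 ms
transient on a 20,000–29,000 Th window with 0.5 Th bins, using the
coarse-to-fine screen:
at 32 ms the ~2 kDa serotype residual between one VP1 and three VP2
extensions stays blended inside the ~25 Th peaks, and under the default
noise the ridge direction is not recoverable — the same reason long
transients were needed to resolve AAV9 fine structure in practice.  Ten
seeds per ratio, with 9/10 required, keeps the check sensitive without
being brittle to a single unlucky noise draw.

## Numerical choices and degenerate inputs

* Multinomial log-probabilities agree with an exact rational-arithmetic
  oracle to better than 1e−12 relative error.
* Enumeration order is lexicographic in (n1, n2); all tie-breaks
  (modal stoichiometry, matching, screen argmax) resolve to the first
  entry in a documented deterministic order.
* Charge envelopes below z = 1 are truncated and renormalized; a charge
  width of 0 collapses the envelope to a single state.
* Ions outside the m/z grid are dropped and counted in the spectrum
  metadata; an empty ion list renders an all-zero spectrum; an all-zero
  spectrum yields an empty centroid list and the worst score, 0.
* Spectra validate a strictly uniform ascending axis and nonnegative
  intensities on construction.

## Known limitations

* The charge-envelope width (σ = 6 charges) and the reference resolving
  power are not identifiable from the data the package consumes; both are
  config parameters, and screens fit only the VP ratios.
* Scoring in m/z space means a screen's precision depends on the
  experimental window actually covering the informative fine structure.
* The multinomial model has no way to express inter-subunit cooperativity;
  systematic deviations between its best fit and an experimental spectrum
  are evidence about the assembly process, not fit noise.
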