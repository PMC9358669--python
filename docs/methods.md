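# Methods

`nativemet` analyzes post-column protein-infusion LC-MS screens ("native
metabolomics"): an intact protein is infused after the chromatographic
column under near-native buffer conditions, so metabolites that bind it
produce transient mass shifts of the protein envelope at their elution
time. A paired conventional LC-MS/MS run over the same gradient provides
precursor masses and fragment spectra for the small molecules. The package
covers the computational side of that design end to end; this note records
the models, the defaults that matter, and the choices made where the design
was genuinely open.

## Charge-state deconvolution

Under positive-mode ESI a species of neutral mass M appears at

    m/z(z) = (M + z * m_p) / z,    m_p = 1.00727646677 Da,

one centroid per charge z. Deconvolution inverts this by *charge-series
consistency*: every (peak, z) combination in the configured charge range is
a mass hypothesis; hypotheses are swept in mass order and grouped while they
stay within the intra-series tolerance, `max(0.05 Da, peak_tol * M)` with
`peak_tol` 10 ppm by default; a group is a species candidate only if
supported by at least `min_charge_support` (default 3) distinct charges with
gaps of at most 2 between successive charge states. Candidates are ranked
by summed intensity and greedily claim their peaks (strongest first, ties
broken toward lower mass, each centroid used once); candidates whose mass is
within tolerance of 2x, 3x, 1/2 or 1/3 of an already-accepted species while
sharing at least half of its peaks are discarded as harmonics. The reported
neutral mass is the intensity-weighted mean over the supporting charges.

This is intentionally simpler than isotope-resolved deconvolution
(Xtract-class) or full spectral deconvolution (FLASHDeconv-class): the
envelopes handled here are centroided without isotope structure, and the
downstream matching consumes only neutral masses and summed intensities.
Consequences: species closer than the intra-series tolerance at all shared
charges cannot be separated, and single-charge-state species are invisible
by design.

**Noise floor.** The floor is 3x the median intensity of the scan's noise
population, taken as centroids below 1% of the base peak, capped at 5% of
the base peak (an absolute override is available). A median over the whole
peak list would misbehave on scans that are almost entirely signal — in a
protein-infusion run with few noise centroids the median is itself an
envelope peak and would erase the envelope.

**Traces.** Per-scan species are linked across scans into neutral-mass
traces while they stay within a ±5 Da window of the running
intensity-weighted center (the same ±5 Da used for deconvoluted XICs);
traces split after more than 2 consecutive missing scans and need at least
3 observations. Apo-signal depletion ("negative peaks") is read from the
apo XIC against a 21-point rolling-median baseline; an event is a
contiguous drop of more than 30% below baseline.

## Feature detection

Both protein-side (neutral-mass traces) and metabolite-side (m/z traces
tolerance-linked at 10 ppm across MS1 scans) chromatograms go through the
same detector: 5-point moving-average smoothing, local maxima above a
height threshold, boundaries walked to the bracketing minimum or baseline
crossing, minimum width 0.05 min, trapezoidal areas over the raw trace.
These defaults suit the sharp (σ ≈ 0.02–0.1 min) peaks of short
microflow gradients and are all configurable per run kind.

The constantly infused apo protein never elutes as a peak; a trace
covering ≥ 80% of the run is therefore kept as one *persistent* feature.
That is also how apo autodetection works: the highest-area persistent
candidate wins, and a runner-up within 10% of its area makes the choice
ambiguous (an explicit apo mass is then required; a supplied apo mass
always overrides).

Metabolite features record the measured precursor m/z; MS2 scans are
linked when their precursor lies within tolerance and their retention time
inside the peak boundaries. Co-elution between a protein and a metabolite
feature is the Pearson correlation of the two traces interpolated onto the
union grid of their overlap (undefined without ≥ 3 overlapping points or
with a constant trace; callers treat that as 0).

## Delta-mass / retention-time matching

The core inference: protein feature P and metabolite feature L (neutral
mass from [M+H]+ by subtracting a proton; other adducts are config hooks)
match at stoichiometry n iff

    |(mass(P) - apo) - n * neutral(L)| <= mass_tol   and
    |rt(P) - rt(L)| <= rt_tol,

defaults 4 Da, 0.2 min, n <= 2. Matches are many-to-many (the 4 Da window
is deliberately wide; several isobaric co-eluting ligands may legitimately
share one complex) and are ranked by protein retention time then absolute
mass error; n >= 2 matches carry a nonspecific-binding flag, since a
doubled mass shift can reflect either a second binding site or gas-phase
clustering. The result set is provably identical to brute-force
enumeration over all (P, L, n) triples; the implementation merely prunes
with a bisection on ligand mass.

## Molecular networking

MS/MS similarity uses the modified cosine: square-root intensity
transform, L2 normalization, candidate fragment pairs at equal m/z *or*
offset by the precursor mass difference (0.02 Da fragment tolerance),
greedy one-to-one pairing by decreasing intensity product, score = sum of
paired products. Arguments are canonically ordered internally so the score
is exactly symmetric; an optimal-assignment mode exists for small spectra
(the greedy score is a lower bound, within 5% on ≤ 6-peak spectra in
testing). Edges require score ≥ 0.7 with ≥ 6 matched fragments and must
rank within both endpoints' top 10 partners — conventional molecular-
networking settings, exposed as configuration since no single standard
exists. Binding edges (one per match, annotated with Δmass and co-elution)
connect the protein node to ligand nodes; family components are computed
over msms edges only.

## Quantification

*Titration.* The bound/unbound intensity ratio versus ligand concentration
is fitted with `ratio(c) = Rmax * c / (Kd + c)`. The midpoint is reported
as an **apparent** Kd: ESI response factors of apo and complex are unknown
and no dissociation correction is applied, so the number ranks ligands
rather than measures thermodynamics. Initialization is Kd at the
half-maximal observed ratio and Rmax at the maximum; all-zero ratios are a
hard error ("no binding signal").

*Detection limit.* Serial-dilution series are summarized by the blank +3σ
rule: the LOD is bracketed by the largest tested concentration without
signal and the smallest with signal, plus slope/intercept/R² of the linear
range.

*Dose-response.* The 4PL `y = bottom + (top - bottom)/(1 + (c/ic50)^hill)`
is fitted by least squares with hill ∈ [0.1, 10], initialized at top = max,
bottom = min, ic50 = dose nearest mid-response, hill = 1. The reported IC50
is the curve midpoint (relative IC50, the common Prism convention);
standard errors come from the local curvature. The lower asymptote is free
by default with a `constrain_bottom` option pinning it at 0. A response
without an overall decrease (low-tercile mean minus high-tercile mean less
than 10% of the spread) is flagged `no_inhibition` instead of fitted. All
nonlinear fits use three deterministically perturbed starts, best residual
sum of squares wins.

## Synthetic data: what it emulates and what it does not

The generator plants ground truth for every stage: apo envelope (default
25232.6 Da) with Gaussian charge abundance (mean 8.5, σ 1.2 over z 6–11;
charge states outside the 2500–4000 m/z acquisition window are simply not
recorded, and a species with fewer than three in-window charges is
rejected with the offending charge states listed), Gaussian elution
(default σ 0.03 min on a 10-min gradient), ion-current conservation
(complex intensity is drawn from the apo envelope, producing the negative
apo-XIC peaks), [M+H]+ metabolite features with matched profiles,
DDA-style MS2 triggering near the apex (up to two per cycle), and analog
families sharing fragment ladders whose high-mass rungs shift with the
precursor — the exact pattern the modified cosine detects. Noise is
multiplicative log-normal (σ 0.05) on peak intensities, 1 ppm m/z jitter,
and a sparse exponential noise floor; one seed fixes everything, and
repeated generation is byte-identical through the mzML writer.

Not emulated: isotopic envelopes, adducts beyond protonation, chimeric
MS2, retention-time drift between the paired runs, ion suppression, and
detector saturation. Passing tests therefore demonstrate the correctness
of the algorithms under the stated acquisition geometry, not robustness to
every artifact of real spectra; CSV/MGF interop exists precisely so
real-world feature tables can be brought in from external tools.

The default screen plants 30 binders (the scale of the screening
experiment the defaults are modeled on) in families of five, masses
880–1280 Da spaced ≥ 10 Da (so 5 Da trace windows stay resolved), eluting
between 4 and 6 min, with complex/apo ratios 0.1–0.5, plus 10 decoys. At
these settings the full pipeline recovers 100% of planted matches both
noiselessly and at the default noise model in the shipped tests.

## Problem sizes and runtime

Default runs use 501 native MS1 scans (0.02 min spacing over 10 min) and
the same metabolomics grid; the full synthetic screen plus pipeline runs
in a few seconds, and the complete test suite in well under a minute. The
dose-response recovery check reports the median fitted IC50 over 11 seeded
draws because the single-draw estimator at the reference design (eight
half-log doses, 5% noise, triplicates) has a ~7% coefficient of variation;
the median summarizes the estimator's accuracy without changing the
generating conditions.

## Known limitations

- Neutral masses only: no isotope-level mass accuracy on the protein side;
  mass errors of a few Da at 26 kDa are expected and absorbed by the 4 Da
  matching tolerance.
- Greedy fragment pairing can under-score pathological spectra (bounded in
  tests at 5% versus optimal assignment on small spectra).
- Apparent Kd and single-point binding ratios are relative measures.
- Apo autodetection assumes the infused protein dominates the run; mixed
  infusions need an explicit apo mass.
- Orphan protein features (mass shifts with no co-eluting ligand feature,
  e.g. covalent modifications) are not matched; they remain visible in the
  protein feature table.
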