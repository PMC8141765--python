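# Methods

## Scope and model

The package treats a polyglutamylated coenzyme as a homologous series
`core + n·Glu`, where the glutamate residue contributes C5H7NO3
(129.0426 Da) per unit and the core is tyrosine-containing (C15H18N2O4,
290.1267 Da), tyramine-containing (C14H18N2O2, 246.1368 Da — the
decarboxylated core, 43.9898 Da lighter), or arbitrary. All downstream
computation reduces to exact-mass arithmetic on these compositions.

Charge carriers are protons only: `[M − zH]^z−` and `[M + zH]^z+`, with
m/z = (M ∓ z·1.00727646)/z using the proton mass so that the electron mass
is accounted for implicitly. Adducts (Na+, K+, ion-pair-reagent clusters)
are out of scope.

## Isotopologue patterns

Patterns are computed by per-element convolution of single-atom isotope
distributions (binary exponentiation over atom counts, pruning terms below
1e-13 probability) and aggregated by total nucleon number, because the fine
structure (e.g. 13C1 vs 15N1) is not resolved at the emulated resolution of
35,000. Each aggregated bin carries an abundance-weighted centroid mass.
Isotope masses and abundances are frozen package constants at 7-decimal
precision from a standard atomic-weights compilation (C, H, N, O, P, S).

The retention threshold (default 0.09) keeps isotopologues with at least
9 % abundance. The reference for "abundance" is configurable: relative to
the most abundant bin (default) or to the monoisotopic bin. The default is
the max basis because for species beyond roughly 90 carbons the M+1 bin
exceeds M0 and a mono-based threshold becomes ill-behaved. The test suite
checks the convolution against exhaustive multinomial enumeration to 1e-6
in both centroid mass and relative abundance.

## Targeted quantification

For each species, EIC targets are the m/z of every (charge state,
retained isotopologue) pair for z in [z_min, z_max] (defaults 1..8; raise
z_max to 14 for very large chains). Targets closer than tol_ppm/2 are
clustered and integrated once, so overlapping targets are never
double-counted. EIC extraction sums centroided intensities within a ppm
window (default 5 ppm) per MS1 scan; integration is trapezoidal over RT in
intensity·seconds.

The retention-time window is either explicit or automatic. Auto mode is a
reproducible surrogate for interactive window adjustment: the apex of the
single most intense monoisotopic EIC across the species set, ± 3× its
half-width at half-maximum. When a chain-length series is quantified
(`glutamate_distribution`), one window is derived from the whole set and
shared by all n — weak species at the distribution edges inherit the window
of the strongest species rather than following their own noise-dominated
EIC apex. Distributions are reported both max-normalized (most abundant
species = 1, the usual presentation of chain-length distributions) and
sum-normalized (fractions of the pool).

Core-type pool fractions quantify several cores over the same n range with
the shared window. Same-(n, z) ions of the tyrosine and tyramine cores are
separated by 43.9898/z Th — orders of magnitude beyond a 5 ppm window — but
across *different* (n, z, isotopologue) combinations a handful of
coincidences within 5 ppm do occur. Such ambiguous targets are excluded
from both cores (the same policy as dropping shared peptides in protein
quantification): a small symmetric loss instead of a share-dependent
cross-counting bias. With a zero grand total the fractions are reported as
NaN, not as 0/0.

## Untargeted ladder search

Input is the set of charge-annotated monoisotopic features; features
without charge annotation carry no neutral mass and are excluded (counted
in the log). Because one compound observed at several charge states yields
several features with near-identical neutral mass, features are first
collapsed to neutral compounds (mass within 10 mDa, co-eluting within 5 s;
representative keeps the most intense member's id/m/z/RT, areas and apex
intensities are summed). Without this step every rung of a ladder becomes
several interchangeable nodes and the number of maximal paths grows
exponentially.

Every ordered compound pair with ΔM = k·unit ± k·tol (unit 129.0426 Da,
k ≤ k_max = 5, tol_unit = 10 mDa per unit) becomes a DAG edge. The
per-unit tolerance is absolute, not ppm of the parent mass, because the
error of a mass *difference* does not scale with the parent mass; a ppm
alternative is available. Series are the maximal paths along single-unit
edges (optionally allowing k ≤ 1+gap), enumerated from sources to sinks —
this automates what would otherwise be manual filtering of a pairwise
difference list. Reported series are ranked by length, then summed apex
intensity, then member ids, which makes the output deterministic and
invariant under input permutation. min_length defaults to 3, the shortest
series that is meaningful evidence of a repeat unit. No RT co-elution
constraint links the rungs (chain homologs elute at different times); an
optional monotone-RT filter is off by default. The per-series "core
residual mass" (lowest member's neutral mass modulo the unit) fingerprints
the moiety the repeat units are attached to.

Both the edge set and the maximal-series set are tested for exact equality
against brute-force enumeration, and the false-series rate is measured as 0
across 20 pure-noise runs at 50 noise peaks per scan.

## Feature detection and charge annotation

Mass traces are built by greedy scan-to-scan linking: a centroid joins the
trace whose running mean m/z is nearest within link_ppm (default 7 ppm,
suited to ~35,000-resolution centroid data); traces shorter than 5 scans or
with gaps over 2 scans are dropped. Features are cut at local intensity
maxima, split at the valley between adjacent maxima, trimmed at 5 % of apex
height, and integrated by trapezoid. Charges come from isotope spacing:
co-eluting partners at Δm/z = 1.0033548/z are chained for z = 1..z_max; the
z with the most partners wins, ties prefer lower z (conservative neutral
masses); the lowest-m/z chain member is flagged monoisotopic. The defaults
are this package's own choices — validated against the simulator's ground
truth (recovered neutral masses within 5 ppm), not tuned to reproduce any
particular external feature finder.

## Synthetic data generator

`simdata` emulates the acquisition the analysis assumes: centroid MS1
spectra over m/z 120–1200 (the emulated instrument's range), negative or
positive mode, Gaussian chromatographic peaks, multiplicative centroid
jitter of 1.5 ppm (1 σ; a plausible centroid accuracy at resolution 35,000
— the emulated acquisition states no value), Poisson chemical noise
(default 50 peaks/scan, log-normal intensities), and a detection floor.
Per species the total area is split across a charge-state envelope and
across the retained isotopologues, so noise-free runs conserve injected
area to within discretization (verified at 2 %). Ground truth (per-target
m/z, area shares, RT windows, config echo) is emitted as JSON. Generation
is deterministic per seed down to the byte level of the written mzML.

Charge-state envelopes are a modelling choice, not a measured quantity: a
discretized Gaussian (σ = 1) over the *feasible* charge states (ion inside
the m/z window), centered at M/650 — which puts typical full-length
coenzyme species near z = 4 and keeps both small (z = 1) and very large
(z > 8) species observable.

Named scenarios fix chain-length distributions: `wt_extorquens` (n = 6–24,
maximum at 18), `overexpression` (n = 8–40, broad, center 26),
`gapped_burkholderia` (n = 6–14, maximum at 10, with the n = 11 species
suppressed to ~31 % of its Gaussian value), `invitro_polyglu` (free
polyglutamates, 2–11 units, geometrically decaying). The Gaussian presets
apply a 2 % relative floor so that every chain length in the stated range
is present at a detectable level, as in the distributions these scenarios
emulate. MS2 spectra with diagnostic core fragments can be attached at a
species apex for fragment-verification testing.

What the generator does *not* emulate: a realistic full-metabolome
background, correlated (non-white) noise, peak tailing (a pure Gaussian
shape is used; real ion-pair chromatography shows near-symmetric peaks for
these analytes), retention-time drift with chain length (a linear drift
hook exists, default 0), or detector saturation. Passing recovery tests
therefore demonstrates correctness of the computational pipeline under the
stated statistical assumptions, not robustness to every artifact of real
chromatography.

## MS/MS verification

Diagnostic fragments are core metadata: for the tyramine core the
ammonia-loss assignments [M+H−NH3]+ (C14H16NO2+) and [M+H−2NH3]+
(C14H13O2+), whose exact masses reproduce the observed 230.12 and 213.09
m/z values. These compositions are the interpretation that is numerically
forced among simple neutral losses; they are stored as editable data on the
core definition, not hard-coded. Fragment m/z of a charged composition is
its mass minus (cation) or plus (anion) one electron mass. The default MS2
match tolerance is 10 ppm — looser than the 5 ppm MS1 tolerance because
fragment centroids are noisier. A spectrum is verified when every
diagnostic fragment matches.

## mzML I/O

Both directions are implemented on lxml. The reader is streaming and
resolves controlled-vocabulary terms by accession (ms level, centroid vs
profile, polarity, scan start time with minute→second conversion, selected
ion m/z, array type/precision/compression); profile-mode spectra raise an
explicit unsupported-data error rather than being silently mis-processed.
The writer emits indexed mzML with 64-bit m/z arrays (bit-exact round trip)
and 32-bit intensities, uncompressed, with no timestamps — output is a pure
function of the run, so fixed seeds give byte-identical files. Feature
tables are TSV with a fixed column set; a blank charge cell means
unannotated, and an optional `monoisotopic` column (0/1) preserves isotope-
group flags across the table boundary.

## Problem sizes and numerical choices

Simulated runs in the tests and the acceptance script use 120 s gradients
at 1 s scan interval with species eluting at 60 s (σ = 4 s) — a
structurally faithful scaled-down version of a ~10 min acquisition, chosen
so the full suite runs in seconds while every analytical challenge (charge
deconvolution, isotopologue overlap, coincident targets, noise) is
retained. Recovery criteria: total-variation distance of sum-normalized
distributions < 0.05 over 10 seeded runs per scenario; pool fractions
within ±0.02; Gaussian closed-form integration within 2 %.

Degenerate inputs are defined, not exceptional: empty runs quantify to 0,
an all-noise run yields no series, a zero grand total yields NaN fractions,
and integration windows outside the run's RT span return 0 with a warning.
Ties in charge annotation prefer more isotope partners, then lower z; ties
in series ranking fall back to member ids.

## Known limitations

- Quantification attributes an EIC to every species whose target matches in
  m/z; coincidences across *different* chain lengths or charge states of
  the same core are integrated into both species. At 5 ppm these inflate a
  distribution by at most a few percent (visible as a small over-recovery)
  and are unavoidable without spectral deconvolution.
- The charge annotator assigns one z per isotope chain; overlapping isotope
  clusters of co-eluting unrelated compounds can mis-chain at high noise
  density.
- Absolute (molar) quantification, cross-run alignment and
  biological-replicate statistics are out of scope; areas are comparable
  within one run only.
- The ladder search reports series of one repeat unit at a time; mixed-unit
  ladders require separate passes.
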