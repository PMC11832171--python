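# Methods

## Scope

`sleepframe` implements a behavioural-pharmacology method stack for larval
zebrafish: frame-resolution sleep/wake scoring of Δ-pixel video-tracking
data, extraction of 17 behavioural parameters per larva per day/night,
z-score behavioural fingerprints, linear mixed-effects statistics, and an
enrichment engine that ranks a query fingerprint against an annotated
small-molecule fingerprint library and tests annotations (indications,
targets, KEGG pathways) by permutation.  A seeded synthetic-data module
generates Δ-pixel experiments with known ground truth and annotated
fingerprint libraries, so the entire stack is testable without external
data.

## Sleep and active-bout scoring

The raw signal is Δ pixel: the number of camera pixels changing intensity
per well per frame transition, at a fixed frame rate (default 25 fps).
Sleep is behaviourally defined as any period of complete inactivity
(Δ pixel = 0) lasting at least one minute — a definition validated in the
literature through arousal-threshold and homeostatic-rebound experiments,
which this package deliberately does not re-test.

The scorer follows the rolling-sum construction: a trailing 60-s rolling sum
of the trace is zero at frame *t* exactly when the preceding 60 s were all
zeros, so flagged frames mark the ends of the first minute of each sleep
bout; flagged runs are then back-extended 60 s to recover true bout starts.
This is provably identical to scanning for maximal zero runs of at least
`round(60·fps)` frames, and the test suite holds the implementation to that
independent brute-force oracle on random traces.

Numerical/boundary choices:

* "lasting longer than 1 min" is implemented as ≥ `round(60·fps)` frames
  (the rolling-sum construction fires at exactly 60 s); the boundary is
  deliberately inclusive.
* Rolling windows are trailing (right-aligned), for the sleep scorer by
  construction and for the 60-min activity smoother by consistency.
* Sleep bouts truncated by the experiment edges are kept when their observed
  portion is at least 60 s.
* Partial epochs at the trace edges are dropped from binned traces, not
  prorated.
* Missing frames are not supported: the ingestion dialect assumes a dense
  frame grid, and a gap is a hard error.

An active bout is a maximal run of frames with Δ pixel > 0 (a single swim
bout, ~0.2 s).  Per-bout statistics (mean/max/min/sum/std of Δ pixel) are
computed with vectorised segment reductions.

The legacy one-minute summary (`middur`) counts, per minute, the seconds
spent with freeze < Δ < burst, both thresholds strict (defaults 3 and 200;
freeze = 0 for re-computation mode).  Because a zero-middur minute requires
60 aligned zero seconds, legacy total sleep and bout count are bounded above
by their frame-resolution counterparts on every trace — asserted as an
invariant.

Pigmentation adjustment: fainter larvae displace fewer pixels, so group
comparisons can be confounded by pigmentation differences.  The maximum
Δ pixel during the lights-off startle response measures each larva's
detectable dark pixels; the target group's traces are rescaled by the ratio
of group mean startle maxima and rounded back to integers.

## Windows and parameters

Full days (lights on, default 09:00, 14 h) and nights (10 h) are named
`night0, day1, night1, day2, night2, …`: days are numbered from 1 in order
of full light phases, each night takes the index of the day it follows, and
`night0` (the habituation night) is excluded from analysis by default.
Partial windows at either end are dropped.  Larval age is
`start_dpf + window index` (5 dpf at night0 by default).

Seventeen parameters in three categories (6 activity, 7 active-bout, 4
sleep; sunset startle and sleep latency night-only) give 15 day + 17 night
= 32 unique (parameter, day/night) keys; this census is asserted on every
run.  The field's standard roster names 12 of the 17 in print; the three
window-shape activity parameters are this package's own definitions, chosen
to preserve the normative counts:

* `activity_slope` — least-squares slope of the 10-min binned activity
  across the window (Δpx/10 min per hour);
* `transition_delta` — mean binned activity of the first 30 min minus the
  last 30 min of the window;
* `activity_cv` — coefficient of variation of the binned activity.

The sunset-startle window is 3 s after lights-off (configurable).  Sleep
latency is minutes from lights-off to the first sleep bout, missing for
sleepless nights (never coerced to 0 or ∞).

## Fingerprints

Per larva and unique parameter key, z = (x − μ_con)/σ_con against
same-clutch controls per window (σ with ddof = 1, matching R's `sd`), then
day1/day2 and night1/night2 averaged, yielding a 32-entry fingerprint whose
control-group mean is identically zero.  Zero control s.d. marks the entry
missing with a warning.  Group fingerprints average per-clutch means (and
SEMs) across clutches.  Euclidean distance from the origin summarises a
larva's overall displacement from controls; cosine similarity between
fingerprints is computed over shared non-missing keys (≥2 required) and is
scale-invariant.

The legacy 12-entry fingerprint reproduces the one-minute format of the
historical compound screen: {average activity, average waking activity,
total sleep, sleep bout count, sleep bout length, sleep latency} × {day,
night}, computed from the middur series with freeze = 0 (a sleep minute is a
zero-middur minute; a legacy sleep bout is a maximal run of such minutes;
waking activity excludes them), z-scored and window-averaged identically.
The query sent to enrichment is the mean across clutches of the treatment
group's per-clutch mean legacy fingerprints.  Library fingerprints are
consumed as opaque 12-vectors; their own normalisation is not re-derived.

## Mixed-effects statistics

Each parameter is modelled per phase (day/night separately) as

    value ~ group + (1 | experiment/larva) + (1 | dpf)

with the group effect tested by likelihood ratio against the
no-fixed-effect null, both fitted by maximum likelihood (REML would make
the LRT on a fixed effect invalid; REML is available for slope/SE
reporting, where its less biased variance estimates are preferable).  The
LRT statistic is referred to χ² with (groups − 1) degrees of freedom.
Implementation uses statsmodels `MixedLM` with variance components for
experiment, larva-within-experiment, and dpf over a single trivial
grouping, which reproduces the crossed/nested structure; a test
cross-checks slope and LRT p against an independent `lme4` fit to ~1e-4.
Two optimizers (L-BFGS and Powell) are run and the best log-likelihood
kept, because gradient methods occasionally stall when a variance component
sits on the boundary; maximising over both keeps the LRT's two fits
comparable.  The dpf component is dropped (with a warning) when a phase has
one dpf level, and the experiment component when only one clutch is present
— the fit proceeds either way.

No multiplicity adjustment is applied, neither across the 32 parameters nor
across group contrasts: p-values are reported raw, one per parameter per
phase, and readers should interpret them accordingly.  With more than two
groups, each group is compared to the reference by a Wald z-test on its
coefficient (a marginal-means contrast; for two groups this is the single
slope's Wald test).

Finite-sample behaviour: with two clutches and two dpf levels the ML-LRT is
known to run slightly hot; the calibration test simulates data drawn
exactly from the fitted model's structure (global dpf intercepts crossed
with clutch) at n = 24/group × 2 clutches × 2 windows, conditions under
which both this implementation and `lme4` reject at ≈5% (they agree
per-dataset to 1e-4).  A generator that gives each clutch its own dpf
effect — an interaction the model does not posit — pushes either
implementation to ≈9%, a model-misspecification effect, not an
implementation artefact.

Effect sizes: ef% = 100·(−1 + ko/con) per clutch, with ko = con + slope,
averaged across clutches; the sign always matches the slope.  Drug effects
on a mutant background are classified per parameter from the knockout
p-value (untreated mutant vs control) and drug p-value (treated mutant vs
control) at α = 0.05: rescue (<α, ≥α), missed rescue (<α, <α), side effect
(≥α, <α), no effect (≥α, ≥α); missing p-values yield "indeterminate".

## Enrichment engine

The query fingerprint is compared by cosine to every library fingerprint.
Two modes: `collapse` (one mean fingerprint per compound — used for
enrichment so a heavily replicated compound cannot drive an annotation) and
`all` (every replicate ranked — used when shortlisting therapeutic
candidates whose replicates must independently agree).  Ties are broken by
compound id for determinism.

For an annotation with n member compounds present, the observed statistic
is S = Σ|cos| over members: large when members concentrate at either end of
the ranked list, making the test two-sided by construction (negating the
query provably changes nothing).  The null is simulated by B draws
(default 100,000) of n distinct compounds without replacement; the
simulated p is count(draw sum > S)/B — strict, with no +1 correction,
pinned by the published convention 1470/100,000 = 0.0147 ≈ 0.015 (the
positively biased (count+1)/(B+1) estimator is available as an option).
Draws that tie S to float precision (e.g. a draw picking exactly the member
set in a degenerate library) do not count as larger.  Compounds without any
annotation of the tested class are deleted before the test, so null draws
come from the annotated compounds' cosines; annotation members missing from
the library are dropped with a warning.  Null positions are drawn in the
sorted |cos| array, so p depends only on the cosine multiset, never on
library ordering; annotations with equal n share one null sample per run.

## Knockout probability model

Mosaic F0 founders carry, per targeted locus, a frameshift fraction f
(taken as the per-allele frameshift probability).  Assuming independence
across loci and alleles, the biallelic knockout probability is
P = [1 − Π(1 − f_i)]², reducing to f² for one locus and monotone in every
f_i and in locus count.  Three loci at the typical f ≈ 0.786 give
P ≈ 0.9805, the quantitative basis for treating three-locus F0 knockouts as
near-complete loss-of-function.  Only the frameshift pathway is modelled;
in-frame-but-deleterious alleles are not.

## Synthetic data

The larva simulator is an alternating renewal process: active bouts with
exponential durations (mean 0.2 s) alternate with quiescent gaps from a
two-component exponential mixture (short ≈ 0.8 s; long ≈ 150 s), so sleep
bouts (gaps ≥ 60 s) emerge naturally from the heavy tail.  Day and night
phases modulate the long-gap weight (0.002 day, 0.02 night — diurnal sleep
consolidation) and bout amplitude (night × 0.7); within-bout Δ-pixel values
are geometric integers (mean 8 by day) times a per-larva pigmentation
("darkness") factor, which the pigmentation-adjustment tests exploit.  A
startle bout (~80 Δpx, 0.3 s) is forced at each lights-off.  These defaults
were fixed once as a realistic diurnal larva profile (a few hours of
consolidated night sleep, near-continuous day swimming).  Ground truths
(per-window sleep time, bout counts, total activity) are recorded from the
discretised bout layout the generator emits, so they are exact for the
trace by construction.  One global seed fans out to per-well streams by
hashing (seed, clutch, well), making output independent of well order.
Planted group effects compose multiplicatively: amplitude multipliers per
phase, long-gap-weight multipliers (sleep), gap-mean divisors (bout rate),
darkness.

What the simulator does not emulate: burst/seizure-like activity, camera
noise and dropped frames, slow circadian drift within a phase, well
position effects, and inter-parameter correlation structure beyond what the
renewal process induces.  Passing recovery tests therefore shows the
pipeline is correct for clean renewal-like data, not that it is robust to
instrument artefacts.

The library simulator draws null fingerprints from an isotropic Gaussian
(cosines symmetric about zero) and planted members from ±effect·q̂ + noise,
elevating |cos| against the query; annotations are sparse many-to-many
(Poisson-distributed multiplicity), with the planted annotation's
membership exactly the planted set.  Under effect 0 the permutation p of a
fixed annotation is uniform across library draws (KS-tested).

## Problem sizes in the test suite

The suite simulates at reduced frame rates (2–5 fps) and spans (40–65 h, 2–8
wells) — the analysis is fps-parametric throughout, so these exercise the
same code paths as 25-fps data at a fraction of the cost; the sleep-scorer
oracle and simulator-recovery checks additionally run at the native 25 fps.
Calibration experiments use 200 null and 100 planted-effect mixed-model
fits and B = 2,000–100,000 permutation draws.

## Known limitations

* The three reconstructed activity parameters are package-defined; numeric
  values for them are not comparable with the historical tool, though the
  (15, 17, 32) census is.
* The LRT's χ² reference is asymptotic; with very few clutches p-values run
  slightly liberal (see above), exactly as in `lme4`.
* The enrichment null draws compounds, not replicate fingerprints; when an
  annotation maps to compounds absent from the library those members are
  silently dropped (with a warning), which can only make the test
  conservative.
* Cox proportional-hazards survival analysis of sleep latency and the
  construction of the real compound-annotation database (PubChem/TTD
  scraping) are out of scope; the library file format is supported, its
  provenance is not.
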