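# Methods

This note documents the models and procedures implemented in `paddyghg`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot support.

## Water-level series and ingestion

A field's record is a strictly daily series of tube readings in cm
(positive = ponded depth, negative = depth to the saturated front, 0 =
water at the soil surface). Readings below the 15 cm tube depth are
physically unobservable and are stored as −15 with a `censored` flag;
every banding rule treats them as "deeper than −10 cm", which is all that
can be known about them.

Ingestion places each field on a complete calendar grid. Interior gaps of
up to 3 consecutive days are filled by linear interpolation and flagged
`observed=False`; longer gaps invalidate the field (configurable to
drop rather than raise). The 3-day limit is a deliberate compromise:
event-duration descriptors (A5–A8, B4–B6) are sensitive to invented
crossings, and three days is the longest span over which a linear bridge
between tube readings is defensible. Fields monitored for fewer than 30
days are rejected at ingestion — their descriptor percentages are too
unstable to compare across a landscape — while the in-memory container
accepts any series of ≥ 2 days so that short, fully-specified series can
be analyzed directly.

## The 17 hydrologic descriptors

A day is **flooded** iff its level is strictly above 0 cm; a level of
exactly 0 is drained, in the 0→−5 band. Bins are half-open with the upper
edge included: flood bands (0,5], (5,10], (10,∞); drain bands [−5,0],
[−10,−5), (−∞,−10). Flood events are maximal runs of flooded days,
classed by duration as one day, 2–7 days ("within a week"), 8–30 days
("within a month"), or >30 days. A dry event is banded by its deepest
level, which is the depth that matters for re-aeration. Percentages use
the bases the definitions imply: A1 over monitored days; A2–A4 over
flooded days; A5–A8 over flood events; B1–B3 over drained days. B4–B6 are
mean dry-event durations per band, defined as 0 when a band has no event
(avoiding undefined means at the cost of conflating "no event" with
"instantaneous events" — acceptable because the companion counts B1–B3
disambiguate). C2 counts day pairs falling from ≥ +5 cm to ≤ −5 cm; C3
counts day pairs with a drop of more than 10 cm regardless of sign; the
two are defined independently and neither bounds the other.

The engine is validated three ways: a hand-enumerated 10-day toy covering
every descriptor family; boundary-value tests at 0, 5, 10, −5, −10, −15
cm and at the 1/7/8/30/31-day duration edges; and exact agreement with an
independent brute-force day-by-day implementation on 1,000 random series,
together with the composition identities (A2+A3+A4 = 100 whenever any day
is flooded, A5+…+A8 = 100 whenever any event exists, B1+B2+B3 = 100
whenever any day is drained).

## Hydrologic clustering

Descriptors mix percentages, day counts, and event counts, so columns are
z-scored (sd with ddof = 1) before K-means; constant columns are left at
zero with a warning. Clustering is Lloyd's algorithm, best of 50 seeded
restarts, tolerance 1e−8 on within-cluster sum of squares. Cluster count
is chosen by mean silhouette (Euclidean, standardized space) over k =
2..8, subject to every cluster holding at least 3 fields ("a reasonable
number of members"); ties break to the smaller k. Labels are renumbered
so cluster 1 has the driest centroid (smallest unstandardized A1) and
cluster k the wettest. Pseudo-R² is defined as 1 − WCSS/TSS — the share
of standardized descriptor variance the partition explains.

Descriptor importance for membership is permutation-based: the mean
fraction of fields whose nearest-centroid assignment changes when one
column is permuted (200 permutations by default). Between-cluster
emission differences use one-way ANOVA with Fisher's protected LSD:
pairwise tests at α on the pooled error mean square only when the ANOVA
is significant, summarized as a compact letter display ordered by
descending mean. Descriptor–emission association is plain Pearson
correlation per descriptor and gas; a constant descriptor yields a
missing value, never 0.

## Soil pedotransfer functions

Where bulk density is unmeasured it is estimated from organic carbon as
BD = 1.449·e^(−0.03·OC) (g/cm³; OC in %), clamped to (0.8, 1.8) with a
warning; measured values are never overwritten and every output carries a
provenance tag. Porosity is 1 − BD/2.65 with the mineral particle density
fixed at 2.65 g/cm³. Saturated hydraulic conductivity (mm/h) and
volumetric water content at 33 kPa and 1500 kPa follow the Saxton–Rawls
texture/organic-matter equations, with organic matter taken as 1.724·OC.
WFPS% is the retention water content divided by porosity; the published
study does not state its WFPS source unambiguously, so the Saxton–Rawls
retention values are used, a documented fallback. Because retention here
is texture-based while porosity is bulk-density-based, a dense fine soil
can nominally hold more water at field capacity than its pore space; the
pipeline caps θ just below porosity with a warning in that case. All PTF
transcriptions are verified against a second, independently structured
transcription of the same published equations (1e−6 relative agreement on
random texture grids).

## GWP accounting

Seasonal totals are inclusive sums of daily fluxes from sowing to
harvest. CO₂-equivalents use the AR6 GWP100 mass factors — 27 kg CO₂-eq
per kg CH₄ and 273 per kg N₂O — applied to the gases as emitted (no C- or
N-normalization), reported in mt CO₂-eq ha⁻¹. The conversion is linear
and unit-audited (g→kg N₂O path agrees to 1e−12). Landscape summaries
report per-cluster and overall means/ranges and the CH₄ share of total
CO₂-eq.

## Synthetic landscapes

The generator emulates the study design, not any particular data set.
Each scenario ("wet" ≈ a high-rainfall monsoon, 128-day window; "dry" ≈ a
low-rainfall, irrigation-driven monsoon, 120-day window) has five
archetypes ordered driest to wettest:

* wet: rarely-flooded rainfed fields (~20 % of days flooded); half-season
  shallow ponding (0–5 cm); a regular 15-day irrigation rotation; long
  moderate ponding (5–10 cm); and deep ponding (>10 cm).
* dry: parched fields that drain below the tube within weeks; "flashy"
  one-day irrigation floods every ~5 days; a 45 %-prevalent intermittent
  type with week-long floods every ~15 days; and mid-season shallow and
  long moderate ponding types.

A field's series is a piecewise-linear template plus stationary AR(1)
noise (sd 0.5–0.8 cm, ρ 0.5–0.7), plus Poisson-arriving irrigation pulses
that recede linearly (a pulse scheduled on an already-ponded day is
skipped — flooded fields are not irrigated), clamped to [−15, +25] cm
with censoring below tube depth. Two per-field continuous jitters make
within-archetype variation realistic and smooth: a uniform time-stretch
(±25 % for the single-flood-block archetypes; 0 for the cyclic rotations,
whose block count must not change) and a uniform offset of the deep
(< −5 cm) part of the profile, which varies the depth composition of dry
spells. A deliberately descriptive generator was chosen over a 1-D water
balance: observed paddy water regimes emerge from lateral landscape
processes that a one-dimensional balance cannot reproduce, so fitting
archetypes to observed pattern types is the honest model class.

Template design follows two rules worth recording. First, every dry
spell's template depth is kept well clear of the −5 and −10 cm band edges
(or pinned decisively below −10), and band crossings are fast (2–3 days):
otherwise measurement-scale noise flips individual fields across
event-banding boundaries, producing spurious discrete subgroups that any
clustering method will find. Second, the flood-block durations stay clear
of the 7- and 30-day duration-class edges under the time-stretch, for the
same reason. These constraints are what make "five archetypes in, five
clusters out" a property of the design rather than of a lucky seed.

Soils are drawn on realistic alluvial-plain ranges (clay 10–45 %, OC
0.3–1.5 %, pH 6–8.5), with bulk density present for 80 % of fields so the
PTF path is exercised on the remainder.

## The surrogate emission model

Seasonal emissions come from a closed-form surrogate, not from a
process-based biogeochemistry simulation. With a1 = A1/100,
a4 = A4/100, R the residue fraction:

CH₄ (kg ha⁻¹) = 650 · a1^1.4 · (1 + 0.5·a4) · (1 + 0.4·R·a1) · e^ε₁

N₂O (g ha⁻¹) = (10 + 1.2·N_eff) · (1 + 2·T) · (1 + 0.5·clay%/100) · e^ε₂

where N_eff sums only the fertilizer doses applied while the field is not
flooded (a flooded application contributes zero N₂O — ponded soil
suppresses the nitrification/denitrification pulse), T is the number of
flooded↔drained day transitions within ±7 days of any application, per
application, and ε₁, ε₂ are mean-zero Gaussian noise on the log scale
(sd 0.25 and 0.3). Applications dated before the monitored window (the
basal dose at sowing, before tubes are installed) count as unflooded;
this also keeps N₂O strictly increasing in the N rate, as the sensitivity
contract requires. The functional form encodes the qualitative driver
structure a landscape analysis should recover — CH₄ driven by flood
duration first and depth second, boosted by residue only where fields are
wet; N₂O driven by fertilizer meeting drained or transitioning soil, with
a clay modifier — and its parameters are calibrated only so that
wet-scenario landscapes fall within the published seasonal envelope of
7–608 kg CH₄ ha⁻¹ with methane dominating the CO₂-eq budget (≳97 %).

What the surrogate is **not**: it produces no daily flux dynamics, no
soil-carbon or crop feedbacks, and its N₂O magnitudes for highly
intermittent fields (the dry "flashy" archetype, where fertilizer windows
unavoidably contain many transitions) exceed the few-hundred-g ha⁻¹
ceilings reported for comparable field studies — the transition
multiplier is linear and uncapped by construction. Passing tests
therefore demonstrate that the *analysis pipeline* (descriptors,
clustering, accounting, classification, sensitivity) behaves correctly
and recovers planted structure; they say nothing about predictive skill
for real paddies. The sensitivity module accepts any engine with the
same signature, so a wrapper around a process-based model can be
substituted without touching the grid logic.

Wet-year archetype wetness is one further calibration choice: with the
surrogate's fixed parameters, near-continuous deep flooding would place
median CH₄ above the published seasonal maximum, so the wettest wet-year
archetypes flood for roughly half the monitored window rather than
essentially all of it. Relative ordering (driest → wettest) and the
cluster structure are preserved; absolute heatmap realism is traded for
staying inside the published emission envelope.

## Emission-level classification

Pooled-season CH₄ totals are discretized into five ordered levels at the
1/5…4/5 quantiles (equal frequency); fixed published cut sets
(56.6/129/207/317 and 73.6/162/254/383 kg ha⁻¹ — two versions circulate
for the same analysis and disagree; both ship as presets, neither is
endorsed) can replay externally defined levels. The 80:20 split is
stratified per level with the training allocation rounded to the nearest
integer (20 per level ⇒ exactly 16/4) after a seeded shuffle. The forest
uses 500 trees and √p features per split, with OOB error as the headline
metric and Gini importances for ranking; the single tree is grown with
minimum leaf size 5 and pruned by cross-validated cost complexity using
the 1-SE rule (the most-pruned tree within one standard error of the best
cross-validated accuracy). None of these controls are stated in the
analysis this replicates; they are documented here and in the CLI output
metadata.

## Sensitivity grid

Each cluster is represented by its medoid — the member closest to the
centroid in standardized descriptor space, ties to the lexicographically
smallest field id. The grid crosses N multipliers {1.00, 1.25, 1.50,
1.75, 2.00} (all split doses scaled proportionally) with residue
fractions {0, 0.25, 0.50, 0.75, 1.00}; deltas are taken against the
(1.0, 0) cell. Two baselines circulate for the N grid — the configured
schedule total (125 kg ha⁻¹, the default here) and a lower 90 kg ha⁻¹
whose doubled ceiling is 180 kg ha⁻¹ (available as a preset); the
discrepancy is surfaced rather than resolved. With noise off the grid is
deterministic; with noise on each cell reports mean ± sd over seeded
replicates (30 by default).

## Problem sizes and numerical conventions

Tests and examples use landscapes of 47–160 fields and 120–128-day
seasons — the scale of a single-season monitoring campaign — which keeps
every analysis comfortably interactive. Seeds are explicit everywhere
randomness enters (generation, restarts, permutations, splits,
replicates). Degenerate inputs have defined behavior throughout:
constant descriptors standardize to zero with a warning and correlate as
missing; empty bands yield zero mean durations; an all-identical ANOVA is
reported as F = 0, p = 1 with a single letter; clusters of one are
excluded from ANOVA/LSD with a warning.

## Known limitations

* The surrogate's N₂O tail for intermittent fields is unrealistically
  heavy (see above); its CH₄ is insensitive to nitrogen by construction.
* Descriptor banding of censored days assumes "below −10 cm", the best
  available statement given the tube depth.
* Cluster labels are comparable only within a run; archetypes are not
  matched across scenarios (the analysis this supports found cluster
  characteristics unstable across years, and no cross-year matching is
  attempted).
* The permutation importance measures single-column effects; jointly
  redundant descriptor groups (e.g. the B-band compositions) can each
  look individually unimportant in well-separated clusterings.
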