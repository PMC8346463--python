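# Methods

This note documents the models, conventions, and numerical choices behind
`damtrack`, and what the synthetic-data tests do and do not demonstrate about
field data.

## Tag codes and the CRC

A tag message is 31 bits: a 7-bit sync pattern (a Barker-7 constant,
`1110010`), a 16-bit tag identifier (65,536 codes), and an 8-bit CRC over the
identifier. The true over-the-air layout and CRC parameters of commercial
hardware are not public; we adopt the standard CRC-8 generator
x⁸ + x² + x + 1 (0x07), zero init, MSB-first, unreflected, no output XOR —
a well-tested configuration with a published check value (`"123456789"` →
0xF4) — and make every parameter configurable. No interoperability with real
hardware is implied or claimed.

Validation compares only the recomputed and embedded CRC fields. This is
deliberate: the observed false-validation rate of uniformly random words is
then 2⁻⁸ = 1/256, which is the operating point the downstream filters assume.
Checking the sync pattern too would change that rate by a factor of 2⁻⁷ and
contradict the system's known behavior.

**Mimic codes.** The CRC is linear over bit-XOR, so an error pattern
e = (e_id, e_crc) maps *every* valid codeword to a valid codeword exactly when
crc(e_id) = e_crc ("zero syndrome"). Mimic enumeration therefore reduces to
enumerating zero-syndrome patterns up to a weight bound (weight ≤ 2 yields
none — the code detects all double-bit errors at this length — weight 4 yields
80 patterns), independent of the source id. Corrupted sync bits are assumed to
prevent decoding altogether, so the search space is the 24 id+crc bits. The
test suite cross-checks the syndrome enumeration against brute force over all
C(24,≤4) flip patterns applied to actual codewords.

## Data records

All nine deposited table categories (hydrophone configuration, autonomous
deployments, tagged fish, PIT detections, cabled and autonomous event data,
3-D tracks, passage routes) are registered schemas with typed, validated
round-tripping readers/writers. Datetimes are ISO-8601-like strings in files
and UTC epoch seconds in memory; files written by other systems at a constant
UTC offset can be read with `utc_offset_hours`. Because the deposited files'
exact datetime format string is not fixed, a small set of common formats is
accepted and the one used is recorded (`tables.last_datetime_format`).
Header matching tolerates whitespace/underscore/dash variants but emits the
printed form verbatim.

## Synthetic data

The simulator generates the statistical structure the pipeline assumes, not a
hydrodynamic model of a forebay:

* **Movement** is a correlated random walk (heading persistence, speed
  jitter, bounded vertical drift, per-step displacement capped at a maximum
  speed). Real fish respond to flow fields and structures; no such behavior is
  modeled, so passing tests say nothing about behavioral realism.
* **Transmissions**: intervals ~ Normal(PRI, jitter), PRI 4.2 s for study
  tags, 3 s for the survey tag; jitter sd must stay below PRI/2 so the
  transmission lattice survives.
* **Propagation**: arrival = emission + range/c + N(0, σ_t), with σ_t = 10 µs
  by default (survey-grade synchronization). Detection is Bernoulli with a
  logistic range curve p(r) = p_max/(1 + exp((r − r50)/s)), defaults
  p_max = 0.999, r50 = 250 m, s = 25 m, chosen so p(140 m) ≈ 0.99 — the
  *scale* of reported field efficiencies. These defaults are stand-ins, not
  estimates of any physical system; no quantitative range-detection model is
  published for the study deployment.
* **Multipath**: each detected decode spawns an echo with probability
  p_mp (default 0.2) at a uniform positive lag on (0.01, 0.3) s, matching the
  multipath-filter window.
* **False positives**: Poisson per receiver; their id fields are drawn by
  rejection from uniformly random words that passed validation, so their id
  distribution matches real CRC-passing noise. Mimic corruption replaces a
  true decode's id with one of its mimic codes with probability p_mimic.
* **Clocks**: cabled receivers share one clock (GPS-disciplined); autonomous
  receivers get independent constant offsets and are processed one at a time.
* **USV survey**: straight out-and-back transects in front of selected bays,
  5 → 150 m at 0.28 m/s, GPS sampled at 1 Hz with optional noise; connecting
  transits run parallel to the dam.

## Filter cascade

Fixed order, cabled: multipath → message grouping → single-detection →
message-PRI (event building) → mimic. Autonomous: multipath → single-node PRI
→ mimic. Every filter returns a subset of its input and is idempotent.

Numerical conventions:

* **Multipath window** 0.3 s, strict inequality (a decode exactly at
  window survives), greedy left-to-right per (receiver, tag).
* **Grouping window** defaults to array aperture / c + 3σ_t — the maximum
  physical arrival spread of one transmission — since no value is published.
* **PRI filter**: a message joins an event when its spacing to an accepted
  message is within tolerance (0.2 s) of k·PRI, 1 ≤ k ≤ k_max (12); a silence
  longer than gap_close (30·PRI) closes the event; events with fewer than
  min_messages (4) are discarded. The published description defers the exact
  acceptance logic to earlier work; these values are explicit stand-ins chosen
  for robustness (tolerance ≫ jitter, k_max bridging realistic detection
  gaps), and the acceptance suite verifies ≥ 99 % retention of true messages
  and ≥ 99 % removal of PRI-unstructured noise under the default conditions.
* **Mimic filter**: an event is removed when its tag is a mimic of a
  concurrent event's tag, at least 80 % of its message times match the other
  event's within 25 ms, and (when tracks are available) the median 3-D
  separation is below 50 m. The event with fewer messages loses; ties keep the
  tag present in the tagged-fish release list (the field workflow resolves
  such cases manually).
* **Chronology**: migration means non-increasing river kilometre; events
  upstream of the running minimum, events before release, and stationary
  events longer than 24 h (dropped tag near a receiver) are flagged and
  excluded.

## Localization

Sound speed comes from the Marczak (1997) fifth-order pure-water polynomial,
valid 0–40 °C (1402.385 m/s at 0 °C, ≈1482.38 m/s at 20 °C). The temperature
is a single scalar; depth stratification is not modeled, which in the field
is the dominant source of Z error.

The solver minimizes the TDOA least-squares objective with reference at the
earliest-arriving receiver (smallest |Δt|; configurable). The published field
workflow uses an approximate-maximum-likelihood solver whose derivation is
not restated; under i.i.d. Gaussian timing noise the least-squares objective
is the same family. Multi-start is a coarse grid over the search box
(9×11×5 nodes by default) from which the best few nodes are polished with
bounded trust-region least squares (analytic Jacobian); starts are forced at
least one grid spacing apart so they cannot all collapse into a spurious
basin at the box edge — without this, near-dam sources reflected into the
x < 0 half-space pin the solver at the dam face. Near-coplanar receiver sets
(a pier line) trigger a warning rather than a refusal: the out-of-plane
coordinate is weakly constrained, and the generous default depth bounds act
as the prior. Messages with fewer than four receivers are skipped; attempted
fits that fail to converge are dropped but counted, which is what
tracking-efficiency denominators need.

A brute-force lattice oracle over the same objective exists for verification
only. Note that "solver and oracle agree to one lattice spacing" is a
property of well-conditioned geometries: against a thin pier-line array the
objective has a long shallow valley and the lattice argmin can legitimately
sit several spacings along it, so oracle-equivalence tests use a compact
tank-style array with sources inside the receiver hull.

Geographic coordinates: dam-local ↔ state-plane is a rigid rotation +
translation (`DamFrame`), fittable by 2-D Procrustes from the dual
coordinates printed in hydrophone-configuration tables. Latitude/longitude
are produced by an affine fit to control columns when present — adequate over
a ~1 km forebay — and omitted otherwise; no geodesy library is involved.

## Trajectory cleaning and QA

Thresholds: 45 m spatial isolation, 10 min gap split, 2 m/s implied speed
(the speed limit is approximate in the source description and configurable).
"Adjacent" means *surviving* temporal neighbors, and both the distance and
speed rules require violation on both sides so the innocent neighbor of a bad
point is not deleted; endpoints are judged by their single neighbor.
The rules iterate to a fixed point because single-pass results depend on scan
order; fragments shorter than 3 points after a gap split are dropped.
QA trimming restricts tracks to [release time, earliest downstream evidence]
and flags (rather than keeps) points when the release time is unknown.

## Route assignment

The 3-D-track method uses a box spanning the dam plus 25 m on each side and
30 m upstream; the last trimmed point's Y selects the bay, with
outside-the-piers positions mapped to the nearest bay. The last-detection
method averages the pier numbers of the first two hydrophones on different
piers of the last multi-pier message. The pier↔bay convention — bay *b* lies
between piers *b* and *b*+1, so a half-integer average maps uniquely and an
integer average tie-breaks to the lower-indexed bay — is not published; it is
documented here and configurable, including per-dam hole-numbering direction
(one studied dam numbers turbines south→north, the other north→south).

Reconciliation defaults to the 3-D-track assignment and flags (never
auto-resolves) disagreements in main route, subroute, or holes more than two
bays apart; the 'dam' main route is reserved for presence-without-assignment.
PIT detections inside a juvenile bypass upgrade powerhouse fish to the JBS
subroute, otherwise they are turbines. Operations QA flags assignments to
bays closed at passage time, suggesting the nearest open bay.

## Validation metrics

Per-point absolute differences Δx, Δy, Δz between the acoustic fix and the
GPS reference linearly interpolated at the fix time; per-axis medians
(even-count median = mean of the middle two) and RMS = √(mean Δ²). Detection
(tracking) efficiency is the fraction of known transmissions with a matching
message (successful fix) within a 0.5 s window. Binning is half-open
[10k, 10(k+1)) m on the reference distance-from-dam (X), labelled by the
upper edge; all bins out to the transect maximum are emitted.

## Problem sizes

Simulated studies in the tests use a 13-bay dam with 28 pier hydrophones,
a handful of fish over 7–15 min of transmissions, surveys of one to three bay
transects, and Monte-Carlo loops of 100 seeded runs — sizes chosen so the
full suite completes in well under a minute of simulation plus a few tens of
seconds of localization while leaving every statistical check with comfortable
sample sizes. The field-scale totals reported for the original deployment
(millions of decodes, hundreds of thousands of track points) depend on the
physical river deployment and are out of desk-scale reach by design.

## Known limitations

* No waveform-level processing (detection/decoding of acoustic signals is
  upstream of this package).
* Single scalar sound speed; no ray bending or stratification, so simulated
  Z errors are far smaller than field ones.
* The detection-probability curve, PRI-filter internals, and pier/bay
  conventions are documented stand-ins where the source material is silent.
* Survival estimation, forebay residence/tailrace egress metrics, KML export,
  and database loading are out of scope.
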