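# Methods

This note documents the model, the numerical choices and the limits of the
synthetic evaluation. It describes what the code computes; every empirical
statement here is one the test suite or `scripts/acceptance.py` computes at
run time.

## From audit log to network

The atomic observation is an action event `(clinician, specialty, patient,
timestamp, category)` with category one of condition, procedure,
medication, note, order, measurement. Events are reduced to the *set* of
distinct (clinician, patient, calendar day) triples — patient-day units —
so the analysis is invariant to how chatty a clinician's charting is
within a day. Two clinicians are tied if they share at least one
(patient, day); the weight is the count of shared patient days over the
period. This is the one-mode projection of the bipartite clinician ×
patient-day incidence matrix, with co-occurrence counted once per shared
patient day.

"Same day" means the same calendar date in a single configured timezone,
not a rolling 24-hour window (`day_binning: calendar` is the only mode).
The patient-day counting unit presupposes discrete days, and calendar
binning keeps the reduction idempotent and order-invariant; the cost is
that a pair collaborating across midnight on one shift is counted on two
days (or, if each only charts on one side of midnight, not tied at all).
Events whose timestamps have only date resolution are accepted; day
resolution is all the pipeline needs.

Study periods are inclusive date windows from the config (shipped
defaults: 2019-09-01..2019-12-31 and 2020-03-01..2020-06-30, labelled
`pre` and `intra`); events in neither window are dropped and counted, and
overlapping windows are a hard configuration error. Patients whose
exclusion flag is set (e.g. a COVID-19-positive cohort) have all their
events removed before networks are built. Events referencing patients
missing from the patient table warn rather than fail, because audit-log
extracts routinely outlive patient-table extracts. Patients are assigned
to the period containing their admission date; admission defines cohort
membership for the outcome comparison.

Clinicians active in a period but with no same-day co-occurrence stay in
the network as isolated nodes: the node set is defined by activity, and
isolated clinicians legitimately contribute to specialty-level medians
(they score 0 eigenvector, 0 betweenness, 0 eccentricity). No edge
pruning is performed by default; a `min_weight` filter exists but
defaults to 1.

## Sociometrics

All three measures are computed per connected component, from scratch.

**Eigenvector centrality** is the leading eigenvector of the component's
adjacency matrix, max-normalised to 1 within each component. Default
adjacency is binary (an edge either exists or not); patient-day weights
can be switched on. Two reasons for the binary default: it matches the
desktop network tools practitioners use for this analysis, whose
eigenvector routine ignores weights; and empirically, on these heavily
skewed patient-day weights the max-normalised *weighted* eigenvector
localises on the single densest cluster, sending most clinicians' scores
(and hence specialty medians) to ~0, which makes medians an artifact of
which pod happens to be densest rather than a measure of typical roles.

Numerics: power iteration on the shifted matrix `B = A + I` with a
uniform start vector, tolerance 1e-10 in max-norm on successive
max-normalised iterates. The `+I` shift leaves eigenvectors unchanged and
breaks the ±λ symmetry of bipartite components (a star otherwise
oscillates and never converges). The iteration is accelerated by repeated
squaring of `B` (the k-th iterate is `B^(2^k) x₀`), because
period-aggregated co-occurrence networks with several similar sub-teams
have spectral-gap ratios as small as ~1e-6, where plain iteration needs
hundreds of thousands of steps; squaring reaches the same Perron limit in
a few dozen matrix products and is exactly deterministic. Components are
dense-matrix sized (hundreds of clinicians), so the O(m²) memory of a
component's adjacency is not a concern at this scale. Per-component
computation with component-local normalisation is essential: a global
power iteration on a disconnected graph would zero every component but
the dominant one.

**Betweenness centrality** uses Brandes' dependency accumulation over
unweighted breadth-first shortest paths, with fractional counting over
shortest-path multiplicity, normalised by `(n−1)(n−2)/2` with
component-local `n` (so values lie in [0, 1]; components of size ≤ 2
score 0). Hop distances are the default because co-occurrence weights
are similarities, not costs; a `weighted_paths` flag (edge length
1/weight, Dijkstra) exists for sensitivity analysis.

**Eccentricity** is each node's maximum BFS distance within its
component; isolated nodes score 0 by convention (0 occurs only for
isolated nodes).

Specialty summaries report n, median, mean and quartiles of each metric
per specialty plus whole-network rows; a requested specialty with no
clinicians is emitted with n = 0 and null statistics rather than dropped.

## Hypothesis testing

Mann-Whitney U with midranks for ties. Dispatch: exact p by full
enumeration of the C(n₁+n₂, n₁) labelings when both samples have n ≤ 8
and the pooled sample is tie-free; otherwise the normal approximation
with tie-corrected variance and continuity correction (the underlying
computation is scipy's, wrapped behind this dispatch rule; the test suite
checks the exact branch against an independent enumeration oracle and the
normal branch against the exact one). Two designs:

* *Specialty level*: per (specialty × metric), the arrays of per-clinician
  values in the two periods. Default family: six specialties × three
  metrics = 18 tests; a specialty absent from either period is skipped
  with a logged reason and the family shrinks.
* *Network level*: per metric, the arrays of per-specialty mean values
  (one cell per specialty present in that period); family of 3.

Bonferroni within each design family (`p_adj = min(1, m·p)`, m = tests
actually run), never pooled across designs — the two designs are separate
analyses. Tests are two-sided at α = 0.05 by default even though the
substantive hypotheses are directional; two-sided is conservative and an
`alternative` option supports one-sided tests. Ties are certain for
integer eccentricities, hence the midrank/tie-correction choice. The
outcome comparison applies the same test to length of stay (m = 1) and
reports dispositions and demographics descriptively.

## The synthetic NICU

The generator exists to exercise the pipeline end to end and to test
whether the analysis *recovers known structure*, not to estimate any real
unit's parameters. It emulates: a roster of six NICU specialties plus
support staff (defaults: 120 nurses, 12 nurse practitioners, 20
residents, 15 respiratory therapists, 10 cardiac ICU nurses, 6
neonatologists, 30 support — plausible tertiary-NICU scale, documented as
arbitrary), patients admitted uniformly over a four-month window with
lognormal length of stay, and day-by-day staffing that emits 1–5 chart
events per assignment with a note/order-heavy category mix.

Staffing mechanism, with one independent lever per structural effect:

* Nurses are partitioned into pods. Each patient is admitted to a pod and
  covered daily by `nurses_per_patient_day` shifts; each bedside nurse
  takes `patients_per_nurse` patients; any slot is filled from the whole
  unit with probability `nurse_cross_coverage_prob`, and a patient boards
  in the adjacent pod for the day with probability `pod_mixing_prob`.
  Dense multi-shift nursing with high cross-coverage makes the nurse web
  the graph's core (lever for nurse eigenvector and short paths); 1:1
  single-shift nursing with sealed pods removes same-day nurse-nurse
  co-occurrence almost entirely.
* Each neonatologist is cohorted to a span of adjacent pods
  (`physician_cohort_pods`), charts on at most
  `physician_patients_per_day` patients and only on a fraction
  `physician_day_prob` of days, with attending-of-record rotation every
  `physician_rotation_days` days. Sparse pod-local charting keeps
  physicians peripheral; daily charting over a two-pod span makes them
  the only systematic inter-pod bridges (lever for neonatologist
  betweenness, and — together with sealed pods — for eccentricity, since
  inter-pod paths must then chain through physicians around the pod
  ring).
* Each patient has sticky frontline primaries (NP, resident, respiratory
  therapist) from the pod with per-day presence probabilities, an
  optional cardiac-ICU-nurse consult, and occasional one-off
  support-staff consults that hang as pendant nodes and stretch path
  lengths.

Preset parameters (the study conditions):

| knob | `pre_like` | `intra_like` |
|---|---|---|
| n_patients | 386 | 326 |
| admission window | 2019-09-01..12-31 | 2020-03-01..06-30 |
| LOS median (target) | 10.0 | 9.0 |
| LOS quartile targets | 4.0, 20.0 | 3.3, 21.8 |
| pod_count | 6 | 6 |
| nurses_per_patient_day (shifts) | 3 | 1 |
| patients_per_nurse | 2 | 1 |
| nurse_cross_coverage_prob | 0.30 | 0.02 |
| pod_mixing_prob | 0.10 | 0.02 |
| physician_cohort_pods | 1 | 2 |
| physician_patients_per_day | 2 | 18 |
| physician_day_prob | 0.35 | 1.00 |
| staffing probs (NP/res/RT) | .35/.30/.45 | .40/.25/.60 |

Cohort sizes default to 386/326 because the staffing ratios relative to
the default roster only produce realistic workloads at that scale — at a
few dozen patients a 120-nurse roster is so diluted that every specialty's
co-occurrence degree is census-limited rather than schedule-limited, and
network structure (hub identity, diameter) becomes seed noise. For small
cohorts `scaled_preset` shrinks the roster proportionally with floors
(at least a two-pod nursing staff of 18, small frontline pools, and the
full attending group, since physician rotations do not shrink with the
census) and reduces the pod count to keep ~9 nurses per pod. The
family-wise type-I study runs on this proportionally staffed 50-patient
unit: a null comparison is only meaningful when the two cohorts come from
a unit whose structure is staffing-determined rather than census-starved
(underloaded units produce cluster-level noise that unit-level rank tests
mistake for group differences — the same caution applies to real data).
Demographics, dispositions and LOS targets per preset follow the published
cohort table of the NICU population this simulator is patterned on: sex
includes an `unknown` fraction (~17.6%) because the reported female/male
counts each sum to 41.2%, implying an unreported missing category — an
inference, flagged here. LOS is lognormal with μ = ln(median) and σ
fitted to the target q3/q1 ratio; a lognormal cannot hit median 10 *and*
quartiles (4, 20) exactly (its median is the geometric mean of its
quartiles, √80 ≈ 8.94), so the generator matches the median and the
quartile ratio, giving quartiles ≈ (4.5, 22.4). Ages at admission are
mostly 0 days (inborn) with a thin geometric tail of outborn transfers.

Randomness: one root seed; each stage (patients, roster, events) draws
from a fixed substream derived via `SeedSequence([seed, stage])`, so
identical (config, seed) pairs give byte-identical CSVs and adding a
stage never perturbs earlier ones.

**What passing tests do and do not show.** The two regimes reproduce the
three reported directional effects (intra eccentricity up, nurse
eigenvector down, neonatologist betweenness up) in ≥ 90% of seeded runs,
with the corresponding specialty-level tests rejecting after Bonferroni
correction, and two same-regime cohorts reject at no more than the
nominal family-wise rate. That demonstrates the pipeline detects staffing
structure it is pointed at and does not hallucinate differences under the
null. It does not validate the tie rule against real collaboration (audit
co-occurrence includes spurious pairs and misses off-EHR interaction),
and the generator omits circadian timing, absenteeism, vendor audit-log
semantics and infection dynamics; absolute magnitudes of the synthetic
medians are not calibrated to any real unit.

## Degenerate inputs and conventions

Empty event files are valid (empty network, empty tables). A clinician id
mapped to two specialties in one dataset is a hard error. All-tied
Mann-Whitney samples give p = 1. A requested comparison specialty missing
from a period shrinks the family rather than failing. Network-level
comparison requires at least two specialties per period. Isolated-node
conventions are as above. Manifest JSON contains no timestamps, so byte
determinism holds across reruns.

## Known limitations

Single-timezone calendar-day binning (no rolling window, no per-event
timezone); undirected networks only; no sliding-window temporal variant;
betweenness is exact (no sampling), so very large components cost
O(n·m); the exact Mann-Whitney branch is limited to both n ≤ 8, matching
its use here (small-specialty comparisons fall back to the tie-corrected
normal approximation, which the suite shows agrees to < 0.02 in p at
those sizes).
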