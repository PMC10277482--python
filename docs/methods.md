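# Methods

This note documents the models, conventions and numerical choices behind
`cld4`. It is the package's own account of what is computed and why; no
number quoted here is asserted anywhere except by the tests and
`scripts/acceptance.py`, which recompute everything at run time.

## 1. The selection problem

Late micro-bioreactor screening is the first stage of cell line
development where on-line process data (pH, DO₂, temperature, gas flows,
base addition), daily off-line assays (VCD, viability, glucose, lactate),
periodic titres and harvest product quality (monomer, aggregate, fragment,
trisulfide bond) are all available for a few dozen clones at once.
Conventional selection looks mostly at titre; `cld4` formalises the
decision as a multi-criteria problem and mines the on-line data for
process risks that pure titre ranking misses.

## 2. Manufacturability index

For m clones and n criteria the index is a weighted sum

    MI_CL,i = Σ_j w_j · r_ij ,   w_j = raw_j / Σ raw ,
    r_ij = (x_ij − x_j,worst) / (x_j,best − x_j,worst) ,

where best/worst are the campaign extremes of criterion j; for
reverse-rated criteria (lactate, aggregate, fragment, trisulfide bond) the
lowest measured value is best. Both ratings and scores are bounded in
[0, 1]; a clone that is best on every criterion scores exactly 1 because
the weights are normalised. The default registry has 20 criteria —
titre (max/min/mean/end point), q_p (max/min/end point), VCD
(max/mean/end point), viability (max/min/end point), lactate
(max/mean/end point, reversed), monomer, aggregate, fragment and
trisulfide bond end points — with the trisulfide bond end point at raw
weight 3 and everything else at 1. The registry is a YAML file
(`cld4/data/criteria.yaml`) and is meant to be edited per project.

Numerical conventions, chosen where the definition is silent:

* **Degenerate criterion** (identical value for all clones): the rating is
  0/0, so the criterion is excluded and the remaining weights renormalised,
  with a log entry. An uninformative criterion should not distort scores.
* **Missing value** for clone i on criterion j: clone i's score is
  renormalised over its observed criteria and the clone flagged
  "incomplete", rather than silently imputing or zeroing.
* **Ties** in the ranking break lexicographically by clone id, making
  rankings reproducible byte for byte.

## 3. Feature engineering

Each vessel's traces reduce to summary statistics: max, min, end point,
average, sample standard deviation (n−1), cumulative, and time above/below
the controller setpoint. Conventions:

* Time above/below setpoint uses *strict* comparison against the setpoint
  itself (not the dead-band edges — the dead-band is a controller
  property). Each sample owns its forward sampling interval and the final
  sample owns none, so above + below + at-setpoint sums exactly to the run
  span; a 16-day trace sitting above setpoint scores exactly 384 h.
* Averages are plain sample means for uniformly sampled series and
  time-weighted (trapezoidal) means otherwise.
* `cumulative` is the trapezoidal time integral (time in days) for rate
  variables, and the final value for variables the registry flags as
  already cumulative (base addition volume).
* Windowed averages use half-open day windows [start, end), with the final
  window closed at the run end; day = 24 h from inoculation.
* Derived rates (the raw data records neither): specific productivity
  q_p = ΔTitre / ∫VCD dt per titre sampling interval, which with titre in
  mg/L and VCD in 10⁶ cells/mL is directly pg·cell⁻¹·day⁻¹; specific
  growth rate μ = ln(VCD₂/VCD₁)/Δt per day. The inoculation-to-first-titre
  interval is included (titre 0 at t = 0) so that four titre samples give
  four q_p values.

A 16-day pH trace at 90 s spacing holds 15,361 samples; summarising it by
six statistics is a ~2,560-fold data reduction.

The analytics feature set (24 features over productivity, growth, process
parameters and quality, including pH averages over days 0–7 and 7–14) is a
YAML plan (`cld4/data/plans.yaml`) and is configurable; the shipped list
reflects the variables a screening scientist typically inspects.

## 4. Risk analytics

All multivariate analysis standardizes first (subtract mean, divide by
sample sd; constant columns dropped with a warning), so PCA is correlation
PCA. Components come from SVD, capped at the numerical rank, with a
deterministic sign convention (the largest-magnitude loading of each
component is positive). Correlations are pairwise-complete Pearson r;
pairs with fewer than 3 complete observations are masked. Signed values
such as −0.5 are sometimes loosely labelled "R²" in the bioprocess
literature; a coefficient of determination cannot be negative, so the
signed r is what this package computes and reports.

Risk findings flag every process-feature × quality-feature pair with
|r| ≥ 0.7 (default), sorted by |r| descending. The 0.7 default matches the
weakest process-quality correlation worth acting on at this scale
(n = 48); at |r| = 0.7, r² ≈ 0.5 of the quality variance is shared.

Trisulfide-bond end points are banded low [0, 7), medium [7, 14),
high [14, ∞) percent. The bands are half-open and lower-inclusive; any
banding with touching edges needs such a convention and this one keeps 7
and 14 in the higher band.

## 5. Capacity planning

    D_product = N_patients × d_patient_year              (g/year)
    V_batch   = D_product / (T_est · N_batches · Y_DSP · P_s)   (L/batch)

The full product sits in the denominator: higher titre, more batches,
better downstream yield and higher batch success all shrink the required
working volume, and g ÷ (g·L⁻¹) = L dimensionally. T_est defaults to the
selected lead clone's end-point titre and can be overridden in metadata.

## 6. Report generation

The report is rule-based data-to-text: a fixed document plan (campaign
summary → top-clone table → risk findings → capacity recommendation →
metadata/observations) realized from a Markdown template with three token
classes — static text, `{{user.*}}` slots filled from scientist metadata,
and `{{gen.*}}` slots produced by deterministic functions of the report
context. Realization is a pure function; the report date is injected as a
parameter so identical inputs render byte-identical documents. Risk
sentences come from a finite message catalogue keyed by feature-pair
class, not free generation. Missing dose/patient metadata degrades the
capacity section to an explicit "not computed" line instead of failing
the report.

## 7. Synthetic campaign generator

The generator emulates a 48-vessel, 4-station, 16-day fed-batch screen
(11–15 mL scale): pH 7.0 ± 0.1 dead-band, DO₂ 50 %, 33 °C, sensors every
90 s, titres on days 8/10/12/14, five bolus feeds every second day from
day 3. Dynamics are phenomenological, not mechanistic:

* **Phenotypes.** A single latent "health" axis couples peak lactate
  (1.2 + 6.5·(1−h) g/L plus N(0, 0.75) residual), minimum viability
  (40 + 60·h %, ±1.3 %) and growth (logistic carrying capacity
  18 + 32·h ×10⁶ cells/mL). 72 % of non-elite clones are lactate
  *producers* (no back-metabolism: high peak and end-point lactate, more
  base addition, low health range); the rest are *consumers*. Five clones
  per 48 are *elite*: consumers with h ∈ [0.86, 0.95], q_p 11.5–14.5
  pg/cell/day (non-elite 5.5–11), dead-band position bias ∈ [−0.85, −0.55],
  minimum viability drawn in [89.2, 92] % and monomer ≥ 96.8 %. The elite
  band encodes the quality floor a lead clone must clear (end-point
  viability ≥ ~89 %, monomer ≥ ~96.6 %, zero trisulfide bond).
* **Trajectories.** Viability declines sigmoidally from 98.5 % toward the
  clone floor (later for healthy clones); viable cell density is the
  logistic total times viability; glucose is consumed in proportion to
  viable biomass with 3 g/L boluses on feed days; lactate rises smoothly
  to its peak (day ~6 for consumers, ~11 for producers) then decays to the
  end-point fraction; titre accumulates as q_p·VCD with q_p weakly
  depressed at low viability (exponent 0.12 on viability fraction), kept
  non-decreasing under assay noise by construction.
* **pH and trisulfide bond.** The realized pH trace is
  setpoint + bias·dead-band plus autocorrelated AR(1) control error
  (sd 0.018, 3 h correlation time), clipped to the dead-band, plus probe
  noise. The trisulfide-bond end point is a hinge function of the realized
  mean pH over days 0–7: zero below pH 6.96, then 150 %/pH-unit, with
  proportional (12 %) assay noise — so clones sitting low in the dead-band
  measure exactly 0 % and TSB is monotone in the dead-band position.
  With all noise scales zeroed and bias 0 the pH trace is identically the
  setpoint.
* **Calibration.** The couplings are generator parameters with documented
  targets: |r|(peak lactate, minimum viability) = 0.9 and r(viability
  drop, mean q_p) = −0.5 across the 48 clones. The defaults above recover
  both within ±0.05 and ±0.1 respectively, averaged over 10 seeds
  (verified by the acceptance tests); they are conditions of the study
  design, not outputs to be tuned per run.
* **Determinism.** Every draw derives from `config.seed` (per-vessel
  substreams), so a configuration reproduces its raw files byte for byte.

What the generator does *not* emulate: mechanistic CHO metabolism,
mixing/CFD, scale-up effects, assay drift/batch effects, missing or
mislabelled files, or correlated station-level failures. Passing tests
therefore demonstrate that the pipeline recovers structure that is present
and documented in the data; they do not validate the biology of any real
campaign.

## 8. Raw file dialect and warehouse

The micro-bioreactor vendor format is proprietary, so the package defines
an open reference dialect: one CSV per stream with header
`timestamp_s,variable,value,unit`, 12 streams per vessel (pH, DO₂,
temperature, stirrer, O₂ flow, CO₂ flow, base volume, antifoam events,
feed events, alarms, titre samples, offline samples) and 4 per station
(station temperature, station log, calibration, gas supply) — 592 files
for the default campaign — plus campaign `metadata.json` and a manifest.
Harvest quality records (monomer, aggregate, fragment, trisulfide bond)
travel as end-of-run rows in each vessel's offline-samples file; the
variable registry maps each variable to its category, unit and source
instrument and ships as editable YAML (synonyms included) so real exports
can be mapped without code changes.

The warehouse stores one record per raw row, keyed by vessel/station ID,
timestamp (seconds from inoculation) and source, tagged with one of five
categories (process parameters, growth, productivity, product quality,
metadata). Persistence is JSON Lines: streamable and diff-able. Numeric
records are deduplicated on (vessel, variable, timestamp, source); text
records (events, logs, metadata) legitimately share that key and dedupe on
the full row. Ingest is idempotent and skips malformed rows with a counted
warning.

## 9. Pipeline and problem sizes

`run_pipeline` wires simulate → ingest → features → rank → analyze →
report; each stage's outputs are pure functions of configuration and seed,
verified by SHA-256 manifest equality across reruns. The default
48-vessel campaign produces ~5.2 M warehouse records and runs end to end
in about a minute and a half on one core. The test suite exercises most
behaviour on an 8-clone, 6-day, 30-minute-interval campaign and reserves
the full 48-clone configuration for the campaign-level contract tests;
the acceptance script averages correlation recovery over 10 full
campaigns.

## 10. Known limitations

* The weighted sum is compensatory: a clone can offset poor quality with
  productivity unless quality weights are raised (hence TSB weight 3).
  No Pareto or outranking alternatives are provided.
* Minimum viability and end-point viability coincide in the simulator
  (viability declines monotonically), so those two criteria are nearly
  collinear there; on real data they differ.
* PCA handles missing values by dropping incomplete feature columns
  rather than imputing.
* The capacity model is a single steady-state equation; no cost model,
  facility fit or schedule constraints.
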