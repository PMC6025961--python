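# Model and methods

`metaswitch` simulates and analyses dynamic metabolic subpopulations in a
clonal *Bacillus subtilis* culture.  Two stochastically occupied gene-expression
states interact through the shared medium: a competence-associated state
(marked by the *sucC* promoter) whose cells secrete acetate while the culture
grows on glucose and malate, and an acetolactate-synthase state (marked by
*alsS*) that acetate induces and whose cells drain acetate into acetoin, a
pH-neutral overflow product.  The package contains an agent-based generative
model of this loop together with the estimators used on real single-cell data
— snapshot classification, lineage event/dwell/elongation statistics,
genealogy trees and metabolite phase detection — so that every estimator can
be validated against data with known ground truth.

Units everywhere: minutes, µm, mM, AU (arbitrary fluorescence units).

## Generative model

**States.**  Each cell carries two independent binary states.  Transitions
are memoryless with exponential waiting times:

- sucC+/competent: entry `k_on_sucC · quorum · W(od)`, exit `k_off_sucC`.
  Competence excitability is deliberately reduced to constant-rate Poisson
  entry/exit — the excitable-circuit dynamics behind competence are outside
  this package's scope, and a telegraph process reproduces every statistic the
  estimators consume (occupancy, episode durations, event rates).
- alsS+: entry `k0_alsS + kmax_alsS · A^h/(K_alsS^h + A^h)` at ambient acetate
  `A` (Hill induction), exit `k_off_alsS`.

`W(od)` is a density window applied in growing cultures (batch/pad):
`rise(od) · close(od)` with Hill terms rising at `K_quorum_od` (quorum
activation at moderate density) and closing at `K_close_od` (shut-off toward
stationary phase).  In the chemostatic device the window is replaced by the
scenario's fixed `media_quorum`, encoding the conditioned-media state.  A
glucose-based entry gate was tried first and rejected during calibration:
glucose stays high until late exponential phase, so an entry gate tied to it
closes too late to reproduce a mid-exponential sucC+ fraction peak.

**Growth.**  Cell length elongates exponentially,
`dL/dt = r · L`, with

```
r = r_base · g_cell · penalty_sucC^[sucC+] · penalty_alsS^[alsS+]
    · K_tox/(K_tox + A) · C/(K_carbon + C)
```

where `g_cell` is a lognormal per-cell-cycle factor (CV `growth_cv`, redrawn
at each division), the penalties are the in-state growth costs, the acetate
toxicity factor is a saturating phenomenological stand-in for the
pH/anion-stress biochemistry, and `C` is the remaining glucose+malate pool
(omitted in the device, constant on pads).  Penalties act on the exponential
rate `s`, while elongation is reported as `100·(e^{60 s} − 1)` %/hr, so the
defaults are fixed in log space — `penalty_alsS = ln(1.63)/ln(1.74)` — which
makes a 74 %/hr out-of-state rate map to exactly 63 %/hr in-state (and 67.7 to
47.4 %/hr for sucC+).  Taking the plain ratio of %/hr values instead would
miss the printed in-state rates by ~3 %/hr.

**Division** is a sizer: a cell splits on reaching `L_div`, at a site drawn
around mid-cell with CV `div_cv` (clipped to [0.1, 0.9]).  Reporter
*concentrations* are inherited unchanged by both daughters
(concentration-conserving partition).  In batch and device modes the dividing
cell keeps its identity (the device mother persists at the capped channel
end); in pad mode the mother row closes with fate `divided` and two new
daughter ids open, giving the binary genealogy that the tree builder expects.

**Reporters** are stable fluorescent proteins: concentration obeys
`dF/dt = β − r·F` with `β = beta_on` or `beta_off` by state and **no active
degradation** — dilution by growth is the only removal.  The update integrates
this exactly over each sub-step, so `F* = β/r` and relaxation is `e^{-r t}`.
Recorded fluorescence adds multiplicative lognormal measurement noise
(`meas_cv`); recorded lengths are noise-free.

**Environment.**  One well-mixed compartment per scenario, advanced by an
explicit fixed-step update at `dt = frame_interval / 10` (stiffness is mild at
default parameters; concentrations are clamped at zero via `min()` guards so
the carbon ledger stays exact):

- growth consumes glucose and malate proportionally to their abundance at
  `yield_carbon` mM per µm of new length;
- each sucC+ cell secretes acetate at `p_A · C/(K_sec + C)` — overflow
  acetate is drawn from the carbon pool at 0.5 pool-mol per acetate-mol
  (glucose → 2 acetate), which ties the end of the production phase to carbon
  exhaustion and prevents a runaway in which toxicity stalls growth while
  secretion continues;
- each alsS+ cell takes up acetate at `c_A` (capped by availability), and
  `y_acetoin` mol acetoin appear per mol acetate consumed (two
  acetate-equivalents per acetoin at the default 0.5).

Cumulative production and consumption are accumulated alongside the state, so
`produced − consumed = ΔA` holds to floating-point accuracy in any closed run.

**Scenarios.**
- *batch*: 300 founders, 22 mM glucose + 50 mM malate, 600 min at 12-min
  frames.  The duration matches the growth-curve window the analyses target;
  in much longer runs the culture sits in a zero-growth state where dilution
  stops and a stable reporter makes the relative (mean + 2 SD) classifier
  drift — a real limitation of stable reporters, not of the classifier.
- *mother_machine*: dead-end channels of capacity 6 (washout is silent
  removal, fate `washed_out`), environment fixed.  Presets:
  `sucC_mother_machine` (2 mM acetate, quorum 0.15 → ~1.7 rare events/100 hr)
  and `alsS_mother_machine` (12 mM acetate, quorum 0 → frequent alsS pulses).
  Each preset rescales `r_base` so out-of-state cells elongate at the
  condition's observed rate (67.7 / 74 %/hr) under the ambient toxicity.
- *pad*: 8 founders, 20 mM starting acetate (mid-exponential-like), 22 h at
  12-min frames; carbon is treated as an agarose reservoir (constant), only
  acetate/acetoin evolve.

All randomness flows from one `numpy` generator seeded by the scenario; the
same seed and config reproduce every table bit for bit.

## Parameter defaults and provenance

All defaults live in `src/metaswitch/defaults.yaml`.  Anchored values:
`k_off_sucC = 1/252 min⁻¹` (mean episode 252 min), the two growth penalties
(from 47.4/67.7 and 63/74 %/hr), `r_base = ln(1.74)/60` (74 %/hr), batch
carbon 22 mM glucose + 50 mM malate, pad acetate 20 mM, 12-min frames.
The remaining constants are the package's own calibration, chosen once so the
defaults reproduce the qualitative phenomenology and then frozen:
`K_alsS = 10 mM, h = 2` (half-induction below the 20 mM mid-exponential
level), `k_off_alsS = 1/150 min⁻¹` (alsS pulses shorter and more frequent
than competence episodes), `k_on_sucC = 1.6e-3 min⁻¹` with the OD window
(classified sucC+ pulse of ~4–6% against the ~2.3% Gaussian floor of the 2-SD
rule), `K_tox = 25 mM`, `p_A = 7e-4` and `c_A = 1.6e-4 mM·min⁻¹`/cell (peak
acetate ~25 mM at mid/late exponential, drawn down but not exhausted by
600 min), `beta_on/beta_off = 80/8 AU·min⁻¹` (on-state steady level ~10× the
basal one, matching the >3-fold tails seen in snapshots), `meas_cv = 0.03`,
`growth_cv = 0.08`, `L_div = 4 µm`, `div_cv = 0.05`.

## Estimators

**Skewness** is the adjusted Fisher–Pearson statistic
`g1·√(n(n−1))/(n−2)` — the common statistics-package default; the estimator
name is recorded in outputs.

**Positive cells**: value ≥ mean + k·SD (inclusive), sample SD, k = 2,
computed per snapshot — never pooled across time points, because the
fractions of interest are reported at specific culture densities.  A
zero-variance snapshot returns zero positives with a warning.  Note the rule
has an intrinsic floor: on pure Gaussian noise it labels ~2.3% of cells
positive, so classified-fraction time courses never drop to zero.

**Events** open at the first frame at or above threshold after a
sub-threshold frame and close at the first frame below (optional hysteresis
`h·threshold`, optional 3-frame median pre-filter; minimal event length one
frame).  Boundary-touching events are censored: excluded from dwell
statistics (a dwell needs both crossings) but counted in `events_per_100hr`
(an onset does not).  `dwell_min = n_frames × frame_interval` exactly; the
reported corrected mean adds `frame_interval/2` for interval censoring at
frame resolution.  For real fluorescence traces the per-movie default
threshold is mean + 2 SD of all frame values (consistent with the snapshot
rule), overridable.

Two known biases are documented rather than hidden.  (1) Threshold crossing
on a *stable* reporter is lag-censored: with dilution-only turnover
(1/r ≈ 110 min) short episodes never cross threshold and crossing times lag
state changes, which distorts the mean dwell by tens of percent in either
direction depending on the threshold.  Estimator-validation studies therefore
run the event machinery on the recorded state columns of synthetic lineage
tables, where the only distortions are frame discretisation and censoring.
(2) Excluding right-censored events length-biases the dwell mean downward by
roughly `mean²/T_movie` (−2.6% at a 252-min mean over 72-h movies, verified
against a pure telegraph oracle); movie length is chosen so this sits well
inside the 10% recovery band.

**Elongation** is the least-squares slope `s` of ln(length) against time over
a window of ≥3 frames with no division inside (a division is recognised as a
frame-to-frame length drop below 0.7), reported as `100·(e^{60 s} − 1)` %/hr
so that one doubling per hour reads 100 %/hr.  The estimator is invariant to
the length unit and exact on noiseless exponentials.

**Per-state growth** splits each cell cycle at event boundaries and fits
elongation on segments of constant event coverage (≥3 frames); a window is
assigned "on" when ≥50% of its frames lie inside an event (ties → on).
Whole-cycle windows were rejected during validation: straddling windows pull
the on-class up by ~1.3 %/hr, which exceeds 3 SEM once thousands of windows
accumulate.  Class summaries are mean ± SEM with the window count; the
headline comparison expects ≥50 windows per class.

**Genealogy**: pad tables become a `networkx` digraph; every division must
have exactly two daughters, birth times must increase along lineages, orphan
parent references are reported by id.  Newick export writes one line per
founder with branch lengths equal to cell-cycle durations
(`n_frames × frame_interval`) and optional NHX `expr=` annotations (per-cycle
mean alsS fluorescence); a matching parser provides exact round trips and the
output is cross-checked against an independent Newick reader in the tests.

**Metabolite phases**: derivative by central differences (one-sided at the
boundaries), 3-point moving-average smoothing, magnitudes ≤ eps
(default 0.005 mM/min, an HPLC-scale floor) treated as zero.  The production
interval is the longest positive run and consumption the longest negative run
(first-run rule by flag); a run's start extends to the previous sample, where
the sign change occurred; endpoints are reported at sample times, not
interpolated, because real sampling is sparse.  The peak is the raw series
maximum.  Phase/fraction alignment reports each reporter's argmax time, its
containing phase (production checked first; intervals inclusive) and the
fraction of each phase during which the reporter exceeds half its maximum.

**Dose response**: bounded least squares on
`baseline + amplitude·d^h/(K^h + d^h)` (amplitude, baseline ∈ [0,1], K > 0,
h ∈ [0.5, 6]), K initialised at the dose nearest half-maximal response and
h at 2 — robust on 3–8-dose designs.  Flat responses return amplitude ≈ 0
with K and h flagged non-identifiable (NaN).  A single 8-dose dataset at
noise σ = 0.02 leaves h poorly identified in ~10% of noise draws, so
recovery studies fit several replicate datasets and report the median.

## What the synthetic data does and does not emulate

Emulated: right-skewed unimodal snapshot distributions with a high tail
(mixture of basal cells, actively expressing cells and decaying ex-expressers
under measurement noise); two-state switching lineages under chemostatic and
cumulative environments; mother-machine queues with washout; full pad
genealogies; the rise-then-fall acetate curve with concomitant acetoin rise;
the ΔcomK and ΔalsS knockout contrasts; the acetate dose response of alsS
activation.

Not emulated: excitable competence dynamics (entry is Poisson), spatial
structure and mechanics on pads, nutrient/oxygen gradients, pH and anion
biochemistry (toxicity is one saturating factor), segmentation and tracking
artefacts (lengths are exact; fluorescence noise is iid lognormal),
photobleaching and reporter maturation, and any acetoin re-consumption.
Passing tests therefore demonstrate that the estimators are correct on data
satisfying the model's assumptions — not that real micrographs are free of
the tracking and background-correction issues these estimators inherit.

## Numerical choices and degenerate inputs

Fixed-step environment update at `frame_interval/10`; exact exponential
reporter integration per sub-step; switching sampled per sub-step with
`p = 1 − e^{−k·dt}` (discretisation error ~dt/2 ≪ frame interval); all
concentrations clamped at zero through availability caps so ledgers stay
exact; division-site fractions clipped to [0.1, 0.9]; `L_div = ∞` disables
division (founders then start at 2 µm).  Degenerate inputs fail loudly:
zero-variance samples (skewness error / classification warning), all-censored
dwell input (error carrying the censored count), non-monotone time vectors,
orphan lineage references, non-binary divisions, zero observation time.

## Problem sizes

Validation studies are sized for laptop-scale runs while keeping Monte-Carlo
error inside each tolerance: the default batch culture (300 founders →
~6,000 cells, 600 min), device runs up to 150 channels × 96 h (~14,000
mother-hours, ≥300 completed episodes, >1e4 cell-hours of occupancy), the
per-state growth study at 6 channels × 36 h (~80 on-windows and ~900
off-windows), and 30 device runs for the dose-response monotonicity mean.
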