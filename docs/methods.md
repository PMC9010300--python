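# Methods

## The model

A methyl probe exchanging between a ground conformation A and a sparsely
populated excited conformation B is described by four kinds of parameters:

* `kex = k_AB + k_BA` — the exchange rate (1/s), shared by every probe
  reporting on the same process, with `k_AB = p_b * kex` and
  `k_BA = (1 - p_b) * kex`;
* `p_b` — the excited-state population, constrained to (0, 0.5) to break
  the `p_b <-> 1 - p_b` labelling symmetry;
* `dw_H`, `dw_C` — per-residue 1H and 13C chemical-shift differences
  (excited minus ground) in ppm, shared across static fields;
* `r2_0` — the exchange-free intrinsic transverse relaxation rate of each
  curve (one per residue, coherence type and field).  `r2_0` is not part of
  the exchange model itself but is required by any dispersion fit; ground
  and excited state are assumed to share it, the standard simplification
  when nothing constrains their difference.

During a constant-time CPMG element of length `T_relax` containing `N`
refocusing pulses (`nu_cpmg = N / T_relax`; delay `1/nu_cpmg` between pulse
centres), exchange dephasing is partially refocused, giving the measured

```
R2eff(nu_cpmg) = -(1 / T_relax) * ln(I(nu_cpmg) / I0)
```

its characteristic dispersion.  Requested frequencies are snapped to the
nearest integer `N`, with a warning when the relative snap error exceeds 2%.

## Forward models

Single-quantum (SQ) coherences are propagated with the 2x2 complex
two-site evolution matrix; an ideal 180-degree pulse is complex
conjugation, so a pair of echoes is the linear map `U conj(U) conj(U) U`
with `U = expm(L tau)`.  The closed form evaluates integer matrix powers of
this echo-pair block through its analytic eigendecomposition — the same
quantity the classical Carver-Richards expression approximates, but exact:
Carver-Richards retains only the slowly decaying eigenvalue and deviates
from the explicit propagator by up to a few 1/s once `p_b * dw` is large
(e.g. ~2.4 1/s at `p_b = 0.1`, `dw_C = 2 ppm`, 800 MHz).  The classical
formula is still exposed (`carver_richards_r2eff`) and verified against the
Luz-Meiboom limit in fast exchange.

Multiple-quantum (MQ) coherence is modelled with the standard
single-pathway treatment: the selected 1H/13C coherence alternates between
a manifold evolving at `dw_C - dw_H` and one at `-(dw_C + dw_H)` at every
13C refocusing pulse, and the central 1H inversion is absorbed by
real-part detection (conjugating the remainder of the train does not change
the detected component).  Because the two manifolds mix both nuclei's
shifts asymmetrically in time, MQ dispersion depends on `dw_H`, `dw_C`
*and their relative sign*, while a global sign flip is invisible — the key
qualitative difference from SQ data, which are blind to the sign of a
single `dw`.  With `dw_H = 0` the MQ expression collapses to the SQ one
exactly.  An earlier design that propagated a symmetric DQ+ZQ
superposition was discarded: it carries an exact conjugation+swap symmetry
that erases relative-sign sensitivity and does not represent the pathway
selection of the real experiment.

Both coherence families have two independent implementations: the fast
eigen/matrix-power closed forms used in fitting, and a step-by-step
propagator (`scipy.linalg.expm` per delay, one step per pulse) used as the
oracle.  They agree to machine precision; the test suite enforces
< 0.5 1/s over a seeded sweep of `kex` in [100, 3000] 1/s, `p_b` in
[0.005, 0.2], `|dw_C|` up to 3 ppm, `|dw_H|` up to 0.3 ppm at both fields.
The exact propagator shows tiny (< 0.05 1/s) odd/even pulse-count parity
effects, so "monotone decay toward `r2_0`" is asserted up to that
tolerance, together with the `O(1/nu^2)` refocusing tail.

All ppm-to-rad/s conversions go through the single frequency-ratio
constant `gamma_C / gamma_H = 0.251450`.

## Fitting

Weighted least squares (`scipy.optimize.least_squares`, trust-region
reflective) minimises `sum(((obs - calc) / sigma)^2)`.

* **Individual fits.**  Each dispersive residue is fit alone (own `kex`,
  `p_b`) from a multi-start grid, `kex` in {100, 250, 500, 1000, 2000,
  3000} x `p_b` in {0.005, 0.01, 0.05, 0.1, 0.2}: the objective is
  multimodal and a single start is not trustworthy.  Each start gets a
  short exploratory solve (8 function evaluations); the best two are
  refined to convergence (relative chi-square change < 1e-8, at most 500
  evaluations).  Residues whose largest dispersion amplitude is below
  twice the median noise are flagged `no_dispersion` — their exchange
  parameters are reported but not identifiable.
* **Global fit.**  `kex` and `p_b` are shared; shifts stay per-residue,
  `r2_0` per curve (per field — whether the study shared it between fields
  is not recorded; a config switch covers both).  The start is the median
  of the individual fits; if that stalls above reduced chi-square 1.5 the
  multi-start grid is replayed.  The Jacobian's block-sparsity
  (shared parameters + per-residue + per-curve columns) is declared to the
  solver, which makes finite differencing O(1) rather than O(n_params).
* **Pruning.**  After each global fit, each residue's group residual
  `chi2_group` is compared with its individual `chi2_indiv`; residues with
  ratio > 2 (strict) are removed — all offenders at once by default, the
  single worst per round as a config option — and the fit repeated, at
  most 10 rounds.  Pruning to fewer than two residues raises: the data do
  not support one mutually consistent process.
* **Errors.**  One-sigma uncertainties come from the covariance matrix
  (SVD-based pseudo-inverse of `J^T J` at the optimum).  Singular
  directions (condition number > 1e8) are flagged unidentifiable and their
  errors reported as infinite rather than spuriously small.  A Monte-Carlo
  check (50 replicate datasets) verifies the covariance error agrees with
  the empirical scatter of recovered `kex` within a factor of 2.
* **Bounds.**  `kex` in (10, 1e4) 1/s, `p_b` in (1e-4, 0.5), `|dw_H|` <= 1
  ppm (signed — it carries the relative sign), `dw_C` in [0, 6] ppm (the
  magnitude; the absolute sign is not encoded in dispersion data and is
  attached downstream), `r2_0` in (0, 200) 1/s.

A residue counts as *dynamic* when its dispersion amplitude — `R2eff` at
the slowest minus the fastest pulsing rate, endpoint duplicates averaged —
exceeds 2 1/s in any experiment.  Note the amplitude is not monotone in
`dw_C`: in slow exchange a very large shift difference is not refocused
even at the fastest pulsing rate, which shrinks the endpoint difference
again.

Measurement weights come from replicated `nu_cpmg` points: the pooled
intensity SD over replicate groups (n-1 denominator), propagated through
the intensity equation as `sigma / (T_relax * I)` and floored point-wise
by the spectral-noise propagation.  Taking the maximum of a noisy SD
estimate and the true floor overstates sigma slightly, which is why
correctly specified fits settle at reduced chi-square ~0.8 rather than
exactly 1; the acceptance band [0.7, 1.3] covers this deliberately.

## Shift analysis

* **CSP.**  `delta = sqrt(dH^2 + (0.25 * dC)^2)`; "perturbed" residues are
  those above the mean CSP (default) or above a fixed 0.04 ppm cutoff
  (cross-check mode).
* **Sign determination.**  Dispersion fitting yields `|dw_C|` only.  The
  sign comes from comparing the exchange-shifted ground-line position
  between HSQC-type (SQ) and HMQC-type (MQ) spectra at one field (default)
  or between HSQC spectra at two fields.  Predicted positions use the
  imaginary part of the slowly decaying eigenvalue of the free-precession
  exchange matrix per coherence — standard and adequate at small `p_b`,
  and testable against the propagator — with the HMQC 13C position the
  mean of the two MQ manifolds' shifts.  The SQ/MQ position difference is
  second order in `dw_H`, so probes with sizeable 1H shift differences
  determine signs most reliably; when the predicted or observed difference
  is below the supplied position uncertainty the result is `undetermined`
  (0), and reconstruction then emits both candidates flagged ambiguous.
* **State-model discrimination.**  Four shift tables (two grounds, two
  reconstructed excited states) are compared pairwise on 13C (1H as
  secondary evidence).  Residues whose ground-state shifts already differ
  between nucleotide forms are excluded — the bound nucleotide alone can
  explain them.  A residue is off-diagonal when its difference exceeds
  `z = 3` pooled sigmas; the visual scatter-plot judgement of the original
  analysis has no printed criterion, so the z-threshold is this package's
  computable substitute and is config-exposed.  The two-state hypothesis
  (one conformational pair, differentially populated) fails if ADP and
  ATP* discord; the three-state hypothesis (common excited state) fails if
  ATP* and ADP* discord; whatever survives is the minimal consistent
  model.

## Synthetic data

The generator emulates the study design: 24 resolved Ile delta1-methyl
probes (three more overlap and are omitted by default), MQ CPMG at 600 and
800 MHz (grids 80-880 and 80-1000 Hz, `T_relax` 25 ms), 1H SQ CPMG
(66-1000 Hz at 30 ms, or 80-1000 Hz at 25 ms), 13C SQ for the mutant
scenario, with two duplicated points per 600 MHz dataset and three per 800
MHz dataset.  Scenario truths: ATP (`kex` 510 1/s, `p_b` 0.83%, 9
dispersive probes), ADP (1194 1/s, 10%, 6 probes, three of them with
substantial `dw_H`), K118N (450 1/s, 1.6%, ATP's probe pattern).  These
global pairs are the only literature-anchored truths; per-residue shift
differences are drawn per seed from plausible methyl ranges (`|dw_C|`
0.5-2.5 ppm, `|dw_H|` up to 0.05 ppm, or 0.08-0.15 ppm for the 1H-active
ADP probes), since the per-residue values are published only as figures.
Intensity noise (SD 0.004 of the reference intensity) reproduces
`sigma_R2eff` of roughly 0.2-0.4 1/s, the order of magnitude of the
reported error bars; noise is added independently to every replicate and
to the reference intensity, and R2eff plus uncertainties are then derived
exactly as for real data.  Everything is deterministic given scenario and
seed.

What the generator does *not* emulate: spectral lineshapes and peak
overlap, temperature or concentration effects, pulse imperfections and
off-resonance effects, differential ground/excited intrinsic relaxation,
and any deviation from two-state kinetics.  Passing recovery tests
therefore show that the pipeline inverts its own measurement model at
realistic noise — not that real spectra are free of these further
complications.

Shift-table scenarios instantiate the 2-/3-/4-state hypotheses directly
(with "boxed" residues given purely nucleotide-chemical ground-state
differences, kept disjoint from the conformationally dynamic set so the
two effects cannot cancel), and sign-determination inputs come from the
same eigenvalue oracle the analysis uses, plus position noise.

## Problem sizes

Recovery checks run the full pipeline (generate, classify, individually
fit, globally fit with pruning) over 10 seeds per scenario — roughly 10-25
seconds per seed on one core, dominated by the multi-start individual
fits.  The acceptance script reproduces the ADP/ATP population fold-change
from 10 paired seeds.  These sizes keep the whole suite within a
half-hour on a single core while leaving the medians stable.

## Known limitations

* The MQ forward model assumes ideal pulses and pathway selection; real
  MQ data carry small artifacts the model cannot represent.
* Carver-Richards is provided for reference but is not used in fitting;
  analyses wanting the classical formula should expect the documented
  bias at large `p_b * dw`.
* Covariance errors assume a locally quadratic objective; strongly
  unidentifiable fits (flat dispersions) are flagged rather than given
  meaningful errors.
* The state-model verdict depends on the chosen `z` and on the exclusion
  list; both are inputs, not outputs, of the analysis.
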