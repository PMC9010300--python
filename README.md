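# cpmgdisp

Analysis of μs–ms conformational exchange from CPMG relaxation-dispersion
NMR, built for methyl-TROSY studies of large proteins such as monomeric
(G-)actin, where a sparsely populated excited conformation is invisible in
spectra but betrays itself through exchange broadening.

A methyl probe interconverting between a ground state A and an excited
state B (populations p_a = 1 − p_b and p_b, exchange rate
k_ex = k_AB + k_BA with k_AB = p_b·k_ex) shows an effective transverse
relaxation rate

    R₂eff(ν_CPMG) = −(1/T_relax) · ln(I(ν_CPMG)/I₀)

that depends on the repetition rate ν_CPMG of refocusing pulses in a
constant-time CPMG element.  Fitting R₂eff(ν_CPMG) across two static
fields and several coherence types to the two-state exchange model yields
k_ex, p_b and the per-residue chemical-shift differences |Δω| between the
states; comparing peak positions between HSQC- and HMQC-type spectra then
fixes the *sign* of Δω_C, so the excited state's chemical shifts can be
reconstructed as δ* = δ + sign·|Δω| and compared across ligand states to
count how many distinct conformations the data demand.

The package covers the full pipeline:

* **`cpmgdisp.spin_models`** — forward models: exact closed forms and an
  explicit Bloch–McConnell pulse-train propagator for ¹H/¹³C
  multiple-quantum (MQ) and ¹H or ¹³C single-quantum (SQ) CPMG, the
  intensity→R₂eff transform, rate algebra and unit bridges.  MQ
  dispersion senses both Δω_H and Δω_C *and their relative sign*; SQ is
  sign-blind.
* **`cpmgdisp.dispersion_fit`** — per-residue fits, then a global fit
  sharing (k_ex, p_b) across residues with iterative χ²-ratio pruning
  (residues with χ²_group/χ²_indiv > 2 are dropped and the fit repeated),
  covariance errors, the ΔR₂ > 2 s⁻¹ dynamic-residue classifier, and
  replicate-based error propagation.
* **`cpmgdisp.shift_analysis`** — chemical-shift perturbation maps
  (Δ = √(δH² + (0.25·δC)²)), Δω sign determination from SQ/MQ peak
  positions, excited-state shift reconstruction, and 2-/3-/4-state
  model discrimination with ground-state-perturbed residues excluded.
* **`cpmgdisp.synthetic_data`** — scenario generators emulating the
  measurement design (two fields, MQ+SQ grids, duplicated points,
  intensity-level noise) with known ground truth for every stage.
* **`cpmgdisp.io_cli`** — plain-TSV formats with provenance headers and
  the `cpmgdisp` command-line pipeline.

## Worked example

Simulate the ADP-state scenario (k_ex = 1194 s⁻¹, p_b = 10%, six
dispersive isoleucine methyls, MQ + ¹H SQ at 600 and 800 MHz) and fit it:

```sh
cpmgdisp simulate --scenario ADP --seed 3 --outdir run
cpmgdisp fit --input run/ADP_dispersion.tsv --outdir run
```

which prints

```
kex = 1169.1 1/s, p_b = 10.219 %, reduced chi2 = 1.085 (6 residues)
```

and writes `run/fit_report.txt`:

```
kex_s = 1169.097
kex_err_s = 20.153
p_b = 0.102187
p_b_err = 0.001268
chi2 = 310.429
n_data = 324
n_params = 38
reduced_chi2 = 1.0854
dynamic_threshold_s = 2.0
n_residues = 6
pruning_iterations = 1
pruning_1_ratios = I317=1.02, I34=1.12, I64=1.00, I71=1.01, I75=1.02, I85=1.02
pruning_1_removed = none
```

Reading: the six residues classified as dynamic (ΔR₂ > 2 s⁻¹) were fit
globally to one exchange process; the recovered k_ex = 1169 ± 20 s⁻¹ and
p_b = 10.22 ± 0.13 % bracket the generating truth (1194 s⁻¹, 10 %), the
reduced χ² near 1 says the two-state model accounts for the data at the
measurement noise, and no residue was pruned — all six report the same
process.  `run/fit_params.tsv` carries the per-residue |Δω_C| and Δω_H in
ppm with covariance errors.

The same pipeline is available as library calls
(`generate_dispersion_dataset`, `classify_dynamic_residues`,
`fit_global`, …), and the remaining subcommands (`csp`, `signs`,
`statemodel`, `report`) carry the analysis through excited-state shift
reconstruction and conformational-state counting.

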