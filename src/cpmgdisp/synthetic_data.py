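"""Synthetic dispersion datasets, shift tables and sign-determination inputs.

The generator emulates the measurement design of a methyl-TROSY CPMG
study of a ~42 kDa protein: ~27 Ile delta1-methyl probes (24 resolved), a
subset of which feel a shared two-state exchange process; 1H/13C MQ and
1H (or 13C) SQ constant-time CPMG profiles at 600 and 800 MHz with
duplicated nu_cpmg points for error estimation; Gaussian noise applied at
the peak-intensity level.  Three ready-made scenarios carry the exchange
parameters of the study conditions this package targets:

========  =======  ======  ==========================================
scenario  kex /s   p_b     dispersive probes
========  =======  ======  ==========================================
ATP       510      0.0083  9 of 24, spread over all four subdomains
ADP       1194     0.10    6 of 24, mostly subdomains 1-2, 1H-active
K118N     450      0.016   same pattern as ATP (13C SQ instead of 1H)
========  =======  ======  ==========================================

Per-residue shift differences are drawn per seed from plausible methyl
ranges (|dw_c| 0.5-2.5 ppm, |dw_h| up to 0.15 ppm) — the global (kex,
p_b) pairs are the only literature-anchored truths.  Every routine is
deterministic given its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_SEED
from .dispersion_fit import propagate_duplicate_errors
from .shift_analysis import (
    ShiftTable,
    apparent_shift_mq_c_ppm,
    apparent_shift_sq_ppm,
)
from .spin_models import (
    DispersionCurve,
    ExperimentGeometry,
    TwoStateParams,
    closed_form_r2eff,
)

__all__ = [
    "ExperimentDesign",
    "ScenarioSpec",
    "atp_scenario",
    "adp_scenario",
    "k118n_scenario",
    "scenario_by_name",
    "generate_dispersion_dataset",
    "generate_shift_scenario",
    "generate_sign_inputs",
]

#: Ile residues resolved in the methyl spectra (the overlapped
#: I136/I309/I369 cluster is omitted by default).  Labels beyond the
#: dynamically characterised set are synthetic fillers chosen to bring
#: the count to 24 resolved probes.
RESOLVED_RESIDUES = (
    "I4", "I34", "I43", "I64", "I71", "I75", "I85", "I93", "I104", "I122",
    "I129", "I151", "I165", "I175", "I192", "I208", "I250", "I274", "I282",
    "I289", "I317", "I327", "I341", "I357",
)

ATP_DISPERSIVE = ("I64", "I75", "I175", "I208", "I274", "I282", "I289", "I317", "I327")
ADP_DISPERSIVE = ("I34", "I64", "I71", "I75", "I85", "I317")
ADP_H_ACTIVE = ("I34", "I71", "I85")  # probes with substantial 1H shift changes


@dataclass(frozen=True)
class ExperimentDesign:
    """One experiment of a scenario: coherence, field, constant-time delay,
    pulse-count grid and which counts are duplicated once more."""

    coherence_type: str
    field_h1: float
    t_relax: float
    pulse_counts: tuple
    duplicates: tuple = ()

    def geometry(self) -> ExperimentGeometry:
        counts = list(self.pulse_counts) + list(self.duplicates)
        grid = tuple(n / self.t_relax for n in counts)
        return ExperimentGeometry(self.coherence_type, self.field_h1, self.t_relax, grid)


# Grid templates.  MQ grids: 80-880 Hz at 600 MHz and 80-1000 Hz at
# 800 MHz with T_relax = 25 ms; 1H SQ grids: 66-1000 Hz at T_relax =
# 30 ms (ATP) or 80-1000 Hz at 25 ms (ADP).  Duplicated points: two per
# 600 MHz dataset and three per 800 MHz dataset.
_MQ_600 = ExperimentDesign("MQ_HC", 600.0, 0.025, (2, 3, 4, 5, 6, 8, 10, 12, 14, 18, 22), (2, 10))
_MQ_800 = ExperimentDesign("MQ_HC", 800.0, 0.025, (2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25), (2, 10, 25))
_SQH_600_30 = ExperimentDesign("SQ_H", 600.0, 0.030, (2, 3, 4, 6, 8, 10, 12, 15, 18, 24, 30), (2, 12))
_SQH_800_30 = ExperimentDesign("SQ_H", 800.0, 0.030, (2, 3, 4, 6, 8, 10, 12, 15, 18, 24, 30), (2, 12, 30))
_SQH_600_25 = ExperimentDesign("SQ_H", 600.0, 0.025, (2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25), (2, 10))
_SQH_800_25 = ExperimentDesign("SQ_H", 800.0, 0.025, (2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25), (2, 10, 25))
_SQC_600 = ExperimentDesign("SQ_C", 600.0, 0.025, (2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25), (2, 10))
_SQC_800 = ExperimentDesign("SQ_C", 800.0, 0.025, (2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25), (2, 10, 25))


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete recipe for one synthetic dispersion dataset."""

    name: str
    kex: float
    p_b: float
    dw: dict                    # residue -> (dw_h, dw_c) ppm, signed
    experiments: tuple
    r2_0_range: tuple = (12.0, 25.0)
    noise_sigma_i: float = 0.004  # intensity noise, units of the reference
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not 0 < self.p_b < 0.5:
            raise ValueError(f"p_b must lie in (0, 0.5), got {self.p_b}")
        if self.kex <= 0:
            raise ValueError(f"kex must be positive, got {self.kex}")


def _draw_dw(rng, dispersive, h_scale=(0.0, 0.05), c_scale=(0.5, 2.5), h_active=(),
             h_active_scale=(0.08, 0.15)):
    """Per-residue shift differences: zero for quiet residues, drawn with
    random sign from the given ppm ranges for dispersive ones."""
    dw = {res: (0.0, 0.0) for res in RESOLVED_RESIDUES}
    for res in dispersive:
        lo, hi = h_active_scale if res in h_active else h_scale
        dw_h = rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)
        dw_c = rng.choice([-1.0, 1.0]) * rng.uniform(*c_scale)
        dw[res] = (float(dw_h), float(dw_c))
    return dw


def atp_scenario(seed=DEFAULT_SEED) -> ScenarioSpec:
    """ATP-bound form: slow concerted exchange felt across the molecule,
    13C-dominated (1H SQ dispersions stay small)."""
    rng = np.random.default_rng([seed, 11])
    return ScenarioSpec(
        name="ATP",
        kex=510.0,
        p_b=0.0083,
        dw=_draw_dw(rng, ATP_DISPERSIVE),
        experiments=(_MQ_600, _MQ_800, _SQH_600_30, _SQH_800_30),
        seed=seed,
    )


def adp_scenario(seed=DEFAULT_SEED) -> ScenarioSpec:
    """ADP-bound form: faster exchange, ~12-fold larger excited-state
    population, with substantial 1H contributions for several probes."""
    rng = np.random.default_rng([seed, 13])
    return ScenarioSpec(
        name="ADP",
        kex=1194.0,
        p_b=0.10,
        dw=_draw_dw(rng, ADP_DISPERSIVE, h_active=ADP_H_ACTIVE),
        experiments=(_MQ_600, _MQ_800, _SQH_600_25, _SQH_800_25),
        seed=seed,
    )


def k118n_scenario(seed=DEFAULT_SEED) -> ScenarioSpec:
    """Fast-nucleating point mutant: the ATP exchange pattern with roughly
    twice the excited-state population; 13C SQ replaces 1H SQ."""
    rng = np.random.default_rng([seed, 17])
    return ScenarioSpec(
        name="K118N",
        kex=450.0,
        p_b=0.016,
        dw=_draw_dw(rng, ATP_DISPERSIVE),
        experiments=(_MQ_600, _MQ_800, _SQC_600, _SQC_800),
        seed=seed,
    )


_SCENARIOS = {"ATP": atp_scenario, "ADP": adp_scenario, "K118N": k118n_scenario}


def scenario_by_name(name, seed=DEFAULT_SEED) -> ScenarioSpec:
    try:
        return _SCENARIOS[name.upper()](seed)
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}"
        ) from None


def generate_dispersion_dataset(spec: ScenarioSpec):
    """Simulate a full dispersion dataset from a scenario.

    Intensities come from the forward model through the constant-time
    decay, ``I(nu) = I0 * exp(-R2eff * t_relax)``; Gaussian noise of SD
    ``spec.noise_sigma_i`` is added independently to every measured point
    (duplicates included) and to the reference intensity.  R2eff and its
    per-point sigma are then derived exactly as for real data (intensity
    equation + pooled duplicate errors floored by the noise estimate).

    Returns ``(residue_curves, truth)`` where ``residue_curves`` maps
    residue -> list of DispersionCurve and ``truth`` records every
    generating parameter for recovery tests.
    """
    rng = np.random.default_rng([spec.seed, 29])
    residue_curves = {res: [] for res in spec.dw}
    truth_r2 = {}
    for design in spec.experiments:
        geometry = design.geometry()
        nu_actual = geometry.nu_actual
        for res, (dw_h, dw_c) in spec.dw.items():
            r2_0 = float(rng.uniform(*spec.r2_0_range))
            params = TwoStateParams(
                kex=spec.kex, p_b=spec.p_b, dw_h=dw_h, dw_c=dw_c, r2_0=r2_0
            )
            r2_true = closed_form_r2eff(params, geometry)
            i_true = np.exp(-r2_true * design.t_relax)
            i_obs = i_true + rng.normal(0.0, spec.noise_sigma_i, size=i_true.shape)
            i0_obs = 1.0 + float(rng.normal(0.0, spec.noise_sigma_i))
            if spec.noise_sigma_i == 0.0:
                r2_obs = r2_true.copy()
                sigma = np.full_like(r2_obs, 1e-6)  # exact data still need weights
            else:
                if np.any(i_obs <= 0) or i0_obs <= 0:
                    raise RuntimeError(
                        f"noise drove an intensity non-positive for {res}; "
                        f"lower noise_sigma_i or the exchange amplitude"
                    )
                r2_obs = -np.log(i_obs / i0_obs) / design.t_relax
                sigma = propagate_duplicate_errors(
                    nu_actual, i_obs, design.t_relax, sigma_i=spec.noise_sigma_i
                )
            curve = DispersionCurve(
                residue_id=res,
                geometry=geometry,
                points=np.column_stack([nu_actual, r2_obs, sigma]),
                reference_intensity=i0_obs if spec.noise_sigma_i else 1.0,
            )
            residue_curves[res].append(curve)
            label = f"{res}:{design.coherence_type}:{design.field_h1:g}:{design.t_relax:g}"
            truth_r2[label] = r2_0
    truth = {
        "name": spec.name,
        "kex": spec.kex,
        "p_b": spec.p_b,
        "dw": dict(spec.dw),
        "r2_0": truth_r2,
        "seed": spec.seed,
        "noise_sigma_i": spec.noise_sigma_i,
    }
    return residue_curves, truth


# ---------------------------------------------------------------------------
# Shift-table scenarios for state-model discrimination
# ---------------------------------------------------------------------------

def generate_shift_scenario(
    hypothesis,
    separation=10.0,
    seed=DEFAULT_SEED,
    n_residues=20,
    n_excluded=4,
    n_dynamic=12,
    sigma_h=0.004,
    sigma_c=0.02,
):
    """Four shift tables (ATP, ADP, ATP*, ADP*) realising one hypothesis.

    ``separation`` is the conformational shift-difference scale in units
    of the pooled 13C sigma; at 0 all four tables coincide.  ``n_excluded``
    residues get ground-state differences between the nucleotide forms
    (the "boxed" residues) to exercise the exclusion logic.  Returns
    ``(tables, exclusion)``.
    """
    if hypothesis not in ("two_state", "three_state", "four_state"):
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng([seed, 31])
    residues = [f"I{int(n)}" for n in sorted(rng.choice(np.arange(4, 380), n_residues, replace=False))]
    base_c = rng.uniform(9.0, 15.5, n_residues)
    base_h = rng.uniform(0.2, 1.2, n_residues)

    pooled_c = np.sqrt(2.0) * sigma_c
    pooled_h = np.sqrt(2.0) * sigma_h
    scale_c = separation * pooled_c
    scale_h = separation * pooled_h

    # boxed residues are drawn first and kept out of the dynamic set, so
    # their ATP/ADP ground-state difference is purely nucleotide-chemical
    excluded = list(rng.choice(residues, n_excluded, replace=False))
    dynamic = set(rng.choice([r for r in residues if r not in excluded],
                             n_dynamic, replace=False))

    def offsets(unit):
        """Per-residue conformational offset of magnitude >= `unit` scale,
        zero for non-dynamic residues."""
        mag_c = unit * scale_c * rng.uniform(1.0, 1.5, n_residues)
        mag_h = unit * scale_h * rng.uniform(1.0, 1.5, n_residues)
        sign = rng.choice([-1.0, 1.0], n_residues)
        mask = np.array([r in dynamic for r in residues], dtype=float)
        return sign * mag_c * mask, sign * mag_h * mask

    zero = (np.zeros(n_residues), np.zeros(n_residues))
    if hypothesis == "two_state":
        conf = offsets(1.0)
        state_offsets = {"ATP": zero, "ADP": conf, "ATP*": conf, "ADP*": zero}
    elif hypothesis == "three_state":
        d1 = offsets(1.0)
        d2 = (-2.0 * d1[0], -2.0 * d1[1])  # common excited state, away from both grounds
        state_offsets = {"ATP": zero, "ADP": d1, "ATP*": d2, "ADP*": d2}
    else:  # four_state
        d1 = offsets(1.0)
        d2 = (-d1[0], -d1[1])
        d3 = (2.0 * d1[0], 2.0 * d1[1])
        state_offsets = {"ATP": zero, "ADP": d1, "ATP*": d2, "ADP*": d3}

    # "boxed" residues: nucleotide chemistry moves the ADP-side grounds
    # (and their excited states) regardless of hypothesis
    chem_c = np.zeros(n_residues)
    chem_h = np.zeros(n_residues)
    for res in excluded:
        i = residues.index(res)
        chem_c[i] = rng.choice([-1.0, 1.0]) * max(scale_c, 10.0 * pooled_c)
        chem_h[i] = rng.choice([-1.0, 1.0]) * max(scale_h, 10.0 * pooled_h)

    tables = {}
    for label, (off_c, off_h) in state_offsets.items():
        adp_side = label in ("ADP", "ADP*")
        dc = base_c + off_c + (chem_c if adp_side else 0.0)
        dh = base_h + off_h + (chem_h if adp_side else 0.0)
        noise_c = rng.normal(0.0, sigma_c, n_residues) if sigma_c else 0.0
        noise_h = rng.normal(0.0, sigma_h, n_residues) if sigma_h else 0.0
        tables[label] = ShiftTable.from_records(
            label,
            [
                (res, float(dh[i] + (noise_h[i] if sigma_h else 0.0)),
                 float(dc[i] + (noise_c[i] if sigma_c else 0.0)),
                 sigma_h, sigma_c)
                for i, res in enumerate(residues)
            ],
        )
    return tables, excluded


def generate_sign_inputs(params, geometry, seed=DEFAULT_SEED,
                         ground=(0.8, 12.5), position_sigma=(0.001, 0.005)):
    """Noisy SQ (HSQC-type) and MQ (HMQC-type) peak positions for one
    residue, generated from the eigenvalue peak-position oracle.

    ``ground`` is the true ground-state (dH, dC) in ppm; ``position_sigma``
    the (1H, 13C) position noise in ppm.  Returns a dict with the observed
    ``sq`` and ``mq`` peaks, the noiseless predictions and the noise used.
    """
    rng = np.random.default_rng([seed, 37])
    dh0, dc0 = ground
    sig_h, sig_c = position_sigma
    shift_sq_c = apparent_shift_sq_ppm(
        params.dw_c, "C13", geometry.field_h1, params.kex, params.p_b
    )
    shift_sq_h = apparent_shift_sq_ppm(
        params.dw_h, "H1", geometry.field_h1, params.kex, params.p_b
    )
    shift_mq_c = apparent_shift_mq_c_ppm(
        params.dw_h, params.dw_c, geometry.field_h1, params.kex, params.p_b
    )
    sq_true = (dh0 + shift_sq_h, dc0 + shift_sq_c)
    mq_true = (dh0 + shift_sq_h, dc0 + shift_mq_c)
    sq_obs = (sq_true[0] + rng.normal(0, sig_h), sq_true[1] + rng.normal(0, sig_c))
    mq_obs = (mq_true[0] + rng.normal(0, sig_h), mq_true[1] + rng.normal(0, sig_c))
    return {
        "sq": sq_obs,
        "mq": mq_obs,
        "sq_true": sq_true,
        "mq_true": mq_true,
        "position_sigma": position_sigma,
    }
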