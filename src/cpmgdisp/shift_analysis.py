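"""Chemical-shift analyses downstream of dispersion fitting.

Four related tasks live here:

* chemical-shift-perturbation (CSP) mapping between two ligand states of
  the same protein, ``delta = sqrt(dH^2 + (0.25 * dC)^2)``;
* determination of the *sign* of the 13C shift difference between ground
  and excited state, by comparing exchange-shifted peak positions between
  HSQC (SQ) and HMQC (MQ) spectra at one field, or between HSQC spectra
  at two fields — dispersion fitting yields only ``|dw|``;
* reconstruction of excited-state chemical shifts,
  ``delta_excited = delta_ground + sign * |dw|``;
* discrimination among 2-/3-/4-state conformational equilibria by
  comparing ground and excited shift tables across ligand states
  (residues whose *ground-state* shifts already differ between ligand
  states are excluded: the bound nucleotide alone can explain them).

Peak-position predictions use the imaginary part of the slowly decaying
eigenvalue of the free-precession exchange matrix for each coherence —
the standard small-``p_b`` treatment, adequate far from coalescence and
directly testable against the explicit propagator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spin_models import nucleus_frequency_mhz, ppm_to_rad_s

__all__ = [
    "ShiftTable",
    "StateModelVerdict",
    "csp",
    "csp_between",
    "flag_perturbed",
    "exchange_shift_rad",
    "apparent_shift_sq_ppm",
    "apparent_shift_mq_c_ppm",
    "determine_sign",
    "determine_sign_two_field",
    "reconstruct_excited_shifts",
    "compare_state_models",
]

#: Fixed CSP significance cutoff (ppm) used by the fixed-threshold mode.
CSP_FIXED_CUTOFF = 0.04

#: Comparisons evaluated by the state-model discrimination, in the order
#: they bear on the hypotheses.
STATE_MODEL_PAIRS = (
    ("ADP", "ATP*"),
    ("ATP", "ADP*"),
    ("ATP*", "ADP*"),
    ("ATP", "ADP"),
)


@dataclass
class ShiftTable:
    """Residue-indexed (1H, 13C) chemical shifts for one state.

    ``data`` is a DataFrame indexed by residue label with columns
    ``delta_h_ppm``, ``delta_c_ppm``, ``sigma_h``, ``sigma_c``.
    """

    state_label: str
    data: pd.DataFrame

    REQUIRED = ("delta_h_ppm", "delta_c_ppm", "sigma_h", "sigma_c")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"shift table missing columns: {missing}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate residue labels: {dupes}")
        if (self.data[["sigma_h", "sigma_c"]] < 0).any().any():
            raise ValueError("shift uncertainties must be non-negative")

    @classmethod
    def from_records(cls, state_label, records):
        """Build from an iterable of (residue, dH, dC, sigma_h, sigma_c)."""
        df = pd.DataFrame(
            records,
            columns=["residue", "delta_h_ppm", "delta_c_ppm", "sigma_h", "sigma_c"],
        ).set_index("residue")
        return cls(state_label, df)

    @property
    def residues(self):
        return list(self.data.index)


# ---------------------------------------------------------------------------
# CSP mapping
# ---------------------------------------------------------------------------

def csp(delta_h, delta_c):
    """Combined 1H/13C chemical-shift distance in ppm.

    ``delta = sqrt(dH^2 + (0.25 * dC)^2)`` — the 13C axis is compressed
    four-fold to put both nuclei on a comparable ppm scale.  Vectorised.
    """
    dh = np.asarray(delta_h, dtype=float)
    dc = np.asarray(delta_c, dtype=float)
    out = np.sqrt(dh**2 + (0.25 * dc) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_between(table_a: ShiftTable, table_b: ShiftTable) -> pd.DataFrame:
    """Per-residue shift differences (b - a) and CSP over shared residues."""
    shared = table_a.data.index.intersection(table_b.data.index)
    if shared.empty:
        raise ValueError(
            f"no shared residues between {table_a.state_label!r} and "
            f"{table_b.state_label!r}"
        )
    dh = table_b.data.loc[shared, "delta_h_ppm"] - table_a.data.loc[shared, "delta_h_ppm"]
    dc = table_b.data.loc[shared, "delta_c_ppm"] - table_a.data.loc[shared, "delta_c_ppm"]
    return pd.DataFrame(
        {"delta_h_ppm": dh, "delta_c_ppm": dc, "csp_ppm": csp(dh.values, dc.values)},
        index=shared,
    )


def flag_perturbed(csp_table, mode="mean", cutoff=CSP_FIXED_CUTOFF):
    """Residues with a significant CSP.

    ``mode='mean'`` flags residues strictly above the mean CSP of all
    residues; ``mode='fixed'`` uses the fixed ppm ``cutoff``.  Accepts the
    frame returned by :func:`csp_between` or a bare Series of CSP values.
    """
    vals = csp_table["csp_ppm"] if isinstance(csp_table, pd.DataFrame) else csp_table
    if len(vals) < 2:
        raise ValueError("need at least 2 residues to judge perturbation")
    if mode == "mean":
        thr = float(vals.mean())
    elif mode == "fixed":
        thr = float(cutoff)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'mean' or 'fixed'")
    # strict inequality, robust to float noise when all values coincide
    return list(vals.index[vals > thr + 1e-12])


# ---------------------------------------------------------------------------
# Exchange-induced peak positions and sign determination
# ---------------------------------------------------------------------------

def exchange_shift_rad(dw_rad, kex, p_b):
    """Exchange-induced displacement (rad/s) of the observed ground-state
    line: the imaginary part of the slowly decaying eigenvalue of the
    free-precession two-site evolution matrix."""
    k_ab = p_b * kex
    k_ba = (1.0 - p_b) * kex
    mat = np.array(
        [[-k_ab + 0j, k_ba], [k_ab, 1j * dw_rad - k_ba]], dtype=complex
    )
    eig = np.linalg.eigvals(mat)
    slow = eig[np.argmax(eig.real)]
    return float(slow.imag)


def apparent_shift_sq_ppm(dw_ppm, nucleus, field_h1, kex, p_b):
    """Apparent ppm displacement of the ground line in a single-quantum
    (HSQC-type) spectrum."""
    dw_rad = ppm_to_rad_s(dw_ppm, nucleus, field_h1)
    shift_rad = exchange_shift_rad(dw_rad, kex, p_b)
    return shift_rad / (2.0 * np.pi * nucleus_frequency_mhz(nucleus, field_h1))


def apparent_shift_mq_c_ppm(dw_h_ppm, dw_c_ppm, field_h1, kex, p_b):
    """Apparent 13C ppm displacement of the ground line in a
    multiple-quantum (HMQC-type) spectrum.

    The 13C dimension of an HMQC accrues half its phase as double-quantum
    (evolving at ``w_H + w_C``) and half as zero-quantum (``w_C - w_H``),
    so the apparent 13C displacement is the mean of the two coherences'
    eigenvalue shifts.
    """
    dwh = ppm_to_rad_s(dw_h_ppm, "H1", field_h1)
    dwc = ppm_to_rad_s(dw_c_ppm, "C13", field_h1)
    s_dq = exchange_shift_rad(dwh + dwc, kex, p_b)
    s_zq = exchange_shift_rad(dwc - dwh, kex, p_b)
    shift_rad = 0.5 * (s_dq + s_zq)
    return shift_rad / (2.0 * np.pi * nucleus_frequency_mhz("C13", field_h1))


def determine_sign(ground_peak_sq, ground_peak_mq, params, geometry, position_sigma):
    """Sign of ``dw_c`` from the SQ/MQ peak-position comparison at one field.

    ``ground_peak_sq`` and ``ground_peak_mq`` are observed ``(dH, dC)``
    positions (ppm) of the same residue in HSQC- and HMQC-type spectra.
    The exchange-shifted 13C position differs between the two spectra in a
    direction set by ``sign(dw_c)``; the observed difference is compared
    with the eigenvalue-predicted difference computed from the fitted
    ``(kex, p_b, |dw|)``.

    Returns ``+1``, ``-1``, or ``0`` when the prediction or the
    observation is smaller than ``position_sigma`` (undetermined).
    """
    if params.dw_c is None or np.isnan(params.dw_c):
        raise ValueError("sign determination needs a fitted |dw_c|")
    abs_dw_c = abs(params.dw_c)
    d_obs = ground_peak_mq[1] - ground_peak_sq[1]
    sq = apparent_shift_sq_ppm(abs_dw_c, "C13", geometry.field_h1, params.kex, params.p_b)
    mq = apparent_shift_mq_c_ppm(
        params.dw_h, abs_dw_c, geometry.field_h1, params.kex, params.p_b
    )
    d_pred = mq - sq  # prediction for dw_c > 0
    if abs(d_pred) < position_sigma or abs(d_obs) < position_sigma:
        return 0
    return +1 if d_obs * d_pred > 0 else -1


def determine_sign_two_field(
    peak_low, peak_high, params, field_low, field_high, position_sigma
):
    """Sign of ``dw_c`` from HSQC 13C positions at two static fields.

    The exchange-induced ppm displacement of the ground line is
    field-dependent in intermediate exchange; its change from
    ``field_low`` to ``field_high`` carries the sign of ``dw_c``.
    """
    if params.dw_c is None or np.isnan(params.dw_c):
        raise ValueError("sign determination needs a fitted |dw_c|")
    abs_dw_c = abs(params.dw_c)
    d_obs = peak_high[1] - peak_low[1]
    d_pred = apparent_shift_sq_ppm(
        abs_dw_c, "C13", field_high, params.kex, params.p_b
    ) - apparent_shift_sq_ppm(abs_dw_c, "C13", field_low, params.kex, params.p_b)
    if abs(d_pred) < position_sigma or abs(d_obs) < position_sigma:
        return 0
    return +1 if d_obs * d_pred > 0 else -1


# ---------------------------------------------------------------------------
# Excited-state reconstruction
# ---------------------------------------------------------------------------

def reconstruct_excited_shifts(ground: ShiftTable, fit, signs) -> ShiftTable:
    """Excited-state shift table ``delta_ground + sign * |dw|``.

    ``fit`` is a FitResult (its ``dw_c`` entries are magnitudes and its
    ``dw_h`` entries carry the 1H/13C *relative* sign); ``signs`` maps
    residue to the absolute sign of ``dw_c`` (+1, -1, or 0 when
    undetermined).  An undetermined residue yields two candidate rows
    (labels suffixed ``(+)`` / ``(-)``) flagged ``ambiguous``.
    Uncertainties combine the ground-state sigma and the fitted dw error
    in quadrature.
    """
    rows = []
    for res in fit.residues:
        if res not in ground.data.index:
            raise KeyError(
                f"residue {res!r} is in the fit but missing from the "
                f"{ground.state_label!r} shift table"
            )
        g = ground.data.loc[res]
        dw_c_err = fit.errors.get(f"dw_c:{res}", 0.0)
        dw_h_err = fit.errors.get(f"dw_h:{res}", 0.0)
        sig_h = float(np.hypot(g.sigma_h, dw_h_err)) if np.isfinite(dw_h_err) else float(g.sigma_h)
        sig_c = float(np.hypot(g.sigma_c, dw_c_err)) if np.isfinite(dw_c_err) else float(g.sigma_c)
        sign_c = signs.get(res, 0)
        candidates = [sign_c] if sign_c in (+1, -1) else [+1, -1]
        for cand in candidates:
            label = res if sign_c else f"{res}({'+' if cand > 0 else '-'})"
            rows.append(
                {
                    "residue": label,
                    "delta_h_ppm": float(g.delta_h_ppm + cand * fit.dw_h[res]),
                    "delta_c_ppm": float(g.delta_c_ppm + cand * abs(fit.dw_c[res])),
                    "sigma_h": sig_h,
                    "sigma_c": sig_c,
                    "ambiguous": sign_c == 0,
                }
            )
    df = pd.DataFrame(rows).set_index("residue")
    return ShiftTable(f"{ground.state_label}*", df)


# ---------------------------------------------------------------------------
# State-model discrimination
# ---------------------------------------------------------------------------

@dataclass
class StateModelVerdict:
    """Outcome of the 2-/3-/4-state comparison.

    ``table`` holds one row per (comparison pair, residue) with the shift
    difference, pooled sigma, and off-diagonal/excluded flags; ``verdict``
    is the minimal model consistent with the non-excluded residues.
    """

    table: pd.DataFrame
    verdict: str
    ruled_out: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


def _pair_differences(tables, pair, exclusion, z, column, sigma_column):
    a, b = tables[pair[0]], tables[pair[1]]
    shared = a.data.index.intersection(b.data.index)
    rows = []
    for res in shared:
        # strip reconstruction-candidate suffixes when matching exclusions
        base = res.split("(")[0]
        diff = float(b.data.loc[res, column] - a.data.loc[res, column])
        pooled = float(
            np.hypot(a.data.loc[res, sigma_column], b.data.loc[res, sigma_column])
        )
        rows.append(
            {
                "pair": f"{pair[0]} vs {pair[1]}",
                "residue": res,
                "difference_ppm": diff,
                "pooled_sigma": pooled,
                "off_diagonal": abs(diff) > z * pooled,
                "excluded": base in exclusion,
            }
        )
    return rows


def compare_state_models(tables, exclusion=(), z=3.0, nucleus="C"):
    """Discriminate among 2-/3-/4-state conformational equilibria.

    ``tables`` maps the state labels ``ATP``, ``ADP``, ``ATP*``, ``ADP*``
    to ShiftTable objects; ``exclusion`` lists residues whose ground-state
    shifts differ between nucleotide forms (these are never counted as
    evidence).  A residue is "off-diagonal" in a comparison when its shift
    difference exceeds ``z`` pooled sigmas.

    The two-state hypothesis (one pair of conformations, differentially
    populated) predicts ADP == ATP*; the three-state hypothesis (distinct
    grounds, common excited state) predicts ATP* == ADP*.  Whichever
    concordances survive determine the minimal consistent model:
    ``2-state``, ``3-state``, ``4-state``, or ``indistinguishable`` when
    nothing separates at all.
    """
    missing = [k for k in ("ATP", "ADP", "ATP*", "ADP*") if k not in tables]
    if missing:
        raise ValueError(f"missing state tables: {missing}")
    column = "delta_c_ppm" if nucleus == "C" else "delta_h_ppm"
    sigma_column = "sigma_c" if nucleus == "C" else "sigma_h"
    exclusion = set(exclusion)

    rows = []
    for pair in STATE_MODEL_PAIRS:
        rows.extend(_pair_differences(tables, pair, exclusion, z, column, sigma_column))
    table = pd.DataFrame(rows)

    informative = table[~table.excluded]
    if informative.empty:
        return StateModelVerdict(table=table, verdict="insufficient evidence")

    discord = {}
    counts = {}
    for pair in STATE_MODEL_PAIRS:
        name = f"{pair[0]} vs {pair[1]}"
        sub = informative[informative.pair == name]
        discord[name] = bool(sub.off_diagonal.any())
        counts[name] = (int(sub.off_diagonal.sum()), int(len(sub)))

    ruled_out = {
        "2-state": discord["ADP vs ATP*"],
        "3-state": discord["ATP* vs ADP*"],
    }
    if not any(discord.values()):
        verdict = "indistinguishable"
    elif not ruled_out["2-state"]:
        verdict = "2-state"
    elif not ruled_out["3-state"]:
        verdict = "3-state"
    else:
        verdict = "4-state"
    return StateModelVerdict(table=table, verdict=verdict, ruled_out=ruled_out, counts=counts)
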