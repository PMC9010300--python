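"""Per-residue and global fitting of multi-field MQ/SQ dispersion data.

The fitting strategy mirrors standard relaxation-dispersion practice:

1. every residue showing dispersion is first fit *individually* to the
   two-state model (its own ``kex``, ``p_b``, shift differences and
   per-curve intrinsic rates), yielding a residual ``chi2_indiv``;
2. all residues are then fit *globally* with ``kex`` and ``p_b`` shared
   across the group (shift differences stay per-residue, in ppm, shared
   across fields; intrinsic rates stay per-curve), yielding per-residue
   residuals ``chi2_group``;
3. residues whose ``chi2_group / chi2_indiv`` ratio exceeds 2 are pruned
   and the global fit repeated until all remaining ratios are below the
   threshold — the survivors report a single mutually consistent exchange
   process.

Parameter uncertainties are one-sigma values from the covariance matrix
(inverse curvature) at the optimum.  The sign of the 13C shift difference
is not determined by dispersion data; fits parameterise ``|dw_c|`` (the
relative 1H/13C sign, which MQ data do sense, lives on ``dw_h``).  Signs
are attached downstream by the shift-analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy import sparse

from .spin_models import (
    DispersionCurve,
    TwoStateParams,
    closed_form_r2eff_group,
    compute_delta_r2,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "PruningIteration",
    "PruningLog",
    "fit_single_residue",
    "fit_global",
    "estimate_errors",
    "classify_dynamic_residues",
    "propagate_duplicate_errors",
]


@dataclass
class FitConfig:
    """Tunable knobs of the fitting pipeline (defaults are the package's
    standard conditions; see the methods note for rationale)."""

    kex_bounds: tuple = (10.0, 1.0e4)
    p_b_bounds: tuple = (1.0e-4, 0.5)
    dw_h_max: float = 1.0     # ppm, fitted signed
    dw_c_max: float = 6.0     # ppm, fitted as a magnitude
    r2_0_bounds: tuple = (0.0, 200.0)
    #: multi-start grid for individual fits
    kex_starts: tuple = (100.0, 250.0, 500.0, 1000.0, 2000.0, 3000.0)
    p_b_starts: tuple = (0.005, 0.01, 0.05, 0.1, 0.2)
    #: function evaluations allotted to each exploratory start
    start_max_nfev: int = 8
    #: number of best exploratory starts refined to convergence
    polish_top: int = 2
    ftol: float = 1.0e-8
    max_nfev: int = 500
    prune_ratio: float = 2.0
    max_prune_iterations: int = 10
    #: remove every offending residue per iteration (the quoted rule);
    #: False removes only the worst offender each round
    prune_all_at_once: bool = True
    dynamic_threshold: float = 2.0  # 1/s, dispersion-amplitude cutoff
    #: if the global fit from the consensus start stalls above this reduced
    #: chi2, re-try from the multi-start grid
    global_retry_redchi2: float = 1.5


def _curve_label(curve: DispersionCurve) -> str:
    g = curve.geometry
    return f"{curve.residue_id}:{g.coherence_type}:{g.field_h1:g}:{g.t_relax:g}"


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

class _Layout:
    """Maps the flat optimiser vector onto (kex, p_b, per-residue dw,
    per-curve r2_0) and back, and evaluates residuals in batched passes
    (all curves sharing one geometry are computed together)."""

    def __init__(self, residue_curves: dict, config: FitConfig):
        self.residues = list(residue_curves)
        self.curves = [c for res in self.residues for c in residue_curves[res]]
        self.config = config
        self.idx_dw_h = {}
        self.idx_dw_c = {}
        self.idx_r2 = {}
        i = 2
        for res in self.residues:
            self.idx_dw_h[res] = i
            self.idx_dw_c[res] = i + 1
            i += 2
        for c in self.curves:
            self.idx_r2[_curve_label(c)] = i
            i += 1
        self.n_params = i
        self.n_data = sum(len(c.points) for c in self.curves)
        self._build_groups()

    def _build_groups(self):
        """Batch curves by geometry; residual rows are laid out group by
        group (ordering is arbitrary but fixed, matching jac_sparsity)."""
        by_geom = {}
        for c in self.curves:
            by_geom.setdefault(c.geometry, []).append(c)
        self.groups = []
        pos = 0
        for geom, curves in by_geom.items():
            n = len(curves) * len(curves[0].points)
            self.groups.append(
                {
                    "geometry": geom,
                    "curves": curves,
                    "obs": np.array([c.r2eff for c in curves]),
                    "sigma": np.array([c.sigma for c in curves]),
                    "i_dw_h": np.array([self.idx_dw_h[c.residue_id] for c in curves]),
                    "i_dw_c": np.array([self.idx_dw_c[c.residue_id] for c in curves]),
                    "i_r2": np.array([self.idx_r2[_curve_label(c)] for c in curves]),
                    "rows": slice(pos, pos + n),
                }
            )
            pos += n

    @property
    def param_names(self):
        names = ["kex", "p_b"]
        for res in self.residues:
            names += [f"dw_h:{res}", f"dw_c:{res}"]
        names += [f"r2_0:{lbl}" for lbl in self.idx_r2]
        return names

    def bounds(self):
        cfg = self.config
        lo = np.empty(self.n_params)
        hi = np.empty(self.n_params)
        lo[0], hi[0] = cfg.kex_bounds
        lo[1], hi[1] = cfg.p_b_bounds
        for res in self.residues:
            lo[self.idx_dw_h[res]], hi[self.idx_dw_h[res]] = -cfg.dw_h_max, cfg.dw_h_max
            lo[self.idx_dw_c[res]], hi[self.idx_dw_c[res]] = 0.0, cfg.dw_c_max
        for j in self.idx_r2.values():
            lo[j], hi[j] = cfg.r2_0_bounds
        return lo, hi

    def params_for(self, x, curve):
        res = curve.residue_id
        return TwoStateParams(
            kex=x[0],
            p_b=x[1],
            dw_h=x[self.idx_dw_h[res]],
            dw_c=x[self.idx_dw_c[res]],
            r2_0=x[self.idx_r2[_curve_label(curve)]],
        )

    def _group_calc(self, x, group):
        return closed_form_r2eff_group(
            x[0],
            x[1],
            x[group["i_dw_h"]],
            x[group["i_dw_c"]],
            x[group["i_r2"]],
            group["geometry"],
        )

    def residuals(self, x):
        out = np.empty(self.n_data)
        for group in self.groups:
            calc = self._group_calc(x, group)
            out[group["rows"]] = ((calc - group["obs"]) / group["sigma"]).ravel()
        return out

    def chi2_by_residue(self, x):
        chi2 = {res: 0.0 for res in self.residues}
        for group in self.groups:
            calc = self._group_calc(x, group)
            per_curve = np.sum(((calc - group["obs"]) / group["sigma"]) ** 2, axis=1)
            for c, val in zip(group["curves"], per_curve):
                chi2[c.residue_id] += float(val)
        return chi2

    def jac_sparsity(self):
        """Block structure of the Jacobian: every point depends on the two
        shared parameters, its residue's shifts and its curve's r2_0."""
        mat = sparse.lil_matrix((self.n_data, self.n_params), dtype=np.uint8)
        for group in self.groups:
            npts = group["obs"].shape[1]
            start = group["rows"].start
            for j, c in enumerate(group["curves"]):
                rows = slice(start + j * npts, start + (j + 1) * npts)
                mat[rows, 0] = 1
                mat[rows, 1] = 1
                mat[rows, self.idx_dw_h[c.residue_id]] = 1
                mat[rows, self.idx_dw_c[c.residue_id]] = 1
                mat[rows, self.idx_r2[_curve_label(c)]] = 1
        return mat

    def x_scale(self):
        scale = np.ones(self.n_params)
        scale[0] = 500.0   # kex, 1/s
        scale[1] = 0.02    # p_b
        scale[2 : 2 + 2 * len(self.residues)] = 0.5  # dw, ppm
        scale[2 + 2 * len(self.residues) :] = 5.0    # r2_0, 1/s
        return scale


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Optimised two-state parameters with covariance-derived errors and
    chi-square bookkeeping."""

    kex: float
    p_b: float
    dw_h: dict
    dw_c: dict
    r2_0: dict
    errors: dict
    chi2: float
    n_data: int
    n_params: int
    chi2_by_residue: dict
    flags: list = field(default_factory=list)
    param_names: list = field(default_factory=list)
    cov: np.ndarray | None = None
    jac: np.ndarray | None = None

    @property
    def reduced_chi2(self):
        dof = self.n_data - self.n_params
        if dof <= 0:
            raise ValueError("fit has no degrees of freedom")
        return self.chi2 / dof

    @property
    def residues(self):
        return list(self.dw_c)

    def params_for_curve(self, curve: DispersionCurve) -> TwoStateParams:
        return TwoStateParams(
            kex=self.kex,
            p_b=self.p_b,
            dw_h=self.dw_h[curve.residue_id],
            dw_c=self.dw_c[curve.residue_id],
            r2_0=self.r2_0[_curve_label(curve)],
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-residue parameter table (ppm shifts and their errors)."""
        rows = []
        for res in self.residues:
            rows.append(
                {
                    "residue": res,
                    "dw_h_ppm": self.dw_h[res],
                    "dw_h_err": self.errors.get(f"dw_h:{res}", np.nan),
                    "dw_c_ppm": self.dw_c[res],
                    "dw_c_err": self.errors.get(f"dw_c:{res}", np.nan),
                    "chi2": self.chi2_by_residue.get(res, np.nan),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PruningIteration:
    residues: list
    ratios: dict
    removed: list


@dataclass
class PruningLog:
    iterations: list = field(default_factory=list)

    @property
    def final_residues(self):
        last = self.iterations[-1]
        return [r for r in last.residues if r not in last.removed]


# ---------------------------------------------------------------------------
# Error estimation
# ---------------------------------------------------------------------------

def estimate_errors(jac, param_names, cond_threshold=1.0e8):
    """One-sigma parameter uncertainties from the curvature at the optimum.

    With residuals already weighted by their sigma, the covariance matrix is
    ``(J^T J)^-1`` evaluated via SVD.  Directions whose singular value is
    smaller than ``s_max / cond_threshold`` are unidentifiable; the
    parameters dominating them are reported in ``flags`` and their errors
    set to infinity rather than a spuriously precise number.

    Returns ``(errors, cov, flags)``.
    """
    jac = np.asarray(jac)
    _, s, vt = np.linalg.svd(jac, full_matrices=False)
    flags = []
    s_max = s[0] if s.size else 0.0
    good = s > s_max / cond_threshold
    if not np.all(good):
        for row in np.flatnonzero(~good):
            dominant = int(np.argmax(np.abs(vt[row])))
            flags.append(f"unidentifiable:{param_names[dominant]}")
    s_inv2 = np.where(good, 1.0 / np.maximum(s, 1e-300) ** 2, 0.0)
    cov = (vt.T * s_inv2) @ vt
    err = np.sqrt(np.diag(cov))
    # mark errors along dead directions as infinite
    if not np.all(good):
        dead = (np.abs(vt[~good]) > 0.5).any(axis=0)
        err = np.where(dead, np.inf, err)
    errors = dict(zip(param_names, err))
    return errors, cov, flags


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _initial_r2(curve):
    return float(np.clip(np.min(curve.r2eff), 0.5, 150.0))


def _has_dispersion(curves, factor=2.0):
    """True if any curve's amplitude beats ``factor`` times its noise."""
    for c in curves:
        if len(np.unique(c.nu_cpmg)) < 2:
            continue
        if compute_delta_r2(c) > factor * float(np.median(c.sigma)):
            return True
    return False


def _solve(layout, x0, max_nfev, config, jac_sparsity=None):
    lo, hi = layout.bounds()
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
    return least_squares(
        layout.residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        ftol=config.ftol,
        xtol=1e-10,
        gtol=1e-8,
        max_nfev=max_nfev,
        x_scale=layout.x_scale(),
        jac_sparsity=jac_sparsity,
    )


def _result_from_solution(layout, sol, flags):
    errors, cov, err_flags = estimate_errors(
        sol.jac.toarray() if sparse.issparse(sol.jac) else sol.jac,
        layout.param_names,
    )
    x = sol.x
    dw_h = {res: float(x[layout.idx_dw_h[res]]) for res in layout.residues}
    dw_c = {res: float(x[layout.idx_dw_c[res]]) for res in layout.residues}
    r2_0 = {lbl: float(x[j]) for lbl, j in layout.idx_r2.items()}
    return FitResult(
        kex=float(x[0]),
        p_b=float(x[1]),
        dw_h=dw_h,
        dw_c=dw_c,
        r2_0=r2_0,
        errors=errors,
        chi2=float(np.sum(sol.fun**2)),
        n_data=layout.n_data,
        n_params=layout.n_params,
        chi2_by_residue=layout.chi2_by_residue(x),
        flags=flags + err_flags,
        param_names=layout.param_names,
        cov=cov,
        jac=sol.jac.toarray() if sparse.issparse(sol.jac) else sol.jac,
    )


def fit_single_residue(curves, config=None):
    """Weighted least-squares fit of one residue's curves (all coherence
    types and fields simultaneously) to the two-state model.

    Multi-start initialisation over a (kex, p_b) grid guards against the
    multimodal dispersion objective; each start gets a cheap exploratory
    solve and the best few are refined to convergence.  Residues whose
    dispersion amplitude is below the noise are fitted anyway but flagged
    ``no_dispersion`` — their exchange parameters are not identifiable.
    """
    config = config or FitConfig()
    curves = list(curves)
    if not curves:
        raise ValueError("no curves supplied")
    res_ids = {c.residue_id for c in curves}
    if len(res_ids) != 1:
        raise ValueError(f"curves span several residues: {sorted(res_ids)}")
    if not any(len(np.unique(c.nu_cpmg)) >= 4 for c in curves):
        raise ValueError("need at least one curve with >= 4 distinct nu_cpmg points")
    residue = curves[0].residue_id
    layout = _Layout({residue: curves}, config)
    if layout.n_data <= layout.n_params:
        raise ValueError("not enough data points for the number of parameters")

    flags = []
    if not _has_dispersion(curves):
        flags.append("no_dispersion")

    r2_init = [_initial_r2(c) for c in curves]
    trials = []
    for kex0 in config.kex_starts:
        for pb0 in config.p_b_starts:
            x0 = np.concatenate([[kex0, pb0, 0.05, 1.0], r2_init])
            trials.append(_solve(layout, x0, config.start_max_nfev, config))
    trials.sort(key=lambda s: s.cost)
    polished = [
        _solve(layout, s.x, config.max_nfev, config)
        for s in trials[: config.polish_top]
    ]
    best = min(polished, key=lambda s: s.cost)
    return _result_from_solution(layout, best, flags)


def _global_start(layout, individual_fits):
    """Consensus starting vector from the individual fits: median shared
    parameters over the identifiable residues, per-residue shifts and
    per-curve baselines taken directly."""
    usable = [
        f for f in individual_fits.values() if "no_dispersion" not in f.flags
    ] or list(individual_fits.values())
    kex0 = float(np.median([f.kex for f in usable]))
    pb0 = float(np.median([f.p_b for f in usable]))
    x0 = np.empty(layout.n_params)
    x0[0], x0[1] = kex0, pb0
    for res in layout.residues:
        f = individual_fits[res]
        x0[layout.idx_dw_h[res]] = f.dw_h[res]
        x0[layout.idx_dw_c[res]] = f.dw_c[res]
    for lbl, j in layout.idx_r2.items():
        res = lbl.split(":", 1)[0]
        x0[j] = individual_fits[res].r2_0[lbl]
    return x0


def _fit_group(residue_curves, individual_fits, config):
    layout = _Layout(residue_curves, config)
    if layout.n_data <= layout.n_params:
        raise ValueError("not enough data points for a global fit")
    sparsity = layout.jac_sparsity()
    x0 = _global_start(layout, individual_fits)
    sol = _solve(layout, x0, config.max_nfev, config, jac_sparsity=sparsity)
    red = np.sum(sol.fun**2) / max(layout.n_data - layout.n_params, 1)
    if red > config.global_retry_redchi2:
        # consensus start stalled in a poor basin; fall back to the grid
        for kex0 in config.kex_starts:
            for pb0 in config.p_b_starts:
                x1 = x0.copy()
                x1[0], x1[1] = kex0, pb0
                alt = _solve(layout, x1, config.start_max_nfev, config,
                             jac_sparsity=sparsity)
                if alt.cost < sol.cost:
                    sol = _solve(layout, alt.x, config.max_nfev, config,
                                 jac_sparsity=sparsity)
    return layout, sol


def fit_global(residue_curves, config=None):
    """Global two-state fit with shared (kex, p_b) and iterative pruning.

    ``residue_curves`` maps residue label to that residue's list of
    DispersionCurve objects.  Residues whose group-fit residual exceeds
    twice their individual-fit residual are removed (all offenders at
    once by default) and the global fit repeated, until the surviving set
    is mutually consistent.  Returns ``(FitResult, PruningLog)``.
    """
    config = config or FitConfig()
    residue_curves = {res: list(cs) for res, cs in residue_curves.items()}
    if len(residue_curves) < 2:
        raise ValueError("global fitting needs at least 2 residues")

    individual_fits = {
        res: fit_single_residue(cs, config) for res, cs in residue_curves.items()
    }
    chi2_indiv = {res: f.chi2 for res, f in individual_fits.items()}

    active = dict(residue_curves)
    log = PruningLog()
    layout = sol = None
    for _ in range(config.max_prune_iterations):
        layout, sol = _fit_group(active, individual_fits, config)
        chi2_group = layout.chi2_by_residue(sol.x)
        ratios = {
            res: chi2_group[res] / max(chi2_indiv[res], 1e-12) for res in active
        }
        offenders = [res for res, r in ratios.items() if r > config.prune_ratio]
        if offenders and not config.prune_all_at_once:
            offenders = [max(offenders, key=lambda r: ratios[r])]
        log.iterations.append(
            PruningIteration(residues=list(active), ratios=ratios, removed=offenders)
        )
        if not offenders:
            break
        for res in offenders:
            active.pop(res)
        if len(active) < 2:
            raise ValueError(
                "pruning removed almost every residue: no mutually consistent "
                "dynamic process in this dataset"
            )
    result = _result_from_solution(layout, sol, [])
    return result, log


# ---------------------------------------------------------------------------
# Classification and error propagation
# ---------------------------------------------------------------------------

def classify_dynamic_residues(residue_curves, threshold=2.0):
    """Residues whose dispersion amplitude exceeds ``threshold`` (1/s) in
    any experiment, with per-residue provenance of the triggering curves.

    Returns an ordered mapping residue -> list of curve labels whose
    ``delta_R2 = R2eff(slowest) - R2eff(fastest)`` beat the threshold.
    """
    out = {}
    for res, curves in residue_curves.items():
        triggers = []
        for c in curves:
            if len(np.unique(c.nu_cpmg)) < 2:
                continue
            if compute_delta_r2(c) > threshold:
                triggers.append(_curve_label(c))
        if triggers:
            out[res] = triggers
    return out


def propagate_duplicate_errors(nu_cpmg, intensities, t_relax, sigma_i=None):
    """Per-point R2eff uncertainties from replicated nu_cpmg measurements.

    The replicate scatter at duplicated frequencies gives a pooled
    intensity SD (n-1 denominator per group, variances pooled across
    groups); each point's sigma_R2eff is that SD propagated through the
    intensity equation, ``sigma / (t_relax * I)``, floored point-wise by
    the spectral-noise propagation when ``sigma_i`` is supplied.

    Raises if the data contain no duplicates and no noise estimate —
    without either there is nothing to weight a fit with.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if nu.shape != inten.shape:
        raise ValueError("nu_cpmg and intensities must have the same shape")
    if np.any(inten <= 0):
        raise ValueError("non-positive intensity: cannot propagate errors")

    ss = 0.0
    dof = 0
    for val in np.unique(nu):
        group = inten[nu == val]
        if group.size > 1:
            ss += float(np.sum((group - group.mean()) ** 2))
            dof += group.size - 1
    if dof == 0 and sigma_i is None:
        raise ValueError(
            "no duplicated nu_cpmg points and no spectral noise estimate: "
            "cannot assign uncertainties"
        )
    pooled = np.sqrt(ss / dof) if dof > 0 else 0.0
    floor = np.zeros_like(inten) if sigma_i is None else np.broadcast_to(
        np.asarray(sigma_i, dtype=float), inten.shape
    )
    sig_i = np.maximum(pooled, floor)
    return sig_i / (t_relax * inten)
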