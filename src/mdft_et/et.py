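"""Electron-transfer pipeline: η scans, free-energy curves, λ.

The two redox states 0 and 1 share their Lennard-Jones sites and differ
by point charges, so they define two functionals F_0 and F_1 differing
only in the external term.  For each coupling η the interpolated
potential V_η = V_0 + η(V_1 − V_0) is minimized to give ρ_η; the mean
vertical energy gap

    ⟨ΔE⟩_η = ∫∫ ρ_η (V_1 − V_0) dr dΩ

is the solvent order parameter, and the diabatic curves are the point
sets (⟨ΔE⟩_η, F_A[ρ_η]) for A = 0, 1.  Key exact identities, used here
both as outputs and as internal consistency guards:

* Warshel:   F_1[ρ_η] − F_0[ρ_η] = ⟨ΔE⟩_η  (so the curves cross at 0)
* λ_0 = F_0[ρ_1] − F_0[ρ_0] = ΔW − ⟨ΔE⟩_1
* λ_1 = F_1[ρ_0] − F_1[ρ_1] = ⟨ΔE⟩_0 − ΔW
* λ_0 + λ_1 = ⟨ΔE⟩_0 − ⟨ΔE⟩_1
* linear response: λ_LR = (⟨ΔE⟩_0 − ⟨ΔE⟩_1)/2, exact when the
  functional is quadratic (Marcus limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .functional import (
    FunctionalSpec,
    MinimizeOptions,
    evaluate_at_density,
    minimize_functional,
)
from .grids import DensityField, OrientationQuadrature, PotentialField, SpatialGrid, integrate_field
from .kernels import CorrelationKernel
from .systems import EtaSchedule, SoluteState, SolventModel, build_external_potential, interpolate_potentials

__all__ = [
    "EtaScanRecord",
    "EtaScanResult",
    "FreeEnergyCurve",
    "ReorganizationSummary",
    "DiagnosticsReport",
    "vertical_energy_gap",
    "run_eta_scan",
    "build_free_energy_curves",
    "parabola_fit",
    "reorganization_summary",
    "consistency_diagnostics",
    "distance_scan",
]


def vertical_energy_gap(fieldobj: DensityField, V0: PotentialField, V1: PotentialField) -> float:
    """⟨ΔE⟩ = ∫∫ ρ (V_1 − V_0) dr dΩ for the given density."""
    if not (fieldobj.grid.same_as(V0.grid) and fieldobj.grid.same_as(V1.grid)):
        raise ValueError("density and potentials live on different grids")
    return integrate_field(
        fieldobj.values * (V1.values - V0.values), fieldobj.grid, fieldobj.quad
    )


@dataclass
class EtaScanRecord:
    eta: float
    coupling: float  # s(η); equals η for the linear schedule
    gap: float  # ⟨ΔE⟩_η, kJ/mol
    f_self: float  # F_η[ρ_η], the minimized value
    f0: float  # F_0[ρ_η]
    f1: float  # F_1[ρ_η]
    f0_terms: dict[str, float]
    f1_terms: dict[str, float]
    converged: bool
    grad_norm: float
    iterations: int
    density: DensityField | None = None


@dataclass
class EtaScanResult:
    records: list[EtaScanRecord]
    state0_label: str
    state1_label: str
    ideal_mode: str

    def __post_init__(self) -> None:
        etas = [r.eta for r in self.records]
        if np.any(np.diff(etas) <= 0):
            raise ValueError("scan records must be strictly increasing in eta")

    @property
    def gaps(self) -> np.ndarray:
        return np.array([r.gap for r in self.records])

    @property
    def couplings(self) -> np.ndarray:
        return np.array([r.coupling for r in self.records])

    def record_at(self, coupling: float) -> EtaScanRecord:
        for r in self.records:
            if abs(r.coupling - coupling) < 1e-12:
                return r
        raise ValueError(f"scan has no record at coupling {coupling}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "eta": r.eta,
                    "coupling": r.coupling,
                    "gap_kJmol": r.gap,
                    "F_self_kJmol": r.f_self,
                    "F0_kJmol": r.f0,
                    "F1_kJmol": r.f1,
                    "F0_id": r.f0_terms["ideal"],
                    "F0_ext": r.f0_terms["external"],
                    "F0_exc": r.f0_terms["excess"],
                    "F1_id": r.f1_terms["ideal"],
                    "F1_ext": r.f1_terms["external"],
                    "F1_exc": r.f1_terms["excess"],
                    "converged": r.converged,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# states: {self.state0_label} -> {self.state1_label}\n")
            fh.write(f"# ideal_mode: {self.ideal_mode}\n")
            fh.write("# units: energies kJ/mol, gap kJ/mol\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def _check_shared_lj(state0: SoluteState, state1: SoluteState) -> None:
    same = (
        state0.positions.shape == state1.positions.shape
        and np.allclose(state0.positions, state1.positions, atol=0)
        and np.allclose(state0.sigmas, state1.sigmas, atol=0)
        and np.allclose(state0.epsilons, state1.epsilons, atol=0)
    )
    if not same:
        raise ValueError(
            "redox states must share their Lennard-Jones sites "
            "(only charges may differ)"
        )


def run_eta_scan(
    state0: SoluteState,
    state1: SoluteState,
    solvent: SolventModel,
    kernel: CorrelationKernel,
    grid: SpatialGrid,
    quad: OrientationQuadrature,
    schedule: EtaSchedule | None = None,
    ideal_mode: str = "exact",
    options: MinimizeOptions | None = None,
    electrostatics: str = "periodic",
    warm_start: bool = True,
    store_densities: bool = False,
    potential_kwargs: dict | None = None,
) -> EtaScanResult:
    """Minimize F_η along the schedule and record every ET quantity.

    Each η is warm-started from the previous equilibrium density unless
    ``warm_start`` is disabled (cold starts test initialization
    independence).  A non-converged η is flagged and the scan continues.
    """
    _check_shared_lj(state0, state1)
    schedule = schedule or EtaSchedule.uniform(11)
    pkw = dict(potential_kwargs or {})
    V0 = build_external_potential(state0, solvent, grid, quad, electrostatics, **pkw)
    V1 = build_external_potential(state1, solvent, grid, quad, electrostatics, **pkw)

    records: list[EtaScanRecord] = []
    previous: DensityField | None = None
    for eta, s in zip(schedule.etas, schedule.couplings):
        V_eta = interpolate_potentials(V0, V1, float(s))
        spec = FunctionalSpec(solvent, kernel, V_eta, ideal_mode)
        result = minimize_functional(spec, options, initial=previous if warm_start else None)
        rho = result.density
        gap = vertical_energy_gap(rho, V0, V1)
        f0, f0_terms = evaluate_at_density(rho, V0, kernel, solvent, ideal_mode)
        # F_1 shares the ideal and excess pieces (same density); its external
        # term is integrated independently so the Warshel identity
        # F_1 − F_0 = ⟨ΔE⟩ stays a live numerical check
        f1_ext = integrate_field(rho.values * V1.values, grid, quad)
        f1_terms = {**f0_terms, "external": f1_ext}
        f1 = f0_terms["ideal"] + f1_ext + f0_terms["excess"]
        records.append(
            EtaScanRecord(
                eta=float(eta),
                coupling=float(s),
                gap=gap,
                f_self=result.free_energy,
                f0=f0,
                f1=f1,
                f0_terms=f0_terms,
                f1_terms=f1_terms,
                converged=result.converged,
                grad_norm=result.grad_norm,
                iterations=result.iterations,
                density=rho if store_densities else None,
            )
        )
        previous = rho
    return EtaScanResult(records, state0.label, state1.label, ideal_mode)


@dataclass
class FreeEnergyCurve:
    """One diabatic curve: W(x) sampled at the scan's gap values."""

    label: str
    x: np.ndarray  # ⟨ΔE⟩ values, sorted
    w: np.ndarray  # F_state at those densities
    lambda_fit: float | None = None
    x_min: float | None = None
    w_min: float | None = None
    fit_window: float = 90.0


def parabola_fit(x, w, window: float = 90.0):
    """Fit W(x) = (x − x_min)²/(4λ) + W_min to points within ``window``.

    Only points with W − min(W) ≤ window enter the fit (the Marcus-fit
    convention).  Returns (λ, x_min, W_min); degenerate point sets
    (collinear, or fewer than 3 in the window) raise ValueError.
    """
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    sel = w - w.min() <= window
    if sel.sum() < 3:
        raise ValueError("need at least 3 points within the fit window")
    coef = np.polyfit(x[sel], w[sel], 2)
    a, b, c = coef
    # a ≈ 0 means the windowed points are (numerically) collinear
    a_floor = 1e-10 * (np.ptp(w[sel]) + 1e-30) / max(np.ptp(x[sel]) ** 2, 1e-30)
    if not np.isfinite(a) or a <= a_floor:
        raise ValueError("points are not convex-parabolic; fit is degenerate")
    lam = 1.0 / (4.0 * a)
    x_min = -b / (2.0 * a)
    w_min = c - b * b / (4.0 * a)
    return lam, x_min, w_min


def build_free_energy_curves(scan: EtaScanResult, window: float = 90.0):
    """(curve for state 0, curve for state 1), fitted when possible."""
    x = scan.gaps
    order = np.argsort(x)
    curves = []
    for label, w in (
        (scan.state0_label, np.array([r.f0 for r in scan.records])),
        (scan.state1_label, np.array([r.f1 for r in scan.records])),
    ):
        xs, ws = x[order], w[order]
        fit = None
        if len(xs) >= 3:
            try:
                fit = parabola_fit(xs, ws, window)
            except ValueError:
                fit = None
        curves.append(
            FreeEnergyCurve(
                label,
                xs,
                ws,
                lambda_fit=fit[0] if fit else None,
                x_min=fit[1] if fit else None,
                w_min=fit[2] if fit else None,
                fit_window=window,
            )
        )
    return tuple(curves)


@dataclass
class ReorganizationSummary:
    delta_w: float
    lambda_0: float
    lambda_1: float
    lambda_lr: float
    gap_0: float
    gap_1: float
    lambda_0_terms: dict[str, float]
    lambda_1_terms: dict[str, float]
    delta_w_corrected: float | None = None
    corrections: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "delta_w_kJmol": self.delta_w,
            "lambda_0_kJmol": self.lambda_0,
            "lambda_1_kJmol": self.lambda_1,
            "lambda_lr_kJmol": self.lambda_lr,
            "gap_0_kJmol": self.gap_0,
            "gap_1_kJmol": self.gap_1,
            "lambda_0_terms": self.lambda_0_terms,
            "lambda_1_terms": self.lambda_1_terms,
        }
        if self.delta_w_corrected is not None:
            out["delta_w_corrected_kJmol"] = self.delta_w_corrected
            out["corrections_kJmol"] = self.corrections
        return out


def reorganization_summary(
    scan: EtaScanResult,
    state_corrections: tuple[float, float] | None = None,
) -> ReorganizationSummary:
    """ΔW, λ_0, λ_1, λ_LR and their term decompositions from a scan.

    ``state_corrections`` are optional additive post-hoc corrections
    (finite-size + pressure) for states 0 and 1; being constants per
    state they shift ΔW but cancel in every λ.
    """
    r0 = scan.record_at(0.0)
    r1 = scan.record_at(1.0)
    delta_w = r1.f1 - r0.f0
    lam0 = r1.f0 - r0.f0
    lam1 = r0.f1 - r1.f1
    lam_lr = 0.5 * (r0.gap - r1.gap)
    lam0_terms = {
        key: r1.f0_terms[key] - r0.f0_terms[key] for key in ("ideal", "external", "excess")
    }
    lam1_terms = {
        key: r0.f1_terms[key] - r1.f1_terms[key] for key in ("ideal", "external", "excess")
    }
    corrected = None
    corr: dict[str, float] = {}
    if state_corrections is not None:
        c0, c1 = state_corrections
        corrected = delta_w + c1 - c0
        corr = {"state0": c0, "state1": c1}
    return ReorganizationSummary(
        delta_w=delta_w,
        lambda_0=lam0,
        lambda_1=lam1,
        lambda_lr=lam_lr,
        gap_0=r0.gap,
        gap_1=r1.gap,
        lambda_0_terms=lam0_terms,
        lambda_1_terms=lam1_terms,
        delta_w_corrected=corrected,
        corrections=corr,
    )


@dataclass
class DiagnosticsReport:
    warshel_residual: float  # max |F1 − F0 − gap| / max|gap|
    crossing_gap: float  # interpolated zero of W1 − W0 on the gap axis
    monotonicity_violations: int
    chong_hirata_max_rel: float
    parametrization_max_dev: float | None = None

    def as_dict(self) -> dict:
        out = {
            "warshel_residual": self.warshel_residual,
            "crossing_gap_kJmol": self.crossing_gap,
            "monotonicity_violations": self.monotonicity_violations,
            "chong_hirata_max_rel": self.chong_hirata_max_rel,
        }
        if self.parametrization_max_dev is not None:
            out["parametrization_max_dev"] = self.parametrization_max_dev
        return out


def _interp_curve(x_base, w_base, x_query):
    order = np.argsort(x_base)
    xs, ws = x_base[order], w_base[order]
    if len(xs) >= 4:
        # not-a-knot spline: exact for polynomial curves up to cubic, so
        # the parametrization-invariance check is not limited by the
        # interpolant on (quadratic-model) parabolic curves
        from scipy.interpolate import CubicSpline

        return CubicSpline(xs, ws)(x_query)
    return np.interp(x_query, xs, ws)


def consistency_diagnostics(
    scan: EtaScanResult,
    alt_scan: EtaScanResult | None = None,
    monotonicity_tol: float = 0.0,
) -> DiagnosticsReport:
    """Exactness checks every scan must satisfy.

    (i) Warshel residual; (ii) curve-crossing location on the gap axis
    (must be 0); (iii) count of monotonicity violations of ⟨ΔE⟩_η along
    the schedule; (iv) the thermodynamic-cycle route
    F̃_0(η) = F_η[ρ_η] + ⟨V_0 − V_η⟩_η recomputed from stored pieces and
    compared with the direct F_0[ρ_η]; (v) optionally, whether a
    reparametrized scan traces the same free-energy curve.
    """
    gaps = scan.gaps
    scale = max(np.abs(gaps).max(), 1e-30)
    warshel = max(abs(r.f1 - r.f0 - r.gap) for r in scan.records) / scale

    # crossing of W1 − W0 (= gap, by Warshel) along the gap axis
    diff = np.array([r.f1 - r.f0 for r in scan.records])
    order = np.argsort(gaps)
    xs, ds = gaps[order], diff[order]
    crossing = np.nan
    sign_change = np.where(np.diff(np.sign(ds)) != 0)[0]
    if ds[0] == 0:
        crossing = xs[0]
    elif len(sign_change):
        i = sign_change[0]
        t = ds[i] / (ds[i] - ds[i + 1])
        crossing = xs[i] + t * (xs[i + 1] - xs[i])

    d = np.diff(gaps)
    direction = np.sign(gaps[-1] - gaps[0])
    violations = int(np.sum(direction * d < -abs(monotonicity_tol)))

    # cycle route: solvation free energy of the fictitious solute η plus
    # the work of discharging it in its own frozen solvent
    ch_err = 0.0
    fscale = max(max(abs(r.f0) for r in scan.records), 1e-30)
    for r in scan.records:
        f0_cycle = r.f_self - r.coupling * r.gap
        ch_err = max(ch_err, abs(f0_cycle - r.f0) / fscale)

    param_dev = None
    if alt_scan is not None:
        devs = []
        for w_attr in ("f0", "f1"):
            wb = np.array([getattr(r, w_attr) for r in scan.records])
            wa = np.array([getattr(r, w_attr) for r in alt_scan.records])
            xa = alt_scan.gaps
            inside = (xa >= gaps.min()) & (xa <= gaps.max())
            pred = _interp_curve(gaps, wb, xa[inside])
            rng = max(wb.max() - wb.min(), 1e-30)
            if inside.any():
                devs.append(np.abs(pred - wa[inside]).max() / rng)
        param_dev = float(max(devs)) if devs else 0.0

    return DiagnosticsReport(
        warshel_residual=float(warshel),
        crossing_gap=float(crossing),
        monotonicity_violations=violations,
        chong_hirata_max_rel=float(ch_err),
        parametrization_max_dev=param_dev,
    )


def distance_scan(
    wall: SoluteState,
    state0: SoluteState,
    state1: SoluteState,
    solvent: SolventModel,
    kernel: CorrelationKernel,
    grid: SpatialGrid,
    quad: OrientationQuadrature,
    z_values: Sequence[float],
    xy: tuple[float, float] | None = None,
    schedule: EtaSchedule | None = None,
    **scan_kwargs,
) -> pd.DataFrame:
    """λ(z) for a redox couple approaching a wall.

    The redox site is placed at lateral position ``xy`` (box centre by
    default) and height wall_z + z for every z in ``z_values``; the wall
    enters only through the solvent (no direct solute–wall terms exist
    anywhere in the formalism).  Default schedule is endpoints only,
    which is all λ and ΔW require.
    """
    _check_shared_lj(state0, state1)
    if len(state0.positions) != 1:
        raise ValueError("distance_scan supports single-site redox solutes")
    schedule = schedule or EtaSchedule((0.0, 1.0))
    cx, cy = xy if xy is not None else (0.5 * grid.box_lengths[0], 0.5 * grid.box_lengths[1])
    wall_z = float(np.mean(wall.positions[:, 2]))
    box_z = grid.box_lengths[2]

    rows = []
    for z in z_values:
        target = np.array([cx, cy, wall_z + float(z)])
        if not (0.0 <= target[2] < box_z):
            warnings.warn(f"z = {z} places the solute outside the box; skipped")
            continue
        s0 = wall.merged_with(
            state0.translated(target - state0.positions[0]), label=f"{state0.label}@z={z}"
        )
        s1 = wall.merged_with(
            state1.translated(target - state1.positions[0]), label=f"{state1.label}@z={z}"
        )
        scan = run_eta_scan(s0, s1, solvent, kernel, grid, quad, schedule, **scan_kwargs)
        summ = reorganization_summary(scan)
        rows.append(
            {
                "z": float(z),
                "delta_w_kJmol": summ.delta_w,
                "lambda_0_kJmol": summ.lambda_0,
                "lambda_1_kJmol": summ.lambda_1,
                "lambda_lr_kJmol": summ.lambda_lr,
                "lambda_0_id": summ.lambda_0_terms["ideal"],
                "lambda_0_ext": summ.lambda_0_terms["external"],
                "lambda_0_exc": summ.lambda_0_terms["excess"],
                "lambda_1_id": summ.lambda_1_terms["ideal"],
                "lambda_1_ext": summ.lambda_1_terms["external"],
                "lambda_1_exc": summ.lambda_1_terms["excess"],
                "converged": all(r.converged for r in scan.records),
            }
        )
    return pd.DataFrame(rows)
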