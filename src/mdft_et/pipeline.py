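"""Pipeline driver: configuration in, tables and summaries on disk.

All numeric results go to files (TSV with '#' metadata headers, JSON
summaries, optional cube volumes); logging goes to stderr.  Runs are
deterministic: re-running a configuration reproduces every output byte
for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .cube import write_cube
from .et import (
    build_free_energy_curves,
    consistency_diagnostics,
    reorganization_summary,
    run_eta_scan,
)
from .functional import (
    FunctionalSpec,
    MinimizeOptions,
    finite_size_correction,
    minimize_functional,
    pressure_correction,
)
from .grids import number_density
from .kernels import kernel_bulk_pressure
from .structure import partial_molar_volume, solvent_charge_density
from .systems import build_external_potential

__all__ = ["run_et_pipeline", "run_solvation"]

log = logging.getLogger("mdft_et")


def _write_fec(curve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# state: {curve.label}\n")
        if curve.lambda_fit is not None:
            fh.write(
                f"# parabola fit (window {curve.fit_window} kJ/mol): "
                f"lambda = {curve.lambda_fit:.12g} kJ/mol, "
                f"x_min = {curve.x_min:.12g}, W_min = {curve.w_min:.12g}\n"
            )
        fh.write("gap_kJmol\tW_kJmol\n")
        for x, w in zip(curve.x, curve.w):
            fh.write(f"{x:.12g}\t{w:.12g}\n")


def _state_correction(cfg: RunConfig, solvent, kernel, state, density) -> float:
    total = 0.0
    if cfg.finite_size:
        total += finite_size_correction(state.net_charge, cfg.box, cfg.solvent_dielectric)
    if cfg.pressure is not None:
        P = kernel_bulk_pressure(kernel, solvent) if cfg.pressure == "auto" else float(cfg.pressure)
        total += pressure_correction(partial_molar_volume(density), P)
    return total


def run_et_pipeline(cfg: RunConfig) -> dict:
    """Run a full ET study and write its artifact bundle.

    Returns a dict with the output paths, the summary, and an
    ``all_converged`` flag the CLI maps to its exit status.
    """
    cfg = cfg.validated()
    outdir = Path(cfg.output_dir)
    if not outdir.is_absolute():
        outdir = cfg.base_dir / outdir
    outdir.mkdir(parents=True, exist_ok=True)

    grid = cfg.grid()
    solvent = cfg.solvent()
    quad = cfg.quadrature()
    kernel = cfg.kernel()
    state0, state1 = cfg.solutes()
    schedule = cfg.schedule()
    options = MinimizeOptions(cfg.grad_tol, cfg.f_tol, cfg.max_iter)

    log.info(
        "ET scan %s -> %s: box %s, %s points, %d orientations, ideal_mode=%s, "
        "grad_tol=%g, f_tol=%g, max_iter=%d",
        state0.label, state1.label, cfg.box, cfg.points, quad.n_orientations,
        cfg.ideal_mode, cfg.grad_tol, cfg.f_tol, cfg.max_iter,
    )
    need_density = cfg.write_cubes or cfg.pressure is not None
    scan = run_eta_scan(
        state0, state1, solvent, kernel, grid, quad,
        schedule=schedule,
        ideal_mode=cfg.ideal_mode,
        options=options,
        electrostatics=cfg.electrostatics,
        store_densities=need_density,
    )

    corrections = None
    if cfg.finite_size or cfg.pressure is not None:
        r0, r1 = scan.record_at(0.0), scan.record_at(1.0)
        corrections = (
            _state_correction(cfg, solvent, kernel, state0, r0.density),
            _state_correction(cfg, solvent, kernel, state1, r1.density),
        )
        log.info("post-hoc corrections (kJ/mol): state0 %+.4f, state1 %+.4f", *corrections)

    summary = reorganization_summary(scan, corrections)
    diagnostics = consistency_diagnostics(scan)
    curve0, curve1 = build_free_energy_curves(scan)

    paths = {"scan": outdir / "scan.tsv"}
    scan.to_tsv(paths["scan"])
    paths["fec_state0"] = outdir / "fec_state0.tsv"
    paths["fec_state1"] = outdir / "fec_state1.tsv"
    _write_fec(curve0, paths["fec_state0"])
    _write_fec(curve1, paths["fec_state1"])

    if cfg.write_cubes:
        for tag, rec in (("state0", scan.record_at(0.0)), ("state1", scan.record_at(1.0))):
            n = number_density(rec.density)
            p = outdir / f"number_density_{tag}.cube"
            write_cube(n, grid, p, comment=f"solvent number density, {tag} (1/A^3)")
            paths[f"cube_{tag}"] = p
            rho_c = solvent_charge_density(rec.density, solvent)
            pc = outdir / f"charge_density_{tag}.cube"
            write_cube(rho_c, grid, pc, comment=f"solvent charge density, {tag} (e/A^3)")
            paths[f"cube_charge_{tag}"] = pc

    all_converged = all(r.converged for r in scan.records)
    blob = {
        "states": [state0.label, state1.label],
        "summary": summary.as_dict(),
        "diagnostics": diagnostics.as_dict(),
        "lambda_fit_state0_kJmol": curve0.lambda_fit,
        "lambda_fit_state1_kJmol": curve1.lambda_fit,
        "all_converged": all_converged,
        "ideal_mode": cfg.ideal_mode,
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(blob, indent=2, sort_keys=True) + "\n")
    log.info(
        "done: dW = %.6g, lambda_0 = %.6g, lambda_1 = %.6g, lambda_LR = %.6g kJ/mol",
        summary.delta_w, summary.lambda_0, summary.lambda_1, summary.lambda_lr,
    )
    return {"paths": paths, "summary": blob, "scan": scan, "all_converged": all_converged}


def run_solvation(cfg: RunConfig) -> dict:
    """Single-state solvation free energy (state 0 of the configuration)."""
    cfg = cfg.validated(require_solutes=False)
    if cfg.solute0_path is None:
        raise ValueError("solvation needs solutes.state0")
    outdir = Path(cfg.output_dir)
    if not outdir.is_absolute():
        outdir = cfg.base_dir / outdir
    outdir.mkdir(parents=True, exist_ok=True)

    grid, solvent = cfg.grid(), cfg.solvent()
    quad, kernel = cfg.quadrature(), cfg.kernel()
    from .systems import SoluteState

    state = SoluteState.from_file(cfg._resolve(cfg.solute0_path))
    V = build_external_potential(state, solvent, grid, quad, cfg.electrostatics)
    spec = FunctionalSpec(solvent, kernel, V, cfg.ideal_mode)
    res = minimize_functional(spec, MinimizeOptions(cfg.grad_tol, cfg.f_tol, cfg.max_iter))
    corr = _state_correction(cfg, solvent, kernel, state, res.density)
    blob = {
        "solute": state.label,
        "free_energy_kJmol": res.free_energy,
        "terms_kJmol": res.terms,
        "correction_kJmol": corr,
        "free_energy_corrected_kJmol": res.free_energy + corr,
        "partial_molar_volume_A3": partial_molar_volume(res.density),
        "converged": res.converged,
        "iterations": res.iterations,
    }
    path = outdir / "solvation.json"
    path.write_text(json.dumps(blob, indent=2, sort_keys=True) + "\n")
    return {"paths": {"solvation": path}, "summary": blob, "result": res,
            "all_converged": res.converged}
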