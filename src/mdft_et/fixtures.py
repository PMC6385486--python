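"""Generation of ready-to-run input files.

``chlorine-states`` emits the single-site chloride-like redox solutes
(σ = 4.404 Å, ε = 0.4190 kJ/mol, charge −1, 0 or +1 e); ``fcc-wall``
the 400-atom square (100) surface layer; ``toy-solvent`` and
``toy-kernel`` the desk-scale dipolar solvent and its analytic kernel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import write_solvent_file
from .kernels import make_builtin_kernel, write_kernel_table
from .systems import SoluteState, build_fcc100_wall, toy_dipolar_solvent

__all__ = ["generate_fixture", "CHLORINE_SIGMA", "CHLORINE_EPSILON", "TOY_KERNEL_DEFAULTS"]

CHLORINE_SIGMA = 4.404  # Å
CHLORINE_EPSILON = 0.4190  # kJ/mol

#: Gaussian channel amplitudes (Å³) and widths (Å) of the default toy
#: kernel: a compressibility-lowering density channel and a screening
#: (negative longitudinal) dipole channel, the sign structure of a
#: polar liquid, at amplitudes far below the stability bounds.
TOY_KERNEL_DEFAULTS = {
    "a_s": -30.0, "w_s": 1.0,
    "a_l": -20.0, "w_l": 1.0,
    "a_t": 5.0, "w_t": 1.0,
}


def chlorine_state(charge: float, position=(20.0, 20.0, 20.0)) -> SoluteState:
    name = {-1.0: "Cl-", 0.0: "Cl0", 1.0: "Cl+"}.get(float(charge), f"Cl({charge:+g})")
    return SoluteState(
        positions=np.array([position]),
        charges=np.array([charge]),
        sigmas=np.array([CHLORINE_SIGMA]),
        epsilons=np.array([CHLORINE_EPSILON]),
        label=name,
        names=("Cl",),
    )


def generate_fixture(kind: str, outdir=".", **params) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if kind == "chlorine-states":
        position = params.pop("position", (20.0, 20.0, 20.0))
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        for q, stem in ((-1.0, "cl_minus"), (0.0, "cl_0"), (1.0, "cl_plus")):
            p = outdir / f"{stem}.solute"
            chlorine_state(q, position).to_file(p)
            written.append(p)
    elif kind == "fcc-wall":
        wall = build_fcc100_wall(
            lattice_spacing=params.pop("lattice_spacing", 2.0),
            n_atoms_per_side=params.pop("n_atoms_per_side", 20),
            lj_sigma=params.pop("lj_sigma", 3.37),
            lj_epsilon=params.pop("lj_epsilon", 0.23),
            z=params.pop("z", 0.0),
        )
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        p = outdir / "wall.solute"
        wall.to_file(p)
        written.append(p)
    elif kind == "toy-solvent":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        p = outdir / "toy_solvent.toml"
        write_solvent_file(toy_dipolar_solvent(), p)
        written.append(p)
    elif kind == "toy-kernel":
        kparams = dict(TOY_KERNEL_DEFAULTS)
        kparams.update(params)
        kernel = make_builtin_kernel("dipolar-toy", **kparams)
        kernel.metadata.update({"solvent": "toy-dipolar", "T": 298.15, "n_bulk": 0.0333})
        p = outdir / "toy_kernel.tsv"
        write_kernel_table(kernel, p)
        written.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
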