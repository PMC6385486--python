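"""Run configuration: TOML in, validated dataclass out, TOML back.

The configuration mirrors the pipeline inputs: grid, orientation rule,
solvent, kernel, the two redox solute files, the η schedule, the
post-hoc corrections and the minimizer tolerances.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .grids import build_orientation_quadrature, build_spatial_grid
from .kernels import load_kernel_table, make_builtin_kernel
from .systems import EtaSchedule, SoluteState, SolventModel, SolventSite, spce_water, toy_dipolar_solvent

__all__ = ["RunConfig", "ConfigError", "load_solvent_file", "write_solvent_file"]


class ConfigError(ValueError):
    """Raised with every validation failure listed at once."""


_BUILTIN_SOLVENTS = {"spce": spce_water, "toy-dipolar": toy_dipolar_solvent}


def load_solvent_file(path) -> SolventModel:
    with open(path, "rb") as fh:
        d = tomllib.load(fh)
    sites = tuple(
        SolventSite(s[0], (float(s[1]), float(s[2]), float(s[3])),
                    float(s[4]), float(s[5]), float(s[6]))
        for s in d["sites"]
    )
    return SolventModel(
        sites=sites,
        n_bulk=float(d["n_bulk"]),
        temperature=float(d["temperature"]),
        symmetry_order=int(d.get("symmetry_order", 1)),
        name=d.get("name", "solvent"),
    )


def write_solvent_file(solvent: SolventModel, path) -> None:
    lines = [
        f'name = "{solvent.name}"',
        f"n_bulk = {solvent.n_bulk!r}",
        f"temperature = {solvent.temperature!r}",
        f"symmetry_order = {solvent.symmetry_order}",
        "sites = [",
    ]
    for s in solvent.sites:
        p = s.position
        lines.append(
            f'    ["{s.name}", {p[0]!r}, {p[1]!r}, {p[2]!r}, '
            f"{s.charge!r}, {s.sigma!r}, {s.epsilon!r}],"
        )
    lines.append("]")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    box: tuple[float, float, float] = (16.0, 16.0, 16.0)
    points: tuple[int, int, int] = (16, 16, 16)
    n_theta: int = 2
    n_phi: int = 2
    n_psi: int = 1
    solvent_builtin: str | None = "toy-dipolar"
    solvent_path: str | None = None
    kernel_builtin: str | None = "zero"
    kernel_parameters: dict = dc_field(default_factory=dict)
    kernel_path: str | None = None
    solute0_path: str | None = None
    solute1_path: str | None = None
    etas: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 11))
    schedule_power: float = 1.0
    finite_size: bool = False
    solvent_dielectric: float = 71.0
    pressure: float | str | None = None  # number, "auto", or None (off)
    electrostatics: str = "periodic"
    ideal_mode: str = "exact"
    grad_tol: float = 1e-8
    f_tol: float = 1e-10
    max_iter: int = 2000
    output_dir: str = "out"
    write_cubes: bool = False
    base_dir: Path = dc_field(default_factory=Path, repr=False)

    # ---- parsing -----------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict, base_dir: Path | str = ".") -> "RunConfig":
        g = d.get("grid", {})
        o = d.get("orientations", {})
        sv = d.get("solvent", {})
        kr = d.get("kernel", {})
        so = d.get("solutes", {})
        sc = d.get("schedule", {})
        co = d.get("corrections", {})
        mi = d.get("minimizer", {})
        ou = d.get("output", {})
        el = d.get("electrostatics", {})
        etas = sc.get("etas")
        if etas is None and "n" in sc:
            etas = list(np.linspace(0.0, 1.0, int(sc["n"])))
        cfg = cls(
            box=tuple(g.get("box", (16.0, 16.0, 16.0))),
            points=tuple(g.get("points", (16, 16, 16))),
            n_theta=int(o.get("n_theta", 2)),
            n_phi=int(o.get("n_phi", 2)),
            n_psi=int(o.get("n_psi", 1)),
            solvent_builtin=sv.get("builtin") if "path" not in sv else None,
            solvent_path=sv.get("path"),
            kernel_builtin=kr.get("builtin") if "path" not in kr else None,
            kernel_parameters=dict(kr.get("parameters", {})),
            kernel_path=kr.get("path"),
            solute0_path=so.get("state0"),
            solute1_path=so.get("state1"),
            etas=tuple(etas) if etas is not None else cls.etas,
            schedule_power=float(sc.get("power", 1.0)),
            finite_size=bool(co.get("finite_size", False)),
            solvent_dielectric=float(co.get("solvent_dielectric", 71.0)),
            pressure=co.get("pressure"),
            electrostatics=el.get("mode", "periodic"),
            ideal_mode=mi.get("ideal_mode", "exact"),
            grad_tol=float(mi.get("grad_tol", 1e-8)),
            f_tol=float(mi.get("f_tol", 1e-10)),
            max_iter=int(mi.get("max_iter", 2000)),
            output_dir=ou.get("directory", "out"),
            write_cubes=bool(ou.get("write_cubes", False)),
            base_dir=Path(base_dir),
        )
        return cfg

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh), base_dir=path.parent)

    def to_toml_string(self) -> str:
        def fmt(v):
            if isinstance(v, (bool, np.bool_)):
                return "true" if v else "false"
            if isinstance(v, str):
                return f'"{v}"'
            if isinstance(v, (list, tuple)):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            if isinstance(v, (int, np.integer)):
                return str(int(v))
            return repr(float(v))

        out = []
        out.append("[grid]")
        out.append(f"box = {fmt(list(self.box))}")
        out.append(f"points = {fmt(list(self.points))}")
        out.append("\n[orientations]")
        for k in ("n_theta", "n_phi", "n_psi"):
            out.append(f"{k} = {getattr(self, k)}")
        out.append("\n[solvent]")
        if self.solvent_path:
            out.append(f'path = "{self.solvent_path}"')
        else:
            out.append(f'builtin = "{self.solvent_builtin}"')
        out.append("\n[kernel]")
        if self.kernel_path:
            out.append(f'path = "{self.kernel_path}"')
        else:
            out.append(f'builtin = "{self.kernel_builtin}"')
        if self.kernel_parameters:
            out.append("\n[kernel.parameters]")
            for k, v in self.kernel_parameters.items():
                out.append(f"{k} = {fmt(v)}")
        out.append("\n[solutes]")
        if self.solute0_path:
            out.append(f'state0 = "{self.solute0_path}"')
        if self.solute1_path:
            out.append(f'state1 = "{self.solute1_path}"')
        out.append("\n[schedule]")
        out.append(f"etas = {fmt(list(self.etas))}")
        out.append(f"power = {self.schedule_power!r}")
        out.append("\n[corrections]")
        out.append(f"finite_size = {fmt(self.finite_size)}")
        out.append(f"solvent_dielectric = {self.solvent_dielectric!r}")
        if self.pressure is not None:
            out.append(f"pressure = {fmt(self.pressure)}")
        out.append("\n[electrostatics]")
        out.append(f'mode = "{self.electrostatics}"')
        out.append("\n[minimizer]")
        out.append(f'ideal_mode = "{self.ideal_mode}"')
        out.append(f"grad_tol = {self.grad_tol!r}")
        out.append(f"f_tol = {self.f_tol!r}")
        out.append(f"max_iter = {self.max_iter}")
        out.append("\n[output]")
        out.append(f'directory = "{self.output_dir}"')
        out.append(f"write_cubes = {fmt(self.write_cubes)}")
        return "\n".join(out) + "\n"

    # ---- validation & realization ------------------------------------

    def _resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q

    def validate(self, require_solutes: bool = True) -> list[str]:
        errors = []
        if any(L <= 0 for L in self.box):
            errors.append("grid.box lengths must be positive")
        if any(n < 2 for n in self.points):
            errors.append("grid.points must be >= 2 per axis")
        if min(self.n_theta, self.n_phi, self.n_psi) < 1:
            errors.append("orientation counts must be >= 1")
        if self.solvent_builtin and self.solvent_builtin not in _BUILTIN_SOLVENTS:
            errors.append(f"unknown builtin solvent {self.solvent_builtin!r}")
        if self.solvent_path and not self._resolve(self.solvent_path).exists():
            errors.append(f"solvent file not found: {self.solvent_path}")
        if self.kernel_builtin and self.kernel_builtin not in ("zero", "dipolar-toy"):
            errors.append(f"unknown builtin kernel {self.kernel_builtin!r}")
        if self.kernel_path and not self._resolve(self.kernel_path).exists():
            errors.append(f"kernel table not found: {self.kernel_path}")
        for attr in ("solute0_path", "solute1_path"):
            p = getattr(self, attr)
            if p is None:
                if require_solutes:
                    errors.append(f"{attr} is required")
            elif not self._resolve(p).exists():
                errors.append(f"solute file not found: {p}")
        try:
            self.schedule()
        except ValueError as exc:
            errors.append(f"schedule: {exc}")
        if self.ideal_mode not in ("exact", "quadratic"):
            errors.append("minimizer.ideal_mode must be 'exact' or 'quadratic'")
        if self.electrostatics not in ("periodic", "direct", "none"):
            errors.append("electrostatics.mode must be periodic/direct/none")
        if isinstance(self.pressure, str) and self.pressure != "auto":
            errors.append("corrections.pressure must be a number or 'auto'")
        return errors

    def validated(self, require_solutes: bool = True) -> "RunConfig":
        errors = self.validate(require_solutes)
        if errors:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
        return self

    def grid(self):
        return build_spatial_grid(self.box, self.points)

    def solvent(self) -> SolventModel:
        if self.solvent_path:
            return load_solvent_file(self._resolve(self.solvent_path))
        return _BUILTIN_SOLVENTS[self.solvent_builtin]()

    def quadrature(self):
        return build_orientation_quadrature(
            self.n_theta, self.n_phi, self.n_psi, self.solvent().symmetry_order
        )

    def kernel(self):
        if self.kernel_path:
            return load_kernel_table(self._resolve(self.kernel_path))
        return make_builtin_kernel(self.kernel_builtin, **self.kernel_parameters)

    def solutes(self) -> tuple[SoluteState, SoluteState]:
        return (
            SoluteState.from_file(self._resolve(self.solute0_path)),
            SoluteState.from_file(self._resolve(self.solute1_path)),
        )

    def schedule(self) -> EtaSchedule:
        p = self.schedule_power
        repar = None if p == 1.0 else (lambda e, p=p: e**p)
        return EtaSchedule(tuple(float(e) for e in self.etas), repar)
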