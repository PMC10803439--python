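"""TOML run configuration and the bundled example parameter sets.

Configs are strict: unknown keys are errors, so a typo like ``gama`` fails
loudly instead of being silently ignored.  Regulator and cell indices are
1-based in config files (mirroring the usual notation) and converted to
0-based internally.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .mesh import TruncatedGrid
from .model import DegradationSpec, GRNModel, RegulationSpec, validate_model

__all__ = ["RunConfig", "load_config", "load_example", "EXAMPLE_NAMES"]

EXAMPLE_NAMES = ("example1", "example2", "example3", "example4", "example5")


@dataclass(frozen=True)
class RunConfig:
    """Validated model + grid + solver settings for one run."""

    model: GRNModel
    grid: TruncatedGrid
    stationary_method: str = "direct"
    tolerance: float = 1e-12
    dt: float | None = None
    t_final: float | None = None
    gamma_ref: float = 1.0
    quadrature_order: int = 1
    initial_pdf: dict = field(default_factory=lambda: {"kind": "uniform"})
    seed: int = 0
    name: str = ""


class ConfigError(ValueError):
    """Configuration parse/validation failure, with the offending key path."""


def _require_keys(section: dict, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in [{path}]")


def _parse_regulation(entry: dict, idx: int) -> RegulationSpec:
    path = f"model.regulation[{idx}]"
    form = entry.get("form")
    if form == "constant":
        _require_keys(entry, {"form"}, path)
        return RegulationSpec(form="constant")
    if form == "hill_univariate":
        _require_keys(entry, {"form", "regulator", "K", "H", "eps"}, path)
        return RegulationSpec(
            form="hill_univariate",
            regulators=(int(entry["regulator"]) - 1,),
            K=(float(entry["K"]),),
            H=(float(entry["H"]),),
            eps=(float(entry["eps"]),),
        )
    if form == "hill_generalized":
        _require_keys(entry, {"form", "regulators", "K", "H", "eps"}, path)
        regs = tuple(int(r) - 1 for r in entry["regulators"])
        eps = tuple(float(e) for e in entry["eps"])
        if len(regs) != 2 or len(eps) != 3:
            raise ConfigError(f"[{path}]: hill_generalized needs 2 regulators and 3 leakages")
        return RegulationSpec(
            form="hill_generalized",
            regulators=regs,
            K=tuple(float(v) for v in entry["K"]),
            H=tuple(float(v) for v in entry["H"]),
            eps=eps,
        )
    raise ConfigError(f"[{path}]: unknown regulation form {form!r}")


def _parse_degradation(entry: dict, idx: int) -> DegradationSpec:
    path = f"model.degradation[{idx}]"
    form = entry.get("form")
    if form == "constant":
        _require_keys(entry, {"form", "rate"}, path)
        return DegradationSpec(form="constant", rate=float(entry["rate"]))
    if form == "competence_rational":
        _require_keys(entry, {"form", "delta", "gamma_k", "gamma_s"}, path)
        return DegradationSpec(
            form="competence_rational",
            delta=float(entry["delta"]),
            gamma_k=float(entry["gamma_k"]),
            gamma_s=float(entry["gamma_s"]),
        )
    raise ConfigError(f"[{path}]: unknown degradation form {form!r}")


def parse_config(raw: dict, name: str = "") -> RunConfig:
    """Build a validated :class:`RunConfig` from a parsed TOML/JSON mapping."""
    _require_keys(raw, {"name", "model", "grid", "solver", "initial_pdf"}, "<root>")
    name = raw.get("name", name)
    try:
        msec = raw["model"]
        gsec = raw["grid"]
    except KeyError as err:
        raise ConfigError(f"missing required section [{err.args[0]}]") from None

    _require_keys(msec, {"n", "km", "burst", "regulation", "degradation"}, "model")
    n = int(msec["n"])
    grid_allowed = {"N", "L"}
    _require_keys(gsec, grid_allowed, "grid")
    grid = TruncatedGrid([int(v) for v in gsec["N"]], [float(v) for v in gsec["L"]])

    model = GRNModel(
        n=n,
        km=tuple(float(v) for v in msec["km"]),
        burst=tuple(float(v) for v in msec["burst"]),
        regulation=tuple(_parse_regulation(e, i) for i, e in enumerate(msec["regulation"])),
        degradation=tuple(_parse_degradation(e, i) for i, e in enumerate(msec["degradation"])),
        domain=grid.L,
        name=name,
    )
    problems = validate_model(model)
    if problems:
        raise ConfigError("invalid model: " + "; ".join(problems))
    if grid.n != n:
        raise ConfigError(f"grid has {grid.n} dimensions but model has {n} genes")

    ssec = dict(raw.get("solver", {}))
    _require_keys(
        ssec,
        {"stationary_method", "tolerance", "dt", "t_final", "gamma_ref", "quadrature_order"},
        "solver",
    )
    pdf_sec = dict(raw.get("initial_pdf", {"kind": "uniform"}))
    _require_keys(pdf_sec, {"kind", "center", "width", "cell", "seed"}, "initial_pdf")
    return RunConfig(
        model=model,
        grid=grid,
        stationary_method=str(ssec.get("stationary_method", "direct")),
        tolerance=float(ssec.get("tolerance", 1e-12)),
        dt=float(ssec["dt"]) if ssec.get("dt") else None,
        t_final=float(ssec["t_final"]) if ssec.get("t_final") else None,
        gamma_ref=float(ssec.get("gamma_ref", 1.0)),
        quadrature_order=int(ssec.get("quadrature_order", 1)),
        initial_pdf=pdf_sec,
        seed=int(pdf_sec.get("seed", 0)),
        name=name,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML (or JSON) run configuration file."""
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    return parse_config(raw, name=path.stem)


def load_example(name: str, N=None, L=None) -> RunConfig:
    """Load one of the bundled example parameter sets by name.

    ``N`` and ``L`` optionally override the grid (per-dimension sequences or
    scalars applied to every dimension).
    """
    if name not in EXAMPLE_NAMES:
        raise KeyError(f"unknown example {name!r}; available: {EXAMPLE_NAMES}")
    text = resources.files("grnfvm").joinpath(f"examples/{name}.toml").read_text()
    raw = tomllib.loads(text)
    if N is not None or L is not None:
        n = int(raw["model"]["n"])
        if N is not None:
            N = [N] * n if isinstance(N, int) else list(N)
            raw["grid"]["N"] = [int(v) for v in N]
        if L is not None:
            L = [L] * n if isinstance(L, (int, float)) else list(L)
            raw["grid"]["L"] = [float(v) for v in L]
    return parse_config(raw, name=name)
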