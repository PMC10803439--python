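"""Declarative parameterization of an n-gene bursty expression network.

A :class:`GRNModel` holds, per gene ``i``: the transcription (burst
frequency) rate ``km[i]`` (1/time), the mean burst size ``burst[i]``
(protein units), a regulation function ``c_i : R_+^n -> (0, 1]`` and a
degradation-rate function ``gamma_i : R_+^n -> R_+`` (1/time), plus the
truncation length ``L[i]`` of the computational domain.

Regulation functions are signed Hill functions in the convention where a
*positive* Hill coefficient ``H`` means repression (c falls from 1 to the
leakage ``eps`` as the regulator grows) and a *negative* ``H`` means
activation (c rises from ``eps`` at zero regulator to 1).  All forms are
evaluated through the logistic saturation variable

    w = expit(H * log(x / K)) = x^H / (K^H + x^H),

which is finite and overflow-free for every ``x >= 0`` including the
``x = 0`` limit with ``H < 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "RegulationSpec",
    "DegradationSpec",
    "GRNModel",
    "eval_regulation",
    "eval_degradation",
    "validate_model",
]

RegulationForm = Literal["hill_univariate", "hill_generalized", "constant"]
DegradationForm = Literal["constant", "competence_rational"]


def _saturation(x: np.ndarray, K: float, H: float) -> np.ndarray:
    """w = x^H / (K^H + x^H), computed as expit(H log(x/K)).

    Monotone from 0 to 1 in x for H > 0 and from 1 to 0 for H < 0; the
    x = 0 endpoint is taken in the limit sense (w = 0 for H > 0, w = 1 for
    H < 0).
    """
    with np.errstate(divide="ignore"):
        s = H * (np.log(x) - np.log(K))
    return expit(s)


@dataclass(frozen=True)
class RegulationSpec:
    """Transcription-regulation function of a single gene.

    form = "hill_univariate":
        c(x) = (K^H + eps * x_r^H) / (K^H + x_r^H), one regulator ``r``.
    form = "hill_generalized":
        two-regulator rational Hill form; with saturation variables
        w_1, w_2 of the two regulators it is the bilinear blend
        c = eps_both*w1*w2 + eps_second*(1-w1)*w2
            + eps_first*w1*(1-w2) + (1-w1)*(1-w2),
        i.e. corner leakages when one or both regulators saturate.
    form = "constant":
        c = 1 (unregulated; equivalent to eps = 1).

    ``regulators`` are 0-based gene indices.
    """

    form: RegulationForm
    regulators: tuple[int, ...] = ()
    K: tuple[float, ...] = ()
    H: tuple[float, ...] = ()
    eps: tuple[float, ...] = ()

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate c at points ``x`` of shape (..., n)."""
        x = np.asarray(x, dtype=float)
        if self.form == "constant":
            return np.ones(x.shape[:-1])
        if self.form == "hill_univariate":
            (r,) = self.regulators
            w = _saturation(x[..., r], self.K[0], self.H[0])
            return 1.0 - (1.0 - self.eps[0]) * w
        if self.form == "hill_generalized":
            r1, r2 = self.regulators
            w1 = _saturation(x[..., r1], self.K[0], self.H[0])
            w2 = _saturation(x[..., r2], self.K[1], self.H[1])
            e_both, e_second, e_first = self.eps
            return (
                e_both * w1 * w2
                + e_second * (1.0 - w1) * w2
                + e_first * w1 * (1.0 - w2)
                + (1.0 - w1) * (1.0 - w2)
            )
        raise ValueError(f"unknown regulation form {self.form!r}")


@dataclass(frozen=True)
class DegradationSpec:
    """Protein degradation-rate function gamma(x) of a single gene.

    form = "constant": gamma = rate.
    form = "competence_rational": the MecA-mediated shared-degradation form
        gamma(x) = delta * Gk * Gs / (Gk * Gs + Gs * x_1 + Gk * x_2),
    strictly positive and bounded by delta (requires a 2-gene model).
    """

    form: DegradationForm
    rate: float = 0.0
    delta: float = 0.0
    gamma_k: float = 0.0
    gamma_s: float = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "constant":
            return np.full(x.shape[:-1], self.rate)
        if self.form == "competence_rational":
            gk, gs = self.gamma_k, self.gamma_s
            return self.delta * gk * gs / (gk * gs + gs * x[..., 0] + gk * x[..., 1])
        raise ValueError(f"unknown degradation form {self.form!r}")


@dataclass(frozen=True)
class GRNModel:
    """Full parameterization of the n-gene PIDE model."""

    n: int
    km: tuple[float, ...]
    burst: tuple[float, ...]
    regulation: tuple[RegulationSpec, ...]
    degradation: tuple[DegradationSpec, ...]
    domain: tuple[float, ...]
    name: str = ""

    def __post_init__(self):
        for fname in ("km", "burst", "domain"):
            v = getattr(self, fname)
            if len(v) != self.n:
                raise ValueError(f"{fname} must have length n={self.n}, got {len(v)}")
        if len(self.regulation) != self.n or len(self.degradation) != self.n:
            raise ValueError("regulation and degradation must have one entry per gene")


def eval_regulation(model: GRNModel, gene: int, x) -> np.ndarray:
    """c_gene(x) for points ``x`` of shape (..., n); values in (0, 1].

    ``gene`` is a 0-based index.  Raises for negative coordinates.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape[-1] != model.n:
        raise ValueError(f"points must have {model.n} coordinates, got shape {x.shape}")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("regulation evaluated outside the nonnegative domain")
    return model.regulation[gene](x)


def eval_degradation(model: GRNModel, gene: int, x) -> np.ndarray:
    """gamma_gene(x) (the rate, not the flux -gamma*x_i) at points ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape[-1] != model.n:
        raise ValueError(f"points must have {model.n} coordinates, got shape {x.shape}")
    return model.degradation[gene](x)


def validate_model(model: GRNModel) -> list[str]:
    """Collect human-readable invariant violations; empty when valid."""
    out: list[str] = []
    if model.n < 1:
        out.append(f"gene count n must be >= 1, got {model.n}")
    for i in range(model.n):
        if model.km[i] <= 0:
            out.append(f"gene {i}: transcription rate km={model.km[i]} must be positive")
        if model.burst[i] <= 0:
            out.append(f"gene {i}: burst size b={model.burst[i]} must be positive")
        if model.domain[i] <= 0:
            out.append(f"gene {i}: domain length L={model.domain[i]} must be positive")
        reg = model.regulation[i]
        if reg.form != "constant":
            for K in reg.K:
                if K <= 0:
                    out.append(f"gene {i}: Hill threshold K={K} must be positive")
            for e in reg.eps:
                if not 0.0 <= e <= 1.0:
                    out.append(f"gene {i}: leakage eps={e} outside the range [0, 1]")
            for r in reg.regulators:
                if not 0 <= r < model.n:
                    out.append(f"gene {i}: regulator index {r} out of range")
        deg = model.degradation[i]
        if deg.form == "constant" and deg.rate <= 0:
            out.append(f"gene {i}: degradation rate {deg.rate} must be positive")
        if deg.form == "competence_rational":
            if model.n != 2:
                out.append(f"gene {i}: competence_rational degradation requires n=2")
            for pname in ("delta", "gamma_k", "gamma_s"):
                if getattr(deg, pname) <= 0:
                    out.append(f"gene {i}: {pname}={getattr(deg, pname)} must be positive")
    return out
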