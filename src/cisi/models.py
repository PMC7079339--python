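"""Parameter containers and deterministic right-hand sides of the three
tumor-immune interaction models.

Three nested models are provided:

* **base** -- tumor cells ``T`` grow logistically and are killed by effector
  cells ``E`` at mass-action rate ``k``; effectors are supplied at a constant
  rate, die, and experience a *net* per-tumor-cell modulation ``m`` that can
  be proliferative (``m > 0``) or suppressive (``m < 0``).
* **saturation** -- the net modulation is split into Michaelis-Menten
  saturating proliferation (``b_e``, ``kappa_e``) and exhaustion
  (``d_e``, ``kappa_d``) terms.
* **nkctl** -- effectors are split into NK cells ``N`` (constant supply,
  saturating proliferation/exhaustion) and CTLs ``E`` (no constant supply;
  primed by NK-tumor encounters at rate ``omega``).

All states are real-valued densities in units of cells; time is measured in
days.  Parameter containers are immutable; time-varying killing efficacies
used by treatment protocols are realized by constructing modified copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace
from typing import Union

import numpy as np

__all__ = [
    "BaseParams",
    "SaturationParams",
    "NkCtlParams",
    "base_rhs",
    "saturation_rhs",
    "nkctl_rhs",
    "rhs_for",
    "PRESETS",
    "get_preset",
]


class InvalidStateError(ValueError):
    """Raised when a state vector is non-finite or has the wrong dimension."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class BaseParams:
    """Rates of the two-compartment base model.

    Parameters
    ----------
    a : float
        Maximum tumor replication rate (day^-1).
    b : float
        Inverse carrying capacity (cells^-1).
    k : float
        Effector killing efficacy (cells^-1 day^-1).
    sigma : float
        Constant effector replenishment rate (cells day^-1).
    d : float
        Effector death rate (day^-1).
    m : float
        Net effector proliferation (m > 0) or suppression (m < 0) rate per
        tumor cell (cells^-1 day^-1).  The biologically plausible regime is
        m < 0; a warning is emitted otherwise.
    """

    a: float
    b: float
    k: float
    sigma: float
    d: float
    m: float

    def __post_init__(self) -> None:
        _require(self.a > 0, f"a must be > 0, got {self.a}")
        _require(self.b > 0, f"b must be > 0, got {self.b}")
        _require(self.k >= 0, f"k must be >= 0, got {self.k}")
        _require(self.sigma >= 0, f"sigma must be >= 0, got {self.sigma}")
        _require(self.d > 0, f"d must be > 0, got {self.d}")
        if self.m >= 0:
            warnings.warn(
                "m >= 0 (net immunoproliferative regime) is biologically "
                "implausible for these models",
                UserWarning,
                stacklevel=2,
            )

    @property
    def carrying_capacity(self) -> float:
        return 1.0 / self.b

    def with_k(self, k: float) -> "BaseParams":
        """Return a copy with the killing efficacy replaced."""
        return replace(self, k=k)


@dataclass(frozen=True)
class SaturationParams:
    """Rates of the saturating proliferation/exhaustion model.

    ``a, b, k, sigma, d`` as in :class:`BaseParams`; in addition effector
    proliferation saturates at maximum rate ``b_e`` (half-saturation
    ``kappa_e`` cells) and tumor-contact exhaustion kills effectors at
    maximum rate ``d_e`` (half-saturation ``kappa_d`` cells).
    """

    a: float
    b: float
    k: float
    sigma: float
    d: float
    b_e: float
    kappa_e: float
    d_e: float
    kappa_d: float

    def __post_init__(self) -> None:
        _require(self.a > 0, f"a must be > 0, got {self.a}")
        _require(self.b > 0, f"b must be > 0, got {self.b}")
        _require(self.k >= 0, f"k must be >= 0, got {self.k}")
        _require(self.sigma >= 0, f"sigma must be >= 0, got {self.sigma}")
        _require(self.d > 0, f"d must be > 0, got {self.d}")
        _require(self.b_e >= 0, f"b_e must be >= 0, got {self.b_e}")
        _require(self.d_e >= 0, f"d_e must be >= 0, got {self.d_e}")
        _require(self.kappa_e > 0, f"kappa_e must be > 0, got {self.kappa_e}")
        _require(self.kappa_d > 0, f"kappa_d must be > 0, got {self.kappa_d}")

    @property
    def carrying_capacity(self) -> float:
        return 1.0 / self.b

    def with_k(self, k: float) -> "SaturationParams":
        return replace(self, k=k)


@dataclass(frozen=True)
class NkCtlParams:
    """Rates of the three-compartment NK + CTL model.

    Tumor cells are killed by NK cells at rate ``c`` and by CTLs at rate
    ``k``.  NK cells have a constant supply ``sigma``, death rate ``mu`` and
    saturating proliferation/exhaustion (``b_n``/``kappa_bn``,
    ``d_n``/``kappa_dn``).  CTLs have no constant supply: they are primed by
    NK-tumor encounters at rate ``omega`` and otherwise die at rate ``d``
    with saturating proliferation/exhaustion (``b_e``/``kappa_be``,
    ``d_e``/``kappa_de``).
    """

    a: float
    b: float
    c: float
    k: float
    sigma: float
    mu: float
    b_n: float
    kappa_bn: float
    d_n: float
    kappa_dn: float
    d: float
    b_e: float
    kappa_be: float
    d_e: float
    kappa_de: float
    omega: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "mu", "d"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        for name in ("c", "k", "sigma", "b_n", "d_n", "b_e", "d_e", "omega"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("kappa_bn", "kappa_dn", "kappa_be", "kappa_de"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    @property
    def carrying_capacity(self) -> float:
        return 1.0 / self.b

    def with_k(self, k: float) -> "NkCtlParams":
        return replace(self, k=k)


Params = Union[BaseParams, SaturationParams, NkCtlParams]


def _as_state(state, dim: int) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (dim,):
        raise InvalidStateError(f"expected state of dimension {dim}, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidStateError(f"state contains non-finite components: {x}")
    return x


def base_rhs(state, params: BaseParams) -> np.ndarray:
    """Time derivative (dT/dt, dE/dt) of the base model in cells/day."""
    T, E = _as_state(state, 2)
    p = params
    dT = p.a * T * (1.0 - p.b * T) - p.k * T * E
    dE = p.sigma - p.d * E + p.m * E * T
    return np.array([dT, dE])


def saturation_rhs(state, params: SaturationParams) -> np.ndarray:
    """Time derivative (dT/dt, dE/dt) of the saturation model in cells/day."""
    T, E = _as_state(state, 2)
    p = params
    dT = p.a * T * (1.0 - p.b * T) - p.k * T * E
    dE = (
        p.sigma
        - p.d * E
        + p.b_e * T / (p.kappa_e + T) * E
        - p.d_e * T / (p.kappa_d + T) * E
    )
    return np.array([dT, dE])


def nkctl_rhs(state, params: NkCtlParams) -> np.ndarray:
    """Time derivative (dT/dt, dN/dt, dE/dt) of the NK + CTL model."""
    T, N, E = _as_state(state, 3)
    p = params
    dT = p.a * T * (1.0 - p.b * T) - p.c * N * T - p.k * T * E
    dN = (
        p.sigma
        - p.mu * N
        + p.b_n * T / (p.kappa_bn + T) * N
        - p.d_n * T / (p.kappa_dn + T) * N
    )
    dE = (
        -p.d * E
        + p.b_e * T / (p.kappa_be + T) * E
        - p.d_e * T / (p.kappa_de + T) * E
        + p.omega * N * T
    )
    return np.array([dT, dN, dE])


def rhs_for(params: Params):
    """Return the RHS function matching a parameter container's model."""
    if isinstance(params, BaseParams):
        return base_rhs
    if isinstance(params, SaturationParams):
        return saturation_rhs
    if isinstance(params, NkCtlParams):
        return nkctl_rhs
    raise TypeError(f"unknown parameter type {type(params)!r}")


def state_dim(params: Params) -> int:
    return 3 if isinstance(params, NkCtlParams) else 2


# ---------------------------------------------------------------------------
# Presets.
#
# ``table1``: standard base-model values (d = 1e-2/day).  ``fig2``: same
# values except d = 2e-2/day, as used in the killing-efficacy bifurcation
# diagram.  The two death rates are shipped as distinct presets on purpose;
# they are not reconciled.  The killing efficacy default k = 1e-4 is the
# lower end of the quoted plausible range (1e-4 .. 10) and the value used by
# the untreated/treated simulation experiments.
#
# ``saturation_default`` and ``nkctl_default`` are NOT canonical: the source
# supplementary values were unavailable, so these are documented plausible
# sets chosen to lie in the exhaustion-dominated (bistable-capable) regime.
# ---------------------------------------------------------------------------

TABLE1 = BaseParams(a=0.514, b=1.02e-9, k=1e-4, sigma=10.0, d=1e-2, m=-1e-6)
FIG2 = BaseParams(a=0.514, b=1.02e-9, k=1e-4, sigma=10.0, d=2e-2, m=-1e-6)

SATURATION_DEFAULT = SaturationParams(
    a=0.514,
    b=1.02e-9,
    k=1e-3,
    sigma=10.0,
    d=1e-2,
    b_e=0.1,
    kappa_e=1e4,
    d_e=2.0,
    kappa_d=1e4,
)

NKCTL_DEFAULT = NkCtlParams(
    a=0.514,
    b=1.02e-9,
    c=1e-3,
    k=1e-3,
    sigma=10.0,
    mu=1e-2,
    b_n=0.1,
    kappa_bn=1e4,
    d_n=2.0,
    kappa_dn=1e4,
    d=1e-2,
    b_e=0.1,
    kappa_be=1e4,
    d_e=2.0,
    kappa_de=1e4,
    omega=1e-7,
)

PRESETS: dict[str, Params] = {
    "table1": TABLE1,
    "fig2": FIG2,
    "saturation_default": SATURATION_DEFAULT,
    "nkctl_default": NKCTL_DEFAULT,
}


def get_preset(name: str) -> Params:
    """Look up a named parameter preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def params_to_dict(params: Params) -> dict:
    """Flat dict representation (model tag + named rates)."""
    model = {BaseParams: "base", SaturationParams: "saturation", NkCtlParams: "nkctl"}[
        type(params)
    ]
    out = {"model": model}
    for f in fields(params):
        out[f.name] = getattr(params, f.name)
    return out
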