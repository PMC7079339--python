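"""Fixed points, stability, and bistability/multistability conditions.

The base model's nontrivial equilibria are roots of a quadratic, the
saturation model's of a cubic, and the NK+CTL model's of a quintic (treated
numerically).  Closed-form regime conditions are evaluated exactly as
printed; whenever a closed-form trigonometric root representation is
numerically indeterminate, numeric root counting is authoritative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root as _root_nd

from .models import (
    BaseParams,
    NkCtlParams,
    SaturationParams,
    base_rhs,
    nkctl_rhs,
    rhs_for,
    saturation_rhs,
)

__all__ = [
    "Equilibrium",
    "RegimeClassification",
    "CubicCoefficients",
    "base_equilibria",
    "base_k_thresholds",
    "classify_base_regime",
    "saturation_cubic_coeffs",
    "saturation_bistability",
    "saturation_multistability",
    "saturation_equilibria",
    "nkctl_plausibility",
    "nkctl_equilibria",
    "stability_of",
]

# Tolerances (days^-1 for eigenvalues; residuals scaled by state magnitude).
TOL_EIG = 1e-10
TOL_RESID = 1e-6
TOL_DEDUP = 1e-4

STABLE = "stable"
UNSTABLE = "unstable"
SADDLE = "saddle"
MARGINAL = "marginal"


class NotAnEquilibriumError(ValueError):
    """Raised when stability is requested at a point with a large RHS residual."""


class RegimeError(ValueError):
    """Raised when closed-form thresholds are requested outside their regime."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its linear stability.

    ``state`` is (T, E) or (T, N, E); ``stability`` is one of
    ``stable``/``unstable``/``saddle``/``marginal``; ``method`` records
    whether the point came from a closed form or a numeric search.
    """

    state: tuple
    stability: str
    method: str
    eigenvalues: tuple

    @property
    def T(self) -> float:
        return self.state[0]

    @property
    def E(self) -> float:
        return self.state[-1]

    @property
    def max_real_eig(self) -> float:
        return max(ev.real for ev in self.eigenvalues)


@dataclass(frozen=True)
class RegimeClassification:
    """Root-sign regime of a model's positive equilibria.

    For the base model ``case_label`` is ``"i"`` (only the cancer-free
    state), ``"ii"`` (single positive attractor), ``"iii"`` (bistable) or
    ``"marginal"`` at a threshold.  ``conditions_satisfied`` maps the named
    closed-form conditions to booleans (``None`` = indeterminate).
    """

    case_label: str
    n_positive_roots: int
    conditions_satisfied: dict


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of the saturation-model equilibrium cubic A T^3 + B T^2 + C T + D."""

    A: float
    B: float
    C: float
    D: float

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D])


# ---------------------------------------------------------------------------
# Stability by linearization
# ---------------------------------------------------------------------------


def _fd_jacobian(f, x: np.ndarray) -> np.ndarray:
    """Central finite-difference Jacobian with per-component scaled steps."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2.0 * h)
    return J


def _label_from_eigs(eigs: np.ndarray, tol: float = TOL_EIG) -> str:
    re = eigs.real
    if np.all(re < -tol):
        return STABLE
    if np.any(re > tol):
        return UNSTABLE
    return MARGINAL


def stability_of(point, params, rhs=None, *, tol_resid: float = TOL_RESID):
    """Stability label and eigenvalues of a fixed point by linearization.

    The Jacobian is computed by central finite differences with steps scaled
    per component.  A point is ``stable`` iff all eigenvalue real parts are
    below ``-TOL_EIG``, ``unstable`` if any exceeds ``+TOL_EIG`` (this
    includes saddles), else ``marginal``.

    Raises
    ------
    NotAnEquilibriumError
        If the RHS residual at ``point`` exceeds ``tol_resid`` times the
        state scale.
    """
    if rhs is None:
        rhs = rhs_for(params)
    x = np.asarray(point, dtype=float)
    resid = np.asarray(rhs(x, params))
    scale = max(np.max(np.abs(x)), 1.0)
    if np.max(np.abs(resid)) > tol_resid * scale:
        raise NotAnEquilibriumError(
            f"RHS residual {resid} too large at {x} (scale {scale:g})"
        )
    J = _fd_jacobian(lambda y: rhs(y, params), x)
    eigs = np.linalg.eigvals(J)
    return _label_from_eigs(eigs), eigs


def _make_equilibrium(state, params, method: str, rhs=None) -> Equilibrium:
    label, eigs = stability_of(state, params, rhs)
    return Equilibrium(
        state=tuple(float(v) for v in state),
        stability=label,
        method=method,
        eigenvalues=tuple(complex(ev) for ev in eigs),
    )


# ---------------------------------------------------------------------------
# Base model
# ---------------------------------------------------------------------------


def base_discriminant(p: BaseParams) -> float:
    """Discriminant of the quadratic for the positive equilibria."""
    return (p.a * (p.m + p.b * p.d)) ** 2 - 4.0 * p.a * p.b * p.m * (
        p.a * p.d - p.k * p.sigma
    )


def base_positive_roots(p: BaseParams) -> list[float]:
    """Real roots T* > 0 of the nontrivial equilibrium quadratic.

    Uses the closed form T = [a(m+bd) +/- sqrt(D)] / (2abm); degenerate
    m = 0 or k = 0 cases use explicit reduced formulas.
    """
    if p.k == 0.0:
        # killing decoupled: tumor is purely logistic
        return [1.0 / p.b]
    if p.m == 0.0:
        # E* = sigma/d always; linear equation for T*
        T = (1.0 - p.k * p.sigma / (p.a * p.d)) / p.b
        return [T] if T > 0 else []
    disc = base_discriminant(p)
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    denom = 2.0 * p.a * p.b * p.m
    roots = [(p.a * (p.m + p.b * p.d) + sq) / denom, (p.a * (p.m + p.b * p.d) - sq) / denom]
    tol = TOL_DEDUP
    return sorted(r for r in roots if r > tol)


def _base_E_star(T: float, p: BaseParams) -> float:
    """Effector level solving dT/dt = 0 at tumor level T > 0."""
    if p.k > 0:
        return p.a * (1.0 - p.b * T) / p.k
    # k = 0: recover E* from the effector equation instead
    return p.sigma / (p.d - p.m * T)


def base_equilibria(params: BaseParams) -> list[Equilibrium]:
    """All non-negative fixed points of the base model, with stability.

    Always contains the cancer-free point (0, sigma/d).  Positive tumor
    equilibria come from the closed-form quadratic; points with E* < 0 are
    discarded.  Results are sorted by T*.
    """
    p = params
    out = [_make_equilibrium((0.0, p.sigma / p.d), p, "analytic", base_rhs)]
    for T in base_positive_roots(p):
        E = _base_E_star(T, p)
        if E < 0:
            continue
        out.append(_make_equilibrium((T, E), p, "analytic", base_rhs))
    return sorted(out, key=lambda eq: eq.T)


def base_k_thresholds(params: BaseParams) -> tuple[float, float]:
    """Closed-form killing-efficacy bounds (k_l, k_u) of the bistable window.

    Valid only in the plausibility regime m < 0 and m + b d < 0; for
    k_l < k < k_u the model has two positive equilibria besides T = 0.
    """
    p = params
    if p.m >= 0:
        raise RegimeError(f"thresholds require m < 0 (got m={p.m})")
    if p.m + p.b * p.d >= 0:
        raise RegimeError(
            f"thresholds require m + b*d < 0 (got {p.m + p.b * p.d})"
        )
    k_l = p.a * p.d / p.sigma
    k_u = k_l - (p.a * (p.m + p.b * p.d)) ** 2 / (4.0 * p.a * p.b * p.m) / p.sigma
    return k_l, k_u


def classify_base_regime(
    params: BaseParams, *, rel_tol: float = 1e-12
) -> RegimeClassification:
    """Sign-arrangement case of the base model's quadratic roots.

    ``i``: k > k_u, only the cancer-free state; ``ii``: k < k_l, a single
    positive attractor; ``iii``: k_l < k < k_u, bistable.  k within
    ``rel_tol`` of a threshold is labeled ``marginal``.
    """
    p = params
    k_l, k_u = base_k_thresholds(p)
    conditions = {
        "eq5": p.m < 0,
        "eq6": p.m + p.b * p.d < 0,
        "eq7": p.k > k_l,
        "eq8": p.k < k_u,
    }
    n_pos = len(base_positive_roots(p))
    if math.isclose(p.k, k_l, rel_tol=rel_tol) or math.isclose(
        p.k, k_u, rel_tol=rel_tol
    ):
        label = MARGINAL
    elif p.k > k_u:
        label = "i"
    elif p.k < k_l:
        label = "ii"
    else:
        label = "iii"
    return RegimeClassification(
        case_label=label, n_positive_roots=n_pos, conditions_satisfied=conditions
    )


# ---------------------------------------------------------------------------
# Saturation model
# ---------------------------------------------------------------------------


def saturation_cubic_coeffs(params: SaturationParams) -> CubicCoefficients:
    """Coefficients A, B, C, D of the positive-equilibrium cubic."""
    p = params
    ke, kd = p.kappa_e, p.kappa_d
    A = -p.a * p.b * (p.d - p.b_e + p.d_e)
    B = (
        p.a * p.b * (p.b_e * kd - p.d_e * ke - p.d * (kd + ke))
        + p.a * (p.d_e + p.d - p.b_e)
        - p.sigma * p.k
    )
    C = (
        p.a * (p.d_e * ke - p.b_e * kd)
        + p.a * p.d * (kd + ke - p.b * kd * ke)
        - p.sigma * p.k * (kd + ke)
    )
    D = kd * ke * (p.a * p.d - p.sigma * p.k)
    return CubicCoefficients(A=A, B=B, C=C, D=D)


def cubic_discriminant(c: CubicCoefficients) -> float:
    """18ABCD - 4B^3 D + B^2 C^2 - 4AC^3 - 27 A^2 D^2 (> 0 iff 3 distinct real roots)."""
    A, B, C, D = c.A, c.B, c.C, c.D
    return (
        18.0 * A * B * C * D
        - 4.0 * B**3 * D
        + B**2 * C**2
        - 4.0 * A * C**3
        - 27.0 * A**2 * D**2
    )


def _trig_roots(c: CubicCoefficients, *, arg_tol: float = 1e-12):
    """Smallest and middle roots via the closed trigonometric representation.

    Evaluated in extended precision.  Returns (x_small, x_mid) or None when
    the representation is indeterminate: it requires three real roots
    (B^2 - 3AC > 0, arccos argument in [-1, 1]) and cannot resolve roots
    whose magnitude is below its numerical resolution (a fixed multiple of
    sqrt(machine epsilon) times the root scale -- arccos near +/-1 loses
    half the mantissa).
    """
    L = np.longdouble
    A, B, C, D = L(c.A), L(c.B), L(c.C), L(c.D)
    if A == 0.0:
        return None
    q = B * B - 3.0 * A * C
    if q <= 0.0:
        return None
    sq = np.sqrt(q / (9.0 * A * A))
    num = B * (2.0 * B * B - 9.0 * A * C) + 27.0 * A * A * D
    arg13 = num / (6.0 * A * q * sq)
    if abs(arg13) > 1.0 + L(arg_tol):
        return None
    arg13 = min(L(1.0), max(L(-1.0), arg13))
    arg14 = -arg13
    x_small = -2.0 * sq * np.cos(np.arccos(arg13) / 3.0) - B / (3.0 * A)
    x_mid = (
        2.0 * sq * np.cos(np.arccos(arg14) / 3.0 - 2.0 * np.pi / 3.0)
        - B / (3.0 * A)
    )
    resolution = 10.0 * math.sqrt(float(np.finfo(np.longdouble).eps)) * float(sq)
    if min(abs(float(x_small)), abs(float(x_mid))) < resolution:
        return None
    return float(x_small), float(x_mid)


def _cubic_positive_roots(c: CubicCoefficients, *, tol: float = TOL_DEDUP) -> list[float]:
    """Numeric real roots T > 0 of the cubic (degenerate degrees handled)."""
    coeffs = c.as_array()
    nz = np.flatnonzero(np.abs(coeffs) > 0)
    if nz.size == 0:
        return []
    coeffs = coeffs[nz[0] :]
    if coeffs.size == 1:
        return []
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9 * np.maximum(np.abs(roots.real), 1.0)].real
    return sorted(float(r) for r in real if r > tol)


def saturation_bistability(
    params: SaturationParams,
) -> tuple[bool, RegimeClassification]:
    """Whether the saturation model has exactly two positive tumor equilibria.

    Evaluates the printed closed-form conditions: the cubic discriminant
    positivity plus the two trigonometric root-location inequalities (the
    smallest root negative, the middle root positive).  If the trig forms
    are indeterminate the result falls back to numeric root counting, which
    is always authoritative.
    """
    c = saturation_cubic_coeffs(params)
    disc = cubic_discriminant(c)
    n_pos = len(_cubic_positive_roots(c))
    conds: dict = {"eq12": disc > 0.0}
    if disc > 0.0:
        tr = _trig_roots(c)
        if tr is None:
            conds["eq13"] = None
            conds["eq14"] = None
            bistable = n_pos == 2
        else:
            x_small, x_mid = tr
            conds["eq13"] = x_small < 0.0
            conds["eq14"] = x_mid > 0.0
            bistable = conds["eq12"] and conds["eq13"] and conds["eq14"]
    else:
        conds["eq13"] = False
        conds["eq14"] = False
        bistable = False
    label = "bistable" if bistable else ("multistable" if n_pos == 3 else "other")
    return bistable, RegimeClassification(
        case_label=label, n_positive_roots=n_pos, conditions_satisfied=conds
    )


def saturation_multistability(params: SaturationParams) -> bool:
    """Whether the model has four equilibria in T (three positive roots plus 0).

    Closed form: discriminant > 0 and the smallest trigonometric root > 0;
    numeric root counting is the fallback/cross-check.
    """
    c = saturation_cubic_coeffs(params)
    if cubic_discriminant(c) <= 0.0:
        return False
    tr = _trig_roots(c)
    if tr is None:
        return len(_cubic_positive_roots(c)) == 3
    return tr[0] > 0.0


def saturation_equilibria(params: SaturationParams) -> list[Equilibrium]:
    """All non-negative fixed points of the saturation model, with stability."""
    p = params
    out = [_make_equilibrium((0.0, p.sigma / p.d), p, "analytic", saturation_rhs)]
    if p.k == 0.0:
        Ts = [1.0 / p.b]
    else:
        Ts = _cubic_positive_roots(saturation_cubic_coeffs(p))
    for T in Ts:
        if p.k > 0:
            E = p.a * (1.0 - p.b * T) / p.k
        else:
            denom = p.d - p.b_e * T / (p.kappa_e + T) + p.d_e * T / (p.kappa_d + T)
            if denom <= 0:
                continue
            E = p.sigma / denom
        if E < 0:
            continue
        out.append(_make_equilibrium((T, E), p, "analytic", saturation_rhs))
    return sorted(out, key=lambda eq: eq.T)


# ---------------------------------------------------------------------------
# NK + CTL model
# ---------------------------------------------------------------------------


def nkctl_plausibility(params: NkCtlParams) -> bool:
    """Net-suppression plausibility condition of the NK+CTL model.

    True iff  -a*b*((b_e-d_e-d)*(b_n-d_n-mu)) - k*sigma*omega < 0.  The
    expression does not involve the four half-saturation constants.
    """
    p = params
    expr = (
        -p.a * p.b * ((p.b_e - p.d_e - p.d) * (p.b_n - p.d_n - p.mu))
        - p.k * p.sigma * p.omega
    )
    return expr < 0.0


def _nkctl_NE_of_T(T: float, p: NkCtlParams):
    """(N*, E*) solving the NK and CTL equations at fixed T (may be invalid)."""
    dn_den = (
        p.mu - p.b_n * T / (p.kappa_bn + T) + p.d_n * T / (p.kappa_dn + T)
    )
    if dn_den <= 0:
        return None
    N = p.sigma / dn_den
    de_den = p.d - p.b_e * T / (p.kappa_be + T) + p.d_e * T / (p.kappa_de + T)
    if de_den <= 0:
        return None
    E = p.omega * N * T / de_den
    return N, E


def _nkctl_quintic_candidates(p: NkCtlParams, t_max: float) -> list[float]:
    """Positive roots of the polynomial form of dT/dt(T) = 0 (T > 0 branch).

    Assembled by numpy polynomial arithmetic from the rational reduction;
    used as high-quality seeds for the 3-D root polish.
    """
    P = np.polynomial.polynomial.Polynomial
    Pbn = P([p.kappa_bn, 1.0])
    Pdn = P([p.kappa_dn, 1.0])
    Pbe = P([p.kappa_be, 1.0])
    Pde = P([p.kappa_de, 1.0])
    T = P([0.0, 1.0])
    n_den = p.mu * Pbn * Pdn - p.b_n * T * Pdn + p.d_n * T * Pbn
    n_num = p.sigma * Pbn * Pdn
    g = p.d * Pbe * Pde - p.b_e * T * Pde + p.d_e * T * Pbe
    lhs = P([p.a, -p.a * p.b]) * n_den * g - p.c * n_num * g - p.k * p.omega * T * n_num * Pbe * Pde
    roots = lhs.roots()
    real = roots[np.abs(roots.imag) < 1e-8 * np.maximum(np.abs(roots.real), 1.0)].real
    return sorted(float(r) for r in real if TOL_DEDUP < r <= t_max)


def nkctl_equilibria(
    params: NkCtlParams,
    search_box=None,
    *,
    n_starts: int = 64,
) -> list[Equilibrium]:
    """Fixed points of the NK+CTL model: tumor-free plus numeric positive ones.

    The tumor-free point (0, sigma/mu, 0) is exact.  Positive fixed points
    are located by a deterministic multi-start Newton search over
    ``search_box`` (default: T, N, E each in (0, upper] with upper
    2/b for T and generous immune bounds), seeded both from a fixed
    log-spaced lattice and from the roots of the reduced quintic in T.
    Solutions are residual-checked and deduplicated; at most six fixed
    points are ever reported.
    """
    p = params
    if search_box is None:
        search_box = ((0.0, 2.0 / p.b), (0.0, 1e2 * p.sigma / p.mu), (0.0, 1e12))
    box = [(float(lo), float(hi)) for lo, hi in search_box]
    out = [_make_equilibrium((0.0, p.sigma / p.mu, 0.0), p, "analytic", nkctl_rhs)]

    def fun(x):
        return nkctl_rhs(np.maximum(x, 0.0), p)

    # deterministic lattice of starts (log-spaced per axis, fixed ordering)
    n_axis = max(2, round(n_starts ** (1.0 / 3.0)))
    axes = []
    for lo, hi in box:
        lo_eff = max(lo, 1e-3)
        axes.append(np.geomspace(lo_eff, max(hi, 10 * lo_eff), n_axis))
    starts = [np.array([t, n, e]) for t in axes[0] for n in axes[1] for e in axes[2]]
    # quintic-derived seeds (exact N*, E* at candidate T*)
    for T in _nkctl_quintic_candidates(p, box[0][1]):
        ne = _nkctl_NE_of_T(T, p)
        if ne is not None:
            starts.append(np.array([T, ne[0], ne[1]]))

    found: list[np.ndarray] = []
    for x0 in starts:
        sol = _root_nd(fun, x0, method="hybr", options={"xtol": 1e-12})
        if not sol.success:
            continue
        x = sol.x
        if np.any(x < -TOL_DEDUP) or x[0] <= TOL_DEDUP:
            continue
        if not all(lo - TOL_DEDUP <= xi <= hi * (1 + TOL_DEDUP) for xi, (lo, hi) in zip(x, box)):
            continue
        scale = max(np.max(np.abs(x)), 1.0)
        if np.max(np.abs(nkctl_rhs(x, p))) > TOL_RESID * scale:
            continue
        x = np.maximum(x, 0.0)
        if any(
            np.all(np.abs(x - y) <= TOL_DEDUP * np.maximum(np.maximum(np.abs(x), np.abs(y)), 1.0))
            for y in found
        ):
            continue
        found.append(x)
    for x in sorted(found, key=lambda v: v[0]):
        out.append(_make_equilibrium(x, p, "numeric", nkctl_rhs))
    return out[:6]
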