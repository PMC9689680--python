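"""Johnson-Cook flow-stress and damage model for soft protein gels.

The flow stress of the gel in the plastic regime is modeled with the
Johnson-Cook law

    sigma = (A + B * eps_p**n) * (1 + C * ln(eps_dot_p / eps_dot_ref))

optionally multiplied by a thermal-softening bracket
``1 - ((T - T_material) / (T_melt - T_material))**m`` when a thermal block
is configured.  Failure is governed by the companion damage model: plastic
strain increments are integrated against the fracture strain

    eps_f = (d1 + d2 * exp(-d3 * triax)) * (1 + d4 * ln(rate ratio)) * (1 + d5)

and the material fails once the damage variable D reaches 1.

Units are N-mm-MPa throughout (1 MPa = 1 N/mm^2), strain rates in 1/s.

A note on the rate bracket: quasi-static gel tests run far below the
reference rate (pin speeds of 0.5-1 mm/s give strain rates of order
1e-2 1/s against a reference of 1 1/s).  A raw logarithm there is large and
negative and drives both the flow stress and the fracture strain negative,
which is unphysical.  Following the convention of explicit structural
codes, the rate ratio is clamped at 1 from below by default; pass
``clamp_rate=False`` to evaluate the raw bracket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ThermalBlock",
    "DamageConstants",
    "MaterialCard",
    "DamageState",
    "FitResult",
    "surimi_gel_card",
    "jc_flow_stress",
    "jc_flow_stress_thermal",
    "failure_strain",
    "accumulate_damage",
    "fit_jc_hardening",
    "fit_jc_rate",
    "fit_damage",
    "UnidentifiableError",
]


class UnidentifiableError(RuntimeError):
    """Raised when a fit's design cannot identify the requested parameters."""


@dataclass(frozen=True)
class ThermalBlock:
    """Thermal-softening parameters (disabled unless attached to a card)."""

    m: float
    T_melt: float
    T_material: float
    T: float


@dataclass(frozen=True)
class DamageConstants:
    d1: float
    d2: float
    d3: float
    d4: float
    d5: float

    def __post_init__(self) -> None:
        if self.d1 <= 0:
            raise ValueError("d1 must be positive")

    def as_dict(self) -> dict:
        return {f"d{i}": getattr(self, f"d{i}") for i in range(1, 6)}


@dataclass(frozen=True)
class MaterialCard:
    """Elastic constants plus Johnson-Cook hardening and damage parameters.

    E in MPa, density in g/mm^3, A and B in MPa, eps_dot_ref in 1/s; the
    remaining constants are dimensionless.
    """

    E: float
    poisson_nu: float
    density_rho: float
    A: float
    B: float
    n: float
    C: float
    eps_dot_ref: float
    damage: DamageConstants
    thermal: ThermalBlock | None = None
    name: str = "material"

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young modulus E must be positive")
        if not 0.0 < self.poisson_nu <= 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5]")
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must be positive")
        if self.eps_dot_ref <= 0:
            raise ValueError("reference strain rate must be positive")
        if not 0.0 < self.n < 1.0:
            warnings.warn(
                f"strain hardening exponent n={self.n} outside the expected (0, 1)",
                stacklevel=2,
            )

    @property
    def yield_strain(self) -> float:
        """Elastic strain at the initial yield stress, A / E."""
        return self.A / self.E

    def with_damage(self, **kwargs) -> "MaterialCard":
        return replace(self, damage=replace(self.damage, **kwargs))


def surimi_gel_card() -> MaterialCard:
    """Material card for a heat-set Alaska-pollock surimi gel.

    Elastic constants, Johnson-Cook hardening/rate parameters and damage
    constants identified for the gel at room temperature.  Density is
    stored in g/mm^3 (0.97 g/cm^3, water-like).
    """
    return MaterialCard(
        E=0.01719,
        poisson_nu=0.5,
        density_rho=0.00097,
        A=0.00833,
        B=0.01212,
        n=0.6752,
        C=0.07,
        eps_dot_ref=1.0,
        damage=DamageConstants(d1=0.35, d2=0.001, d3=0.001, d4=0.021, d5=0.001),
        name="surimi_gel",
    )


@dataclass
class DamageState:
    """Accumulated damage along a loading path; failure at D >= 1."""

    D: float = 0.0
    eps_plastic_cum: float = 0.0

    @property
    def failed(self) -> bool:
        return self.D >= 1.0


def _rate_bracket(eps_dot: np.ndarray | float, card: MaterialCard, coeff: float,
                  clamp_rate: bool) -> np.ndarray | float:
    ratio = np.asarray(eps_dot, dtype=float) / card.eps_dot_ref
    if np.any(ratio <= 0):
        raise ValueError("plastic strain rate must be positive")
    if clamp_rate:
        ratio = np.maximum(ratio, 1.0)
    return 1.0 + coeff * np.log(ratio)


def jc_flow_stress(eps_plastic, eps_dot_plastic, card: MaterialCard, *,
                   clamp_rate: bool = True):
    """Johnson-Cook flow stress (MPa) at a plastic strain and strain rate.

    Vectorized over both strain and rate.  The rate ratio is clamped at 1
    from below unless ``clamp_rate=False`` (see module docstring).
    """
    eps_p = np.asarray(eps_plastic, dtype=float)
    if np.any(eps_p < 0):
        raise ValueError("plastic strain must be non-negative")
    hard = card.A + card.B * np.power(eps_p, card.n)
    out = hard * _rate_bracket(eps_dot_plastic, card, card.C, clamp_rate)
    return float(out) if np.isscalar(eps_plastic) and np.isscalar(eps_dot_plastic) else out


def jc_flow_stress_thermal(eps_plastic, eps_dot_plastic, card: MaterialCard, *,
                           clamp_rate: bool = True):
    """Flow stress including the thermal-softening bracket.

    Requires ``card.thermal``; the working temperature must lie between the
    material transition temperature and the melting temperature.
    """
    th = card.thermal
    if th is None:
        raise ValueError("material card has no thermal block")
    if not th.T_material <= th.T <= th.T_melt:
        raise ValueError("temperature outside [T_material, T_melt]")
    homologous = (th.T - th.T_material) / (th.T_melt - th.T_material)
    soft = 1.0 - homologous ** th.m
    return jc_flow_stress(eps_plastic, eps_dot_plastic, card, clamp_rate=clamp_rate) * soft


def failure_strain(sigma_m_over_sigma, eps_dot_plastic, card: MaterialCard, *,
                   clamp_rate: bool = True):
    """True fracture strain from the Johnson-Cook damage model.

    ``sigma_m_over_sigma`` is the stress triaxiality (mean over equivalent
    stress).  The trailing (1 + d5) bracket is a constant factor: with the
    thermal term dropped, d5 acts as a fixed multiplier.
    """
    d = card.damage
    triax = np.asarray(sigma_m_over_sigma, dtype=float)
    base = d.d1 + d.d2 * np.exp(-d.d3 * triax)
    out = base * _rate_bracket(eps_dot_plastic, card, d.d4, clamp_rate) * (1.0 + d.d5)
    scalar = np.isscalar(sigma_m_over_sigma) and np.isscalar(eps_dot_plastic)
    return float(out) if scalar else out


def accumulate_damage(eps_plastic_path, eps_f_path, state: DamageState | None = None
                      ) -> DamageState:
    """Integrate damage D += sum(d eps_p / eps_f) along a loading path.

    ``eps_plastic_path`` must be non-decreasing and continue from
    ``state.eps_plastic_cum``; ``eps_f_path`` gives the fracture strain in
    effect over each increment (rectangle rule, right endpoint).  Returns a
    new state; D never decreases.
    """
    if state is None:
        state = DamageState()
    eps_p = np.asarray(eps_plastic_path, dtype=float)
    eps_f = np.asarray(eps_f_path, dtype=float)
    if eps_p.shape != eps_f.shape:
        raise ValueError("paths must have equal length")
    if eps_p.size == 0:
        return DamageState(D=state.D, eps_plastic_cum=state.eps_plastic_cum)
    if np.any(np.diff(eps_p) < 0) or eps_p[0] < state.eps_plastic_cum - 1e-12:
        raise ValueError("plastic strain path must be non-decreasing")
    if np.any(eps_f <= 0):
        raise ValueError("fracture strain must be positive")
    increments = np.diff(np.concatenate(([state.eps_plastic_cum], eps_p)))
    increments = np.maximum(increments, 0.0)
    D = state.D + float(np.sum(increments / eps_f))
    return DamageState(D=D, eps_plastic_cum=float(eps_p[-1]))


@dataclass
class FitResult:
    """Parameter estimates with standard errors and the residual norm."""

    params: dict
    stderr: dict
    residual_norm: float
    flags: list = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def _stderr_from_jacobian(res, names) -> dict:
    """Gauss-Newton standard errors from a scipy least_squares result."""
    m, p = res.jac.shape
    dof = max(m - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se))


def fit_jc_hardening(sigma_true, eps_plastic) -> FitResult:
    """Fit (A, B, n) of the hardening law sigma = A + B * eps_p**n.

    Nonlinear least squares at the reference rate (rate bracket = 1), with
    a fixed multi-start over n in {0.2, 0.5, 0.8}; the best residual wins.
    A practically zero hardening modulus is flagged as
    ``"n_unidentifiable"`` and A falls back to the mean stress.
    """
    sigma = np.asarray(sigma_true, dtype=float)
    eps_p = np.asarray(eps_plastic, dtype=float)
    if sigma.size < 20:
        raise ValueError("need at least 20 points to fit the hardening law")
    pos = eps_p[eps_p > 0]
    if pos.size == 0 or pos.max() / pos.min() < 10.0:
        raise ValueError("plastic strain must span at least one decade")

    def resid(theta):
        A, B, n = theta
        return A + B * np.power(eps_p, n) - sigma

    A0 = max(float(sigma.min()), 1e-12)
    B0 = max(float(sigma.max() - sigma.min()), 1e-12)
    best = None
    for n0 in (0.2, 0.5, 0.8):
        try:
            res = least_squares(
                resid, x0=[A0, B0, n0],
                bounds=([0.0, 0.0, 1e-3], [np.inf, np.inf, 3.0]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("hardening fit failed to converge from all starts")

    names = ["A", "B", "n"]
    params = dict(zip(names, best.x))
    flags = []
    if params["B"] < 1e-6 * max(params["A"], 1e-12):
        flags.append("n_unidentifiable")
        params = {"A": float(np.mean(sigma)), "B": 0.0, "n": np.nan}
    return FitResult(params=params, stderr=_stderr_from_jacobian(best, names),
                     residual_norm=float(np.sqrt(2.0 * best.cost)), flags=flags)


def fit_jc_rate(curves, A: float, B: float, n: float, card: MaterialCard) -> FitResult:
    """Fit the strain-rate sensitivity C with (A, B, n) held fixed.

    ``curves`` is an iterable of (eps_plastic, sigma_true, eps_dot) tuples
    at distinct strain rates at or above the reference rate.  The rate
    bracket is linear in ln(rate ratio), so C is the through-origin
    least-squares slope of sigma / (A + B eps_p**n) - 1 on that logarithm.
    """
    xs, ys = [], []
    for eps_p, sigma, rate in curves:
        eps_p = np.asarray(eps_p, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        ratio = rate / card.eps_dot_ref
        if ratio < 1.0 - 1e-12:
            raise ValueError("rates below the reference rate are clamped; "
                             "use rates >= eps_dot_ref")
        x = np.log(max(ratio, 1.0))
        y = sigma / (A + B * np.power(eps_p, n)) - 1.0
        xs.append(np.full_like(y, x))
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise UnidentifiableError(
            "all rates at the reference rate: the clamped bracket is 1 and C "
            "cannot be identified")
    C = float(np.sum(x * y) / sxx)
    dof = max(x.size - 1, 1)
    s2 = float(np.sum((y - C * x) ** 2)) / dof
    return FitResult(params={"C": C}, stderr={"C": float(np.sqrt(s2 / sxx))},
                     residual_norm=float(np.linalg.norm(y - C * x)))


def fit_damage(eps_f_obs, triaxiality, eps_dot, card: MaterialCard, *,
               ridge: float = 0.1) -> FitResult:
    """Fit the damage constants d1..d5 to observed fracture strains.

    ``triaxiality`` and ``eps_dot`` give the design point for each
    observation.  d2, d3 and d5 are weakly identified for this material and
    are bounded to [0, 0.1]; d1 and d4 are free.  At least two distinct
    rates above the reference rate are required to identify d4.

    When d3 is small the data only constrain the combination
    (d1 + d2)(1 + d5), a flat ridge in parameter space.  A light ridge
    penalty (weight ``ridge``) shrinks the nuisance constants d2, d3, d5
    toward zero so the identified magnitude is attributed to d1, the
    dominant constant; set ``ridge=0`` for the raw least-squares problem.
    """
    y = np.asarray(eps_f_obs, dtype=float)
    t = np.asarray(triaxiality, dtype=float)
    r = np.asarray(eps_dot, dtype=float) / card.eps_dot_ref
    if not (y.shape == t.shape == r.shape):
        raise ValueError("observations and design must have equal length")
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    L = np.log(np.maximum(r, 1.0))
    if np.unique(np.round(L, 12)).size < 2:
        raise UnidentifiableError(
            "need >=2 distinct rates above the reference rate to identify d4")

    pen = np.sqrt(ridge)

    def resid(theta):
        d1, d2, d3, d4, d5 = theta
        model = (d1 + d2 * np.exp(-d3 * t)) * (1.0 + d4 * L) * (1.0 + d5)
        return np.concatenate([model - y, pen * np.array([theta[1], theta[2],
                                                          theta[4]])])

    x0 = [float(np.median(y[L == L.min()])), 0.0, 0.0, 0.0, 0.0]
    res = least_squares(
        resid, x0=x0,
        bounds=([1e-9, 0.0, 0.0, -1.0, 0.0], [10.0, 0.1, 0.1, 1.0, 0.1]),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )
    # d2/d3/d5 span a near-flat ridge; the optimizer may stop on its
    # evaluation budget with the gradient already negligible, which is a
    # converged answer in every practical sense.
    stalled_but_flat = res.status == 0 and res.optimality < 1e-8
    if not (res.success or stalled_but_flat):
        raise RuntimeError(f"damage fit did not converge: {res.message}; "
                           f"residual norm {np.sqrt(2 * res.cost):.3g}")
    names = [f"d{i}" for i in range(1, 6)]
    return FitResult(params=dict(zip(names, res.x)),
                     stderr=_stderr_from_jacobian(res, names),
                     residual_norm=float(np.sqrt(2.0 * res.cost)))
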