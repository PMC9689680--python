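"""Engineering/true stress-strain mechanics for the ring tensile test.

Converts texture-analyzer force-displacement records into stress-strain
curves, extracts the Young modulus from the linear region, decomposes the
strain into elastic and plastic parts, and segments the curve into its
elastic / strain-hardening / failure stages.

Conventions: forces in N, lengths in mm, stresses in MPa.  Engineering
stress is load over the undeformed wall cross-section w*H; engineering
strain is elongation over the initial ring length L0, which defaults to
the ring's mean circumference pi*(OD+ID)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RingGeometry",
    "ForceDisplacementCurve",
    "StressStrainCurve",
    "StageSegmentation",
    "eng_stress",
    "eng_strain",
    "to_true",
    "from_true",
    "decompose_strain",
    "fit_young_modulus",
    "segment_stages",
    "curve_from_force",
    "FitRegionError",
]

#: Coefficient-of-determination threshold that defines the linear region.
LINEAR_R2_THRESHOLD = 0.995
#: Minimum number of samples in a linear-region fit window.
LINEAR_MIN_POINTS = 5
#: Relative stress drop after the peak that marks specimen failure.
FAILURE_DROP_FRACTION = 0.5
#: Samples within this relative band of the peak stress count as the peak;
#: the failure index is the last of them (the edge of the post-peak cliff).
PEAK_TOLERANCE = 0.02


class FitRegionError(RuntimeError):
    """No acceptable linear window found; supply manual bounds."""


@dataclass(frozen=True)
class RingGeometry:
    """Ring specimen and pin geometry (mm)."""

    outer_diameter: float = 40.0
    inner_diameter: float = 35.0
    height_H: float = 20.0
    pin_diameter: float = 10.0
    initial_length_L0: float | None = None

    def __post_init__(self) -> None:
        if self.outer_diameter <= self.inner_diameter:
            raise ValueError("outer diameter must exceed inner diameter")
        if self.height_H <= 0:
            raise ValueError("height must be positive")
        if self.initial_length_L0 is not None and self.initial_length_L0 <= 0:
            raise ValueError("L0 must be positive")

    @property
    def width_w(self) -> float:
        """Ring wall width (OD - ID) / 2."""
        return (self.outer_diameter - self.inner_diameter) / 2.0

    @property
    def L0(self) -> float:
        """Initial ring length; defaults to the mean circumference."""
        if self.initial_length_L0 is not None:
            return self.initial_length_L0
        return math.pi * (self.outer_diameter + self.inner_diameter) / 2.0


@dataclass
class ForceDisplacementCurve:
    """Raw mechanical test record: displacement (mm), force (N)."""

    displacement: np.ndarray
    force: np.ndarray
    time: np.ndarray | None = None
    speed: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != self.displacement.shape:
                raise ValueError("time and displacement must have equal length")
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force contains non-finite values")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing")

    def __len__(self) -> int:
        return self.displacement.size


@dataclass
class StressStrainCurve:
    """Paired engineering and true stress/strain with an elastic/plastic split.

    The elastic and plastic components are filled once the modulus is
    known (``decompose_strain``); until then they are None.
    """

    eps_eng: np.ndarray
    sigma_eng: np.ndarray
    eps_true: np.ndarray
    sigma_true: np.ndarray
    eps_elastic: np.ndarray | None = None
    eps_plastic: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("eps_eng", "sigma_eng", "eps_true", "sigma_true"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


def eng_stress(F, geometry: RingGeometry):
    """Engineering stress F / (w * H) in MPa, one ring wall carrying the load."""
    w, H = geometry.width_w, geometry.height_H
    if w <= 0 or H <= 0:
        raise ZeroDivisionError("ring wall width and height must be positive")
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    out = F / (w * H)
    return float(out) if out.ndim == 0 else out

def eng_strain(delta_L, L0: float):
    """Engineering strain: elongation over the initial ring length."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    dL = np.asarray(delta_L, dtype=float)
    if np.any(dL < 0):
        raise ValueError("elongation must be non-negative")
    out = dL / L0
    return float(out) if out.ndim == 0 else out

def to_true(sigma_eng, eps_eng):
    """True stress sigma_eng*(1+eps_eng) and logarithmic strain ln(1+eps_eng)."""
    s = np.asarray(sigma_eng, dtype=float)
    e = np.asarray(eps_eng, dtype=float)
    if np.any(e <= -1):
        raise ValueError("engineering strain must exceed -1")
    st, et = s * (1.0 + e), np.log1p(e)
    if st.ndim == 0:
        return float(st), float(et)
    return st, et

def from_true(sigma_true, eps_true):
    """Inverse of :func:`to_true`."""
    st = np.asarray(sigma_true, dtype=float)
    et = np.asarray(eps_true, dtype=float)
    e = np.expm1(et)
    s = st / (1.0 + e)
    if s.ndim == 0:
        return float(s), float(e)
    return s, e

def decompose_strain(sigma_true, eps_total, E: float, *, clip_tol: float = 1e-9):
    """Split total strain into elastic (sigma/E) and plastic parts.

    The split conserves total strain exactly; tiny negative plastic values
    (within ``clip_tol``) are clipped to zero.
    """
    if E <= 0:
        raise ValueError("Young modulus must be positive")
    st = np.asarray(sigma_true, dtype=float)
    et = np.asarray(eps_total, dtype=float)
    eps_el = st / E
    eps_pl = et - eps_el
    eps_pl = np.where((eps_pl < 0) & (eps_pl > -clip_tol), 0.0, eps_pl)
    if eps_el.ndim == 0:
        return float(eps_el), float(eps_pl)
    return eps_el, eps_pl


def _window_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the least-squares line on (x, y)."""
    sy = y - y.mean()
    ss_tot = float(sy @ sy)
    if ss_tot == 0.0:
        return 1.0
    sx = x - x.mean()
    sxx = float(sx @ sx)
    if sxx == 0.0:
        return 0.0
    slope = float(sx @ sy) / sxx
    ss_res = ss_tot - slope * float(sx @ sy)
    return 1.0 - ss_res / ss_tot


def fit_young_modulus(curve: StressStrainCurve, *,
                      r2_threshold: float = LINEAR_R2_THRESHOLD,
                      min_points: int = LINEAR_MIN_POINTS):
    """Young modulus from the slope of the initial linear region.

    The linear region is the longest initial window of the true
    stress-strain curve whose least-squares line has R^2 at or above
    ``r2_threshold`` (at least ``min_points`` samples).  Returns
    ``(E, end_index)`` with ``end_index`` the exclusive end of the window.
    """
    x = np.asarray(curve.eps_true, dtype=float)
    y = np.asarray(curve.sigma_true, dtype=float)
    if x.size < 10 or np.any(np.diff(x) <= 0):
        raise ValueError("need >=10 samples with strictly increasing strain")
    end = 0
    for k in range(min_points, x.size + 1):
        if _window_r2(x[:k], y[:k]) >= r2_threshold:
            end = k
    if end == 0:
        raise FitRegionError(
            f"no initial window of >= {min_points} points reaches "
            f"R^2 >= {r2_threshold}; supply manual bounds")
    # The R^2 scan tolerates a short run of off-line points past the true
    # linear region; trim trailing points whose residual exceeds 3x the
    # scatter of the first half of the window.
    core = max(min_points, end // 2)
    slope, icept = np.polyfit(x[:core], y[:core], 1)
    resid_core = y[:core] - (slope * x[:core] + icept)
    tol = 3.0 * float(np.sqrt(np.mean(resid_core ** 2)))
    tol = max(tol, 1e-12 * max(np.abs(y[:end]).max(), 1e-300))
    while end > core and abs(y[end - 1] - (slope * x[end - 1] + icept)) > tol:
        end -= 1
    E = float(np.polyfit(x[:end], y[:end], 1)[0])
    return E, end


@dataclass
class StageSegmentation:
    """Elastic / hardening / failure stage boundaries of a test record."""

    elastic_end_index: int
    hardening_end_index: int | None
    failure_index: int | None
    failure_displacement: float | None
    failed: bool

    def __post_init__(self) -> None:
        if self.failure_index is not None:
            if not (self.elastic_end_index <= self.hardening_end_index
                    <= self.failure_index):
                raise ValueError("stage indices must be ordered")


def segment_stages(curve: StressStrainCurve, *, displacement=None,
                   drop_fraction: float = FAILURE_DROP_FRACTION,
                   r2_threshold: float = LINEAR_R2_THRESHOLD) -> StageSegmentation:
    """Identify the three stages of a ring tensile record.

    Stage 1 ends where the initial linear (elastic) window ends; the
    failure point is the global stress maximum, provided the stress
    subsequently drops by at least ``drop_fraction``; the hardening stage
    ends at the failure point.  With no qualifying drop the record is
    flagged as not failed and the failure fields stay unset.
    """
    sigma = np.asarray(curve.sigma_true, dtype=float)
    try:
        _, elastic_end = fit_young_modulus(curve, r2_threshold=r2_threshold)
    except FitRegionError:
        # e.g. a record that yields immediately: no resolvable elastic stage
        elastic_end = 0
    # The failure point is the edge of the post-peak cliff: the last sample
    # whose stress is within the peak tolerance of the global maximum.
    # Taking the last such sample (rather than the argmax itself) keeps the
    # detection from drifting early on noisy, slowly-hardening records.
    peak = float(sigma.max())
    i_max = int(np.flatnonzero(sigma >= (1.0 - PEAK_TOLERANCE) * peak)[-1])
    failed = bool(i_max < sigma.size - 1
                  and sigma[i_max:].min() <= (1.0 - drop_fraction) * sigma[i_max])
    if not failed:
        return StageSegmentation(elastic_end_index=elastic_end,
                                 hardening_end_index=None, failure_index=None,
                                 failure_displacement=None, failed=False)
    fail_disp = None
    if displacement is not None:
        fail_disp = float(np.asarray(displacement, dtype=float)[i_max])
    return StageSegmentation(elastic_end_index=min(elastic_end, i_max),
                             hardening_end_index=i_max, failure_index=i_max,
                             failure_displacement=fail_disp, failed=True)


def curve_from_force(curve: ForceDisplacementCurve,
                     geometry: RingGeometry) -> StressStrainCurve:
    """Build a stress-strain curve from a ring tensile force record.

    Pin displacement u stretches both ring arms: the elongation is 2u.
    """
    delta_L = 2.0 * curve.displacement
    s_eng = eng_stress(curve.force, geometry)
    e_eng = eng_strain(delta_L, geometry.L0)
    s_true, e_true = to_true(s_eng, e_eng)
    return StressStrainCurve(eps_eng=e_eng, sigma_eng=s_eng, eps_true=e_true,
                             sigma_true=s_true,
                             metadata=dict(curve.metadata))
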