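"""Synthetic data with known ground truth for every pipeline stage.

Generators for: Johnson-Cook-shaped stress-strain curves (with relative
load-cell-like noise), ring tensile force records with an embedded
failure point, speckle-pattern images (Gaussian blobs over a uniform
background with additive sensor noise), and image sequences warped by
analytic displacement fields (translation, uniform stretch, or a
ring-stretch field whose strain concentrates near the lower pin-contact
region, as a stretched gel ring does).

All generators are pure functions of their parameters and seed, and every
dataset carries its generating truth in metadata so recovery tests need
no re-derivation.  Warped frames are resampled bilinearly; the analytic
displacement field is exact, so DIC accuracy checks are honest about
interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .material import MaterialCard, jc_flow_stress
from .mechanics import ForceDisplacementCurve, StressStrainCurve, from_true
from .ring import RingTensileSetup, simulate_ring_tensile

__all__ = ["SpeckleSpec", "WarpSchedule", "WarpTruth",
           "gen_jc_curve", "gen_elastic_curve", "gen_ring_force_curve",
           "gen_speckle_image", "warp_sequence",
           "translation_schedule", "stretch_schedule", "ring_stretch_schedule"]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Stress-strain and force curves

def gen_jc_curve(card: MaterialCard, eps_dot: float = 1.0, eps_max: float = 1.0,
                 n_points: int = 300, noise_rel: float = 0.0,
                 seed: int = 0) -> StressStrainCurve:
    """Noisy Johnson-Cook flow curve: true stress vs plastic strain.

    Stress gets multiplicative Gaussian noise of relative size
    ``noise_rel`` (load-cell error scales with signal).  The elastic
    strain, total true strain and engineering pairs are filled in
    consistently with the card's modulus.
    """
    if noise_rel < 0:
        raise ValueError("noise_rel must be non-negative")
    eps_p = np.linspace(0.0, eps_max, n_points)
    sigma = jc_flow_stress(eps_p, eps_dot, card)
    if noise_rel > 0:
        sigma = sigma * (1.0 + noise_rel * _rng(seed).standard_normal(n_points))
    eps_el = sigma / card.E
    eps_true = eps_p + eps_el
    sigma_eng, eps_eng = from_true(sigma, eps_true)
    return StressStrainCurve(
        eps_eng=eps_eng, sigma_eng=sigma_eng, eps_true=eps_true,
        sigma_true=sigma, eps_elastic=eps_el, eps_plastic=eps_p,
        metadata={"generator": "gen_jc_curve", "card": card.name,
                  "A": card.A, "B": card.B, "n": card.n, "C": card.C,
                  "eps_dot": eps_dot, "noise_rel": noise_rel, "seed": seed},
    )


def gen_elastic_curve(card: MaterialCard, n_points: int = 200,
                      noise_rel: float = 0.005, seed: int = 1,
                      eps_max: float | None = None) -> StressStrainCurve:
    """Linear-elastic stress-strain curve up to the yield strain.

    True stress is E times true strain with multiplicative Gaussian
    noise; used to exercise the linear-region modulus fit.
    """
    if eps_max is None:
        eps_max = card.yield_strain
    eps_true = np.linspace(0.0, eps_max, n_points)
    sigma = card.E * eps_true
    if noise_rel > 0:
        sigma = sigma * (1.0 + noise_rel * _rng(seed).standard_normal(n_points))
    sigma_eng, eps_eng = from_true(sigma, eps_true)
    return StressStrainCurve(
        eps_eng=eps_eng, sigma_eng=sigma_eng, eps_true=eps_true,
        sigma_true=sigma,
        metadata={"generator": "gen_elastic_curve", "E": card.E,
                  "noise_rel": noise_rel, "seed": seed},
    )


def gen_ring_force_curve(setup: RingTensileSetup, noise_rel: float = 0.0,
                         seed: int = 0,
                         target_failure_displacement: float | None = None,
                         tail_mm: float = 2.0) -> ForceDisplacementCurve:
    """Ring tensile force-displacement record with an embedded failure.

    Runs the quasi-static ring simulation, converts stress to force, adds
    multiplicative lognormal noise, and appends a sharp post-failure force
    drop.  ``target_failure_displacement`` rescales d1 so the embedded
    failure lands at a chosen pin displacement (closed form under the
    clamped rate bracket); the true failure displacement is recorded in
    the metadata.
    """
    if target_failure_displacement is not None:
        d = setup.card.damage
        eps_f_needed = 2.0 * target_failure_displacement / setup.geometry.L0
        if setup.strain_measure == "true":
            eps_f_needed = np.log1p(eps_f_needed)
        rate = 2.0 * setup.pin_speed / setup.geometry.L0
        ratio = rate / setup.card.eps_dot_ref
        if setup.clamp_rate:
            ratio = max(ratio, 1.0)
        bracket = 1.0 + d.d4 * np.log(ratio)
        d1 = (eps_f_needed / ((1.0 + d.d5) * bracket)
              - d.d2 * np.exp(-d.d3 * setup.triaxiality))
        setup = replace(setup, card=setup.card.with_damage(d1=float(d1)))
    res = simulate_ring_tensile(setup)
    disp, force = res.displacement, res.force
    time = res.time
    if res.failed:
        du = setup.pin_speed * setup.dt
        n_tail = max(int(round(tail_mm / du)), 2)
        tail_d = disp[-1] + du * np.arange(1, n_tail + 1)
        tail_f = np.concatenate(([0.3 * force[-1]],
                                 np.full(n_tail - 1, 0.05 * force[-1])))
        disp = np.concatenate([disp, tail_d])
        force = np.concatenate([force, tail_f])
        time = np.concatenate([time, time[-1] + setup.dt * np.arange(1, n_tail + 1)])
    if noise_rel > 0:
        force = force * np.exp(noise_rel * _rng(seed).standard_normal(force.size))
    return ForceDisplacementCurve(
        displacement=disp, force=force, time=time, speed=setup.pin_speed,
        metadata={"generator": "gen_ring_force_curve",
                  "true_failure_displacement": res.failure_displacement,
                  "true_failure_time": res.failure_time,
                  "noise_rel": noise_rel, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Speckle images and warped sequences

@dataclass(frozen=True)
class SpeckleSpec:
    """Parameters of a synthetic sprayed-ink speckle pattern.

    Dark Gaussian blobs (ink dots) on a light background, with additive
    Gaussian sensor noise, on an 8-bit intensity scale by default.
    """

    image_size: tuple = (256, 256)      # (height, width) px
    speckle_density: float = 0.02       # blobs per px^2
    blob_radius_range: tuple = (1.5, 3.0)  # Gaussian sigma range, px
    background_level: float = 200.0
    speckle_level: float = 30.0
    noise_sd: float = 2.0
    seed: int = 0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        top = 2 ** self.bit_depth - 1
        if not (0 <= self.speckle_level <= top and 0 <= self.background_level <= top):
            raise ValueError("intensity levels must fit the bit depth")
        if self.speckle_density < 0 or self.noise_sd < 0:
            raise ValueError("density and noise must be non-negative")


def gen_speckle_image(spec: SpeckleSpec) -> np.ndarray:
    """Render a speckle image as a float array clipped to the bit depth."""
    h, w = spec.image_size
    rng = _rng(spec.seed)
    img = np.full((h, w), spec.background_level, dtype=float)
    n_blobs = rng.poisson(spec.speckle_density * h * w)
    amp = spec.speckle_level - spec.background_level
    xs = rng.uniform(0, w, n_blobs)
    ys = rng.uniform(0, h, n_blobs)
    sig = rng.uniform(*spec.blob_radius_range, n_blobs)
    for x0, y0, s in zip(xs, ys, sig):
        r = int(np.ceil(3 * s))
        cx, cy = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(cx - r, 0), min(cx + r + 1, w)
        y_lo, y_hi = max(cy - r, 0), min(cy + r + 1, h)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        img[y_lo:y_hi, x_lo:x_hi] += amp * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * s * s))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 2 ** spec.bit_depth - 1)


@dataclass(frozen=True)
class WarpSchedule:
    """Per-frame analytic warp parameters; frame 0 must be the identity.

    kind 'translation': params are (dx, dy) pixel shifts per frame.
    kind 'uniform_stretch': params are isotropic stretch factors about the
    image center per frame.
    kind 'ring_stretch': params are peak x-stretch amounts s per frame;
    the stretch amplitude varies with y as a Gaussian bump centered at
    ``y_peak_frac`` of the image height (the lower contact region), so
    strain concentrates there as in a stretched gel ring.
    """

    kind: str
    params: tuple
    y_peak_frac: float = 0.75
    width_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("translation", "uniform_stretch", "ring_stretch"):
            raise ValueError("unknown warp kind")
        p0 = self.params[0]
        identity = {"translation": (0.0, 0.0), "uniform_stretch": 1.0,
                    "ring_stretch": 0.0}[self.kind]
        if not np.allclose(np.asarray(p0, dtype=float), identity):
            raise ValueError("frame 0 of a warp schedule must be the identity")

    @property
    def frame_count(self) -> int:
        return len(self.params)


def translation_schedule(shifts) -> WarpSchedule:
    return WarpSchedule("translation", tuple((float(a), float(b)) for a, b in shifts))


def stretch_schedule(factors) -> WarpSchedule:
    return WarpSchedule("uniform_stretch", tuple(float(f) for f in factors))


def ring_stretch_schedule(n_frames: int, peak_gl_strain: float = 0.5,
                          y_peak_frac: float = 0.75,
                          width_frac: float = 0.25) -> WarpSchedule:
    """Ramped ring-stretch schedule reaching a target Green-Lagrange Exx.

    The final peak stretch amount s solves Exx = s + s^2/2, i.e.
    s = sqrt(1 + 2 Exx) - 1.
    """
    s_final = float(np.sqrt(1.0 + 2.0 * peak_gl_strain) - 1.0)
    s = np.linspace(0.0, s_final, n_frames)
    return WarpSchedule("ring_stretch", tuple(float(v) for v in s),
                        y_peak_frac=y_peak_frac, width_frac=width_frac)


class WarpTruth:
    """Exact analytic displacement of a warp schedule over a reference image."""

    def __init__(self, schedule: WarpSchedule, shape: tuple):
        self.schedule = schedule
        self.shape = shape

    def _center(self):
        h, w = self.shape
        return (w - 1) / 2.0, (h - 1) / 2.0

    def _bump(self, y):
        h = self.shape[0]
        y0 = self.schedule.y_peak_frac * (h - 1)
        width = self.schedule.width_frac * h
        return np.exp(-(((np.asarray(y, dtype=float) - y0) / width) ** 2))

    def forward(self, frame: int, x, y):
        """Mapped position of reference point (x, y) in the given frame."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p = self.schedule.params[frame]
        if self.schedule.kind == "translation":
            return x + p[0], y + p[1]
        cx, cy = self._center()
        if self.schedule.kind == "uniform_stretch":
            return cx + p * (x - cx), cy + p * (y - cy)
        return cx + (x - cx) * (1.0 + p * self._bump(y)), y

    def inverse(self, frame: int, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p = self.schedule.params[frame]
        if self.schedule.kind == "translation":
            return x - p[0], y - p[1]
        cx, cy = self._center()
        if self.schedule.kind == "uniform_stretch":
            return cx + (x - cx) / p, cy + (y - cy) / p
        return cx + (x - cx) / (1.0 + p * self._bump(y)), y

    def displacement(self, frame: int, x, y):
        """(u, v, in_frame) at reference points; out-of-frame is flagged."""
        fx, fy = self.forward(frame, x, y)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h, w = self.shape
        in_frame = (fx >= 0) & (fx <= w - 1) & (fy >= 0) & (fy <= h - 1)
        return fx - x, fy - y, in_frame

    def gl_strain_exact(self, frame: int, x, y):
        """Closed-form Green-Lagrange (Exx, Eyy, Exy) of the analytic warp."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        p = self.schedule.params[frame]
        zeros = np.zeros(np.broadcast(x, y).shape)
        if self.schedule.kind == "translation":
            return zeros, zeros.copy(), zeros.copy()
        if self.schedule.kind == "uniform_stretch":
            e = (p * p - 1.0) / 2.0
            return zeros + e, zeros + e, zeros.copy()
        cx, _ = self._center()
        h = self.shape[0]
        y0 = self.schedule.y_peak_frac * (h - 1)
        width = self.schedule.width_frac * h
        bump = self._bump(y)
        s = p * bump
        ds_dy = p * bump * (-2.0 * (y - y0) / width ** 2)
        ux = s
        uy = (x - cx) * ds_dy
        Exx = ux + 0.5 * ux * ux
        Eyy = 0.5 * uy * uy
        Exy = 0.5 * (uy + ux * uy)
        return Exx, Eyy, Exy


def warp_sequence(ref: np.ndarray, schedule: WarpSchedule):
    """Resample a reference image through a warp schedule.

    Returns ``(stack, truth)``: the list of bilinearly warped frames
    (frame 0 is the reference itself) and a :class:`WarpTruth` giving the
    exact analytic displacement field of every frame.
    """
    ref = np.asarray(ref, dtype=float)
    truth = WarpTruth(schedule, ref.shape)
    h, w = ref.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    stack = [ref.copy()]
    fill = float(np.median(ref))
    for i in range(1, schedule.frame_count):
        sx, sy = truth.inverse(i, xx, yy)
        frame = map_coordinates(ref, [sy, sx], order=1, mode="constant",
                                cval=fill)
        stack.append(frame)
    return stack, truth
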