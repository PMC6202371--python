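"""Coupling-prior observer model for visuo-proprioceptive localization.

The observer sees a visual target at ``m_v`` and feels a proprioceptive target
at ``m_p`` (1-D azimuth, mm, positive rightward).  The likelihood over joint
locations (v, p) is a separable bivariate Gaussian centred on the targets with
dispersions fixed by unisensory reach variability.  The prior mixes a Gaussian
ridge along the identity line v = p (integration; dispersion ``sigma_c``) with
a uniform component over a bounded workspace of area ``A`` (segregation), with
mixing weight ``lam``.  Percepts are decoded by taking the maximum of the
posterior (MAP).  The forced-fusion special case (``lam`` = 1, ``sigma_c`` ->
0) collapses to the classic reliability-weighted average of the two cues.

All densities are evaluated in log space.  The prior is treated as an
unnormalized score over the bounded workspace: the ridge is normalized only
across the identity line, and the uniform component needs the bounded support
of area ``A``.  The MAP location depends on ``lam`` and ``A`` only through the
ratio of component heights, so ``A`` is fixed (default (600 mm)^2) and
reported rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite, log, pi

import numba
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_AREA_MM2",
    "MLE_SIGMA_C_MM",
    "ParameterError",
    "GridBoundaryError",
    "StimulusPair",
    "SensoryNoise",
    "CouplingPriorParams",
    "EvalGrid",
    "LocationEstimate",
    "likelihood_logpdf",
    "coupling_prior_logpdf",
    "posterior_log",
    "component_modes",
    "map_estimate",
    "map_estimates",
    "mle_estimate",
    "predict_mean_estimates",
]

#: Default area of the uniform prior component: a 600 mm x 600 mm workspace.
DEFAULT_AREA_MM2 = 600.0 ** 2

#: Forced-fusion coupling dispersion: sigma_c^2 = 1e-4 mm^2.
MLE_SIGMA_C_MM = 1e-2

#: Two log-posterior peaks closer than this are considered tied; the tie is
#: broken toward the identity line.
_TIE_TOL = 1e-12


class ParameterError(ValueError):
    """A model parameter violates its domain (e.g. non-positive sigma)."""


class GridBoundaryError(RuntimeError):
    """The posterior maximum fell on or outside the evaluation grid."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class StimulusPair:
    """Visual/proprioceptive target placement for one bimodal presentation.

    The signed disparity is ``m_p - m_v``: negative means the proprioceptive
    target sits to the left of the visual one.
    """

    m_v: float
    m_p: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "m_v", _require_finite("m_v", self.m_v))
        object.__setattr__(self, "m_p", _require_finite("m_p", self.m_p))

    @property
    def disparity(self) -> float:
        return self.m_p - self.m_v


@dataclass(frozen=True)
class SensoryNoise:
    """Unisensory localization dispersions fixing the likelihood (mm)."""

    sigma_v: float
    sigma_p: float

    def __post_init__(self) -> None:
        for name in ("sigma_v", "sigma_p"):
            value = _require_finite(name, getattr(self, name))
            if value <= 0:
                raise ParameterError(f"{name} must be > 0, got {value}")
            object.__setattr__(self, name, value)


@dataclass(frozen=True)
class CouplingPriorParams:
    """Coupling-prior parameters: mixing weight, ridge dispersion, area."""

    lam: float
    sigma_c: float
    area_A: float = DEFAULT_AREA_MM2

    def __post_init__(self) -> None:
        lam = _require_finite("lam", self.lam)
        if not 0.0 <= lam <= 1.0:
            raise ParameterError(f"lam must be in [0, 1], got {lam}")
        sigma_c = _require_finite("sigma_c", self.sigma_c)
        if sigma_c <= 0:
            raise ParameterError(f"sigma_c must be > 0, got {sigma_c}")
        area = _require_finite("area_A", self.area_A)
        if area <= 0:
            raise ParameterError(f"area_A must be > 0, got {area}")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "sigma_c", sigma_c)
        object.__setattr__(self, "area_A", area)


@dataclass(frozen=True)
class EvalGrid:
    """Bounds and spacing of the (v, p) evaluation window (mm)."""

    lo: float = -300.0
    hi: float = 300.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ParameterError(f"grid needs lo < hi, got [{self.lo}, {self.hi}]")
        if self.step <= 0:
            raise ParameterError(f"grid step must be > 0, got {self.step}")

    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        return self.lo + self.step * np.arange(n)

    def covers(self, x: float, margin: float = 0.0) -> bool:
        return (self.lo + margin) <= x <= (self.hi - margin)


@dataclass(frozen=True)
class LocationEstimate:
    """MAP-decoded visual and proprioceptive coordinates (mm)."""

    v_hat: float
    p_hat: float


# ---------------------------------------------------------------------------
# log-densities


def likelihood_logpdf(v, p, center: StimulusPair, noise: SensoryNoise):
    """Log of the separable bivariate Gaussian likelihood l(v, p).

    Uses the proper bivariate normalization 1 / (2 pi sigma_v sigma_p); the
    MAP location is invariant to any positive rescaling.
    """
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    const = -log(2.0 * pi * noise.sigma_v * noise.sigma_p)
    out = (
        const
        - (v - center.m_v) ** 2 / (2.0 * noise.sigma_v ** 2)
        - (p - center.m_p) ** 2 / (2.0 * noise.sigma_p ** 2)
    )
    return out if out.shape else float(out)


def _log_weights(params: CouplingPriorParams) -> tuple[float, float]:
    """Log heights of the two prior components (ridge at v=p, uniform)."""
    with np.errstate(divide="ignore"):
        log_wc = float(np.log(params.lam)) - 0.5 * log(2.0 * pi * params.sigma_c ** 2)
        log_wu = float(np.log1p(-params.lam)) - log(params.area_A)
    return log_wc, log_wu


def coupling_prior_logpdf(v, p, params: CouplingPriorParams):
    """Log of the mixture prior P(v, p) = lam * delta(v, p) + (1 - lam) / A.

    Depends on (v, p) only through v - p; maximal on the identity line;
    tends to log((1 - lam) / A) as |v - p| grows.
    """
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    log_wc, log_wu = _log_weights(params)
    ridge = log_wc - (v - p) ** 2 / (2.0 * params.sigma_c ** 2)
    out = np.logaddexp(ridge, log_wu)
    return out if out.shape else float(out)


def posterior_log(v, p, center: StimulusPair, noise: SensoryNoise,
                  params: CouplingPriorParams):
    """Log posterior score log r(v, p) = log P(v, p) + log l(v, p)."""
    return coupling_prior_logpdf(v, p, params) + likelihood_logpdf(v, p, center, noise)


# ---------------------------------------------------------------------------
# component modes and MAP search


def _ridge_mode(m_v, m_p, sv2: float, sp2: float, sc2: float):
    """Stationary point of the (ridge x likelihood) component.

    Solves the 2x2 linear system for the quadratic
    -(v - m_v)^2 / 2 sv2 - (p - m_p)^2 / 2 sp2 - (v - p)^2 / 2 sc2.
    """
    a11 = 1.0 / sv2 + 1.0 / sc2
    a22 = 1.0 / sp2 + 1.0 / sc2
    a12 = -1.0 / sc2
    det = a11 * a22 - a12 * a12  # = 1/(sv2 sp2) + 1/(sv2 sc2) + 1/(sp2 sc2) > 0
    b1 = np.asarray(m_v, dtype=float) / sv2
    b2 = np.asarray(m_p, dtype=float) / sp2
    v = (a22 * b1 - a12 * b2) / det
    p = (a11 * b2 - a12 * b1) / det
    return v, p


def component_modes(center: StimulusPair, noise: SensoryNoise,
                    params: CouplingPriorParams) -> tuple[LocationEstimate, LocationEstimate]:
    """Closed-form stationary points of the two posterior components.

    Returns ``(uniform_mode, ridge_mode)``: the uniform x likelihood component
    peaks at the targets themselves, the ridge x likelihood component at the
    coupling-shrunk point that tends to the reliability-weighted average as
    ``sigma_c -> 0``.
    """
    sv2 = noise.sigma_v ** 2
    sp2 = noise.sigma_p ** 2
    sc2 = params.sigma_c ** 2
    v, p = _ridge_mode(center.m_v, center.m_p, sv2, sp2, sc2)
    return (
        LocationEstimate(center.m_v, center.m_p),
        LocationEstimate(float(v), float(p)),
    )


@numba.njit(cache=True, fastmath=False)
def _f_g_scalar(v, p, m_v, m_p, sv2, sp2, sc2, log_wc, log_wu):
    """Scalar log posterior (up to the likelihood constant), its gradient and
    the ridge-responsibility curvature term used by the Newton ascent."""
    dv = v - m_v
    dp = p - m_p
    u = v - p
    ridge = log_wc - u * u / (2.0 * sc2)
    # logaddexp(ridge, log_wu)
    if ridge >= log_wu:
        mix = ridge + np.log1p(np.exp(log_wu - ridge)) if log_wu - ridge > -745.0 else ridge
        r = 1.0 / (1.0 + np.exp(log_wu - ridge)) if log_wu - ridge > -745.0 else 1.0
    else:
        mix = log_wu + np.log1p(np.exp(ridge - log_wu)) if ridge - log_wu > -745.0 else log_wu
        r = 0.0 if ridge - log_wu <= -745.0 else 1.0 - 1.0 / (1.0 + np.exp(ridge - log_wu))
    f = mix - dv * dv / (2.0 * sv2) - dp * dp / (2.0 * sp2)
    g_v = -dv / sv2 - r * u / sc2
    g_p = -dp / sp2 + r * u / sc2
    fp = r / sc2 - r * (1.0 - r) * u * u / (sc2 * sc2)  # d/du [r(u) u / sc2]
    return f, g_v, g_p, fp


@numba.njit(cache=True, fastmath=False)
def _newton_ascent(v0, p0, m_v, m_p, sv2, sp2, sc2, log_wc, log_wu,
                   max_iter=80, gtol=1e-10):
    """Damped-Newton ascent on the log posterior, one point per entry.

    Falls back to scaled gradient ascent where the Hessian is not negative
    definite, with Armijo backtracking.  Returns converged (v, p) and the
    log-posterior score there.
    """
    n = v0.shape[0]
    out_v = np.empty(n)
    out_p = np.empty(n)
    out_f = np.empty(n)
    grad_scale = 1.0 / (1.0 / min(sv2, sp2) + 1.0 / sc2)
    for k in range(n):
        v = v0[k]
        p = p0[k]
        mv = m_v[k]
        mp_ = m_p[k]
        f, g_v, g_p, fp = _f_g_scalar(v, p, mv, mp_, sv2, sp2, sc2, log_wc, log_wu)
        for _ in range(max_iter):
            if max(abs(g_v), abs(g_p)) <= gtol:
                break
            h_vv = -1.0 / sv2 - fp
            h_pp = -1.0 / sp2 - fp
            h_vp = fp
            det = h_vv * h_pp - h_vp * h_vp
            if det > 0.0 and h_vv < 0.0:  # negative definite -> Newton step
                d_v = -(h_pp * g_v - h_vp * g_p) / det
                d_p = -(h_vv * g_p - h_vp * g_v) / det
            else:
                d_v = grad_scale * g_v
                d_p = grad_scale * g_p
            slope = g_v * d_v + g_p * d_p
            t = 1.0
            accepted = False
            for _bt in range(40):
                f_try, gv_t, gp_t, fp_t = _f_g_scalar(
                    v + t * d_v, p + t * d_p, mv, mp_, sv2, sp2, sc2,
                    log_wc, log_wu)
                if f_try >= f + 1e-4 * t * slope:
                    v += t * d_v
                    p += t * d_p
                    f, g_v, g_p, fp = f_try, gv_t, gp_t, fp_t
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                break  # stalled at machine precision: treat as converged
        out_v[k] = v
        out_p[k] = p
        out_f[k] = f
    return out_v, out_p, out_f


def map_estimates(centers: np.ndarray, noise: SensoryNoise,
                  params: CouplingPriorParams) -> np.ndarray:
    """Batched MAP decoding for an (n, 2) array of (m_v, m_p) centers.

    Runs the damped-Newton ascent from the closed-form modes of the two
    posterior components and from their midpoint, then keeps the best peak per
    center (ties within 1e-12 in log score go to the point nearer the identity
    line).  Returns an (n, 2) array of (v_hat, p_hat).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = centers.shape[0]
    sv2 = noise.sigma_v ** 2
    sp2 = noise.sigma_p ** 2
    sc2 = params.sigma_c ** 2
    log_wc, log_wu = _log_weights(params)
    m_v = centers[:, 0]
    m_p = centers[:, 1]
    rv, rp = _ridge_mode(m_v, m_p, sv2, sp2, sc2)
    starts_v = np.concatenate([m_v, rv, 0.5 * (m_v + rv)])
    starts_p = np.concatenate([m_p, rp, 0.5 * (m_p + rp)])
    mv3 = np.tile(m_v, 3)
    mp3 = np.tile(m_p, 3)
    v, p, f = _newton_ascent(starts_v, starts_p, mv3, mp3, sv2, sp2, sc2,
                             log_wc, log_wu)
    v = v.reshape(3, n)
    p = p.reshape(3, n)
    f = f.reshape(3, n)
    best = np.nanmax(f, axis=0)
    if not np.all(np.isfinite(best)):
        raise FloatingPointError("non-finite posterior score in MAP search")
    tied = f >= best[None, :] - _TIE_TOL
    off_identity = np.where(tied, np.abs(v - p), np.inf)
    pick = np.argmin(off_identity, axis=0)
    idx = np.arange(n)
    return np.column_stack([v[pick, idx], p[pick, idx]])


def map_estimate(center: StimulusPair, noise: SensoryNoise,
                 params: CouplingPriorParams,
                 grid: EvalGrid | None = None,
                 coarse_scan: bool = False) -> LocationEstimate:
    """MAP decode a single bimodal presentation.

    The default path refines the closed-form component modes by Newton ascent;
    with ``coarse_scan=True`` the grid is additionally swept at its native
    step and the best node is polished too (robust, slow).  The returned point
    must lie strictly inside ``grid`` (default +/-300 mm, 0.5 mm step) or a
    :class:`GridBoundaryError` is raised.
    """
    grid = grid or EvalGrid()
    est = map_estimates(np.array([[center.m_v, center.m_p]]), noise, params)[0]
    if coarse_scan:
        axis = grid.values()
        vv, pp = np.meshgrid(axis, axis, indexing="ij")
        scores = posterior_log(vv, pp, center, noise, params)
        if np.any(np.isnan(scores)):
            raise FloatingPointError("NaN in posterior scores on grid")
        i, j = np.unravel_index(np.argmax(scores), scores.shape)
        if i in (0, len(axis) - 1) or j in (0, len(axis) - 1):
            raise GridBoundaryError(
                "posterior argmax on grid boundary; enlarge the grid")
        node = np.array([[axis[i], axis[j]]])
        sv2, sp2, sc2 = noise.sigma_v ** 2, noise.sigma_p ** 2, params.sigma_c ** 2
        log_wc, log_wu = _log_weights(params)
        v, p, _ = _newton_ascent(node[:, 0].copy(), node[:, 1].copy(),
                                 np.array([center.m_v]), np.array([center.m_p]),
                                 sv2, sp2, sc2, log_wc, log_wu)
        cand = np.array([est, [v[0], p[0]]])
        scores = posterior_log(cand[:, 0], cand[:, 1], center, noise, params)
        best = scores.max()
        tied = scores >= best - _TIE_TOL
        off = np.where(tied, np.abs(cand[:, 0] - cand[:, 1]), np.inf)
        est = cand[int(np.argmin(off))]
    for x in est:
        if not grid.covers(float(x), margin=grid.step):
            raise GridBoundaryError(
                f"MAP estimate {est} not strictly inside grid "
                f"[{grid.lo}, {grid.hi}]")
    return LocationEstimate(float(est[0]), float(est[1]))


def mle_estimate(center: StimulusPair, noise: SensoryNoise,
                 grid: EvalGrid | None = None) -> LocationEstimate:
    """Forced-fusion (MLE) estimate: lam = 1, sigma_c^2 = 1e-4 mm^2.

    Both coordinates collapse onto the reliability-weighted average of the two
    cues, (m_v / sigma_v^2 + m_p / sigma_p^2) / (1 / sigma_v^2 + 1 / sigma_p^2).
    """
    params = CouplingPriorParams(lam=1.0, sigma_c=MLE_SIGMA_C_MM)
    return map_estimate(center, noise, params, grid=grid)


def predict_mean_estimates(disparities, noise: SensoryNoise,
                           params: CouplingPriorParams,
                           grid: EvalGrid | None = None) -> pd.DataFrame:
    """Deterministic model predictions per signed disparity.

    Centers the visual target at 0 mm and the proprioceptive target at ``d``,
    MAP-decodes each placement and expresses the pulls as percentages of the
    disparity: visual bias% = 100 (v_hat - m_v) / d, proprioceptive bias% =
    100 (m_p - p_hat) / d.  Percentages are undefined at d = 0 and reported
    as missing there.
    """
    grid = grid or EvalGrid()
    d = np.asarray(list(disparities), dtype=float)
    if not np.all(np.isfinite(d)):
        raise ParameterError("disparities must be finite")
    centers = np.column_stack([np.zeros_like(d), d])
    est = map_estimates(centers, noise, params)
    for row in est:
        for x in row:
            if not grid.covers(float(x), margin=grid.step):
                raise GridBoundaryError("prediction outside evaluation grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        vis_pct = np.where(d != 0, 100.0 * est[:, 0] / d, np.nan)
        pro_pct = np.where(d != 0, 100.0 * (d - est[:, 1]) / d, np.nan)
    return pd.DataFrame({
        "disparity_mm": d,
        "v_hat_mm": est[:, 0],
        "p_hat_mm": est[:, 1],
        "visual_bias_pct": vis_pct,
        "proprio_bias_pct": pro_pct,
    })
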