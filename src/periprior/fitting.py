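"""Two-stage multi-start fitting of the coupling prior, plus the forced-fusion
maximum-likelihood-estimation (MLE) contrast.

One fit concerns one participant in one hand-visibility condition.  The free
parameters are the coupling strength ``lam`` and the coupling dispersion
``sigma_c``; the likelihood dispersions are fixed at the participant's
unisensory reach SDs for the same visibility condition.  The cost is the sum
of squared differences between the participant's mean reach endpoints (both
reach modalities, all nine signed disparities, target-relative coordinates)
and the MAP of the posterior.

The optimization runs in two stages of bounded local least-squares descent
(projected Levenberg-Marquardt with numerical Jacobians — the natural local
method for a sum-of-squares cost): stage 1 launches ``n_starts_stage1``
descents from uniform random points inside the bound box, each stopped once
the between-iteration decrease in the sum of squares falls below a lax
tolerance (100 mm^2); stage 2 restarts the ``n_carry_stage2`` best stage-1
endpoints with a stringent tolerance (1e-4 mm^2) and returns the overall
best.  Only the multi-start structure, the bounds and the stopping
tolerances are contractual; the local stepping scheme is an implementation
choice.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    MLE_SIGMA_C_MM,
    CouplingPriorParams,
    EvalGrid,
    ParameterError,
    SensoryNoise,
    map_estimates,
)

__all__ = [
    "DISPARITIES_MM",
    "DataError",
    "FitError",
    "ConditionData",
    "FitConfig",
    "FitResult",
    "sse_cost",
    "fit_condition",
    "fit_mle",
    "goodness_of_fit_r2",
    "residual_table",
]

#: Signed visuo-proprioceptive disparity levels of the design (mm).
DISPARITIES_MM = (-200.0, -100.0, -50.0, -25.0, 0.0, 25.0, 50.0, 100.0, 200.0)

VISIBILITIES = ("visible", "invisible")


class DataError(ValueError):
    """Input data violate the design (missing disparity level, bad counts)."""


class FitError(RuntimeError):
    """No optimization start produced a finite cost."""


@dataclass(frozen=True)
class ConditionData:
    """Mean reach endpoints for one participant x visibility condition.

    ``means`` is indexed by signed disparity (all nine levels) with columns
    ``mean_visual_mm`` / ``mean_proprio_mm`` (mean endpoint of visual- and
    proprioceptive-target reaches, target-relative: the visual target is at
    0 mm, the proprioceptive target at the disparity) and trial counts
    ``n_visual`` / ``n_proprio``.
    """

    participant: str
    visibility: str
    noise: SensoryNoise
    means: pd.DataFrame

    def __post_init__(self) -> None:
        if self.visibility not in VISIBILITIES:
            raise DataError(f"visibility must be one of {VISIBILITIES}")
        required = {"mean_visual_mm", "mean_proprio_mm", "n_visual", "n_proprio"}
        missing_cols = required - set(self.means.columns)
        if missing_cols:
            raise DataError(f"means table missing columns {sorted(missing_cols)}")
        have = set(np.asarray(self.means.index, dtype=float))
        missing = set(DISPARITIES_MM) - have
        if missing:
            raise DataError(f"missing disparity levels: {sorted(missing)}")
        sub = self.means.loc[list(DISPARITIES_MM)]
        if not np.all(np.isfinite(sub[["mean_visual_mm", "mean_proprio_mm"]])):
            raise DataError("non-finite mean response")
        if (sub[["n_visual", "n_proprio"]] < 1).any().any():
            raise DataError("every cell needs at least one trial")

    @property
    def disparities(self) -> np.ndarray:
        return np.asarray(DISPARITIES_MM)

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        sub = self.means.loc[list(DISPARITIES_MM)]
        return (sub["mean_visual_mm"].to_numpy(dtype=float),
                sub["mean_proprio_mm"].to_numpy(dtype=float))


@dataclass(frozen=True)
class FitConfig:
    """Settings of the two-stage multi-start fit."""

    n_starts_stage1: int = 500
    n_carry_stage2: int = 50
    tol_stage1: float = 100.0
    tol_stage2: float = 1e-4
    lam_bounds: tuple[float, float] = (0.01, 0.99)
    master_seed: int = 0
    include_zero_disparity: bool = True
    include_visual: bool = True
    area_A: float = CouplingPriorParams(0.5, 1.0).area_A
    grid: EvalGrid = field(default_factory=EvalGrid)
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.n_starts_stage1 < 1 or self.n_carry_stage2 < 1:
            raise ParameterError("start counts must be positive")
        if self.tol_stage1 <= 0 or self.tol_stage2 <= 0:
            raise ParameterError("tolerances must be positive")
        if not self.lam_bounds[0] < self.lam_bounds[1]:
            raise ParameterError("lam bounds must be ordered")

    def sigma_c_bounds(self, noise: SensoryNoise) -> tuple[float, float]:
        """Per-participant bounds: [min unisensory SD, 2 x max unisensory SD]."""
        return (min(noise.sigma_v, noise.sigma_p),
                2.0 * max(noise.sigma_v, noise.sigma_p))


@dataclass(frozen=True)
class FitResult:
    """Best fit for one participant x visibility condition."""

    participant: str
    visibility: str
    model: str  # "coupling_prior" | "forced_fusion"
    lam_hat: float
    sigma_c_hat: float
    sse: float
    r2_visual: float
    r2_proprio: float
    residuals: pd.DataFrame  # per (disparity, modality), mm and % of disparity
    n_stage1_converged: int
    best_start_index: int
    at_bounds: tuple[str, ...] = ()
    stage1_best_sse: float = float("nan")
    stage1_median_sse: float = float("nan")


def _predictions(lam: float, sigma_c: float, data: ConditionData,
                 area_A: float) -> np.ndarray:
    """Model (v_hat, p_hat) per signed disparity, target-relative, (9, 2)."""
    d = data.disparities
    centers = np.column_stack([np.zeros_like(d), d])
    params = CouplingPriorParams(lam=lam, sigma_c=sigma_c, area_A=area_A)
    return map_estimates(centers, data.noise, params)


def sse_cost(params: CouplingPriorParams, data: ConditionData,
             grid: EvalGrid | None = None,
             include_zero_disparity: bool = True,
             include_visual: bool = True) -> float:
    """Sum of squared residuals (mm^2) between mean endpoints and model MAP.

    By default both reach modalities at all nine signed disparities enter the
    cost; the two switches drop the zero-disparity cell or the visual-reach
    means for sensitivity analyses.
    """
    pred = _predictions(params.lam, params.sigma_c, data, params.area_A)
    obs_v, obs_p = data.observed()
    keep = np.ones(len(DISPARITIES_MM), dtype=bool)
    if not include_zero_disparity:
        keep &= data.disparities != 0
    res_p = obs_p[keep] - pred[keep, 1]
    total = float(np.sum(res_p ** 2))
    if include_visual:
        res_v = obs_v[keep] - pred[keep, 0]
        total += float(np.sum(res_v ** 2))
    return total


def _local_descent(residual_fn, x0, bounds, tol, max_iter):
    """Projected Levenberg-Marquardt descent on a residual vector.

    Accepted iterates always decrease the sum of squares; the descent stops
    once an accepted iteration lowers it by less than ``tol`` (the last,
    small improvement is kept).  Returns (x, sse).
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    r = residual_fn(x)
    sse = float(r @ r)
    if not np.isfinite(sse):
        return x, float("inf")
    mu = 1e-3
    h = 1e-6 * span  # forward-difference Jacobian steps, scaled per parameter
    for _ in range(max_iter):
        J = np.empty((r.size, x.size))
        for j in range(x.size):
            xj = x.copy()
            step = h[j] if xj[j] + h[j] <= hi[j] else -h[j]
            xj[j] += step
            J[:, j] = (residual_fn(xj) - r) / step
        g = J.T @ r
        A = J.T @ J
        accepted = False
        for _damp in range(60):
            M = A + mu * np.diag(np.maximum(np.diag(A), 1e-12))
            try:
                d = np.linalg.solve(M, -g)
            except np.linalg.LinAlgError:
                mu *= 4.0
                continue
            x_new = np.clip(x + d, lo, hi)
            r_new = residual_fn(x_new)
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                decrease = sse - sse_new
                x, r, sse = x_new, r_new, sse_new
                mu = max(mu / 3.0, 1e-12)
                accepted = True
                break
            mu *= 4.0
            if mu > 1e14:
                break
        if not accepted or decrease < tol:
            break
    return x, sse


def goodness_of_fit_r2(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Returns NaN when the observed values have zero variance.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size < 2:
        raise DataError("need at least two observations for R^2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _bias_pct(values: np.ndarray, d: np.ndarray, modality: str) -> np.ndarray:
    """Signed bias as % of disparity; NaN at d = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        if modality == "visual":
            return np.where(d != 0, 100.0 * values / d, np.nan)
        return np.where(d != 0, 100.0 * (d - values) / d, np.nan)


def _result_from_predictions(data: ConditionData, model: str, lam: float,
                             sigma_c: float, pred: np.ndarray, sse: float,
                             n_converged: int, best_start: int,
                             at_bounds: tuple[str, ...],
                             stage1_best: float = float("nan"),
                             stage1_median: float = float("nan")) -> FitResult:
    d = data.disparities
    obs_v, obs_p = data.observed()
    nz = d != 0
    obs_v_pct = _bias_pct(obs_v, d, "visual")
    obs_p_pct = _bias_pct(obs_p, d, "proprio")
    pred_v_pct = _bias_pct(pred[:, 0], d, "visual")
    pred_p_pct = _bias_pct(pred[:, 1], d, "proprio")
    residuals = pd.DataFrame({
        "disparity_mm": np.concatenate([d, d]),
        "modality": ["visual"] * len(d) + ["proprioceptive"] * len(d),
        "observed_mm": np.concatenate([obs_v, obs_p]),
        "predicted_mm": np.concatenate([pred[:, 0], pred[:, 1]]),
        "residual_mm": np.concatenate([obs_v - pred[:, 0], obs_p - pred[:, 1]]),
        "observed_bias_pct": np.concatenate([obs_v_pct, obs_p_pct]),
        "predicted_bias_pct": np.concatenate([pred_v_pct, pred_p_pct]),
    })
    residuals["residual_pct"] = (residuals["observed_bias_pct"]
                                 - residuals["predicted_bias_pct"])
    return FitResult(
        participant=data.participant,
        visibility=data.visibility,
        model=model,
        lam_hat=float(lam),
        sigma_c_hat=float(sigma_c),
        sse=float(sse),
        r2_visual=goodness_of_fit_r2(obs_v_pct[nz], pred_v_pct[nz]),
        r2_proprio=goodness_of_fit_r2(obs_p_pct[nz], pred_p_pct[nz]),
        residuals=residuals,
        n_stage1_converged=n_converged,
        best_start_index=best_start,
        at_bounds=at_bounds,
        stage1_best_sse=stage1_best,
        stage1_median_sse=stage1_median,
    )


def _start_rng(master_seed: int, participant: str, visibility: str) -> np.random.Generator:
    """Deterministic per-(participant, condition) stream for the random starts."""
    return np.random.default_rng(
        [int(master_seed), zlib.crc32(participant.encode()),
         VISIBILITIES.index(visibility)])


def fit_condition(data: ConditionData, config: FitConfig | None = None) -> FitResult:
    """Fit (lam, sigma_c) for one participant x visibility condition.

    Stage 1: ``n_starts_stage1`` bounded descents from uniform random points,
    each stopped at a lax SSE-decrease tolerance.  Stage 2: the
    ``n_carry_stage2`` best stage-1 endpoints are re-descended at the
    stringent tolerance.  The overall best (ties to the earlier candidate) is
    returned; parameters pinned at a bound are flagged, not an error.
    """
    config = config or FitConfig()
    lam_lo, lam_hi = config.lam_bounds
    sc_lo, sc_hi = config.sigma_c_bounds(data.noise)
    bounds = [(lam_lo, lam_hi), (sc_lo, sc_hi)]

    obs_v, obs_p = data.observed()
    keep = np.ones(len(DISPARITIES_MM), dtype=bool)
    if not config.include_zero_disparity:
        keep &= data.disparities != 0

    def residuals(x) -> np.ndarray:
        try:
            pred = _predictions(float(x[0]), float(x[1]), data, config.area_A)
        except FloatingPointError:
            return np.full(2 * int(keep.sum()), np.inf)
        res_p = obs_p[keep] - pred[keep, 1]
        if config.include_visual:
            return np.concatenate([obs_v[keep] - pred[keep, 0], res_p])
        return res_p

    rng = _start_rng(config.master_seed, data.participant, data.visibility)
    starts = np.column_stack([
        rng.uniform(lam_lo, lam_hi, config.n_starts_stage1),
        rng.uniform(sc_lo, sc_hi, config.n_starts_stage1),
    ])

    stage1: list[tuple[float, np.ndarray, int]] = []
    for i, x0 in enumerate(starts):
        x, f = _local_descent(residuals, x0, bounds, config.tol_stage1,
                              config.max_iter)
        if np.isfinite(f):
            stage1.append((f, x, i))
    if not stage1:
        raise FitError(
            f"all {config.n_starts_stage1} starts failed for "
            f"{data.participant}/{data.visibility}")
    stage1.sort(key=lambda t: (t[0], t[2]))

    best_f, best_x, best_i = np.inf, None, -1
    for f1, x1, i in stage1[: config.n_carry_stage2]:
        x, f = _local_descent(residuals, x1, bounds, config.tol_stage2,
                              config.max_iter)
        if f < best_f:
            best_f, best_x, best_i = f, x, i
    if best_x is None:  # pragma: no cover - stage1 guarantees a finite start
        raise FitError("stage 2 produced no finite fit")

    lam_hat, sc_hat = float(best_x[0]), float(best_x[1])
    at_bounds = tuple(
        name for name, val, (lo, hi) in (
            ("lam", lam_hat, (lam_lo, lam_hi)),
            ("sigma_c", sc_hat, (sc_lo, sc_hi)),
        ) if np.isclose(val, lo, atol=1e-9) or np.isclose(val, hi, atol=1e-9)
    )
    pred = _predictions(lam_hat, sc_hat, data, config.area_A)
    stage1_sses = [f for f, _, _ in stage1]
    return _result_from_predictions(
        data, "coupling_prior", lam_hat, sc_hat, pred, best_f,
        n_converged=len(stage1), best_start=best_i, at_bounds=at_bounds,
        stage1_best=float(min(stage1_sses)),
        stage1_median=float(np.median(stage1_sses)))


def fit_mle(data: ConditionData, grid: EvalGrid | None = None,
            area_A: float | None = None) -> FitResult:
    """Evaluate the forced-fusion model (lam = 1, sigma_c^2 = 1e-4 mm^2).

    No optimization: predictions are the reliability-weighted fusion of the
    two targets; residuals and R^2 are computed exactly as for the
    coupling-prior fit.
    """
    kwargs = {} if area_A is None else {"area_A": area_A}
    params = CouplingPriorParams(lam=1.0, sigma_c=MLE_SIGMA_C_MM, **kwargs)
    pred = _predictions(params.lam, params.sigma_c, data, params.area_A)
    obs_v, obs_p = data.observed()
    sse = float(np.sum((obs_v - pred[:, 0]) ** 2) + np.sum((obs_p - pred[:, 1]) ** 2))
    return _result_from_predictions(
        data, "forced_fusion", params.lam, params.sigma_c, pred, sse,
        n_converged=0, best_start=-1, at_bounds=())


def residual_table(fits) -> pd.DataFrame:
    """Long-format residuals over the eight nonzero signed disparities.

    One row per participant x visibility x modality x signed disparity, keyed
    additionally by disparity magnitude and direction.
    """
    rows = []
    for fit in fits:
        res = fit.residuals
        nz = res["disparity_mm"] != 0
        for _, r in res.loc[nz].iterrows():
            d = float(r["disparity_mm"])
            rows.append({
                "participant": fit.participant,
                "visibility": fit.visibility,
                "model": fit.model,
                "modality": r["modality"],
                "disparity_mm": d,
                "magnitude_mm": abs(d),
                "direction": "left" if d < 0 else "right",
                "residual_mm": float(r["residual_mm"]),
                "residual_pct": float(r["residual_pct"]),
            })
    columns = ["participant", "visibility", "model", "modality", "disparity_mm",
               "magnitude_mm", "direction", "residual_mm", "residual_pct"]
    return pd.DataFrame(rows, columns=columns)
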