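"""Descriptive and model-based analysis of trial-level reaching tables.

Reproduces the study's analysis chain on any schema-conforming trial table:
unisensory accuracy/precision, multisensory bias (mm and % of disparity),
direction folding, aggregation to per-condition means, coupling-prior and
forced-fusion fits per participant x visibility, and the group-level paired
contrast of the fitted parameters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    DISPARITIES_MM,
    ConditionData,
    DataError,
    FitConfig,
    FitResult,
    fit_condition,
    fit_mle,
    residual_table,
)
from .model import SensoryNoise

__all__ = [
    "unisensory_summary",
    "bias_percent",
    "fold_directions",
    "aggregate_condition_data",
    "group_parameter_contrast",
    "fits_table",
    "run_full_pipeline",
]


def _uni_rows(trials: pd.DataFrame) -> pd.DataFrame:
    uni = trials[trials["block_type"].isin(["uni_visual", "uni_proprio"])].copy()
    target = np.where(uni["block_type"] == "uni_visual",
                      uni["m_v_mm"], uni["m_p_mm"])
    uni["modality"] = np.where(uni["block_type"] == "uni_visual",
                               "visual", "proprioceptive")
    uni["error_mm"] = uni["response_mm"] - target
    return uni


def unisensory_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Accuracy and precision of unisensory reaches.

    Accuracy is the magnitude of the participant's mean signed error
    (|mean error|, mm); precision is the SD of the signed errors (n-1
    denominator; missing with fewer than two trials).
    """
    uni = _uni_rows(trials)
    if uni.empty:
        raise DataError("no unisensory rows in trial table")

    def agg(g: pd.DataFrame) -> pd.Series:
        err = g["error_mm"].to_numpy()
        return pd.Series({
            "accuracy_mm": abs(float(np.mean(err))),
            "precision_mm": float(np.std(err, ddof=1)) if err.size >= 2 else np.nan,
            "n_trials": int(err.size),
        })

    out = (uni.groupby(["participant_id", "visibility", "modality"])
           .apply(agg, include_groups=False).reset_index())
    out["n_trials"] = out["n_trials"].astype(int)
    return out


def _multi_rows(trials: pd.DataFrame) -> pd.DataFrame:
    multi = trials[trials["block_type"] == "multi"].copy()
    d = multi["disparity_mm"].to_numpy(dtype=float)
    resp = multi["response_mm"].to_numpy(dtype=float)
    m_v = multi["m_v_mm"].to_numpy(dtype=float)
    m_p = multi["m_p_mm"].to_numpy(dtype=float)
    own = np.where(multi["reach_target"] == "visual", m_v, m_p)
    toward_other = np.where(multi["reach_target"] == "visual", 1.0, -1.0) * np.sign(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        multi["bias_pct"] = np.where(
            d != 0,
            np.where(multi["reach_target"] == "visual",
                     100.0 * (resp - m_v) / (m_p - m_v),
                     100.0 * (m_p - resp) / (m_p - m_v)),
            np.nan)
    # signed bias in mm, positive toward the other modality's target;
    # at zero disparity the raw signed error is reported instead
    multi["signed_bias_mm"] = np.where(
        d != 0, (resp - own) * toward_other, resp - own)
    multi["relative_response_mm"] = resp - m_v
    multi["modality"] = np.where(multi["reach_target"] == "visual",
                                 "visual", "proprioceptive")
    return multi


def bias_percent(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell bias summary of multisensory reaches.

    One row per participant x visibility x modality x signed disparity with
    the mean signed bias (mm), the mean bias as % of disparity (missing at
    d = 0), the endpoint SD and the trial count.  Positive bias means a pull
    toward the other modality's target.
    """
    multi = _multi_rows(trials)
    if multi.empty:
        raise DataError("no multisensory rows in trial table")

    def agg(g: pd.DataFrame) -> pd.Series:
        resp = g["response_mm"].to_numpy()
        return pd.Series({
            "signed_bias_mm": float(g["signed_bias_mm"].mean()),
            "bias_pct": float(g["bias_pct"].mean()),
            "endpoint_sd_mm": float(np.std(resp, ddof=1)) if resp.size >= 2 else np.nan,
            "n_trials": int(resp.size),
        })

    out = (multi.groupby(["participant_id", "visibility", "modality",
                          "disparity_mm"])
           .apply(agg, include_groups=False).reset_index())
    out["n_trials"] = out["n_trials"].astype(int)
    return out


def fold_directions(summaries: pd.DataFrame) -> pd.DataFrame:
    """Fold leftward/rightward disparities onto magnitudes.

    Applies the study's convention: within-subject averaging happens on
    signed values per direction first; the absolute value is then taken of
    each subject-level mean, and the two directions are averaged.  Never
    takes absolute values of single trials.  Cells with one direction
    missing are flagged (``complete = False``).
    """
    s = summaries[summaries["disparity_mm"] != 0].copy()
    s["magnitude_mm"] = s["disparity_mm"].abs()

    def agg(g: pd.DataFrame) -> pd.Series:
        n_dir = g["disparity_mm"].nunique()
        return pd.Series({
            "folded_bias_pct": float(g["bias_pct"].abs().mean()),
            "folded_bias_mm": float(g["signed_bias_mm"].abs().mean()),
            "complete": bool(n_dir == 2),
        })

    out = (s.groupby(["participant_id", "visibility", "modality", "magnitude_mm"])
           .apply(agg, include_groups=False).reset_index())
    out["complete"] = out["complete"].astype(bool)
    return out


def aggregate_condition_data(trials: pd.DataFrame) -> list[ConditionData]:
    """Build per participant x visibility inputs for the model fits.

    The likelihood dispersions are the participant's unisensory SDs in the
    same visibility condition; the per-disparity means are reach endpoints
    relative to the visual target (so the model can place m_v at 0).
    """
    uni = unisensory_summary(trials)
    multi = _multi_rows(trials)
    out: list[ConditionData] = []
    for (pid, vis), g in multi.groupby(["participant_id", "visibility"]):
        u = uni[(uni["participant_id"] == pid) & (uni["visibility"] == vis)]
        sd = u.set_index("modality")["precision_mm"]
        if ("visual" not in sd.index or "proprioceptive" not in sd.index
                or not np.all(np.isfinite(sd[["visual", "proprioceptive"]]))):
            raise DataError(
                f"missing unisensory data for {pid}/{vis}: cannot fix likelihood")
        noise = SensoryNoise(float(sd["visual"]), float(sd["proprioceptive"]))
        cell = (g.groupby(["disparity_mm", "modality"])["relative_response_mm"]
                .agg(["mean", "size"]).unstack("modality"))
        try:
            means = pd.DataFrame({
                "mean_visual_mm": cell[("mean", "visual")],
                "mean_proprio_mm": cell[("mean", "proprioceptive")],
                "n_visual": cell[("size", "visual")],
                "n_proprio": cell[("size", "proprioceptive")],
            })
        except KeyError as exc:
            raise DataError(f"incomplete multisensory cells for {pid}/{vis}: {exc}")
        out.append(ConditionData(participant=str(pid), visibility=str(vis),
                                 noise=noise, means=means))
    return out


def fits_table(fits) -> pd.DataFrame:
    """Flatten FitResult records into one row per fit."""
    rows = [{
        "participant": f.participant,
        "visibility": f.visibility,
        "model": f.model,
        "lam_hat": f.lam_hat,
        "sigma_c_hat": f.sigma_c_hat,
        "sse": f.sse,
        "r2_visual": f.r2_visual,
        "r2_proprio": f.r2_proprio,
        "n_stage1_converged": f.n_stage1_converged,
        "at_bounds": ";".join(f.at_bounds),
    } for f in fits]
    return pd.DataFrame(rows, columns=[
        "participant", "visibility", "model", "lam_hat", "sigma_c_hat", "sse",
        "r2_visual", "r2_proprio", "n_stage1_converged", "at_bounds"])


def _paired_t(diff: np.ndarray) -> tuple[float, float]:
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(diff, np.zeros_like(diff))
    return float(t), float(p)


def group_parameter_contrast(fits) -> pd.DataFrame:
    """Paired visible-vs-invisible contrast of the fitted parameters.

    Means and SEMs per condition, plus the paired difference and its t test,
    computed within participants.  Participants missing either condition are
    dropped with a warning.
    """
    table = fits_table([f for f in fits if f.model == "coupling_prior"])
    if table.empty:
        raise DataError("no coupling-prior fits to contrast")
    rows = []
    for param in ("lam_hat", "sigma_c_hat"):
        wide = table.pivot(index="participant", columns="visibility",
                           values=param)
        if not {"visible", "invisible"} <= set(wide.columns):
            raise DataError("need both visibility conditions for the contrast")
        unpaired = wide.index[wide.isna().any(axis=1)]
        if len(unpaired):
            warnings.warn(f"dropping unpaired participants: {list(unpaired)}")
            wide = wide.dropna()
        n = len(wide)
        diff = (wide["invisible"] - wide["visible"]).to_numpy()
        t, p = _paired_t(diff)
        rows.append({
            "parameter": param.replace("_hat", ""),
            "n": n,
            "mean_visible": float(wide["visible"].mean()),
            "sem_visible": float(wide["visible"].std(ddof=1) / np.sqrt(n)),
            "mean_invisible": float(wide["invisible"].mean()),
            "sem_invisible": float(wide["invisible"].std(ddof=1) / np.sqrt(n)),
            "mean_diff": float(np.mean(diff)),
            "sem_diff": float(np.std(diff, ddof=1) / np.sqrt(n)),
            "t_paired": t,
            "p_value": p,
        })
    return pd.DataFrame(rows)


def run_full_pipeline(trials: pd.DataFrame,
                      fit_config: FitConfig | None = None) -> dict:
    """Full analysis: descriptives, both model fits, residuals, contrast.

    Returns a dict of DataFrames (plus the FitResult objects under
    ``"fit_objects"``).  Deterministic given the trial table and the fit
    configuration's master seed.
    """
    if trials is None or len(trials) == 0:
        raise DataError("empty trial table")
    fit_config = fit_config or FitConfig()
    uni = unisensory_summary(trials)
    bias = bias_percent(trials)
    folded = fold_directions(bias)
    condition_data = aggregate_condition_data(trials)
    cp_fits: list[FitResult] = []
    mle_fits: list[FitResult] = []
    for data in condition_data:
        cp_fits.append(fit_condition(data, fit_config))
        mle_fits.append(fit_mle(data, grid=fit_config.grid,
                                area_A=fit_config.area_A))
    contrast = group_parameter_contrast(cp_fits)
    return {
        "unisensory": uni,
        "bias": bias,
        "folded": folded,
        "fits": fits_table(cp_fits + mle_fits),
        "residuals": residual_table(cp_fits + mle_fits),
        "contrast": contrast,
        "fit_objects": {"coupling_prior": cp_fits, "forced_fusion": mle_fits},
    }
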