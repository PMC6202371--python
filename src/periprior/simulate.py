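"""Synthetic reaching cohorts emulating the VR visuo-proprioceptive study.

Each simulated participant reaches toward unisensory visual targets,
unisensory proprioceptive targets, and bimodal visuo-proprioceptive targets
presented at signed azimuthal disparities {0, +/-25, +/-50, +/-100, +/-200}
mm, with the reaching hand either rendered ("visible") or not ("invisible").
Unisensory reaches are targets plus Gaussian sensory noise.  Multisensory
reaches are generated trialwise by sample-then-decode: the observer draws
noisy sensory measurements x_v ~ N(m_v, sigma_v), x_p ~ N(m_p, sigma_p),
forms the posterior with the likelihood centred on the samples and the
participant's coupling prior, and reaches to the MAP coordinates (visual
reach first, then the proprioceptive reach of the same presentation).

The generative defaults are the group-level values the study reports:
condition-specific unisensory dispersions, coupling strength ``lam`` and
coupling dispersion ``sigma_c``, with between-participant spread implied by
the printed standard errors (SD = sqrt(20) x SEM for the 20-participant
group).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .model import CouplingPriorParams, ParameterError, SensoryNoise, map_estimates

__all__ = [
    "N_PARTICIPANTS",
    "CohortDesign",
    "ConditionParams",
    "GenerativeParams",
    "default_generative_params",
    "draw_participant_params",
    "simulate_unisensory",
    "simulate_multisensory",
    "make_cohort",
]

N_PARTICIPANTS = 20

#: Lower truncation for drawn dispersions (mm): keeps every simulated
#: participant's likelihood well-defined.
_MIN_SIGMA_MM = 1.0

VISIBILITIES = ("visible", "invisible")


@dataclass(frozen=True)
class ConditionParams:
    """Generative parameters of one visibility condition."""

    sigma_v: float
    sigma_p: float
    lam: float
    sigma_c: float


@dataclass(frozen=True)
class GenerativeParams:
    """Cohort-level generative settings.

    ``visible`` / ``invisible`` hold the condition means; ``visible_sd`` /
    ``invisible_sd`` the between-participant SDs of each parameter.  Motor
    noise defaults to zero (absorbed into the sensory dispersions).
    """

    visible: ConditionParams
    invisible: ConditionParams
    visible_sd: ConditionParams
    invisible_sd: ConditionParams
    motor_sd: float = 0.0

    def condition(self, visibility: str) -> ConditionParams:
        return self.visible if visibility == "visible" else self.invisible

    def condition_sd(self, visibility: str) -> ConditionParams:
        return self.visible_sd if visibility == "visible" else self.invisible_sd


def default_generative_params(proprio_sd_swapped: bool = False) -> GenerativeParams:
    """Study-level defaults for the two hand-visibility conditions.

    Visible: sigma_v = 6.8, sigma_p = 22.9, lam = 0.44, sigma_c = 16.5;
    invisible: sigma_v = 12.5, sigma_p = 19.8, lam = 0.34, sigma_c = 35.9
    (mm throughout).  Between-participant SDs are sqrt(20) x the printed
    SEMs.  The proprioceptive-SD assignment to conditions follows the
    sentence order of the visual contrast; ``proprio_sd_swapped=True``
    exchanges it (the alternative reading).
    """
    s20 = sqrt(20.0)
    vis = ConditionParams(sigma_v=6.8, sigma_p=22.9, lam=0.44, sigma_c=16.5)
    inv = ConditionParams(sigma_v=12.5, sigma_p=19.8, lam=0.34, sigma_c=35.9)
    vis_sd = ConditionParams(sigma_v=1.1 * s20, sigma_p=2.0 * s20,
                             lam=0.04 * s20, sigma_c=1.2 * s20)
    inv_sd = ConditionParams(sigma_v=1.1 * s20, sigma_p=3.1 * s20,
                             lam=0.04 * s20, sigma_c=5.0 * s20)
    if proprio_sd_swapped:
        vis, inv = (replace(vis, sigma_p=inv.sigma_p),
                    replace(inv, sigma_p=vis.sigma_p))
        vis_sd, inv_sd = (replace(vis_sd, sigma_p=inv_sd.sigma_p),
                          replace(inv_sd, sigma_p=vis_sd.sigma_p))
    return GenerativeParams(visible=vis, invisible=inv,
                            visible_sd=vis_sd, invisible_sd=inv_sd)


@dataclass(frozen=True)
class CohortDesign:
    """Trial counts and structure of the reaching session."""

    n_participants: int = N_PARTICIPANTS
    disparities: tuple = (-200.0, -100.0, -50.0, -25.0, 0.0, 25.0, 50.0, 100.0, 200.0)
    n_uni_visual: int = 48
    n_uni_proprio: int = 48
    n_multi_presentations: int = 216
    multi_block_len: int = 18
    visibility_switch_every: int = 9
    target_half_range_mm: float = 150.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("need at least one participant")
        n_levels = len(self.disparities)
        if self.multi_block_len != 2 * self.visibility_switch_every:
            raise ParameterError("a multisensory block is two visibility mini-blocks")
        if self.visibility_switch_every != n_levels:
            raise ParameterError("each mini-block shows every disparity once")
        if self.n_multi_presentations % self.multi_block_len:
            raise ParameterError("presentations must fill whole blocks")
        reps = self.n_multi_presentations // (2 * n_levels)
        if reps * 2 * n_levels != self.n_multi_presentations or reps < 1:
            raise ParameterError("presentations must balance disparity x visibility")

    @property
    def reps_per_cell(self) -> int:
        """Presentations per signed disparity per visibility (12 by default)."""
        return self.n_multi_presentations // (2 * len(self.disparities))

    @property
    def n_multi_blocks(self) -> int:
        return self.n_multi_presentations // self.multi_block_len


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def draw_participant_params(params: GenerativeParams,
                            rng: np.random.Generator) -> dict[str, ConditionParams]:
    """Draw one participant's condition parameters from truncated Gaussians."""
    out = {}
    for vis in VISIBILITIES:
        mu = params.condition(vis)
        sd = params.condition_sd(vis)
        out[vis] = ConditionParams(
            sigma_v=_truncnorm(rng, mu.sigma_v, sd.sigma_v, _MIN_SIGMA_MM, np.inf),
            sigma_p=_truncnorm(rng, mu.sigma_p, sd.sigma_p, _MIN_SIGMA_MM, np.inf),
            lam=_truncnorm(rng, mu.lam, sd.lam, 0.0, 1.0),
            sigma_c=_truncnorm(rng, mu.sigma_c, sd.sigma_c, _MIN_SIGMA_MM, np.inf),
        )
    return out


def _uni_visibility_sequence(n_trials: int, start: str) -> list[str]:
    # alternate every 12 unisensory trials so both conditions get equal counts
    seq = []
    order = list(VISIBILITIES) if start == "visible" else list(VISIBILITIES)[::-1]
    for i in range(n_trials):
        seq.append(order[(i // 12) % 2])
    return seq


def simulate_unisensory(participant: str, design: CohortDesign,
                        params: dict[str, ConditionParams],
                        rng: np.random.Generator,
                        motor_sd: float = 0.0,
                        start_visibility: str = "visible",
                        trial_offset: int = 0,
                        block_offset: int = 0) -> pd.DataFrame:
    """Unisensory reaching blocks: response = target + sensory (+ motor) noise."""
    rows = []
    trial = trial_offset
    for modality, n_trials, first_block in (
            ("visual", design.n_uni_visual, block_offset),
            ("proprioceptive", design.n_uni_proprio, block_offset + 2)):
        vis_seq = _uni_visibility_sequence(n_trials, start_visibility)
        for i in range(n_trials):
            vis = vis_seq[i]
            p = params[vis]
            target = rng.uniform(-design.target_half_range_mm,
                                 design.target_half_range_mm)
            sigma = p.sigma_v if modality == "visual" else p.sigma_p
            response = target + rng.normal(0.0, sigma)
            if motor_sd > 0:
                response += rng.normal(0.0, motor_sd)
            rows.append({
                "participant_id": participant,
                "visibility": vis,
                "block_type": "uni_visual" if modality == "visual" else "uni_proprio",
                "reach_target": modality if modality == "visual" else "proprioceptive",
                "m_v_mm": target if modality == "visual" else np.nan,
                "m_p_mm": target if modality == "proprioceptive" else np.nan,
                "disparity_mm": np.nan,
                "response_mm": response,
                "trial_index": trial,
                "block_index": first_block + i // 24,
            })
            trial += 1
    return pd.DataFrame(rows)


def simulate_multisensory(participant: str, design: CohortDesign,
                          params: dict[str, ConditionParams],
                          rng: np.random.Generator,
                          motor_sd: float = 0.0,
                          start_visibility: str = "visible",
                          trial_offset: int = 0,
                          block_offset: int = 0) -> pd.DataFrame:
    """Multisensory blocks via sample-then-decode.

    Every presentation yields two rows sharing a ``trial_index``: the visual
    reach (response = MAP visual coordinate) followed by the proprioceptive
    reach (MAP proprioceptive coordinate).  Visibility alternates every
    mini-block of 9 presentations; each mini-block shows each disparity once
    in random order.
    """
    half = design.visibility_switch_every
    order = list(VISIBILITIES) if start_visibility == "visible" else list(VISIBILITIES)[::-1]
    trials = []  # (visibility, disparity, m_v, x_v, x_p, trial_index, block_index)
    trial = trial_offset
    n_minis = design.n_multi_presentations // half
    for mini in range(n_minis):
        vis = order[mini % 2]
        p = params[vis]
        for d in rng.permutation(np.asarray(design.disparities, dtype=float)):
            m_v = rng.uniform(-design.target_half_range_mm,
                              design.target_half_range_mm)
            m_p = m_v + d
            x_v = rng.normal(m_v, p.sigma_v)
            x_p = rng.normal(m_p, p.sigma_p)
            block = block_offset + (mini * half) // design.multi_block_len
            trials.append((vis, float(d), m_v, x_v, x_p, trial, block))
            trial += 1
    frame = pd.DataFrame(trials, columns=[
        "visibility", "disparity_mm", "m_v_mm", "x_v", "x_p",
        "trial_index", "block_index"])
    # decode all presentations of a visibility condition in one batch
    frame["v_hat"] = np.nan
    frame["p_hat"] = np.nan
    for vis in VISIBILITIES:
        mask = frame["visibility"] == vis
        if not mask.any():
            continue
        p = params[vis]
        est = map_estimates(
            frame.loc[mask, ["x_v", "x_p"]].to_numpy(),
            SensoryNoise(p.sigma_v, p.sigma_p),
            CouplingPriorParams(lam=p.lam, sigma_c=p.sigma_c))
        frame.loc[mask, "v_hat"] = est[:, 0]
        frame.loc[mask, "p_hat"] = est[:, 1]
    if motor_sd > 0:
        frame["v_hat"] += rng.normal(0.0, motor_sd, len(frame))
        frame["p_hat"] += rng.normal(0.0, motor_sd, len(frame))
    rows = []
    for rec in frame.itertuples():
        common = {
            "participant_id": participant,
            "visibility": rec.visibility,
            "block_type": "multi",
            "m_v_mm": rec.m_v_mm,
            "m_p_mm": rec.m_v_mm + rec.disparity_mm,
            "disparity_mm": rec.disparity_mm,
            "trial_index": rec.trial_index,
            "block_index": rec.block_index,
        }
        rows.append(dict(common, reach_target="visual", response_mm=rec.v_hat))
        rows.append(dict(common, reach_target="proprioceptive", response_mm=rec.p_hat))
    cols = ["participant_id", "visibility", "block_type", "reach_target",
            "m_v_mm", "m_p_mm", "disparity_mm", "response_mm",
            "trial_index", "block_index"]
    return pd.DataFrame(rows)[cols]


def make_cohort(design: CohortDesign | None = None,
                params: GenerativeParams | None = None,
                master_seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort; returns (trial table, ground-truth record).

    Participant parameters are drawn from truncated Gaussians around the
    condition means; every participant then completes the full session.
    Fully reproducible from ``master_seed``.
    """
    design = design or CohortDesign()
    params = params or default_generative_params()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(design.n_participants + 1)
    draw_rng = np.random.default_rng(children[0])
    tables = []
    truth: dict = {"master_seed": int(master_seed), "participants": {},
                   "condition_means": {
                       vis: vars(params.condition(vis)) for vis in VISIBILITIES}}
    for i in range(design.n_participants):
        pid = f"P{i + 1:02d}"
        p_params = draw_participant_params(params, draw_rng)
        truth["participants"][pid] = {
            vis: {k: float(v) for k, v in vars(p_params[vis]).items()}
            for vis in VISIBILITIES}
        rng = np.random.default_rng(children[i + 1])
        start = VISIBILITIES[i % 2]
        uni = simulate_unisensory(pid, design, p_params, rng,
                                  motor_sd=params.motor_sd,
                                  start_visibility=start)
        n_uni = len(uni)
        multi = simulate_multisensory(pid, design, p_params, rng,
                                      motor_sd=params.motor_sd,
                                      start_visibility=start,
                                      trial_offset=n_uni, block_offset=4)
        tables.extend([uni, multi])
    trials = pd.concat(tables, ignore_index=True)
    return trials, truth
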