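"""Synthetic EMA data with exposed ground truth.

Emulates a one-week intensive-longitudinal protocol: up to six prompts per
day for seven days, a five-item negative-affect scale rated 0-100, a
three-item binary stressful-events scale, integer-second response times, a
missed-prompt rate around 25%, moderate between-person stability (latent
intraclass correlations near 0.31 for drift and 0.39 for boundary),
momentary work/recovery activity shifts on drift and boundary, person-level
covariates (neuroticism, depression) loading on the person means, and
practice trends (drift rising, boundary falling over occasions).

Every item response is sampled from the Wiener first-passage law with
``mu = theta - v_h`` and ``alpha = gamma / a_h``; the truth object aligns
1:1 with the emitted records so recovery can be tested at every pipeline
stage.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import EMARecord, ItemSet, RECOVERY_ACTIVITIES
from .ddm import sample_responses

__all__ = [
    "TrueItem",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "emulate_paper_shape",
    "DEFAULT_AFFECT_ITEMS",
    "DEFAULT_EVENT_ITEMS",
    "affect_item_set",
    "event_item_set",
]


@dataclass(frozen=True)
class TrueItem:
    item_id: str
    v: float      # item drift difficulty
    a: float      # item boundary ("time pressure"), > 0
    scale: str    # "vas" or "binary"


# Negative-affect items: endorsed in a minority of moments, so difficulties
# sit mostly above the zero-anchored person drift; item boundaries near 1
# with a person boundary around exp(1.5) keep RTs inside the 0-30 s window.
DEFAULT_AFFECT_ITEMS = (
    TrueItem("angry", 1.0, 0.80, "vas"),
    TrueItem("dejected", 1.5, 0.95, "vas"),
    TrueItem("frustrated", -0.5, 1.10, "vas"),
    TrueItem("lonely", 0.5, 1.20, "vas"),
    TrueItem("stressed", 0.0, 1.30, "vas"),
)
DEFAULT_EVENT_ITEMS = (
    TrueItem("stressful_event", 0.6, 0.90, "binary"),
    TrueItem("money_worry", 1.0, 1.05, "binary"),
    TrueItem("argument", 1.4, 1.25, "binary"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    seed: int                                     # mandatory
    n_persons: int = 954
    days: int = 7
    prompts_per_day: int = 6
    completion_rate: float = 0.75
    affect_items: tuple = DEFAULT_AFFECT_ITEMS
    event_items: tuple = DEFAULT_EVENT_ITEMS
    # between/within SDs of person drift and log boundary; the defaults give
    # latent intraclass correlations 0.31 (drift) and 0.39 (log boundary)
    sd_theta_between: float = 0.45
    sd_theta_within: float = 0.67
    mean_log_gamma: float = 1.50
    sd_log_gamma_between: float = 0.20
    sd_log_gamma_within: float = 0.25
    # occasion-level activity effects, in within-person SD units of
    # (theta, log gamma)
    work_prob: float = 0.25
    recovery_prob: float = 0.55
    work_effect: tuple = (-0.254, -0.133)
    recovery_effect: tuple = (0.106, 0.075)
    # person covariates: standardized, correlated; loadings shift the person
    # means in between-person SD units
    cov_correlation: float = 0.5
    neuroticism_loading: tuple = (-0.18, -0.11)
    depression_loading: tuple = (-0.21, -0.11)
    # practice trends: gain = asymptote - initial, in total-SD units of the
    # underlying variable; drift rises, boundary falls, as in a practice
    # effect with positive drift gain and negative caution gain
    theta_gain_sd: float = 0.752
    log_gamma_gain_sd: float = -0.825
    trend_rate: float = 0.25
    # nondecision time: lognormal per occasion (log-seconds)
    ter_log_mean: float = 0.85
    ter_log_sd: float = 0.25
    rt_cap: float = 30.0
    integer_round: bool = True

    def __post_init__(self):
        if not (0 < self.completion_rate <= 1):
            raise ValueError("completion_rate must be in (0, 1]")
        for sd in (
            self.sd_theta_between,
            self.sd_theta_within,
            self.sd_log_gamma_between,
            self.sd_log_gamma_within,
            self.ter_log_sd,
        ):
            if sd < 0:
                raise ValueError("variances must be nonnegative")

    @property
    def scheduled_per_person(self) -> int:
        return self.days * self.prompts_per_day

    @property
    def scheduled_total(self) -> int:
        return self.n_persons * self.scheduled_per_person

    @property
    def latent_icc_theta(self) -> float:
        b, w = self.sd_theta_between**2, self.sd_theta_within**2
        return b / (b + w)

    @property
    def latent_icc_log_gamma(self) -> float:
        b, w = self.sd_log_gamma_between**2, self.sd_log_gamma_within**2
        return b / (b + w)


@dataclass
class SyntheticTruth:
    """Ground truth aligned 1:1 with the emitted records."""

    config: SyntheticConfig
    persons: pd.DataFrame      # person_id, neuroticism, depression, theta_mean, log_gamma_mean
    occasions: pd.DataFrame    # person_id, occasion_id, day, completed, theta, gamma, log_gamma, ter, work, recovery
    items: pd.DataFrame        # item_id, v, a, scale


def _trend(cfg: SyntheticConfig, occ0: np.ndarray, gain: float) -> np.ndarray:
    # change accrued by occasion occ0 (0-based): gain * (1 - exp(-r * occ0))
    return gain * (1.0 - np.exp(-cfg.trend_rate * occ0))


def generate_dataset(config: SyntheticConfig):
    """Generate (records, truth) under the configured study conditions.

    Deterministic given ``config.seed``.  Missed prompts are absent rows.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    items = list(cfg.affect_items) + list(cfg.event_items)
    if any(it.a <= 0 for it in items):
        raise ValueError("item boundary parameters must be positive")
    n_p = cfg.n_persons
    n_occ = cfg.scheduled_per_person

    # person level -----------------------------------------------------------
    cov_l = np.linalg.cholesky(
        np.array([[1.0, cfg.cov_correlation], [cfg.cov_correlation, 1.0]])
    )
    nd = rng.standard_normal((n_p, 2)) @ cov_l.T
    neuro, dep = nd[:, 0], nd[:, 1]

    def person_mean(load_n, load_d, sd_b):
        expl = (
            load_n**2 + load_d**2 + 2.0 * cfg.cov_correlation * load_n * load_d
        )
        resid = np.sqrt(max(1.0 - expl, 0.0))
        z = load_n * neuro + load_d * dep + resid * rng.standard_normal(n_p)
        return sd_b * z

    theta_mean = person_mean(
        cfg.neuroticism_loading[0], cfg.depression_loading[0], cfg.sd_theta_between
    )
    lg_mean = cfg.mean_log_gamma + person_mean(
        cfg.neuroticism_loading[1], cfg.depression_loading[1], cfg.sd_log_gamma_between
    )

    # occasion level ----------------------------------------------------------
    occ_idx = np.tile(np.arange(1, n_occ + 1), n_p)            # scheduled, 1-based
    pid_idx = np.repeat(np.arange(n_p), n_occ)
    day = (occ_idx - 1) // cfg.prompts_per_day + 1
    completed = rng.random(n_p * n_occ) < cfg.completion_rate
    work = (rng.random(n_p * n_occ) < cfg.work_prob).astype(int)
    recovery = (rng.random(n_p * n_occ) < cfg.recovery_prob).astype(int)

    sd_tot_theta = np.hypot(cfg.sd_theta_between, cfg.sd_theta_within)
    sd_tot_lg = np.hypot(cfg.sd_log_gamma_between, cfg.sd_log_gamma_within)

    theta = (
        theta_mean[pid_idx]
        + cfg.sd_theta_within * rng.standard_normal(n_p * n_occ)
        + work * cfg.work_effect[0] * cfg.sd_theta_within
        + recovery * cfg.recovery_effect[0] * cfg.sd_theta_within
        + _trend(cfg, occ_idx - 1.0, cfg.theta_gain_sd * sd_tot_theta)
    )
    log_gamma = (
        lg_mean[pid_idx]
        + cfg.sd_log_gamma_within * rng.standard_normal(n_p * n_occ)
        + work * cfg.work_effect[1] * cfg.sd_log_gamma_within
        + recovery * cfg.recovery_effect[1] * cfg.sd_log_gamma_within
        + _trend(cfg, occ_idx - 1.0, cfg.log_gamma_gain_sd * sd_tot_lg)
    )
    gamma = np.exp(log_gamma)
    ter = np.exp(cfg.ter_log_mean + cfg.ter_log_sd * rng.standard_normal(n_p * n_occ))

    # item level (completed prompts only) -------------------------------------
    comp = np.flatnonzero(completed)
    H = len(items)
    mu_mat = theta[comp, None] - np.array([it.v for it in items])[None, :]
    alpha_mat = gamma[comp, None] / np.array([it.a for it in items])[None, :]
    ter_mat = np.broadcast_to(ter[comp, None], mu_mat.shape)
    x_mat, t_mat = sample_responses(mu_mat, alpha_mat, ter_mat, rng)
    if cfg.integer_round:
        t_mat = np.maximum(np.rint(t_mat), 1.0)

    # vas ratings consistent with the sampled binary choice
    u = rng.random(x_mat.shape)
    vas_rating = np.where(x_mat == 1, 50 + np.floor(u * 51), np.floor(u * 50)).astype(int)

    person_ids = np.array([f"p{i:04d}" for i in range(n_p)])
    act_labels = sorted(RECOVERY_ACTIVITIES)
    neutral = ["chores", "eating", "drinking", "other"]
    rec_choice = rng.integers(0, len(act_labels), size=n_p * n_occ)
    neutral_choice = rng.integers(0, len(neutral), size=n_p * n_occ)
    add_neutral = rng.random(n_p * n_occ) < 0.3

    records: list[EMARecord] = []
    for row, occ_flat in enumerate(comp):
        p = pid_idx[occ_flat]
        acts = set()
        if work[occ_flat]:
            acts.add("work")
        if recovery[occ_flat]:
            acts.add(act_labels[rec_choice[occ_flat]])
        if add_neutral[occ_flat] or not acts:
            acts.add(neutral[neutral_choice[occ_flat]])
        acts = frozenset(acts)
        for h, it in enumerate(items):
            rating = int(vas_rating[row, h]) if it.scale == "vas" else int(x_mat[row, h])
            records.append(
                EMARecord(
                    person_id=str(person_ids[p]),
                    occasion_id=int(occ_idx[occ_flat]),
                    day=int(day[occ_flat]),
                    item_id=it.item_id,
                    rating=rating,
                    rt_seconds=float(t_mat[row, h]),
                    activities=acts,
                    neuroticism=float(neuro[p]),
                    depression=float(dep[p]),
                )
            )

    truth = SyntheticTruth(
        config=cfg,
        persons=pd.DataFrame(
            {
                "person_id": person_ids,
                "neuroticism": neuro,
                "depression": dep,
                "theta_mean": theta_mean,
                "log_gamma_mean": lg_mean,
            }
        ),
        occasions=pd.DataFrame(
            {
                "person_id": person_ids[pid_idx],
                "occasion_id": occ_idx,
                "day": day,
                "completed": completed,
                "theta": theta,
                "gamma": gamma,
                "log_gamma": log_gamma,
                "ter": ter,
                "work": work,
                "recovery": recovery,
            }
        ),
        items=pd.DataFrame(
            {
                "item_id": [it.item_id for it in items],
                "v": [it.v for it in items],
                "a": [it.a for it in items],
                "scale": [it.scale for it in items],
            }
        ),
    )
    return records, truth


def emulate_paper_shape(seed: int):
    """Convenience preset at the emulated study's full size.

    954 persons, 7 days x 6 prompts (40,068 scheduled occasions), 75%
    completion, 5 affect + 3 event items, default effect sizes.
    """
    return generate_dataset(SyntheticConfig(seed=seed))


def affect_item_set(cfg: SyntheticConfig = None) -> ItemSet:
    items = cfg.affect_items if cfg is not None else DEFAULT_AFFECT_ITEMS
    return ItemSet("affect", tuple(it.item_id for it in items), "vas")


def event_item_set(cfg: SyntheticConfig = None) -> ItemSet:
    items = cfg.event_items if cfg is not None else DEFAULT_EVENT_ITEMS
    return ItemSet("events", tuple(it.item_id for it in items), "binary")
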