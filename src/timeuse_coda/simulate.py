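"""Synthetic cohort generator with known ground truth.

Emulates the study design the analysis pipeline expects: ~211 adults
wearing an accelerometer for 7 days (daily minutes of sedentary behaviour,
light activity, MVPA and sleep closing to 1440), up to three EMA affect
prompts per day in three daytime windows, and a one-row-per-participant
survey (life satisfaction 0-10 plus demographics).

Daily compositions are logistic-normal: person-mean ilr coordinates are
drawn around the population composition's coordinates, day coordinates
around the person mean, and both are mapped back through the inverse ilr.
Affect responses follow the same linear model the pipeline fits —
between/within ilr effects plus a person random intercept — so every
generated dataset carries its own ground truth for parameter-recovery
checks.  Non-wear minutes come from a two-class compliance mixture tuned
so roughly half the cohort survives the wear-time filters with ~4-5 valid
days each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import coda
from .coda import PARTS

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_cohort"]

# EMA prompt windows (start hour, end hour), 08:00-21:00
EMA_WINDOWS = ((8, 12), (12, 17), (17, 21))
WINDOW_NAMES = ("morning", "afternoon", "evening")

START_DATE = "2023-06-05"

DEFAULT_BETA_BETWEEN = {
    # SB-pivot basis; magnitudes on the scale of the adjusted between-person
    # day-level coefficients so recovery behaviour is realistic
    "happiness": (-1.54, 0.5, 0.15),
    "anxiousness": (1.89, 0.0, -0.30),
    "tiredness": (-0.88, 0.54, -0.24),
}
DEFAULT_BETA_WITHIN = {a: (0.0, 0.0, 0.0) for a in DEFAULT_BETA_BETWEEN}
DEFAULT_AFFECT_MEANS = {"happiness": 7.05, "anxiousness": 2.43, "tiredness": 4.29}

AGE_BANDS = ("<25", "25-34", "35-44", "45-54", "55-64", "65+")
AGE_PROBS = (0.109, 0.213, 0.208, 0.161, 0.189, 0.118)
FEMALE_FRACTION = 0.716
ETHNICITIES = ("NZ European", "Maori", "Pacific Island", "Asian", "Other")
ETHNICITY_PROBS = (0.403, 0.161, 0.317, 0.227, 0.024)
DEPRIVATION_PROBS = (0.0, 0.0, 0.057, 0.057, 0.081, 0.095, 0.047, 0.147, 0.142, 0.374)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_participants: int = 211
    n_days: int = 7
    population_composition: tuple = (682.0, 278.0, 8.0, 471.0)
    # third-coordinate spread (MVPA vs sleep) is wide so the arithmetic
    # mean of MVPA sits near 21 min/day while its geometric mean stays at 8
    between_sd_ilr: tuple = (0.25, 0.25, 1.4)
    within_sd_ilr: tuple = (0.15, 0.2, 1.4)
    true_beta_between: dict = field(default_factory=lambda: dict(DEFAULT_BETA_BETWEEN))
    true_beta_within: dict = field(default_factory=lambda: dict(DEFAULT_BETA_WITHIN))
    affect_means: dict = field(default_factory=lambda: dict(DEFAULT_AFFECT_MEANS))
    person_intercept_sd: float = 1.5
    residual_sd: float = 1.2
    prompts_per_day: int = 3
    ema_response_prob: float = 0.4
    # life satisfaction: null composition effect by default
    ls_beta_between: tuple = (0.0, 0.0, 0.0)
    ls_mean: float = 7.28
    ls_noise_sd: float = 1.9
    # compliance mixture for non-wear
    low_wear_fraction: float = 0.5
    nonwear_exceed_prob_good: float = 0.30
    nonwear_exceed_prob_low: float = 0.9
    # optional rounded-zero censoring of MVPA (minutes below this become 0)
    censor_mvpa_limit: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0 or self.n_days <= 0:
            raise ValueError("n_participants and n_days must be positive")
        if np.any(np.asarray(self.population_composition) <= 0):
            raise ValueError("population composition must be strictly positive")
        if np.any(np.asarray(self.between_sd_ilr) < 0) or np.any(
            np.asarray(self.within_sd_ilr) < 0
        ):
            raise ValueError("ilr SDs must be non-negative")
        for p in (
            self.ema_response_prob,
            self.low_wear_fraction,
            self.nonwear_exceed_prob_good,
            self.nonwear_exceed_prob_low,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Everything needed to recompute expected values in closed form."""

    config: GeneratorConfig
    person_ilr_mean: np.ndarray  # (n, 3) in the SB-pivot basis
    day_ilr: np.ndarray  # (n, n_days, 3)
    person_intercepts: dict  # affect -> (n,)
    alphas: dict  # affect -> intercept used
    valid_day: np.ndarray  # (n, n_days) bool, nonwear <= 120
    surviving_participants: np.ndarray  # (n,) bool, >= 2 valid days

    def to_json_dict(self) -> dict:
        return {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "person_ilr_mean": self.person_ilr_mean.tolist(),
            "alphas": self.alphas,
            "true_beta_between": self.config.true_beta_between,
            "true_beta_within": self.config.true_beta_within,
            "n_surviving_participants": int(self.surviving_participants.sum()),
            "n_valid_days": int(self.valid_day.sum()),
            "seed": self.config.seed,
        }


def _participant_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(1, n + 1)]


def generate_compositions(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Daily behaviour minutes (closed to 1440) with non-wear attached."""
    basis = coda.default_basis("sb")
    n, d = cfg.n_participants, cfg.n_days
    mu = coda.ilr_transform(np.asarray(cfg.population_composition), basis)
    b_sd = np.asarray(cfg.between_sd_ilr)
    w_sd = np.asarray(cfg.within_sd_ilr)

    person_mu = mu + rng.standard_normal((n, 3)) * b_sd
    day_ilr = person_mu[:, None, :] + rng.standard_normal((n, d, 3)) * w_sd
    comps = coda.ilr_inverse(day_ilr.reshape(-1, 3), basis).reshape(n, d, 4)

    low_wear = rng.random(n) < cfg.low_wear_fraction
    p_exceed = np.where(
        low_wear, cfg.nonwear_exceed_prob_low, cfg.nonwear_exceed_prob_good
    )
    exceed = rng.random((n, d)) < p_exceed[:, None]
    nonwear = np.where(
        exceed,
        121.0 + rng.gamma(2.0, 90.0, size=(n, d)),
        rng.gamma(1.5, 10.0, size=(n, d)),
    ).round(1)
    nonwear = np.minimum(nonwear, 1200.0)

    valid = nonwear <= 120.0
    surviving = valid.sum(axis=1) >= 2

    ids = _participant_ids(n)
    dates = pd.date_range(START_DATE, periods=d, freq="D")
    daily = pd.DataFrame(
        {
            "participant_id": np.repeat(ids, d),
            "date": np.tile(dates, n),
            # recorded to 0.1 min; floored so recording never creates a zero
            **{
                p: np.maximum(comps[:, :, k].ravel().round(1), 0.1)
                for k, p in enumerate(PARTS)
            },
            "nonwear": nonwear.ravel(),
        }
    )
    truth = SyntheticTruth(
        config=cfg,
        person_ilr_mean=person_mu,
        day_ilr=day_ilr,
        person_intercepts={},
        alphas={},
        valid_day=valid,
        surviving_participants=surviving,
    )
    return daily, truth


def generate_ema(
    truth: SyntheticTruth, cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """EMA responses: up to ``prompts_per_day`` per day, one per window.

    Latent affect is linear in the ground-truth between/within ilr
    coordinates plus a person intercept and per-response noise; recorded
    scores are clamped to [0, 10] and rounded to one decimal, mimicking
    the 0-10 slider.
    """
    n, d = cfg.n_participants, cfg.n_days
    basis = coda.default_basis("sb")
    mu_pop = coda.ilr_transform(np.asarray(cfg.population_composition), basis)
    ilr_b = truth.person_ilr_mean
    ilr_w = truth.day_ilr - ilr_b[:, None, :]

    alphas, intercepts = {}, {}
    for a, target in cfg.affect_means.items():
        beta_b = np.asarray(cfg.true_beta_between[a])
        alphas[a] = float(target - beta_b @ mu_pop)
        intercepts[a] = rng.standard_normal(n) * cfg.person_intercept_sd
    truth.alphas = alphas
    truth.person_intercepts = intercepts

    windows = EMA_WINDOWS[: cfg.prompts_per_day]
    ids = _participant_ids(n)
    dates = pd.date_range(START_DATE, periods=d, freq="D")
    rows = []
    for i in range(n):
        for day in range(d):
            for w, (lo, hi) in enumerate(windows):
                answered = rng.random() < cfg.ema_response_prob
                minute = float(rng.uniform(lo * 60, hi * 60))
                if not answered:
                    continue
                ts = dates[day] + pd.Timedelta(minutes=round(minute, 1))
                row = {
                    "participant_id": ids[i],
                    "timestamp": ts,
                    "window": WINDOW_NAMES[w],
                }
                for a in cfg.affect_means:
                    latent = (
                        alphas[a]
                        + np.asarray(cfg.true_beta_between[a]) @ ilr_b[i]
                        + np.asarray(cfg.true_beta_within[a]) @ ilr_w[i, day]
                        + intercepts[a][i]
                        + rng.standard_normal() * cfg.residual_sd
                    )
                    row[a] = round(float(np.clip(latent, 0.0, 10.0)), 1)
                rows.append(row)
    cols = ["participant_id", "timestamp", "happiness", "anxiousness", "tiredness", "window"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["participant_id", "timestamp"], ignore_index=True
    )


def generate_survey(
    truth: SyntheticTruth, cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One-row-per-participant survey approximating the cohort's margins."""
    n = cfg.n_participants
    basis = coda.default_basis("sb")
    mu_pop = coda.ilr_transform(np.asarray(cfg.population_composition), basis)
    beta = np.asarray(cfg.ls_beta_between)
    alpha = cfg.ls_mean - beta @ mu_pop
    latent = (
        alpha
        + truth.person_ilr_mean @ beta
        + rng.standard_normal(n) * cfg.ls_noise_sd
    )
    ls = np.clip(np.round(latent), 0, 10).astype(int)

    gender = np.where(rng.random(n) < FEMALE_FRACTION, "Female", "Male")
    age_p = np.asarray(AGE_PROBS) / sum(AGE_PROBS)  # printed margins, renormalised
    age = rng.choice(AGE_BANDS, size=n, p=age_p)
    eth_draws = rng.random((n, len(ETHNICITIES))) < np.asarray(ETHNICITY_PROBS)
    eth = []
    for i in range(n):
        picks = [e for e, hit in zip(ETHNICITIES, eth_draws[i]) if hit]
        if not picks:  # everyone reports at least one ethnicity
            picks = [ETHNICITIES[rng.integers(len(ETHNICITIES))]]
        eth.append(";".join(picks))
    decile = rng.choice(
        np.arange(1, 11), size=n, p=np.asarray(DEPRIVATION_PROBS) / sum(DEPRIVATION_PROBS)
    )
    return pd.DataFrame(
        {
            "participant_id": _participant_ids(n),
            "life_satisfaction": ls,
            "age_band": age,
            "gender": gender,
            "ethnicity": eth,
            "deprivation_decile": decile,
        }
    )


def inject_missingness(
    daily: pd.DataFrame, cfg: GeneratorConfig
) -> pd.DataFrame:
    """Realise the optional rounded-zero censoring of MVPA.

    Day-level exclusions are already implicit in the generated non-wear
    minutes (and recorded in the truth object); this step only censors
    MVPA values below the detection limit to 0 so the imputation path of
    the pipeline is exercised.
    """
    out = daily.copy()
    if cfg.censor_mvpa_limit is not None:
        out.loc[out["mvpa"] < cfg.censor_mvpa_limit, "mvpa"] = 0.0
    return out


def generate_cohort(
    cfg: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate the full cohort: daily minutes, EMA responses and survey.

    Returns ``({"daily": ..., "ema": ..., "survey": ...}, truth)``.  All
    randomness flows from ``cfg.seed`` (or the ``seed`` override), so the
    same configuration reproduces byte-identical tables.
    """
    if cfg is None:
        cfg = GeneratorConfig()
    if seed is not None:
        cfg = GeneratorConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    daily, truth = generate_compositions(cfg, rng)
    ema = generate_ema(truth, cfg, rng)
    survey = generate_survey(truth, cfg, rng)
    daily = inject_missingness(daily, cfg)
    return {"daily": daily, "ema": ema, "survey": survey}, truth
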