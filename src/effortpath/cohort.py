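"""Synthetic inter-individual cohort generator.

Latent standardized variables follow the hypothesized causal chain

    plasma lactate -> dmPFC/dACC lactate -> physical-effort
    sensitivity (log kEp) -> neural effort sensitivity (Ech beta)

with Gaussian residuals, so every configured standardized path
coefficient equals the population correlation of its edge. Behavioral
readouts (HE/HPE/HME choice proportions) are NOT drawn from the chain:
each subject's full 216-trial session is simulated from their own
parameters, so downstream mediation tests are non-circular at the
proportion level. Lactate values are in arbitrary standardized units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import TaskConfig, generate_session, session_to_frame, \
    PHYSICAL, MENTAL
from .model import ModelParams


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DTParams:
    """Lognormal deliberation-time model: DT = exp(b0 - b1*|dSV| + eps),
    eps ~ N(0, sigma^2). Defaults give median DTs around 1.3 s, slower
    for close calls."""

    b0: float = 0.3
    b1: float = 0.15
    sigma: float = 0.25


def simulate_dt(delta_sv, dt_params: DTParams, rng: np.random.Generator):
    """Draw a deliberation time (seconds), decreasing in |dSV|."""
    dsv = np.abs(np.asarray(delta_sv, dtype=float))
    noise = rng.normal(0.0, dt_params.sigma, size=dsv.shape)
    return np.exp(dt_params.b0 - dt_params.b1 * dsv + noise)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Path coefficients are standardized edge weights; the defaults
    encode the emulated study conditions (plasma-dmPFC lactate 0.314,
    dmPFC lactate-kEp 0.317, kEp-Ech beta 0.403).
    ``target_dmpfc_hpe`` records the -0.332 lactate-HPE correlation as
    a qualitative target: it is realized (attenuated) through the
    simulated-choice chain, never injected directly. Missingness rates
    mirror a 63-subject cohort with 1 plasma, 2 dmPFC/dACC and 18 aIns
    lactate values missing.
    """

    n_subjects: int = 63
    path_plasma_dmpfc: float = 0.314
    path_dmpfc_kep: float = 0.317
    path_kep_echbeta: float = 0.403
    target_dmpfc_hpe: float = -0.332
    path_plasma_ains: float = -0.091
    path_kep_echbeta_ains: float = 0.0
    kep_log_mu: float = math.log(0.8)
    kep_log_sd: float = 0.6
    kr_log_mu: float = 0.0
    kr_log_sd: float = 0.5
    kp_log_mu: float = 0.0
    kp_log_sd: float = 0.5
    kem_log_mu: float = math.log(0.5)
    kem_log_sd: float = 0.6
    kfp_log_mu: float = math.log(0.8)
    kfp_log_sd: float = 0.5
    klm_log_mu: float = math.log(0.3)
    klm_log_sd: float = 0.5
    kbias_sd: float = 0.3
    dt_params: DTParams = field(default_factory=DTParams)
    missing_rate_plasma: float = 1 / 63
    missing_rate_dmpfc: float = 2 / 63
    missing_rate_ains: float = 18 / 63
    task: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self) -> None:
        for name in ("path_plasma_dmpfc", "path_dmpfc_kep",
                     "path_kep_echbeta", "path_plasma_ains",
                     "path_kep_echbeta_ains"):
            if abs(getattr(self, name)) >= 1:
                raise CohortConfigError(
                    f"|{name}| must be < 1 for a standardized path")
        for name in ("missing_rate_plasma", "missing_rate_dmpfc",
                     "missing_rate_ains"):
            if not 0 <= getattr(self, name) <= 1:
                raise CohortConfigError(f"{name} outside [0, 1]")

    def configured_paths(self) -> dict[str, float]:
        """Directly configured standardized edges (each equals the
        population correlation of its variable pair)."""
        return {
            "plasma_lactate~dmpfc_lactate": self.path_plasma_dmpfc,
            "dmpfc_lactate~log_kEp": self.path_dmpfc_kep,
            "log_kEp~ech_beta_dmpfc": self.path_kep_echbeta,
            "plasma_lactate~ains_lactate": self.path_plasma_ains,
        }


@dataclass
class SubjectRecord:
    id: int
    plasma_lactate: float
    dmpfc_lactate: float
    ains_lactate: float
    ech_beta_dmpfc: float
    ech_beta_ains: float
    params: ModelParams
    prop_HE: float
    prop_HPE: float
    prop_HME: float
    choices: pd.DataFrame

    def row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("params", "choices")}
        d.update(self.params.to_dict())
        return d


def _chain_step(parent: np.ndarray, coef: float,
                rng: np.random.Generator) -> np.ndarray:
    return coef * parent + math.sqrt(1 - coef**2) * rng.normal(size=parent.shape)


def standardized_chain(n: int, coefficients: tuple[float, ...],
                       seed: int = 0,
                       names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Pure serial chain X1 -> X2 -> ... with given standardized edge
    coefficients and unit marginal variances (used for calibration
    studies of the mediation and path estimators)."""
    rng = np.random.default_rng(seed)
    cols = [rng.normal(size=n)]
    for c in coefficients:
        if abs(c) >= 1:
            raise CohortConfigError("|coefficient| must be < 1")
        cols.append(_chain_step(cols[-1], c, rng))
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(len(cols)))
    return pd.DataFrame(dict(zip(names, cols)))


def _session_arrays(session) -> dict:
    df = session_to_frame(session)
    return {
        "block_index": df["block_index"].to_numpy(),
        "trial_index": df["trial_index"].to_numpy(),
        "domain": df["domain"].to_numpy(),
        "valence": df["valence"].to_numpy(),
        "is_phys": (df["domain"] == PHYSICAL).to_numpy(),
        "is_reward": (df["valence"] == "reward").to_numpy(),
        "inc": df["he_incentive"].to_numpy(float),
        "eff": df["he_effort"].to_numpy(float),
        "block_sizes": df.groupby("block_index").size().to_numpy(),
    }


def simulate_session_fast(arr: dict, params: ModelParams,
                          rng: np.random.Generator,
                          dt_params: DTParams | None = None) -> pd.DataFrame:
    """Sequential session simulation on precomputed design arrays.

    Draws one uniform per trial from ``rng`` in trial order (the same
    stream consumption as :func:`effortpath.model.simulate_choices`
    without a DT model, so both paths produce identical choices for an
    identical generator state)."""
    n = len(arr["inc"])
    u = rng.random(n)
    kR, kP, kEp, kEm, kFp, kLm, kBias = params.to_array()
    is_phys, is_rew = arr["is_phys"], arr["is_reward"]
    inc, eff = arr["inc"], arr["eff"]
    block_index = arr["block_index"]
    dsv = np.empty(n)
    choice = np.empty(n, dtype=int)
    i = 0
    for n_blk in arr["block_sizes"]:
        F = 0.0
        L = 0.0
        eff_max = eff[i:i + n_blk].max()
        for t in range(i, i + n_blk):
            if is_phys[t]:
                cost = (kEp + kFp * F) * eff[t]
            else:
                cost = max(kEm - kLm * L, 0.0) * eff[t]
            d = kBias + (kR if is_rew[t] else kP) * inc[t] - cost
            p = 1.0 / (1.0 + math.exp(-d)) if abs(d) < 500 else (d > 0)
            c = 1 if u[t] < p else 0
            dsv[t] = d
            choice[t] = c
            if is_phys[t]:
                F += eff[t] * c / (eff_max * n_blk)
            else:
                L += 1.0 / n_blk
        i += n_blk
    ech = eff * choice
    p_he = 1.0 / (1.0 + np.exp(-np.clip(dsv, -500, 500)))
    dt = simulate_dt(dsv, dt_params, rng) if dt_params is not None \
        else np.full(n, np.nan)
    return pd.DataFrame({
        "block_index": block_index,
        "trial_index": arr["trial_index"],
        "domain": arr["domain"],
        "valence": arr["valence"],
        "he_incentive": inc.astype(int),
        "he_effort": eff.astype(int),
        "chosen": np.where(choice == 1, "HE", "LE"),
        "choice": choice,
        "p_he": p_he,
        "delta_sv": dsv,
        "Ech": ech.astype(int),
        "SVch": dsv * choice,
        "DT": dt,
        "missed": False,
    })


def generate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> list[SubjectRecord]:
    """Draw a cohort along the latent chain and simulate every
    subject's session.

    Chain order: plasma -> dmPFC lactate -> z(log kEp) -> Ech beta.
    Non-focal behavioral parameters are drawn independently
    (log-normal; Gaussian bias), encoding the specificity of the
    lactate link to physical-effort sensitivity. Missing lactate values
    are injected as NaN at the configured rates.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects

    z_plasma = rng.normal(size=n)
    z_dmpfc = _chain_step(z_plasma, cfg.path_plasma_dmpfc, rng)
    z_kep = _chain_step(z_dmpfc, cfg.path_dmpfc_kep, rng)
    ech_beta = _chain_step(z_kep, cfg.path_kep_echbeta, rng)
    z_ains = _chain_step(z_plasma, cfg.path_plasma_ains, rng)
    ech_beta_ains = _chain_step(z_kep, cfg.path_kep_echbeta_ains, rng)

    miss_plasma = rng.random(n) < cfg.missing_rate_plasma
    miss_dmpfc = rng.random(n) < cfg.missing_rate_dmpfc
    miss_ains = rng.random(n) < cfg.missing_rate_ains

    subjects = []
    for s in range(n):
        params = ModelParams(
            kR=float(np.exp(rng.normal(cfg.kr_log_mu, cfg.kr_log_sd))),
            kP=float(np.exp(rng.normal(cfg.kp_log_mu, cfg.kp_log_sd))),
            kEp=float(np.exp(cfg.kep_log_mu + cfg.kep_log_sd * z_kep[s])),
            kEm=float(np.exp(rng.normal(cfg.kem_log_mu, cfg.kem_log_sd))),
            kFp=float(np.exp(rng.normal(cfg.kfp_log_mu, cfg.kfp_log_sd))),
            kLm=float(np.exp(rng.normal(cfg.klm_log_mu, cfg.klm_log_sd))),
            kBias=float(rng.normal(0.0, cfg.kbias_sd)),
        )
        first = PHYSICAL if s % 2 == 0 else MENTAL
        session = generate_session(cfg.task, first_domain=first,
                                   seed=int(rng.integers(2**31 - 1)))
        choices = simulate_session_fast(_session_arrays(session), params,
                                        rng, cfg.dt_params)
        phys = choices["domain"] == PHYSICAL
        subjects.append(SubjectRecord(
            id=s,
            plasma_lactate=np.nan if miss_plasma[s] else float(z_plasma[s]),
            dmpfc_lactate=np.nan if miss_dmpfc[s] else float(z_dmpfc[s]),
            ains_lactate=np.nan if miss_ains[s] else float(z_ains[s]),
            ech_beta_dmpfc=float(ech_beta[s]),
            ech_beta_ains=float(ech_beta_ains[s]),
            params=params,
            prop_HE=float(choices["choice"].mean()),
            prop_HPE=float(choices.loc[phys, "choice"].mean()),
            prop_HME=float(choices.loc[~phys, "choice"].mean()),
            choices=choices,
        ))
    return subjects


def cohort_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject (without the per-trial tables)."""
    df = pd.DataFrame([s.row() for s in subjects])
    df["log_kEp"] = np.log(df["kEp"])
    return df
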