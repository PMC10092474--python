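"""Synthetic cohort generation with the statistical structure the validation
pipeline assumes.

Respondents carry a pair of correlated standard-normal latent traits
(depression theta, anxiety theta) built from observed covariates plus a
residual:

    theta = treatment offset + sex shift + age slope * z_age + residual,

standardized to unit variance, with the residual correlation solved so the
total trait correlation hits the configured value.  Ordinal 0-4 item
responses arise from a graded probit mechanism whose third cutpoint is tied
to the binary 2PL threshold tau = a*b/sqrt(1+a^2), so dichotomizing at
"Most days" reproduces the published endorsement rates by construction.
Impairment is a probit function of the trait; PHQ-9/GAD-7 comparator items
are generated from the same traits with their own loadings and cutpoints.

Default item parameters are the published IDQ/IAQ 2PL estimates; default
cutpoints are back-solved from the published response-category distributions;
covariate and impairment parameters are calibrated once against the published
summary statistics (group means, sex/age effects, ~7% caseness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import reference_resource
from .irt import ItemParams2PL, threshold_from_params

__all__ = [
    "SimulationConfig",
    "default_config",
    "default_cutpoints",
    "simulate_thetas",
    "simulate_graded",
    "simulate_impairment",
    "simulate_cohort",
]

TREATMENT_LEVELS = ("never", "past", "current", "waiting", "missing")

# Covariate structure calibrated to the published summary statistics:
# treatment-group score separation, female-male d of ~0.09 (IDQ) / 0.19
# (IAQ), age correlation ~ -0.33, and treatment-group shares (1313/402/170/50
# of 1935 plus ~6% missing).
_TRT_PROBS = (0.6380, 0.1953, 0.0826, 0.0243, 0.0598)
_TRT_OFFSETS_DEP = (-0.30, 0.28, 0.98, 1.00, 0.0)
_TRT_OFFSETS_ANX = (-0.33, 0.38, 1.00, 0.98, 0.0)
_SEX_SHIFT = (0.105, 0.225)      # female-minus-male theta shift (dep, anx)
_AGE_SLOPE = (-0.39, -0.38)      # theta change per SD of age
_P_FEMALE = 0.52
_AGE_MEAN, _AGE_SD = 46.5, 15.9

# Impairment probit P(yes | theta) = Phi(intercept + slope * theta),
# calibrated so diagnostic caseness lands near the published ~7%.
_IMPAIR_DEP = (-2.70, 2.00)
_IMPAIR_ANX = (-3.10, 2.00)

# Comparator scales: common loading and 0-3 cutpoints (standard-normal scale
# of the latent item response), calibrated to ~25% PHQ-9 and ~21% GAD-7
# caseness at the >= 10 cut-off with r ~ 0.9 against the matching scale.
_PHQ = {"a": 2.2, "cutpoints": (0.15, 0.88, 1.36), "n_items": 9}
_GAD = {"a": 2.2, "cutpoints": (0.03, 0.89, 1.42), "n_items": 7}


def _published_params(which: str) -> list[ItemParams2PL]:
    res = reference_resource()[which]["params_2pl"]
    return [ItemParams2PL(a, b, sa, sb)
            for a, b, sa, sb in zip(res["a"], res["b"], res["se_a"], res["se_b"])]


def default_cutpoints(which: str) -> np.ndarray:
    """Per-item graded cutpoints (4 per item, standard-normal scale of the
    latent item response), back-solved from the published response-category
    percentages with the third cutpoint tied to the binary 2PL threshold."""
    block = reference_resource()[which]
    pct = np.asarray(block["category_pct"], dtype=float) / 100.0
    params = block["params_2pl"]
    a = np.asarray(params["a"])
    b = np.asarray(params["b"])
    cum = np.cumsum(pct, axis=1)
    cuts = stats.norm.ppf(np.clip(cum[:, :4], 1e-6, 1 - 1e-6))
    cuts[:, 2] = threshold_from_params(a, b)   # endorsement boundary
    if not np.all(np.diff(cuts, axis=1) > 0):
        raise ValueError("back-solved cutpoints are not strictly increasing")
    return cuts


@dataclass
class SimulationConfig:
    """Everything that determines a synthetic cohort.  Identical configs
    (including seed) produce identical cohorts."""

    n_respondents: int = 2058
    seed: int = 20200323
    idq_params: list[ItemParams2PL] = field(default_factory=lambda: _published_params("idq"))
    iaq_params: list[ItemParams2PL] = field(default_factory=lambda: _published_params("iaq"))
    idq_cutpoints: np.ndarray = field(default_factory=lambda: default_cutpoints("idq"))
    iaq_cutpoints: np.ndarray = field(default_factory=lambda: default_cutpoints("iaq"))
    trait_correlation: float = 0.75
    impairment_dep: tuple[float, float] = _IMPAIR_DEP    # (intercept, slope)
    impairment_anx: tuple[float, float] = _IMPAIR_ANX
    treatment_probs: tuple = _TRT_PROBS
    treatment_offsets_dep: tuple = _TRT_OFFSETS_DEP
    treatment_offsets_anx: tuple = _TRT_OFFSETS_ANX
    sex_shift: tuple[float, float] = _SEX_SHIFT
    age_slope: tuple[float, float] = _AGE_SLOPE
    p_female: float = _P_FEMALE

    def validate(self) -> None:
        if not -1.0 < self.trait_correlation < 1.0:
            raise ValueError("trait_correlation must lie in (-1, 1)")
        if abs(sum(self.treatment_probs) - 1.0) > 1e-9:
            raise ValueError("treatment_probs must sum to 1")
        for cuts in (self.idq_cutpoints, self.iaq_cutpoints):
            if not np.all(np.diff(np.asarray(cuts), axis=1) > 0):
                raise ValueError("graded cutpoints must be strictly increasing per item")


def default_config(n_respondents: int = 2058, seed: int = 20200323) -> SimulationConfig:
    return SimulationConfig(n_respondents=n_respondents, seed=seed)


def _structural_moments(config: SimulationConfig):
    """Mean/variance of the covariate part of each trait and their shared
    covariance, used to standardize and to solve the residual correlation."""
    p = np.asarray(config.treatment_probs)
    out = []
    for offs, sex, age in zip(
        (config.treatment_offsets_dep, config.treatment_offsets_anx),
        config.sex_shift, config.age_slope,
    ):
        offs = np.asarray(offs)
        m_trt = float(p @ offs)
        v_trt = float(p @ (offs - m_trt) ** 2)
        v = v_trt + sex**2 * config.p_female * (1 - config.p_female) + age**2
        out.append((m_trt, v))
    offs_d = np.asarray(config.treatment_offsets_dep)
    offs_a = np.asarray(config.treatment_offsets_anx)
    cov = float(p @ ((offs_d - p @ offs_d) * (offs_a - p @ offs_a)))
    cov += config.sex_shift[0] * config.sex_shift[1] * config.p_female * (1 - config.p_female)
    cov += config.age_slope[0] * config.age_slope[1]
    return out[0], out[1], cov


def simulate_thetas(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Draw covariates and the bivariate latent traits.

    Returns a DataFrame with columns theta_dep, theta_anx, sex, age,
    treatment_status, z_age.  Both traits are standardized (mean ~0,
    variance ~1 in the population) with correlation ``trait_correlation``.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_respondents
    trt_idx = rng.choice(len(TREATMENT_LEVELS), size=n, p=config.treatment_probs)
    female = rng.random(n) < config.p_female
    z_age = rng.standard_normal(n)
    age = np.clip(np.round(_AGE_MEAN + _AGE_SD * z_age), 18, 90).astype(int)

    (m_d, v_d), (m_a, v_a), cov_struct = _structural_moments(config)
    s_d = np.sqrt(max(1.0 - v_d, 1e-6))
    s_a = np.sqrt(max(1.0 - v_a, 1e-6))
    rho_res = np.clip((config.trait_correlation - cov_struct) / (s_d * s_a),
                      -0.999, 0.999)
    resid = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho_res], [rho_res, 1.0]], size=n)

    def build(offsets, sex_shift, age_slope, m_struct, s_res, res_col):
        struct = (np.asarray(offsets)[trt_idx]
                  + sex_shift * female.astype(float)
                  + age_slope * z_age)
        return struct - (m_struct + sex_shift * config.p_female) + s_res * res_col

    theta_dep = build(config.treatment_offsets_dep, config.sex_shift[0],
                      config.age_slope[0], m_d, s_d, resid[:, 0])
    theta_anx = build(config.treatment_offsets_anx, config.sex_shift[1],
                      config.age_slope[1], m_a, s_a, resid[:, 1])
    return pd.DataFrame({
        "theta_dep": theta_dep,
        "theta_anx": theta_anx,
        "sex": np.where(female, "female", "male"),
        "age": age,
        "z_age": z_age,
        "treatment_status": np.asarray(TREATMENT_LEVELS)[trt_idx],
    })


def simulate_graded(
    thetas, params: Sequence[ItemParams2PL], cutpoints, rng: np.random.Generator
) -> np.ndarray:
    """Ordinal 0-4 responses from the graded probit mechanism.

    The latent item response (a*theta + e)/sqrt(1+a^2), e ~ N(0,1), is
    standard normal marginally; the category is its position among the four
    cutpoints.  Because the third cutpoint equals the binary threshold
    tau = ab/sqrt(1+a^2), dichotomizing at >= 3 recovers the 2PL model.
    """
    theta = np.asarray(thetas, dtype=float)
    cuts = np.asarray(cutpoints, dtype=float)
    if not np.all(np.diff(cuts, axis=1) > 0):
        raise ValueError("cutpoints must be strictly increasing per item")
    a = np.array([p.a for p in params])
    n, k = theta.size, a.size
    eps = rng.standard_normal((n, k))
    z = (a[None, :] * theta[:, None] + eps) / np.sqrt(1.0 + a**2)[None, :]
    out = np.zeros((n, k), dtype=int)
    for j in range(k):
        out[:, j] = np.searchsorted(cuts[j], z[:, j])
    return out


def simulate_impairment(
    thetas, impairment_model: tuple[float, float], rng: np.random.Generator,
    uniforms: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Yes/no impairment with P(yes | theta) = Phi(intercept + slope*theta).

    ``uniforms`` lets the caller supply the underlying uniform draws so that
    impairment answers for the two instruments share one propensity (a
    respondent who reports impairment on one scale tends to on the other).
    """
    intercept, slope = impairment_model
    p = stats.norm.cdf(intercept + slope * np.asarray(thetas, dtype=float))
    u = rng.random(p.size) if uniforms is None else np.asarray(uniforms)
    return u < p


def _simulate_comparator(theta, spec: dict, rng: np.random.Generator) -> np.ndarray:
    a = spec["a"]
    cuts = np.asarray(spec["cutpoints"])
    n, k = theta.size, spec["n_items"]
    eps = rng.standard_normal((n, k))
    z = (a * theta[:, None] + eps) / np.sqrt(1.0 + a**2)
    return np.searchsorted(cuts, z.ravel()).reshape(n, k)


def simulate_cohort(config: Optional[SimulationConfig] = None) -> pd.DataFrame:
    """Generate a full respondent-level cohort table.

    Columns: respondent_id, idq1..idq9, iaq1..iaq8, idq_impair, iaq_impair
    (yes/no), phq1..phq9, gad1..gad7, sex, age, treatment_status.
    """
    config = config or default_config()
    config.validate()
    if config.n_respondents < 10:
        raise ValueError("cohort of fewer than 10 respondents is degenerate")
    rng = np.random.default_rng(config.seed)
    lat = simulate_thetas(config, rng)
    idq = simulate_graded(lat["theta_dep"], config.idq_params,
                          config.idq_cutpoints, rng)
    iaq = simulate_graded(lat["theta_anx"], config.iaq_params,
                          config.iaq_cutpoints, rng)
    u_imp = rng.random(config.n_respondents)   # shared impairment propensity
    imp_d = simulate_impairment(lat["theta_dep"], config.impairment_dep, rng, u_imp)
    imp_a = simulate_impairment(lat["theta_anx"], config.impairment_anx, rng, u_imp)
    phq = _simulate_comparator(lat["theta_dep"].to_numpy(), _PHQ, rng)
    gad = _simulate_comparator(lat["theta_anx"].to_numpy(), _GAD, rng)

    df = pd.DataFrame({"respondent_id": np.arange(1, config.n_respondents + 1)})
    for j in range(idq.shape[1]):
        df[f"idq{j+1}"] = idq[:, j]
    for j in range(iaq.shape[1]):
        df[f"iaq{j+1}"] = iaq[:, j]
    df["idq_impair"] = np.where(imp_d, "yes", "no")
    df["iaq_impair"] = np.where(imp_a, "yes", "no")
    for j in range(phq.shape[1]):
        df[f"phq{j+1}"] = phq[:, j]
    for j in range(gad.shape[1]):
        df[f"gad{j+1}"] = gad[:, j]
    df["sex"] = lat["sex"].to_numpy()
    df["age"] = lat["age"].to_numpy()
    df["treatment_status"] = lat["treatment_status"].to_numpy()
    return df
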