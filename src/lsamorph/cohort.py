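"""Simulated cohorts for the perforating-artery morphometry statistics.

Generates per-subject tables whose marginals emulate a community-dwelling
elderly cohort (n = 125, age 59.9 +/- 7.1 truncated to 50-82, risk-factor
prevalences 40.8 / 15.2 / 14.4 / 28.8 %, median vessel count 8, median
vessel length 17.8 mm) with configurable, directionally controlled
effects:

* binary risk factors shift subject-level outcome summaries additively,
  by a standardized mean difference expressed in units of the outcome's
  noise SD;
* artery-diameter / outcome associations are induced through a Gaussian
  copula on ranks, so a target *Spearman* correlation is what comes out
  the other end (the latent Pearson correlation is ``2 sin(pi rho / 6)``).

Effects operate on per-subject summaries (median VL and friends), not on
individual vessels, because that is the level at which the cohort
statistics are run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

RISK_FACTORS = ("hypertension", "diabetes", "hyperlipidemia", "smoking")
ARTERIES = ("ica", "ba", "aca", "mca", "pca")
OUTCOMES = ("lsa_count", "median_vl", "mean_vl", "median_dm",
            "mean_dm", "median_vti", "mean_vti")

DEFAULT_PREVALENCES = {
    "hypertension": 0.408,
    "diabetes": 0.152,
    "hyperlipidemia": 0.144,
    "smoking": 0.288,
}

# (location, noise SD) for each outcome on the study's scale
_OUTCOME_MARGINALS = {
    "lsa_count": (8.0, 1.6),
    "median_vl": (17.8, 3.3),      # mm; SD ~ IQR(16.0, 20.5)/1.35
    "mean_vl": (18.2, 3.3),
    "median_dm": (1.18, 0.06),
    "mean_dm": (1.19, 0.06),
    "median_vti": (1.6, 0.5),
    "mean_vti": (1.8, 0.55),
}

# diameter marginals, mm
_DIAMETER_MARGINALS = {
    "ica": (4.0, 0.50),
    "ba": (3.2, 0.40),
    "aca": (2.1, 0.30),
    "mca": (2.8, 0.35),
    "pca": (2.1, 0.30),
}

# mean/median of the same metric move together in real subjects
_OUTCOME_PAIR_CORR = {
    ("median_vl", "mean_vl"): 0.9,
    ("median_dm", "mean_dm"): 0.9,
    ("median_vti", "mean_vti"): 0.9,
}


@dataclass(frozen=True)
class EffectConfig:
    """Knobs of the cohort generator.

    ``effect_sizes`` maps ``(risk_factor, outcome)`` to a standardized
    mean difference (in noise-SD units, sign = direction of the exposed
    group); ``diameter_correlations`` maps ``(artery, outcome)`` to a
    target Spearman correlation.  Empty dicts give a null cohort.
    """

    n_subjects: int = 125
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    effect_sizes: dict[tuple[str, str], float] = field(default_factory=dict)
    diameter_correlations: dict[tuple[str, str], float] = field(
        default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for k, p in self.prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {k!r} must be in [0,1]")
            if k not in RISK_FACTORS:
                raise ValueError(f"unknown risk factor {k!r}")
        for (factor, outcome) in self.effect_sizes:
            if factor not in RISK_FACTORS or outcome not in OUTCOMES:
                raise ValueError(f"unknown effect pair {(factor, outcome)!r}")
        for (artery, outcome), r in self.diameter_correlations.items():
            if artery not in ARTERIES or outcome not in OUTCOMES:
                raise ValueError(
                    f"unknown correlation pair {(artery, outcome)!r}")
            if not -1 < r < 1:
                raise ValueError("target correlations must be in (-1, 1)")


def study_effect_config(n_subjects: int = 125, seed: int = 0,
                        scale: float = 1.0) -> EffectConfig:
    """Config with effects in the directions observed in the study
    cohort: smokers have shorter/straighter vessels, hypertensives lower
    tortuosity, a wider MCA goes with more vessels but lower median
    tortuosity, and a wider PCA with longer, more tortuous vessels.

    Magnitudes are package defaults (moderate, ~0.5 SD, and the reported
    rank correlations), scaled by ``scale``.
    """
    return EffectConfig(
        n_subjects=n_subjects,
        seed=seed,
        effect_sizes={
            ("smoking", "median_vl"): -0.5 * scale,
            ("smoking", "median_dm"): -0.5 * scale,
            ("smoking", "median_vti"): -0.6 * scale,
            ("hypertension", "median_vti"): -0.45 * scale,
        },
        diameter_correlations={
            ("mca", "lsa_count"): 0.278 * scale,
            ("mca", "median_vti"): -0.252 * scale,
            ("pca", "median_dm"): 0.317 * scale,
            ("pca", "mean_vti"): 0.333 * scale,
            ("pca", "mean_vl"): 0.274 * scale,
            ("pca", "median_vl"): 0.306 * scale,
        },
    )


def _latent_correlation(config: EffectConfig) -> np.ndarray:
    """Correlation matrix of the copula latents (diameters + outcomes).

    Target Spearman correlations are converted to latent Pearson with
    ``2 sin(pi rho / 6)``.  Raises on an infeasible (non positive
    definite) combination instead of silently clipping.
    """
    names = list(ARTERIES) + list(OUTCOMES)
    k = len(names)
    corr = np.eye(k)

    def put(a: str, b: str, rho_s: float):
        r = 2 * np.sin(np.pi * rho_s / 6)
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = r

    for (a, b), rho in _OUTCOME_PAIR_CORR.items():
        put(a, b, rho)
    for (artery, outcome), rho in config.diameter_correlations.items():
        put(artery, outcome, rho)
    # mean/median siblings are tightly coupled, so a diameter that tracks
    # one must track the other too; fill the implied value unless the
    # config pins it explicitly, otherwise the matrix cannot be PD
    for (a, b), rho_pair in _OUTCOME_PAIR_CORR.items():
        for artery in ARTERIES:
            for src, dst in ((a, b), (b, a)):
                if (artery, src) in config.diameter_correlations and \
                        (artery, dst) not in config.diameter_correlations:
                    put(artery, dst,
                        config.diameter_correlations[(artery, src)] * rho_pair)
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < 1e-10:
        raise ValueError(
            f"infeasible correlation targets: latent correlation matrix is "
            f"not positive definite (min eigenvalue {eigmin:.3g})")
    return corr


def generate_cohort(config: EffectConfig | None = None) -> pd.DataFrame:
    """Simulate one cohort table; bit-reproducible from ``config.seed``."""
    config = config or EffectConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # demographics
    age = sps.truncnorm.rvs((50 - 59.9) / 7.1, (82 - 59.9) / 7.1,
                            loc=59.9, scale=7.1, size=n, random_state=rng)
    sex = rng.integers(0, 2, size=n)            # balanced binary, 1 = female
    education = np.clip(rng.normal(7.6, 4.0, n), 0, 22)
    icv = rng.normal(1450.0, 130.0, n)          # mL

    # risk factors
    factors = {f: (rng.random(n) < config.prevalences.get(f, 0.0)).astype(int)
               for f in RISK_FACTORS}

    # copula latents for diameters + outcome noise
    corr = _latent_correlation(config)
    z = rng.multivariate_normal(np.zeros(corr.shape[0]), corr, size=n,
                                method="cholesky")
    names = list(ARTERIES) + list(OUTCOMES)
    latent = {name: z[:, i] for i, name in enumerate(names)}

    data: dict[str, np.ndarray] = {
        "id": np.array([f"sub-{i + 1:03d}" for i in range(n)]),
        "age": age, "sex": sex, "education": education, "icv": icv,
    }
    data.update(factors)
    for artery, (mu, sd) in _DIAMETER_MARGINALS.items():
        data[f"{artery}_diameter_mm"] = mu + sd * latent[artery]

    for outcome, (mu, base_sd) in _OUTCOME_MARGINALS.items():
        sd = config.noise_sd.get(outcome, base_sd)
        values = mu + sd * latent[outcome]
        for factor in RISK_FACTORS:
            d = config.effect_sizes.get((factor, outcome), 0.0)
            if d:
                values = values + d * sd * factors[factor]
        if outcome == "lsa_count":
            values = np.clip(np.rint(values), 3, 14).astype(int)
        elif outcome.endswith("vti"):
            values = np.maximum(values, 0.0)
        data[outcome] = values

    # within-subject vessel spread, strictly positive
    data["sd_vl"] = np.abs(rng.normal(2.5, 0.6, n))
    data["sd_dm"] = np.abs(rng.normal(0.08, 0.02, n))
    data["sd_vti"] = np.abs(rng.normal(0.5, 0.15, n))

    # small-vessel-disease markers (mild burden)
    data["wmh_volume_ml"] = np.exp(rng.normal(np.log(1.5), 0.93, n))
    data["pvs_bg_score"] = np.clip(rng.poisson(1.1, n), 0, 4)
    data["pvs_dwm_score"] = np.clip(rng.poisson(1.3, n), 0, 4)
    data["lacune_count"] = rng.poisson(0.05, n)
    data["microbleed_count"] = rng.poisson(0.1, n)

    return pd.DataFrame(data)
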