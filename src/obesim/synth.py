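"""Seeded generators for synthetic country tables and population fixtures.

The country generator draws log-scale covariates (LMDR, GDP, calories,
physical inactivity, antibiotic use) from a multivariate normal with a
target correlation matrix, exponentiates to natural units, plants a
log-linear obesity response with a negative LMDR coefficient, derives MMR
from LMDR via a fertility divisor, and applies per-column missingness.
Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polygenic import GeneticArchitecture

COVARIATES = ("lmdr", "gdp", "calories", "inactivity", "antibiotics")

# log-scale correlation targets among (lmdr, gdp, calories, inactivity,
# antibiotics); LMDR anticorrelates with everything, the development
# covariates correlate positively with one another.
DEFAULT_CORRELATION = np.array(
    [
        [1.00, -0.84, -0.69, -0.45, -0.75],
        [-0.84, 1.00, 0.70, 0.52, 0.67],
        [-0.69, 0.70, 1.00, 0.37, 0.50],
        [-0.45, 0.52, 0.37, 1.00, 0.32],
        [-0.75, 0.67, 0.50, 0.32, 1.00],
    ]
)

# log-scale means/sds giving LMDR in % spanning roughly <0.01 to 15 with a
# right-skewed natural-unit distribution, GDP in $/capita, calories kcal/day,
# inactivity % adults, antibiotics on an arbitrary dose scale.
DEFAULT_LOG_MEANS = {"lmdr": -0.73, "gdp": 9.2, "calories": 7.9, "inactivity": 3.2, "antibiotics": 2.7}
DEFAULT_LOG_SDS = {"lmdr": 1.5, "gdp": 1.2, "calories": 0.15, "inactivity": 0.45, "antibiotics": 0.5}


@dataclass(frozen=True)
class CountryGenSpec:
    """Recipe for a synthetic country table.

    ``obesity_coefficients`` are (intercept, lmdr_beta, calories_beta,
    inactivity_beta) applied to log-scale covariates to produce log obesity
    (% adults); ``lmdr_beta`` must be negative to plant the inverse
    LMDR-obesity dependence the pipeline is meant to recover.
    """

    n_countries: int = 190
    log_lmdr_mean: float = DEFAULT_LOG_MEANS["lmdr"]
    log_lmdr_sd: float = DEFAULT_LOG_SDS["lmdr"]
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    obesity_intercept: float = -4.3
    lmdr_beta: float = -0.20
    calories_beta: float = 0.80
    inactivity_beta: float = 0.25
    noise_sd: float = 0.35
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (len(COVARIATES),) * 2:
            raise ValueError(f"correlation must be {len(COVARIATES)}x{len(COVARIATES)}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation target must be symmetric")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            nearest = _nearest_psd(corr)
            raise ValueError(
                "correlation target is not positive semidefinite "
                f"(min eigenvalue {eigvals.min():.4g}); nearest PSD candidate:\n{nearest}"
            )


def _nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped PSD projection, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(matrix)
    fixed = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _development_classes(gdp: np.ndarray) -> np.ndarray:
    """Assign classes by GDP quantile (top quartile developed, poorest tiers
    below)."""
    q = pd.Series(gdp).rank(pct=True).to_numpy()
    classes = np.full(len(gdp), "developing", dtype=object)
    classes[q <= 0.15] = "least_developed"
    classes[(q > 0.15) & (q <= 0.30)] = "low_income"
    classes[(q > 0.30) & (q <= 0.50)] = "low_middle_income"
    classes[q > 0.75] = "developed"
    return classes


def generate_countries(spec: CountryGenSpec) -> pd.DataFrame:
    """Draw a synthetic country table matching the analysis pipeline's schema.

    Columns follow :data:`obesim.stats.ALL_COLUMNS`; LMDR and obesity are in
    percent, MMR in deaths per 100,000 live births, neonatal mortality per
    1,000 live births. Identical seeds give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_countries

    means = np.array([spec.log_lmdr_mean] + [DEFAULT_LOG_MEANS[c] for c in COVARIATES[1:]])
    sds = np.array([spec.log_lmdr_sd] + [DEFAULT_LOG_SDS[c] for c in COVARIATES[1:]])
    corr = np.asarray(spec.correlation, dtype=float)
    cov = corr * np.outer(sds, sds)
    logs = rng.multivariate_normal(means, cov, size=n, method="cholesky")
    log_lmdr, log_gdp, log_cal, log_inact, log_abx = logs.T

    log_obesity = (
        spec.obesity_intercept
        + spec.lmdr_beta * log_lmdr
        + spec.calories_beta * log_cal
        + spec.inactivity_beta * log_inact
        + rng.normal(0.0, spec.noise_sd, size=n)
    )
    obesity_2016 = np.exp(log_obesity)
    # earlier obesity: strongly rank-correlated, roughly half the level
    obesity_1990 = obesity_2016 * 0.5 * np.exp(rng.normal(0.0, 0.10, size=n))

    # LMDR (lifetime, %) = per-birth MMR x births per woman; higher-LMDR
    # nations get higher fertility, so MMR per 100,000 = LMDR / fertility.
    z_lmdr = (log_lmdr - np.mean(log_lmdr)) / (np.std(log_lmdr) or 1.0)
    fertility = np.clip(4.5 + 1.0 * z_lmdr + rng.normal(0.0, 0.3, size=n), 1.5, 8.5)
    lmdr_pct = np.exp(log_lmdr)
    mmr = (lmdr_pct / 100.0) / fertility * 100_000.0

    # neonatal deaths per 1,000, tightly coupled to LMDR on the log scale
    log_neo = 2.99 + 0.41 * log_lmdr + rng.normal(0.0, 0.25, size=n)
    neonatal = np.exp(log_neo)

    table = pd.DataFrame(
        {
            "nation": [f"country_{i:03d}" for i in range(n)],
            "lmdr_1990": lmdr_pct,
            "mmr_1990": mmr,
            "neonatal_mortality_1990": neonatal,
            "obesity_1990": obesity_1990,
            "obesity_2016": obesity_2016,
            "gdp_per_capita": np.exp(log_gdp),
            "calorie_intake": np.exp(log_cal),
            "insufficient_physical_activity": np.clip(np.exp(log_inact), None, 100.0),
            "antibiotic_consumption": np.exp(log_abx),
            "development_class": _development_classes(np.exp(log_gdp)),
        }
    )
    if spec.missing_rate > 0:
        numeric = table.columns.drop(["nation", "development_class"])
        mask = rng.random((n, len(numeric))) < spec.missing_rate
        for j, col in enumerate(numeric):
            table.loc[mask[:, j], col] = np.nan
    table.attrs["gen_spec"] = {
        "n_countries": n,
        "seed": spec.seed,
        "lmdr_beta": spec.lmdr_beta,
        "noise_sd": spec.noise_sd,
        "missing_rate": spec.missing_rate,
    }
    return table


def generate_contingency_fixture(
    n_low: int, n_high: int, p_low: float, p_high: float, seed: int = 0
) -> np.ndarray:
    """Binomial 2x2 fixture: per-row counts of high-obesity nations.

    Row 0 is the low-MMR stratum (``n_low`` nations, each high-obesity with
    probability ``p_low``), row 1 the high-MMR stratum.
    """
    for p in (p_low, p_high):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k_low = int(rng.binomial(n_low, p_low))
    k_high = int(rng.binomial(n_high, p_high))
    return np.array([[k_low, n_low - k_low], [k_high, n_high - k_high]])


def generate_population(
    arch: GeneticArchitecture, freq: float, n_individuals: int, seed: int = 0
):
    """Sample genotypes and phenotypes at a pooled allele frequency.

    Returns ``(genotypes, phenotypes)``: an (n, slots) 0/1 matrix of allele
    draws (two slots per locus under diploid accounting) and phenotypes equal
    to the additive score plus normal environmental noise.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must be in [0, 1]")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    slots = arch.ploidy_factor * arch.n_loci
    genotypes = (rng.random((n_individuals, slots)) < freq).astype(np.uint8)
    counts = genotypes.sum(axis=1)
    phenotypes = (
        arch.baseline_bmi
        + arch.effect_per_allele * (counts - slots * arch.reference_freq)
        + rng.normal(0.0, arch.env_sd, size=n_individuals)
    )
    return genotypes, phenotypes
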