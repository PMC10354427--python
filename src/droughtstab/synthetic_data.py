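"""In-silico drought-stability study with known ground truth.

Generates every input the pipeline needs — a SNP dosage panel, its genomic
relationship matrix, per-genotype NDVI trajectories from a Legendre
random-coefficient model, and multi-environment fresh weights with a
Finlay-Wilkinson-type genotype sensitivity — so that trajectory modelling,
stability indexing and genomic prediction can all be validated against the
latent values that produced the data.

Generative model
----------------
* Markers: independent biallelic loci; allele frequency per marker uniform in
  ``maf_range``; dosages binomial(2, p) (Hardy-Weinberg, no LD).
* Latents: per genotype, the trajectory coefficients (u_0..u_nr) and a
  drought-sensitivity latent s are drawn jointly from MVN(0, K kron G) with
  G the marker-derived kinship and K assembled from ``q_true``, unit
  sensitivity variance, and cov(u_1, s) set so that
  corr(u_1, s) = ``rg_coeff_stability``.
* NDVI: y_it = b_t + sum_k phi_k(t) u_ik + e_it, e ~ N(0, resid_var_vi), with
  b_t a declining canopy curve.
* Fresh weight: w_ie = env_means[e] + g_ie + eps_ie, g_ie = m_i + s_i d_e,
  where m is a kinship-structured genotype main effect and d_e are environment
  deviations. The deviation grid is equally spaced and skewed toward drought
  (default span [-1.5, 0] x ``env_dev_scale``): per-environment min-max
  normalization removes all environment main effects, so only an asymmetric
  stress profile lets the sensitivity latent leave a linear (recoverable)
  signature in the CV stability index. eps is scaled per environment so the
  realized heritability matches ``env_h2``; weights are truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from droughtstab.genomics import GenotypeMatrix, RelationshipMatrix, compute_grm, write_dosage_csv
from droughtstab.spectral import TimeSeriesTrait
from droughtstab.stability import EnvironmentTable
from droughtstab.rrm import legendre_basis

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "simulate_genotypes",
    "simulate_study",
    "simulate_year_pair",
    "write_study",
]


@dataclass
class SyntheticConfig:
    """Study-design parameters with defaults mirroring a 178-accession drought trial.

    ``q_true`` is the coefficient covariance on the NDVI scale (order 1 by
    default: intercept sd 0.1, slope sd ~0.06); ``env_h2`` is the
    per-environment narrow-sense heritability of fresh weight;
    ``rg_coeff_stability`` is the latent genetic correlation between the
    linear trajectory coefficient u_1 and the drought-sensitivity latent.
    """

    n_genotypes: int = 178
    n_markers: int = 2_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_timepoints: int = 7
    n_environments: int = 9
    q_true: np.ndarray = field(default_factory=lambda: np.array([[0.010, 0.003], [0.003, 0.004]]))
    resid_var_vi: float = 0.005
    env_means: np.ndarray | None = None  # grams; default linspace(320, 130, E)
    env_h2: float | np.ndarray = 0.4
    rg_coeff_stability: float = -0.4
    seed: int = 0
    # weight-model shape parameters (grams)
    var_main: float = 64.0
    var_sens: float = 1.0
    env_dev_scale: float = 30.0
    env_dev_span: tuple[float, float] = (-1.5, 0.0)
    timepoints: np.ndarray | None = None  # DAS; default 7 dates in [35, 65]
    treatment: str = "W10"
    year: str = "2021"

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        self.q_true = np.asarray(self.q_true, dtype=float)
        if not np.allclose(self.q_true, self.q_true.T):
            raise ValueError("q_true must be symmetric")
        if np.linalg.eigvalsh(self.q_true).min() < -1e-10:
            raise ValueError("q_true must be positive semidefinite")
        h2 = np.broadcast_to(np.asarray(self.env_h2, dtype=float), (self.n_environments,))
        if np.any((h2 < 0) | (h2 > 1)):
            raise ValueError("env_h2 entries must be in [0, 1]")
        if not -1.0 <= self.rg_coeff_stability <= 1.0:
            raise ValueError("rg_coeff_stability must be in [-1, 1]")

    @property
    def order(self) -> int:
        return self.q_true.shape[0] - 1

    def resolved_env_means(self) -> np.ndarray:
        if self.env_means is not None:
            return np.asarray(self.env_means, dtype=float)
        return np.linspace(320.0, 130.0, self.n_environments)

    def resolved_env_h2(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.env_h2, dtype=float), (self.n_environments,)).copy()

    def resolved_timepoints(self) -> np.ndarray:
        if self.timepoints is not None:
            return np.asarray(self.timepoints, dtype=float)
        return np.round(np.linspace(35.0, 65.0, self.n_timepoints))

    def env_deviations(self) -> np.ndarray:
        lo, hi = self.env_dev_span
        return np.linspace(lo, hi, self.n_environments) * self.env_dev_scale


@dataclass
class SyntheticStudy:
    """One treatment-year's data bundle plus the latent truth that generated it."""

    genotypes: GenotypeMatrix
    kinship: RelationshipMatrix
    vi_series: TimeSeriesTrait
    weights: EnvironmentTable
    truth: dict

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.genotypes.genotype_ids)


def simulate_genotypes(
    n: int, m: int, maf_range: tuple[float, float], seed: int, return_freqs: bool = False
):
    """Independent Hardy-Weinberg markers: dosage ~ Binomial(2, p), p ~ U(maf_range).

    With ``return_freqs`` the drawn per-marker allele frequencies are returned
    alongside the matrix (useful for calibration checks).
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    ids = [f"G{i:04d}" for i in range(n)]
    markers = [(f"chr{j % 20 + 1}", 1_000 + 100 * j) for j in range(m)]
    geno = GenotypeMatrix(dosages=dosages, genotype_ids=ids, markers=markers)
    return (geno, p) if return_freqs else geno


def _kinship_sqrt(G: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(G)
    return V * np.sqrt(np.clip(w, 0.0, None))


def _latent_covariance(config: SyntheticConfig) -> np.ndarray:
    """K for (u_0..u_nr, s): q_true block, unit var(s), cov(u_1, s) from rg."""
    k = config.order + 1
    K = np.zeros((k + 1, k + 1))
    K[:k, :k] = config.q_true
    K[k, k] = config.var_sens
    if k >= 2:
        c = config.rg_coeff_stability * np.sqrt(config.q_true[1, 1] * config.var_sens)
        K[1, k] = K[k, 1] = c
    else:
        c = config.rg_coeff_stability * np.sqrt(config.q_true[0, 0] * config.var_sens)
        K[0, k] = K[k, 0] = c
    if np.linalg.eigvalsh(K).min() < -1e-10:
        raise ValueError("latent covariance (q_true with rg_coeff_stability) is not PSD")
    return K


def _draw_matrix_normal(rng: np.random.Generator, Lg: np.ndarray, K: np.ndarray) -> np.ndarray:
    """One draw of an N x k matrix with vec-covariance K kron G, G = Lg Lg'."""
    w, V = np.linalg.eigh(K)
    Lk = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((Lg.shape[1], K.shape[0]))
    return Lg @ Z @ Lk.T


def _simulate_vi(rng: np.random.Generator, config: SyntheticConfig, U: np.ndarray,
                 ids: list[str], das: np.ndarray, treatment: str, year: str) -> TimeSeriesTrait:
    basis = legendre_basis(das, config.order)
    x01 = (basis.standardized_times + 1.0) / 2.0
    b = 0.80 - 0.20 * x01 - 0.10 * x01**2  # canopy NDVI declining under stress
    Y = b[None, :] + U @ basis.phi.T + rng.normal(0.0, np.sqrt(config.resid_var_vi), (len(ids), len(das)))
    return TimeSeriesTrait(values=pd.DataFrame(Y, index=ids, columns=range(len(das))),
                           timepoints=das, treatment=treatment, year=year)


def _simulate_weights(rng: np.random.Generator, config: SyntheticConfig,
                      m_eff: np.ndarray, s: np.ndarray, ids: list[str]) -> tuple[EnvironmentTable, np.ndarray]:
    delta = config.env_deviations()
    means = config.resolved_env_means()
    h2 = config.resolved_env_h2()
    g = m_eff[:, None] + s[:, None] * delta[None, :]
    W = np.empty_like(g)
    for e in range(config.n_environments):
        vg = float(np.var(g[:, e]))
        if h2[e] >= 1.0 or vg == 0.0:
            eps = np.zeros(len(ids))
        else:
            ve = vg * (1.0 - h2[e]) / max(h2[e], 1e-12) if h2[e] > 0 else 1.0
            eps = rng.normal(0.0, np.sqrt(ve), len(ids))
        W[:, e] = means[e] + g[:, e] + eps
    W = np.clip(W, 0.0, None)
    cols = [f"env{e + 1}" for e in range(config.n_environments)]
    return EnvironmentTable(values=pd.DataFrame(W, index=ids, columns=cols)), g


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full single treatment-year study with its truth record.

    The truth record holds the marker allele frequencies, the latent
    coefficient matrix ``u_true`` (columns L0..Lnr), the sensitivity latent
    ``s_true``, the weight-model main effect ``m_true``, the genetic value of
    fresh weight per environment ``g_true`` and the environment deviations —
    everything needed to score recovery downstream without refitting.
    """
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config.n_genotypes, config.n_markers, config.maf_range,
                              seed=int(rng.integers(2**31 - 1)))
    kin = compute_grm(geno)
    ids = geno.genotype_ids
    Lg = _kinship_sqrt(kin.values)

    K = _latent_covariance(config)
    lat = _draw_matrix_normal(rng, Lg, K)
    U, s = lat[:, : config.order + 1], lat[:, -1]
    m_eff = Lg @ rng.standard_normal(Lg.shape[1]) * np.sqrt(config.var_main)

    das = config.resolved_timepoints()
    vi = _simulate_vi(rng, config, U, ids, das, config.treatment, config.year)
    weights, g = _simulate_weights(rng, config, m_eff, s, ids)

    truth = {
        "config": config,
        "q_true": config.q_true.copy(),
        "u_true": pd.DataFrame(U, index=ids, columns=[f"L{k}" for k in range(config.order + 1)]),
        "s_true": pd.Series(s, index=ids, name="sensitivity"),
        "m_true": pd.Series(m_eff, index=ids, name="main_effect"),
        "g_true": pd.DataFrame(g, index=ids, columns=weights.environment_ids),
        "env_deviations": config.env_deviations(),
    }
    return SyntheticStudy(genotypes=geno, kinship=kin, vi_series=vi, weights=weights, truth=truth)


def simulate_year_pair(
    config: SyntheticConfig,
    r_years: float = 0.8,
    timepoints_b: np.ndarray | None = None,
    year_b: str | None = None,
) -> tuple[SyntheticStudy, SyntheticStudy]:
    """Two years of the same trial sharing genotypes, kinship and fresh weights.

    Year-specific coefficient latents are correlated ``r_years`` across years
    (same coefficient, different year) and both years' u_1 keep the configured
    correlation with the shared sensitivity latent. Year B gets its own
    measurement dates (default: drop the first timepoint and shift late dates
    by a day, mimicking year-to-year flight scheduling) so that only a subset
    of dates align across years.
    """
    if not -1.0 <= r_years <= 1.0:
        raise ValueError("r_years must be in [-1, 1]")
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config.n_genotypes, config.n_markers, config.maf_range,
                              seed=int(rng.integers(2**31 - 1)))
    kin = compute_grm(geno)
    ids = geno.genotype_ids
    Lg = _kinship_sqrt(kin.values)

    k = config.order + 1
    Kw = _latent_covariance(config)  # (k+1) x (k+1): within-year block + s
    K = np.zeros((2 * k + 1, 2 * k + 1))
    K[:k, :k] = config.q_true
    K[k: 2 * k, k: 2 * k] = config.q_true
    K[:k, k: 2 * k] = r_years * config.q_true
    K[k: 2 * k, :k] = r_years * config.q_true
    K[-1, -1] = config.var_sens
    c = Kw[min(1, k - 1), -1]
    K[min(1, k - 1), -1] = K[-1, min(1, k - 1)] = c
    K[k + min(1, k - 1), -1] = K[-1, k + min(1, k - 1)] = c
    if np.linalg.eigvalsh(K).min() < -1e-10:
        raise ValueError("cross-year latent covariance is not PSD; lower |r_years| or |rg|")

    lat = _draw_matrix_normal(rng, Lg, K)
    Ua, Ub, s = lat[:, :k], lat[:, k: 2 * k], lat[:, -1]
    m_eff = Lg @ rng.standard_normal(Lg.shape[1]) * np.sqrt(config.var_main)

    das_a = config.resolved_timepoints()
    if timepoints_b is None:
        das_b = das_a[1:].copy()
        das_b[-2:] += 1.0  # later flights drift by a day across years
    else:
        das_b = np.asarray(timepoints_b, dtype=float)

    vi_a = _simulate_vi(rng, config, Ua, ids, das_a, config.treatment, config.year)
    vi_b = _simulate_vi(rng, config, Ub, ids, das_b, config.treatment,
                        year_b or str(int(config.year) - 1 if config.year.isdigit() else "yearB"))
    weights, g = _simulate_weights(rng, config, m_eff, s, ids)

    def truth(U: np.ndarray) -> dict:
        return {
            "config": config,
            "q_true": config.q_true.copy(),
            "u_true": pd.DataFrame(U, index=ids, columns=[f"L{j}" for j in range(k)]),
            "s_true": pd.Series(s, index=ids, name="sensitivity"),
            "m_true": pd.Series(m_eff, index=ids, name="main_effect"),
            "g_true": pd.DataFrame(g, index=ids, columns=weights.environment_ids),
            "env_deviations": config.env_deviations(),
            "r_years": r_years,
        }

    study_a = SyntheticStudy(genotypes=geno, kinship=kin, vi_series=vi_a, weights=weights, truth=truth(Ua))
    study_b = SyntheticStudy(genotypes=geno, kinship=kin, vi_series=vi_b, weights=weights, truth=truth(Ub))
    return study_a, study_b


def write_study(study: SyntheticStudy, directory: str | Path) -> None:
    """Write the study as the pipeline's plain-text exchange formats.

    Genotypes as dosage CSV, kinship as a labelled CSV matrix, NDVI series and
    fresh weights as long CSVs, and the truth latents as a separate CSV that
    the pipeline itself never reads.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_dosage_csv(study.genotypes, directory / "genotypes.csv")
    study.kinship.to_frame().to_csv(directory / "kinship.csv", index_label="genotype")
    study.vi_series.to_long().to_csv(directory / "vi_series.csv", index=False)
    study.weights.to_long().to_csv(directory / "weights.csv", index=False)
    truth = pd.concat(
        [study.truth["u_true"], study.truth["s_true"], study.truth["m_true"]], axis=1
    )
    truth.to_csv(directory / "truth.csv", index_label="genotype")
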