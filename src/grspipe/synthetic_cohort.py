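"""Simulated case-control cohorts with LD, polygenic liability and severity.

The generator produces everything the downstream GWAS -> clumping -> scoring ->
evaluation stages need, with known ground truth:

* **Genotypes.**  Haplotypes follow a first-order copying chain: the allele at
  SNP *j* copies the allele at SNP *j-1* with probability ``ld_rho`` and is
  otherwise drawn fresh at a base frequency ``u_j ~ Uniform(maf_range)``.  The
  stationary marginal frequency ``m_j`` follows the recursion
  ``m_j = rho * m_{j-1} + (1 - rho) * u_j`` and the allelic covariance decays
  geometrically, ``Cov(X_a, X_b) = rho^(b-a) * m_a (1 - m_a)`` — a minimal LD
  model with a single knob controlling clumping difficulty.

* **Disease.**  A liability-threshold model: ``n_causal`` SNPs receive normal
  effects rescaled so the genetic value ``G`` has variance exactly ``h2_liab``
  (the rescaling accounts for causal-causal LD covariance); liability
  ``L = G + e`` with ``Var(e) = 1 - h2_liab``; a sample is a case when ``L``
  exceeds the quantile set by ``prevalence``.

* **Severity and onset** (cases only).  Renal involvement is Bernoulli with
  logit ``sev_intercept + sev_slope * G_std``; age of onset is
  ``onset_mean + onset_slope * G_std + Normal(0, onset_sd)`` floored at one
  year, where ``G_std = G / sd(G)`` is the standardized genetic value.

* **Second ancestry.**  Balding-Nichols drift of the base allele frequencies
  with parameter ``fst``, sharing variant identities and causal effects with
  the ancestral population.

Case-control cohorts at low prevalence are drawn by an exact two-pass scheme:
liability is screened on the causal columns of the haplotype chain (cheap),
and the non-causal columns of retained samples are then filled in from the
exact conditional (bridge) distribution of the chain given the causal alleles.
This is equivalent in law to simulating whole individuals until the case and
control quotas are met, which is what it replaces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ConfigError
from .geno_io import GenotypeDataset

#: Fixed inter-SNP spacing of the simulated map (bp); 20k SNPs span ~100 Mb.
SPACING_BP: int = 5000

# Non-ambiguous allele pairs only, so that cross-dataset harmonization (which
# drops A/T and C/G SNPs) never loses simulated variants.
_ALLELE_PAIRS = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                          ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")])

# Stage labels for seed derivation: every source of randomness hangs off the
# master seed through a distinct, fixed stream.
_STAGE_VARIANTS = 11
_STAGE_EFFECTS = 12
_STAGE_HAPLOTYPES = 13
_STAGE_NOISE = 14
_STAGE_SEVERITY = 15
_STAGE_ONSET = 16
_STAGE_DRIFT = 17


def _rng(seed: int, stage: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stage, extra)))


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of a simulated cohort.

    ``sev_slope`` and ``onset_slope`` are per standard deviation of the
    genetic value; a negative ``onset_slope`` makes high-load patients present
    earlier.  ``fst`` > 0 drifts this cohort's allele frequencies away from
    the ancestral population (variant identities and causal effects are kept,
    so cross-ancestry training/testing is meaningful).
    """

    n_samples: int = 1000
    n_snps: int = 1000
    n_causal: int = 100
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.6
    h2_liab: float = 0.3
    prevalence: float = 0.01
    sev_intercept: float = -0.4
    sev_slope: float = 0.5
    onset_mean: float = 33.0
    onset_slope: float = -2.0
    onset_sd: float = 10.0
    fst: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ConfigError("n_samples must be >= 0")
        if self.n_snps < 0:
            raise ConfigError("n_snps must be >= 0")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ConfigError("n_causal must lie in [0, n_snps]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError("ld_rho must lie in [0, 1)")
        if not 0 <= self.h2_liab <= 1:
            raise ConfigError("h2_liab must lie in [0, 1]")
        if not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must lie in (0, 1)")
        if self.onset_sd < 0:
            raise ConfigError("onset_sd must be >= 0")
        if not 0 <= self.fst < 1:
            raise ConfigError("fst must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth retained for parameter-recovery tests.

    Per-sample arrays (``genetic_value``, ``liability``, ``case``, ``renal``,
    ``onset``) align with the dataset rows; ``renal``/``onset`` are NaN for
    controls.  Per-SNP arrays hold the true effects and the population
    (marginal) frequency of allele1.
    """

    config: SimConfig
    beta_true: np.ndarray
    freq_ancestral: np.ndarray
    genetic_value: Optional[np.ndarray] = None
    liability: Optional[np.ndarray] = None
    case: Optional[np.ndarray] = None
    renal: Optional[np.ndarray] = None
    onset: Optional[np.ndarray] = None
    n_population_simulated: Optional[int] = None

    def to_phenotype_frame(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Phenotype table (IID, STATUS, RENAL, ONSET, SEX, POP) for geno_io."""
        pop = "DRIFTED" if self.config.fst > 0 else "ANCESTRAL"
        return pd.DataFrame({
            "IID": samples["iid"].to_numpy(),
            "STATUS": self.case.astype(int),
            "RENAL": self.renal,
            "ONSET": self.onset,
            "SEX": samples["sex"].to_numpy(),
            "POP": pop,
        })


# ---------------------------------------------------------------------------
# Variant model: frequencies, LD chain, alleles, causal effects
# ---------------------------------------------------------------------------

class _VariantModel:
    """Per-SNP quantities shared by every cohort drawn from one SimConfig seed.

    ``u``: base (refresh) frequencies of the copying chain; ``m``: stationary
    marginal frequencies; ``t1``/``t0``: chain transition probabilities
    P(X_j=1 | X_{j-1}=1) and P(X_j=1 | X_{j-1}=0).
    """

    def __init__(self, config: SimConfig):
        self.config = config
        m_snps = config.n_snps
        rng_v = _rng(config.seed, _STAGE_VARIANTS)
        lo, hi = config.maf_range
        u = rng_v.uniform(lo, hi, size=m_snps)
        pair_idx = rng_v.integers(0, len(_ALLELE_PAIRS), size=m_snps)

        if config.fst > 0 and m_snps:
            u = drift_population(u, config.fst, seed=(config.seed, _STAGE_DRIFT))

        rho = config.ld_rho
        m = np.empty(m_snps)
        if m_snps:
            m[0] = u[0]
            for j in range(1, m_snps):
                m[j] = rho * m[j - 1] + (1 - rho) * u[j]
        self.u = u
        self.m = m
        self.t1 = rho + (1 - rho) * u      # P(1|1); entry j governs j-1 -> j
        self.t0 = (1 - rho) * u            # P(1|0)
        self.rho = rho
        self.alleles = _ALLELE_PAIRS[pair_idx] if m_snps else np.empty((0, 2), dtype=str)
        self.positions = (np.arange(m_snps) + 1) * SPACING_BP

        rng_e = _rng(config.seed, _STAGE_EFFECTS)
        beta = np.zeros(m_snps)
        causal = np.sort(rng_e.choice(m_snps, size=config.n_causal, replace=False)) \
            if config.n_causal else np.array([], dtype=int)
        if config.n_causal and config.h2_liab > 0:
            raw = np.zeros(m_snps)
            raw[causal] = rng_e.standard_normal(config.n_causal)
            var_g = self._genetic_variance(raw)
            if var_g > 0:
                beta = raw * np.sqrt(config.h2_liab / var_g)
        self.beta = beta
        self.causal = causal

    def _genetic_variance(self, beta: np.ndarray) -> float:
        """Exact Var(sum_j beta_j g_j) under the chain covariance.

        Var(g_j) = 2 m_j (1-m_j); Cov(X_a, X_b) = rho^(b-a) m_a (1-m_a).
        The cross-term series is truncated where rho^gap < 1e-10.
        """
        v = self.m * (1.0 - self.m)
        total = 2.0 * float(np.sum(beta ** 2 * v))
        if self.rho > 0:
            max_gap = int(np.ceil(np.log(1e-10) / np.log(self.rho)))
            for g in range(1, min(max_gap, len(beta) - 1) + 1):
                total += 4.0 * (self.rho ** g) * float(
                    np.sum(beta[:-g] * beta[g:] * v[:-g]))
        return total

    def variant_table(self) -> pd.DataFrame:
        m_snps = self.config.n_snps
        return pd.DataFrame({
            "snp": [f"rs{j + 1}" for j in range(m_snps)],
            "chrom": "1",
            "cm": 0.0,
            "pos": self.positions,
            "a1": self.alleles[:, 0] if m_snps else [],
            "a2": self.alleles[:, 1] if m_snps else [],
        })


def _forward_haplotypes(rng: np.random.Generator, n_hap: int,
                        model: _VariantModel) -> np.ndarray:
    """Simulate ``n_hap`` haplotypes over all SNPs of the chain (bool array)."""
    m_snps = model.config.n_snps
    x = np.empty((n_hap, m_snps), dtype=bool)
    if m_snps == 0 or n_hap == 0:
        return x
    if model.rho == 0.0:
        return rng.random((n_hap, m_snps)) < model.u
    x[:, 0] = rng.random(n_hap) < model.u[0]
    for j in range(1, m_snps):
        p1 = np.where(x[:, j - 1], model.t1[j], model.t0[j])
        x[:, j] = rng.random(n_hap) < p1
    return x


def _sample_table(n: int, rng: np.random.Generator, prefix: str = "S") -> pd.DataFrame:
    iids = [f"{prefix}{i + 1:06d}" for i in range(n)]
    return pd.DataFrame({
        "fid": iids, "iid": iids, "father": "0", "mother": "0",
        "sex": rng.integers(1, 3, size=n), "phenotype": -9,
    })


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig):
    """Draw a population sample of genotypes plus the ground-truth skeleton.

    Returns ``(GenotypeDataset, SimTruth)``; liability and case status are
    filled in by :func:`assign_case_control`.
    """
    model = _VariantModel(config)
    rng_h = _rng(config.seed, _STAGE_HAPLOTYPES)
    haps = _forward_haplotypes(rng_h, 2 * config.n_samples, model)
    dosages = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8))
    dataset = GenotypeDataset(
        samples=_sample_table(config.n_samples, _rng(config.seed, _STAGE_VARIANTS, 1)),
        variants=model.variant_table(),
        dosages=dosages,
    )
    g = _genetic_values(dosages, model)
    truth = SimTruth(config=config, beta_true=model.beta, freq_ancestral=model.m,
                     genetic_value=g)
    return dataset, truth


def _genetic_values(dosages: np.ndarray, model: _VariantModel) -> np.ndarray:
    centered = dosages.astype(float) - 2.0 * model.m
    return centered @ model.beta


def assign_case_control(dataset: GenotypeDataset, truth: SimTruth,
                        config: SimConfig) -> SimTruth:
    """Add liability and case status under the liability-threshold model."""
    g = truth.genetic_value
    if g is None:
        raise ComputationError("genotypes must be simulated before case assignment")
    rng = _rng(config.seed, _STAGE_NOISE)
    env_sd = np.sqrt(max(0.0, 1.0 - config.h2_liab))
    liab = g + rng.normal(0.0, env_sd, size=len(g)) if env_sd > 0 else g.copy()
    thresh = stats.norm.ppf(1.0 - config.prevalence)
    truth.liability = liab
    truth.case = liab > thresh
    dataset.samples["phenotype"] = np.where(truth.case, 2, 1)
    return truth


def assign_severity_onset(truth: SimTruth, config: SimConfig) -> SimTruth:
    """Add renal status and onset age for cases (NaN elsewhere)."""
    if truth.case is None:
        raise ComputationError("cases must be assigned before severity/onset")
    g = truth.genetic_value
    g_sd = np.sqrt(config.h2_liab)
    g_std = g / g_sd if g_sd > 0 else np.zeros_like(g)
    case = truth.case
    n_case = int(case.sum())

    rng_s = _rng(config.seed, _STAGE_SEVERITY)
    logit = config.sev_intercept + config.sev_slope * g_std[case]
    p_renal = 1.0 / (1.0 + np.exp(-logit))
    renal = np.full(len(g), np.nan)
    renal[case] = (rng_s.random(n_case) < p_renal).astype(float)

    rng_o = _rng(config.seed, _STAGE_ONSET)
    onset = np.full(len(g), np.nan)
    onset[case] = np.maximum(
        1.0,
        config.onset_mean + config.onset_slope * g_std[case]
        + rng_o.normal(0.0, config.onset_sd, size=n_case))
    truth.renal = renal
    truth.onset = onset
    return truth


def simulate_population_cohort(config: SimConfig) -> tuple:
    """Population sampling: genotypes, disease, severity and onset in one call."""
    dataset, truth = simulate_genotypes(config)
    truth = assign_case_control(dataset, truth, config)
    truth = assign_severity_onset(truth, config)
    return dataset, truth


def drift_population(freqs, fst: float, seed=0) -> np.ndarray:
    """Balding-Nichols drift of allele frequencies into a subpopulation.

    Draws ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` per SNP; ``fst = 0`` returns the
    ancestral frequencies unchanged.
    """
    p = np.asarray(freqs, dtype=float)
    if not 0 <= fst < 1:
        raise ConfigError("fst must lie in [0, 1)")
    if p.size and not np.all((p > 0) & (p < 1)):
        raise ConfigError("ancestral frequencies must lie in (0, 1)")
    if fst == 0:
        return p.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scale = (1.0 - fst) / fst
    drifted = rng.beta(p * scale, (1.0 - p) * scale)
    # keep frequencies polymorphic so downstream moments stay defined
    return np.clip(drifted, 1e-6, 1.0 - 1e-6)


def attainable_auc(h2_explained: float, prevalence: float,
                   n_mc: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo ceiling AUC of a score explaining ``h2_explained`` of liability.

    Score and liability are bivariate normal with correlation
    ``sqrt(h2_explained)``; a sample is a case when liability exceeds the
    prevalence threshold.  Returns the estimated P(score_case > score_control).
    """
    if not 0 <= h2_explained <= 1:
        raise ConfigError("h2_explained must lie in [0, 1]")
    if not 0 < prevalence < 1:
        raise ConfigError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 901)))
    liab = rng.standard_normal(n_mc)
    r = np.sqrt(h2_explained)
    score = r * liab + np.sqrt(1.0 - h2_explained) * rng.standard_normal(n_mc)
    case = liab > stats.norm.ppf(1.0 - prevalence)
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise ComputationError("n_mc too small to realize both classes")
    ranks = stats.rankdata(score)
    return float((ranks[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Case-control oversampling (exact two-pass scheme)
# ---------------------------------------------------------------------------

def simulate_case_control_cohort(config: SimConfig, n_cases: int,
                                 n_controls: int, cohort_seed: Optional[int] = None):
    """Simulate individuals until the case and control quotas are met.

    Retrospective (case-control) sampling: population individuals are drawn
    from the :class:`SimConfig` generative model and retained until
    ``n_cases`` cases and ``n_controls`` controls are collected.  Implemented
    as liability screening on causal columns followed by exact conditional
    completion of the remaining columns — equivalent in distribution to
    brute-force simulation, at a fraction of the cost when prevalence is low.

    ``cohort_seed`` (default ``config.seed``) controls the individual-level
    randomness; the variant model (frequencies, LD chain, alleles, causal
    effects) always derives from ``config.seed``, so cohorts simulated with
    different ``cohort_seed`` share a genome and can train/test each other.
    """
    model = _VariantModel(config)
    seed = config.seed if cohort_seed is None else cohort_seed
    rng = _rng(seed, _STAGE_HAPLOTYPES, 2)

    causal = model.causal
    n_want = n_cases + n_controls
    if config.n_snps == 0 or n_want == 0:
        empty = GenotypeDataset(_sample_table(0, rng), model.variant_table(),
                                np.zeros((0, config.n_snps), dtype=np.int8))
        truth = SimTruth(config=config, beta_true=model.beta,
                         freq_ancestral=model.m,
                         genetic_value=np.empty(0), liability=np.empty(0),
                         case=np.zeros(0, dtype=bool))
        return empty, truth

    skip_t1, skip_t0 = _skip_transitions(model, causal)
    env_sd = np.sqrt(max(0.0, 1.0 - config.h2_liab))
    thresh = stats.norm.ppf(1.0 - config.prevalence)
    beta_c = model.beta[causal]
    m_c = model.m[causal]

    kept_haps, kept_liab, kept_g, kept_case = [], [], [], []
    got_cases = got_controls = 0
    n_pop = 0
    max_pop = max(int(50 * n_cases / config.prevalence), 100 * n_want) + 10_000
    while got_cases < n_cases or got_controls < n_controls:
        remaining_case_pop = (n_cases - got_cases) / config.prevalence
        remaining_ctrl_pop = (n_controls - got_controls) / (1 - config.prevalence)
        batch = int(np.clip(1.3 * max(remaining_case_pop, remaining_ctrl_pop),
                            1024, 60_000))
        if n_pop + batch > max_pop:
            raise ComputationError("case quota unreachable at this prevalence")
        haps_c = _screen_haplotypes(rng, 2 * batch, skip_t1, skip_t0, m_c)
        g = ((haps_c[0::2].astype(np.float64) + haps_c[1::2]) - 2.0 * m_c) @ beta_c \
            if causal.size else np.zeros(batch)
        liab = g + (rng.normal(0.0, env_sd, size=batch) if env_sd > 0 else 0.0)
        case = liab > thresh
        keep = np.zeros(batch, dtype=bool)
        case_idx = np.flatnonzero(case)[:max(0, n_cases - got_cases)]
        ctrl_idx = np.flatnonzero(~case)[:max(0, n_controls - got_controls)]
        keep[case_idx] = True
        keep[ctrl_idx] = True
        got_cases += len(case_idx)
        got_controls += len(ctrl_idx)
        n_pop += batch
        hap_keep = np.repeat(keep, 2)
        kept_haps.append(haps_c[hap_keep])
        kept_liab.append(liab[keep])
        kept_g.append(g[keep])
        kept_case.append(case[keep])

    haps_causal = np.concatenate(kept_haps) if kept_haps else \
        np.zeros((0, causal.size), dtype=bool)
    full_haps = _complete_haplotypes(rng, haps_causal, model, causal)
    dosages = full_haps[0::2].astype(np.int8) + full_haps[1::2].astype(np.int8)

    case_arr = np.concatenate(kept_case)
    samples = _sample_table(n_want, _rng(seed, _STAGE_VARIANTS, 3))
    samples["phenotype"] = np.where(case_arr, 2, 1)
    dataset = GenotypeDataset(samples, model.variant_table(), dosages)
    truth = SimTruth(config=config, beta_true=model.beta, freq_ancestral=model.m,
                     genetic_value=np.concatenate(kept_g),
                     liability=np.concatenate(kept_liab),
                     case=case_arr, n_population_simulated=n_pop)
    cfg_for_sev = replace(config, seed=seed)
    return dataset, assign_severity_onset(truth, cfg_for_sev)


def _skip_transitions(model: _VariantModel, causal: np.ndarray):
    """2x2 chain transition products between consecutive causal SNPs.

    Returns arrays (skip_t1, skip_t0) of length ``len(causal)`` where entry k
    gives P(X_{c_k}=1 | X_{c_{k-1}}=1) and P(... | X_{c_{k-1}}=0); entry 0
    holds the marginal m_{c_0} in both slots.
    """
    k = causal.size
    skip_t1 = np.empty(k)
    skip_t0 = np.empty(k)
    if k == 0:
        return skip_t1, skip_t0
    skip_t1[0] = skip_t0[0] = model.m[causal[0]]
    t1, t0 = model.t1, model.t0
    for idx in range(1, k):
        a, b = causal[idx - 1], causal[idx]
        # running product of T_j for j in (a, b]; state = rows of the 2x2
        p11, p01 = 1.0, 0.0   # P(1 | start=1), P(1 | start=0)
        for j in range(a + 1, b + 1):
            p11 = p11 * t1[j] + (1 - p11) * t0[j]
            p01 = p01 * t1[j] + (1 - p01) * t0[j]
        skip_t1[idx] = p11
        skip_t0[idx] = p01
    return skip_t1, skip_t0


def _screen_haplotypes(rng, n_hap, skip_t1, skip_t0, m_c) -> np.ndarray:
    """Simulate only the causal columns of the chain (exact marginal law)."""
    k = len(m_c)
    x = np.empty((n_hap, k), dtype=bool)
    if k == 0:
        return x
    x[:, 0] = rng.random(n_hap) < m_c[0]
    for idx in range(1, k):
        p1 = np.where(x[:, idx - 1], skip_t1[idx], skip_t0[idx])
        x[:, idx] = rng.random(n_hap) < p1
    return x


def _complete_haplotypes(rng, haps_causal: np.ndarray, model: _VariantModel,
                         causal: np.ndarray) -> np.ndarray:
    """Fill non-causal columns given causal alleles (exact chain bridge).

    For each non-causal SNP j between causal anchors a < j < b the conditional
    is P(X_j | X_{j-1}, X_b) ∝ T_j[X_{j-1}, X_j] * R_j[X_j, X_b] with R_j the
    backward product T_{j+1}...T_b; before the first anchor the prior at j=0
    is Bern(u_0), and after the last anchor the chain runs forward freely.
    """
    n_hap = haps_causal.shape[0]
    m_snps = model.config.n_snps
    x = np.empty((n_hap, m_snps), dtype=bool)
    if n_hap == 0 or m_snps == 0:
        return x
    if causal.size == m_snps:
        return haps_causal.copy()
    if causal.size == 0:
        return _forward_haplotypes(rng, n_hap, model)
    x[:, causal] = haps_causal
    t1, t0, u = model.t1, model.t0, model.u

    # Backward products R_j within each anchored segment: R[j] = (r1a, r0a)
    # giving P(X_anchor = x_a | X_j = 1 or 0); only x_a-dependent ratios are
    # needed, so store P(anchor=1 | X_j).
    r1 = np.full(m_snps, np.nan)   # P(X_anchor = 1 | X_j = 1)
    r0 = np.full(m_snps, np.nan)   # P(X_anchor = 1 | X_j = 0)
    anchor_of = np.full(m_snps, -1, dtype=np.int64)
    prev = -1
    segments = []   # (start_j, end_j_exclusive, anchor) for bridged segments
    for a in causal:
        if a - prev > 1:
            segments.append((prev + 1, a, a))
        prev = a
    for start, end, anchor in segments:
        nxt1, nxt0 = 1.0, 0.0
        for j in range(end - 1, start - 1, -1):
            if j + 1 == anchor:
                a1, a0 = t1[anchor], t0[anchor]
            else:   # extend product leftwards: R_j = T_{j+1} @ R_{j+1}
                a1 = t1[j + 1] * nxt1 + (1 - t1[j + 1]) * nxt0
                a0 = t0[j + 1] * nxt1 + (1 - t0[j + 1]) * nxt0
            r1[j], r0[j] = a1, a0
            nxt1, nxt0 = a1, a0
            anchor_of[j] = anchor

    # Forward pass over all SNPs, sampling non-causal columns.
    causal_set = np.zeros(m_snps, dtype=bool)
    causal_set[causal] = True
    first_causal = causal[0]
    for j in range(m_snps):
        if causal_set[j]:
            continue
        if j == 0:
            prior1 = np.full(n_hap, u[0])
        else:
            prior1 = np.where(x[:, j - 1], t1[j], t0[j])
        if j < first_causal or anchor_of[j] >= 0:
            anchor = anchor_of[j]
            xa = x[:, anchor]
            like1 = np.where(xa, r1[j], 1.0 - r1[j])
            like0 = np.where(xa, r0[j], 1.0 - r0[j])
            num = prior1 * like1
            den = num + (1.0 - prior1) * like0
            p1 = np.divide(num, den, out=np.full(n_hap, 0.5), where=den > 0)
        else:               # past the last causal anchor: free forward chain
            p1 = prior1
        x[:, j] = rng.random(n_hap) < p1
    return x
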