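"""Construct genotypes, Bayes-posterior disease risks and disease status.

The generative model: each SNP's genotypes follow Hardy-Weinberg proportions
for its risk-allele frequency, loci are in linkage equilibrium, and the
per-genotype disease risks are chosen so that (i) the odds ratio between
adjacent genotypes equals the per-allele OR (log-additive model) and (ii) the
genotype-frequency-weighted mean risk equals the population disease risk
``d``.  Individual posterior risks follow from Bayes' theorem under the
naive-Bayes (independent effects) assumption:

    posterior odds = d/(1-d) * prod_g LR_{g,i(g)},   risk = odds/(1+odds)

where LR_{g,i} = P(genotype i of SNP g | case) / P(genotype i | control).
Disease status is a Bernoulli draw against each individual's risk, so the
realized prevalence, allele frequencies and ORs match the inputs up to
sampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_io import SNPSpec, StudySpec


@dataclass(frozen=True)
class GenotypeRiskProfile:
    """Per-SNP genotype frequencies, genotype disease risks and likelihood ratios."""

    geno_freqs: tuple[float, float, float]
    geno_risks: tuple[float, float, float]
    lrs: tuple[float, float, float]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Risk-allele counts (0/1/2), one row per individual, one column per SNP."""

    counts: np.ndarray
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.snp_ids):
            raise ValueError("counts must be n_sim x G with one column per snp_id")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class CohortDataset:
    """A simulated cohort: genotypes, posterior risks, disease status, seed."""

    genotypes: GenotypeMatrix
    posterior_risk: np.ndarray
    status: np.ndarray
    seed: int

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())


def hwe_genotype_freqs(raf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    if not (0.0 <= raf <= 1.0):
        raise ValueError(f"raf must lie in [0, 1], got {raf}")
    q = 1.0 - raf
    return (q * q, 2.0 * raf * q, raf * raf)


def sample_genotypes(
    specs: Sequence[SNPSpec], n_sim: int, rng: int | np.random.Generator
) -> GenotypeMatrix:
    """Draw an n_sim x G matrix of risk-allele counts under HWE.

    Each column is an independent trinomial sample (two Bernoulli alleles per
    individual), and columns are mutually independent — linkage equilibrium.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = np.empty((n_sim, len(specs)), dtype=np.int8)
    for j, spec in enumerate(specs):
        # binomial(2, raf) is exactly the HWE trinomial over {0,1,2}
        counts[:, j] = gen.binomial(2, spec.raf, size=n_sim)
    return GenotypeMatrix(counts=counts, snp_ids=tuple(s.snp_id for s in specs))


_LOG_ODDS_LO, _LOG_ODDS_HI = -40.0, 40.0


def solve_baseline_risk(spec: SNPSpec, d: float) -> GenotypeRiskProfile:
    """Solve for per-genotype risks consistent with the OR and prevalence d.

    Finds baseline odds ``odds0`` such that, with per-genotype odds
    ``odds0 * OR**i``, the HWE-weighted mean risk equals ``d``.  The mean
    risk is strictly increasing in odds0, so bisection on ln(odds0) over
    [-40, 40] converges to the unique root.  Likelihood ratios follow as
    LR_i = p_i (1-d) / (d (1-p_i)), giving LR_i/LR_0 = OR**i exactly.
    """
    if not (0.0 < d < 1.0):
        raise ValueError(f"d must lie in (0, 1), got {d}")
    g = np.asarray(hwe_genotype_freqs(spec.raf))
    or_pow = spec.or_allele ** np.arange(3)

    def mean_risk(log_odds0: float) -> float:
        odds = math.exp(log_odds0) * or_pow
        return float((g * odds / (1.0 + odds)).sum())

    lo, hi = _LOG_ODDS_LO, _LOG_ODDS_HI
    if not (mean_risk(lo) <= d <= mean_risk(hi)):
        raise ArithmeticError(
            f"cannot bracket baseline odds for OR={spec.or_allele}, d={d}"
        )
    # bisection: monotone objective, ~60 halvings reach float resolution
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_risk(mid) < d:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 and abs(mean_risk(0.5 * (lo + hi)) - d) <= 1e-12:
            break
    log_odds0 = 0.5 * (lo + hi)
    odds = np.exp(log_odds0) * or_pow
    p = odds / (1.0 + odds)
    lrs = p * (1.0 - d) / (d * (1.0 - p))
    return GenotypeRiskProfile(
        geno_freqs=tuple(g.tolist()),
        geno_risks=tuple(p.tolist()),
        lrs=tuple(lrs.tolist()),
    )


def posterior_risks(
    genotypes: GenotypeMatrix,
    profiles: Sequence[GenotypeRiskProfile],
    d: float,
) -> np.ndarray:
    """Per-individual Bayes posterior disease risks.

    posterior odds = d/(1-d) * prod over SNPs of the genotype's LR; risk =
    odds/(1+odds).  Computed on the log scale for numerical stability with
    large panels.
    """
    if len(profiles) != genotypes.n_snps:
        raise ValueError("profiles must align with genotype columns")
    log_lr_table = np.log([prof.lrs for prof in profiles])  # G x 3
    # individual i, SNP g -> log_lr_table[g, counts[i, g]]
    total_log_lr = log_lr_table[np.arange(genotypes.n_snps), genotypes.counts].sum(axis=1)
    log_odds = math.log(d / (1.0 - d)) + total_log_lr
    risk = 1.0 / (1.0 + np.exp(-log_odds))
    return risk


def assign_status(risks: np.ndarray, rng: int | np.random.Generator) -> np.ndarray:
    """Assign disease status: 1 iff risk exceeds an independent Uniform(0,1) draw."""
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u = gen.uniform(size=len(risks))
    return (risks > u).astype(np.int8)


def simulate_cohort(study: StudySpec, rng_seed: int) -> CohortDataset:
    """Simulate a full cohort for one study: genotypes, risks and status."""
    gen = np.random.default_rng(rng_seed)
    genotypes = sample_genotypes(study.snps, study.n_sim, gen)
    profiles = [solve_baseline_risk(s, study.d) for s in study.snps]
    risks = posterior_risks(genotypes, profiles, study.d)
    status = assign_status(risks, gen)
    return CohortDataset(
        genotypes=genotypes, posterior_risk=risks, status=status, seed=rng_seed
    )


def cohort_to_frame(cohort: CohortDataset) -> pd.DataFrame:
    """One row per individual: genotype columns (0/1/2), posterior_risk, status."""
    df = pd.DataFrame(cohort.genotypes.counts, columns=list(cohort.genotypes.snp_ids))
    df["posterior_risk"] = cohort.posterior_risk
    df["status"] = cohort.status
    return df


def export_cohort(cohort: CohortDataset, path: str | Path, *, sep: str = "\t") -> None:
    """Write the cohort as a delimited table (see :func:`cohort_to_frame`)."""
    cohort_to_frame(cohort).to_csv(path, sep=sep, index=False)
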