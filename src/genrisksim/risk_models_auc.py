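"""Risk-model scores and nonparametric AUC estimation.

Three score types are supported, mirroring how genetic prediction studies
build their models:

* ``unweighted`` — the count of risk alleles across the panel;
* ``weighted``   — the sum of risk-allele counts weighted by ln(OR);
* ``bayes``      — the Bayes posterior disease risk (used to replicate both
  weighted-score and logistic-regression studies; AUC is rank-invariant and
  the posterior odds are monotone in the weighted sum of log likelihood
  ratios).

AUC is the tie-aware Mann-Whitney statistic — the probability that a random
case outscores a random control, ties counted half — computed from rank sums
in O(n log n).  :func:`analytic_auc` is an exact small-panel oracle that
enumerates the 3^G genotype space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata

from .cohort_simulator import CohortDataset, GenotypeMatrix, solve_baseline_risk
from .panel_io import MODEL_TYPES, SNPSpec


@dataclass(frozen=True)
class ScoreSet:
    """Per-individual scores paired with binary disease status."""

    scores: np.ndarray
    status: np.ndarray
    model_type: str

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.status):
            raise ValueError("scores and status must be aligned")
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")


@dataclass(frozen=True)
class AUCEstimate:
    auc: float
    n_cases: int
    n_controls: int


class UndefinedAUCError(ValueError):
    """AUC is undefined without at least one case and one control."""


def unweighted_score(genotypes: GenotypeMatrix) -> np.ndarray:
    """Number of risk alleles across all SNPs (integer, in [0, 2G])."""
    return genotypes.counts.sum(axis=1).astype(np.int64)


def weighted_score(genotypes: GenotypeMatrix, specs: Sequence[SNPSpec]) -> np.ndarray:
    """Sum of risk-allele counts weighted by ln(OR)."""
    if len(specs) != genotypes.n_snps:
        raise ValueError("specs must align with genotype columns")
    weights = np.log([s.or_allele for s in specs])
    return genotypes.counts @ weights


def bayes_score(cohort: CohortDataset) -> np.ndarray:
    """Posterior disease risks used directly as the risk-model score."""
    return cohort.posterior_risk


def score_cohort(cohort: CohortDataset, specs: Sequence[SNPSpec], model_type: str) -> ScoreSet:
    """Compute the requested score type on a simulated cohort."""
    if model_type == "unweighted":
        scores = unweighted_score(cohort.genotypes)
    elif model_type == "weighted":
        scores = weighted_score(cohort.genotypes, specs)
    elif model_type == "bayes":
        scores = bayes_score(cohort)
    else:
        raise ValueError(f"model_type must be one of {MODEL_TYPES}")
    return ScoreSet(scores=np.asarray(scores, dtype=float), status=cohort.status,
                    model_type=model_type)


def auc_mann_whitney(scores: ScoreSet) -> AUCEstimate:
    """Tie-aware Mann-Whitney AUC from rank sums.

    AUC = [#(case > control) + 0.5 * #(ties)] / (n_cases * n_controls),
    identical to the trapezoidal area under the empirical ROC curve.
    """
    status = np.asarray(scores.status).astype(bool)
    n1 = int(status.sum())
    n0 = len(status) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC requires at least one case and one control")
    ranks = rankdata(scores.scores)  # average ranks give ties half credit
    rank_sum_cases = ranks[status].sum()
    auc = (rank_sum_cases - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return AUCEstimate(auc=float(auc), n_cases=n1, n_controls=n0)


_MAX_ENUM_SNPS = 12


def analytic_auc(specs: Sequence[SNPSpec], d: float, model_type: str) -> float:
    """Exact AUC by enumerating the 3^G genotype space (G <= 12).

    Each genotype combination has population probability prod_g P(g_i) and a
    Bayes risk r; its case weight is proportional to P * r and its control
    weight to P * (1 - r).  The returned value is the exact tie-aware
    probability that a random case outscores a random control under
    ``model_type`` scoring — the infinite-cohort limit of the simulated AUC.
    """
    G = len(specs)
    if G > _MAX_ENUM_SNPS:
        raise ValueError(f"analytic_auc enumerates 3^G combinations; G={G} > {_MAX_ENUM_SNPS}")
    profiles = [solve_baseline_risk(s, d) for s in specs]
    combos = np.array(list(itertools.product(range(3), repeat=G)), dtype=np.int64)

    freqs = np.array([p.geno_freqs for p in profiles])  # G x 3
    log_lrs = np.log([p.lrs for p in profiles])
    idx = np.arange(G)
    prob = freqs[idx, combos].prod(axis=1)
    log_odds = math.log(d / (1.0 - d)) + log_lrs[idx, combos].sum(axis=1)
    risk = 1.0 / (1.0 + np.exp(-log_odds))

    if model_type == "unweighted":
        score = combos.sum(axis=1).astype(float)
    elif model_type == "weighted":
        score = combos @ np.log([s.or_allele for s in specs])
    elif model_type == "bayes":
        score = risk
    else:
        raise ValueError(f"model_type must be one of {MODEL_TYPES}")

    w_case = prob * risk
    w_ctrl = prob * (1.0 - risk)
    w_case /= w_case.sum()
    w_ctrl /= w_ctrl.sum()

    order = np.argsort(score, kind="stable")
    score, w_case, w_ctrl = score[order], w_case[order], w_ctrl[order]
    # group tied scores, then P(case > control) + 0.5 P(tie)
    boundaries = np.flatnonzero(np.diff(score) != 0) + 1
    case_g = np.add.reduceat(w_case, np.r_[0, boundaries])
    ctrl_g = np.add.reduceat(w_ctrl, np.r_[0, boundaries])
    ctrl_below = np.concatenate([[0.0], np.cumsum(ctrl_g)[:-1]])
    return float((case_g * (ctrl_below + 0.5 * ctrl_g)).sum())


def refit_logistic_auc(cohort: CohortDataset) -> AUCEstimate:
    """AUC of an additive logistic model refit within the simulated data.

    Fits status ~ genotype counts (main effects, additive coding) and scores
    individuals by the fitted probability.  Validation utility: under linkage
    equilibrium the refit AUC should match the Bayes-score AUC up to
    Monte-Carlo error.
    """
    status = np.asarray(cohort.status)
    if status.sum() == 0 or status.sum() == len(status):
        raise UndefinedAUCError("logistic refit requires both cases and controls")
    X = cohort.genotypes.counts.astype(float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("a genotype column is constant; cannot fit logistic model")
    try:
        fit = sm.Logit(status, sm.add_constant(X)).fit(disp=0, maxiter=200)
    except Exception as err:  # separation / convergence failures
        raise RuntimeError(f"logistic refit failed: {err}") from err
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic refit did not converge")
    fitted = np.asarray(fit.predict())
    return auc_mann_whitney(
        ScoreSet(scores=fitted, status=status, model_type="bayes")
    )
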