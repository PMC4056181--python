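"""Replication protocol: repeated simulation, AUC averaging, comparison.

For each study the protocol simulates ``n_iter`` independent cohorts (seed
``base_seed + k`` for iteration k), scores them under the study's model type
and averages the AUC.  Two odds-ratio strategies are supported: ``point``
uses the published point estimates throughout, ``ci_sampled`` redraws each
SNP's OR once per iteration from a log-normal distribution whose 95% range
matches the published CI.  Comparison against published AUC values is done
on 2-decimal-rounded numbers, matching the precision at which prediction
studies report AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .cohort_simulator import simulate_cohort
from .panel_io import SNPSpec, StudySpec, log_or_sd_from_ci, normalize_snp
from .risk_models_auc import auc_mann_whitney, score_cohort

OR_STRATEGIES = ("point", "ci_sampled")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (printed-table convention, not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _abs_diff_2dp(x: float, y: float) -> float:
    """|x - y| after rounding both to 2 decimals, exact in hundredths."""
    return abs(round(round_half_away(x) * 100) - round(round_half_away(y) * 100)) / 100.0


@dataclass(frozen=True)
class ReplicationResult:
    """Averaged AUC for one study under one OR strategy."""

    study_id: str
    model_type: str
    mean_auc: float
    per_iteration_auc: tuple[float, ...]
    or_strategy: str
    published_auc: float | None = None

    @property
    def abs_diff(self) -> float | None:
        """|estimated - published| on 2-decimal values; None without a published AUC."""
        if self.published_auc is None:
            return None
        return _abs_diff_2dp(self.mean_auc, self.published_auc)


@dataclass(frozen=True)
class GroupSummary:
    model_type: str
    n_studies: int
    median_abs_diff: float
    min_abs_diff: float
    max_abs_diff: float


@dataclass(frozen=True)
class ReplicationReport:
    rows: tuple[ReplicationResult, ...]
    summaries: dict[str, GroupSummary]


def sample_ors(
    specs: list[SNPSpec] | tuple[SNPSpec, ...], rng: int | np.random.Generator
) -> list[SNPSpec]:
    """Redraw each SNP's OR from its published 95% CI.

    Draws ln(OR) ~ Normal(ln or_allele, sd) with sd inferred from the CI
    width, i.e. the OR is log-normal — the standard sampling model for odds
    ratios, which keeps draws positive.  A draw below 1 flips the row to the
    other allele (risk-allele convention preserved, distribution untouched).
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: list[SNPSpec] = []
    for spec in specs:
        sd = log_or_sd_from_ci(spec)  # raises if the CI is absent
        drawn = math.exp(gen.normal(math.log(spec.or_allele), sd))
        out.append(normalize_snp(replace(spec, or_allele=drawn, ci_low=None, ci_high=None)))
    return out


def run_replication(
    study: StudySpec, or_strategy: str, base_seed: int
) -> ReplicationResult:
    """Run the n_iter-fold simulation protocol for one study.

    Iteration k seeds every source of randomness from ``base_seed + k``: the
    OR redraw (when ``ci_sampled``), genotype sampling and status assignment.
    Identical study + seed + strategy therefore reproduce bit-identical
    results.
    """
    if or_strategy not in OR_STRATEGIES:
        raise ValueError(f"or_strategy must be one of {OR_STRATEGIES}")
    aucs: list[float] = []
    for k in range(1, study.n_iter + 1):
        seed = base_seed + k
        snps = study.snps
        if or_strategy == "ci_sampled":
            # independent stream so the OR draw does not perturb cohort sampling
            snps = tuple(sample_ors(study.snps, np.random.default_rng([seed, 1])))
        iter_study = replace(study, snps=snps)
        try:
            cohort = simulate_cohort(iter_study, seed)
            auc = auc_mann_whitney(score_cohort(cohort, snps, study.model_type)).auc
        except Exception as err:
            raise RuntimeError(f"replication iteration {k} failed: {err}") from err
        aucs.append(auc)
    return ReplicationResult(
        study_id=study.study_id,
        model_type=study.model_type,
        mean_auc=float(np.mean(aucs)),
        per_iteration_auc=tuple(aucs),
        or_strategy=or_strategy,
        published_auc=study.published_auc,
    )


def _median_midpoint(values: list[float]) -> float:
    """Median; even-length groups use the midpoint of the two central values."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def compare_to_published(
    results: list[ReplicationResult] | tuple[ReplicationResult, ...],
) -> ReplicationReport:
    """Summarize |estimated - published| AUC differences per model type.

    Differences are taken on 2-decimal values; the group median (midpoint for
    even-sized groups), minimum and maximum are reported rounded to 2
    decimals half-away-from-zero.
    """
    results = tuple(results)
    if not results:
        raise ValueError("compare_to_published requires at least one result")
    missing = [r.study_id for r in results if r.published_auc is None]
    if missing:
        raise ValueError(f"results without a published AUC: {missing}")
    summaries: dict[str, GroupSummary] = {}
    for model_type in dict.fromkeys(r.model_type for r in results):
        diffs = [r.abs_diff for r in results if r.model_type == model_type]
        summaries[model_type] = GroupSummary(
            model_type=model_type,
            n_studies=len(diffs),
            median_abs_diff=round_half_away(_median_midpoint(diffs)),
            min_abs_diff=round_half_away(min(diffs)),
            max_abs_diff=round_half_away(max(diffs)),
        )
    return ReplicationReport(rows=results, summaries=summaries)
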