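"""Reproduce the four standard prediction-study plots from a simulated cohort.

Each plot is produced as a tidy data table (the tested artifact) with an
optional rendered image (cosmetic).  For faithful reproduction of a
published figure the cohort should be regenerated at the published study's
sample size and disease risk, since both affect the CIs in the quintile plot
and the absolute risks in the scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import roc_curve

from .cohort_simulator import CohortDataset
from .panel_io import ci_from_counts
from .risk_models_auc import ScoreSet, UndefinedAUCError, unweighted_score


@dataclass(frozen=True)
class QuintileORTable:
    """Odds ratios of disease by score quintile, relative to the lowest."""

    thresholds: tuple[float, float, float, float]
    table: pd.DataFrame  # columns: quintile, n_cases, n_controls, or_vs_reference, ci_low, ci_high


def allele_count_histogram(cohort: CohortDataset) -> pd.DataFrame:
    """Distribution of the number of risk alleles among patients and nonpatients.

    Returns one row per allele count 0..2G with columns ``prop_cases`` and
    ``prop_controls``, each column summing to 1.
    """
    counts = unweighted_score(cohort.genotypes)
    status = np.asarray(cohort.status).astype(bool)
    if status.sum() == 0 or (~status).sum() == 0:
        raise UndefinedAUCError("histogram requires both patients and nonpatients")
    support = np.arange(0, 2 * cohort.genotypes.n_snps + 1)
    case_counts = np.bincount(counts[status], minlength=len(support))
    ctrl_counts = np.bincount(counts[~status], minlength=len(support))
    return pd.DataFrame(
        {
            "allele_count": support,
            "prop_cases": case_counts / case_counts.sum(),
            "prop_controls": ctrl_counts / ctrl_counts.sum(),
        }
    )


def roc_points(scores: ScoreSet) -> pd.DataFrame:
    """ROC curve points: (1-specificity, sensitivity) per score threshold.

    Includes the (0,0) and (1,1) endpoints; both coordinates are monotone
    nondecreasing and the trapezoidal area equals the Mann-Whitney AUC.
    """
    status = np.asarray(scores.status).astype(int)
    if status.sum() == 0 or (1 - status).sum() == 0:
        raise UndefinedAUCError("ROC requires at least one case and one control")
    fpr, tpr, _ = roc_curve(status, scores.scores, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def quintile_or_table(
    scores: ScoreSet, thresholds: Sequence[float] | None = None
) -> QuintileORTable:
    """ORs with Woolf 95% CIs for score quintiles vs the lowest quintile.

    Default cut-points are the 20/40/60/80 percentiles of the simulated
    score distribution; external thresholds (e.g. from a published study)
    may be injected instead.  The lowest quintile is the reference (OR = 1,
    no CI).  An empty case or control cell raises — no silent continuity
    correction.
    """
    s = np.asarray(scores.scores, dtype=float)
    status = np.asarray(scores.status).astype(bool)
    if thresholds is None:
        if len(np.unique(s)) < 5:
            raise ValueError("need >= 5 distinct score values for internal quintile thresholds")
        thresholds = tuple(np.quantile(s, [0.2, 0.4, 0.6, 0.8]))
    else:
        thresholds = tuple(float(t) for t in thresholds)
        if len(thresholds) != 4 or list(thresholds) != sorted(thresholds):
            raise ValueError("thresholds must be 4 nondecreasing cut-points")
    quintile = np.searchsorted(np.asarray(thresholds), s, side="right")

    rows = []
    ref_cases = int((status & (quintile == 0)).sum())
    ref_ctrls = int((~status & (quintile == 0)).sum())
    for q in range(5):
        n_cases = int((status & (quintile == q)).sum())
        n_ctrls = int((~status & (quintile == q)).sum())
        if q == 0:
            orv, lo, hi = 1.0, np.nan, np.nan
        else:
            if min(n_cases, n_ctrls, ref_cases, ref_ctrls) == 0:
                raise ValueError(
                    f"empty cell in quintile {q + 1} vs reference 2x2 table "
                    f"(cases={n_cases}, controls={n_ctrls}, ref_cases={ref_cases}, "
                    f"ref_controls={ref_ctrls}); apply a correction explicitly"
                )
            orv, lo, hi = ci_from_counts(n_cases, n_ctrls, ref_cases, ref_ctrls)
        rows.append(
            {"quintile": q + 1, "n_cases": n_cases, "n_controls": n_ctrls,
             "or_vs_reference": orv, "ci_low": lo, "ci_high": hi}
        )
    return QuintileORTable(thresholds=thresholds, table=pd.DataFrame(rows))


def risk_vs_allele_scatter(cohort: CohortDataset) -> tuple[pd.DataFrame, float]:
    """Predicted risk against risk-allele count, with the squared Pearson r.

    R^2 is the squared Pearson correlation between allele count and
    posterior risk; it is below 1 whenever SNP weights differ or the
    logistic nonlinearity bends the count-risk relationship.
    """
    counts = unweighted_score(cohort.genotypes)
    risks = np.asarray(cohort.posterior_risk)
    if np.all(counts == counts[0]):
        raise ValueError("allele counts are constant; R^2 undefined")
    if np.allclose(risks, risks[0]):
        raise ValueError("posterior risks are constant; R^2 undefined")
    r, _ = pearsonr(counts, risks)
    points = pd.DataFrame({"allele_count": counts, "posterior_risk": risks})
    return points, float(r**2)


# ---------------------------------------------------------------------------
# rendering: tables are the tested artifact, images are cosmetic

def _save(fig, path: Path) -> None:
    fig.savefig(path, dpi=150, bbox_inches="tight")


def render_plots(
    cohort: CohortDataset,
    scores: ScoreSet,
    out_dir: str | Path,
    *,
    image_format: str = "png",
) -> dict[str, Path]:
    """Write the four plot data tables (TSV) and rendered images to out_dir."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    hist = allele_count_histogram(cohort)
    hist.to_csv(out / "histogram.tsv", sep="\t", index=False)
    written["histogram"] = out / "histogram.tsv"
    fig, ax = plt.subplots()
    w = 0.4
    ax.bar(hist["allele_count"] - w / 2, hist["prop_cases"], width=w, label="patients")
    ax.bar(hist["allele_count"] + w / 2, hist["prop_controls"], width=w, label="nonpatients")
    ax.set_xlabel("number of risk alleles")
    ax.set_ylabel("proportion")
    ax.legend()
    _save(fig, out / f"histogram.{image_format}")
    plt.close(fig)

    roc = roc_points(scores)
    roc.to_csv(out / "roc.tsv", sep="\t", index=False)
    written["roc"] = out / "roc.tsv"
    fig, ax = plt.subplots()
    ax.plot(roc["fpr"], roc["tpr"])
    ax.plot([0, 1], [0, 1], ls="--", c="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    _save(fig, out / f"roc.{image_format}")
    plt.close(fig)

    qt = quintile_or_table(scores)
    qt.table.to_csv(out / "quintiles.tsv", sep="\t", index=False)
    written["quintiles"] = out / "quintiles.tsv"
    fig, ax = plt.subplots()
    t = qt.table
    yerr = np.vstack(
        [t["or_vs_reference"] - t["ci_low"], t["ci_high"] - t["or_vs_reference"]]
    )
    yerr = np.nan_to_num(yerr, nan=0.0)
    ax.errorbar(t["quintile"], t["or_vs_reference"], yerr=yerr, fmt="o", capsize=3)
    ax.axhline(1.0, ls="--", c="grey")
    ax.set_xlabel("quintile of genetic risk")
    ax.set_ylabel("odds ratio vs lowest quintile")
    _save(fig, out / f"quintiles.{image_format}")
    plt.close(fig)

    points, r2 = risk_vs_allele_scatter(cohort)
    points.to_csv(out / "scatter.tsv", sep="\t", index=False)
    (out / "scatter_metadata.tsv").write_text(
        "metric\tvalue\nr_squared_pearson\t%.6f\n" % r2, encoding="utf-8"
    )
    written["scatter"] = out / "scatter.tsv"
    fig, ax = plt.subplots()
    ax.scatter(points["allele_count"], points["posterior_risk"], s=4, alpha=0.2)
    ax.set_xlabel("number of risk alleles")
    ax.set_ylabel("predicted risk")
    ax.set_title(f"$R^2$ = {r2:.2f}")
    _save(fig, out / f"scatter.{image_format}")
    plt.close(fig)

    return written
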