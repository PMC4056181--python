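"""Read, validate and normalize SNP panels and study configurations.

A panel is a list of :class:`SNPSpec` rows — one per SNP, carrying the
risk-allele frequency (RAF), the per-allele odds ratio (OR) and, when
available, its 95% confidence interval.  Everything downstream assumes the
*risk-allele* convention: OR >= 1 and ``raf`` is the frequency of the allele
that increases disease odds.  :func:`normalize_snp` enforces that convention
by flipping alleles where needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: z quantile for a two-sided 95% interval.
Z95 = 1.959964

MODEL_TYPES = ("unweighted", "weighted", "bayes")


class PanelFormatError(ValueError):
    """A panel file is structurally malformed (e.g. a required column is missing)."""


class PanelValidationError(ValueError):
    """A panel row violates a domain constraint (bounds, CI ordering, ...)."""


@dataclass(frozen=True)
class SNPSpec:
    """One SNP's simulation parameters.

    Parameters
    ----------
    snp_id:
        Identifier, typically an rsID.
    raf:
        Risk-allele frequency in the population, in (0, 1).
    or_allele:
        Per-allele odds ratio (multiplicative change in disease odds per
        risk-allele copy under a log-additive model), > 0.
    ci_low, ci_high:
        Optional 95% CI bounds on ``or_allele``.
    """

    snp_id: str
    raf: float
    or_allele: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.raf < 1.0):
            raise PanelValidationError(
                f"SNP {self.snp_id!r}: raf must lie in (0, 1), got {self.raf}"
            )
        if not self.or_allele > 0.0:
            raise PanelValidationError(
                f"SNP {self.snp_id!r}: or_allele must be positive, got {self.or_allele}"
            )
        if (self.ci_low is None) != (self.ci_high is None):
            raise PanelValidationError(
                f"SNP {self.snp_id!r}: ci_low and ci_high must be given together"
            )
        if self.ci_low is not None:
            if not (0.0 < self.ci_low <= self.ci_high):
                raise PanelValidationError(
                    f"SNP {self.snp_id!r}: require 0 < ci_low <= ci_high, "
                    f"got ({self.ci_low}, {self.ci_high})"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None


def normalize_snp(spec: SNPSpec) -> SNPSpec:
    """Return ``spec`` in risk-allele orientation (OR >= 1).

    If the OR is below 1 the row describes the protective allele; the unique
    consistent conversion swaps alleles: raf -> 1 - raf, OR -> 1/OR, and the
    CI bounds become reciprocals in reversed order.  Applying the rule to an
    already-normalized spec is the identity.
    """
    if spec.or_allele >= 1.0:
        return spec
    return replace(
        spec,
        raf=1.0 - spec.raf,
        or_allele=1.0 / spec.or_allele,
        ci_low=None if spec.ci_high is None else 1.0 / spec.ci_high,
        ci_high=None if spec.ci_low is None else 1.0 / spec.ci_low,
    )


@dataclass(frozen=True)
class StudySpec:
    """A prediction study to replicate: a SNP panel plus cohort parameters.

    ``d`` is the population disease risk used as the Bayes prior;
    ``model_type`` selects how individual scores are computed (allele count,
    log-OR-weighted sum, or Bayes posterior risk); ``n_sim`` individuals are
    simulated per iteration and ``n_iter`` iterations are averaged.
    """

    study_id: str
    disease: str
    d: float
    model_type: str
    snps: tuple[SNPSpec, ...]
    n_sim: int = 100_000
    n_iter: int = 100
    published_auc: float | None = None
    published_n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        if not self.snps:
            raise PanelValidationError(f"study {self.study_id!r}: empty SNP panel")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise PanelValidationError(f"study {self.study_id!r}: duplicate snp_id values")
        if not (0.0 < self.d < 1.0):
            raise PanelValidationError(f"study {self.study_id!r}: d must lie in (0, 1)")
        if self.model_type not in MODEL_TYPES:
            raise PanelValidationError(
                f"study {self.study_id!r}: model_type must be one of {MODEL_TYPES}"
            )
        if self.n_sim < 1 or self.n_iter < 1:
            raise PanelValidationError(f"study {self.study_id!r}: n_sim and n_iter must be >= 1")
        if self.published_auc is not None and not (0.5 <= self.published_auc <= 1.0):
            raise PanelValidationError(
                f"study {self.study_id!r}: published_auc must lie in [0.5, 1]"
            )


_REQUIRED_COLUMNS = ("snp_id", "raf", "or_allele")


def read_panel(
    path: str | Path,
    *,
    sep: str = "\t",
    raf: Mapping[str, float] | str | Path | None = None,
) -> list[SNPSpec]:
    """Read a SNP panel from a delimited text file.

    The file is UTF-8, has a header row, and ``#`` lines are comments.
    Required columns: ``snp_id``, ``raf``, ``or_allele``; optional:
    ``ci_low``, ``ci_high``.  Rows are validated and normalized to
    risk-allele orientation, in file order.

    ``raf`` supplies frequencies externally when the panel file has no
    ``raf`` column (or to override it): either a mapping ``snp_id -> raf``
    or the path of a two-column ``snp_id``/``raf`` table.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"snp_id": str})

    raf_map: Mapping[str, float] | None = None
    if raf is not None:
        if isinstance(raf, (str, Path)):
            rdf = pd.read_csv(raf, sep=sep, comment="#", dtype={"snp_id": str})
            for col in ("snp_id", "raf"):
                if col not in rdf.columns:
                    raise PanelFormatError(f"{raf}: missing required column {col!r}")
            raf_map = dict(zip(rdf["snp_id"], rdf["raf"].astype(float)))
        else:
            raf_map = dict(raf)
        if "raf" not in df.columns:
            df = df.assign(raf=df["snp_id"].map(raf_map))
        else:
            df = df.assign(raf=df["snp_id"].map(raf_map).fillna(df["raf"]))
        missing = df.loc[df["raf"].isna(), "snp_id"].tolist()
        if missing:
            raise PanelValidationError(f"{path}: no raf supplied for SNPs {missing}")

    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PanelFormatError(f"{path}: missing required column {col!r}")

    has_ci = "ci_low" in df.columns and "ci_high" in df.columns
    specs: list[SNPSpec] = []
    for idx, row in df.iterrows():
        ci_low = ci_high = None
        if has_ci and not (pd.isna(row["ci_low"]) or pd.isna(row["ci_high"])):
            ci_low, ci_high = float(row["ci_low"]), float(row["ci_high"])
        try:
            spec = SNPSpec(
                snp_id=str(row["snp_id"]),
                raf=float(row["raf"]),
                or_allele=float(row["or_allele"]),
                ci_low=ci_low,
                ci_high=ci_high,
            )
        except PanelValidationError as err:
            raise PanelValidationError(f"{path}, row {idx}: {err}") from err
        specs.append(normalize_snp(spec))
    return specs


def ci_from_counts(a: float, b: float, c: float, e: float) -> tuple[float, float, float]:
    """Odds ratio and Woolf 95% CI from a 2x2 allele-by-status table.

    ``a``/``b`` are risk/nonrisk allele counts in cases, ``c``/``e`` in
    controls.  OR = (a*e)/(b*c); the CI is computed on the log scale with
    SE = sqrt(1/a + 1/b + 1/c + 1/e).  Zero cells are rejected — the caller
    must apply a continuity correction explicitly if wanted.
    """
    if min(a, b, c, e) <= 0:
        raise ValueError(
            "ci_from_counts requires strictly positive counts; apply a continuity "
            "correction explicitly before calling (none is applied silently)"
        )
    orv = (a * e) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / e)
    log_or = math.log(orv)
    return orv, math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)


def log_or_sd_from_ci(spec: SNPSpec) -> float:
    """Standard deviation of ln(OR) implied by a Woolf-symmetric 95% CI.

    Used when resampling ORs from published intervals: assuming the CI is
    symmetric about ln(OR), sd = (ln ci_high - ln ci_low) / (2 * 1.959964).
    """
    if not spec.has_ci:
        raise ValueError(
            f"SNP {spec.snp_id!r} has no CI; use the point-estimate strategy instead"
        )
    return (math.log(spec.ci_high) - math.log(spec.ci_low)) / (2.0 * Z95)


def read_study_config(path: str | Path, *, snps: Sequence[SNPSpec]) -> StudySpec:
    """Build a :class:`StudySpec` from a flat YAML key-value file plus a panel.

    Recognized keys mirror the StudySpec fields (``study_id``, ``disease``,
    ``d``, ``model_type``, ``n_sim``, ``n_iter``, ``published_auc``,
    ``published_n``); the SNP panel is passed separately.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PanelFormatError(f"{path}: expected a flat key-value mapping")
    known = {
        "study_id", "disease", "d", "model_type",
        "n_sim", "n_iter", "published_auc", "published_n",
    }
    unknown = set(cfg) - known
    if unknown:
        raise PanelFormatError(f"{path}: unknown keys {sorted(unknown)}")
    return StudySpec(snps=tuple(snps), **cfg)
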