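"""Accessors for the packaged fixture tables.

Ships the two 18-SNP type 2 diabetes panels (GWAS-reported ORs with 95%
CIs), the population disease risks for the six replicated diseases, the
published-vs-simulated AUC comparison table, and a *synthetic* stand-in set
of risk-allele frequencies for the 18-SNP panels (the exact frequencies used
originally are not distributed; see ``t2d_raf_synthetic.tsv``).
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path
from typing import Mapping

import pandas as pd

from .panel_io import SNPSpec, read_panel


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    path = files("genrisksim").joinpath("fixtures", name)
    return Path(str(path))


def load_t2d_panel(
    study: str, *, raf: Mapping[str, float] | str | Path | None = "synthetic"
) -> list[SNPSpec]:
    """Load one of the 18-SNP type 2 diabetes panels ("godarts" or "rotterdam").

    The packaged panels carry ORs and CIs only; ``raf`` supplies the
    risk-allele frequencies.  The default ``"synthetic"`` uses the packaged
    stand-in frequencies; pass a mapping or a file path to use your own.
    """
    if study not in ("godarts", "rotterdam"):
        raise ValueError('study must be "godarts" or "rotterdam"')
    if raf == "synthetic":
        raf = fixture_path("t2d_raf_synthetic.tsv")
    return read_panel(fixture_path(f"t2d_{study}.tsv"), raf=raf)


def disease_risks() -> dict[str, float]:
    """Population disease risks for the six replicated diseases."""
    df = pd.read_csv(fixture_path("disease_risks.tsv"), sep="\t", comment="#")
    return dict(zip(df["disease"], df["d"].astype(float)))


def table1_auc() -> pd.DataFrame:
    """Published and simulation-estimated AUC values, by study and model type."""
    return pd.read_csv(fixture_path("table1_replication.tsv"), sep="\t", comment="#")
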