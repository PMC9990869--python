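"""Deaminase-expression association analyses.

ADAR1 (gene symbol ADAR) is the dominant editor of repetitive regions;
its expression is expected to track the global editing level across
samples.  This module provides the global Spearman association between
per-sample mean editing level and each ADAR's expression, the same
correlation per site, the paired tumor/normal differential-expression
test for the ADAR family, and the stratification of sample pairs into
ADAR1-upregulated vs -downregulated groups with the within-stratum
level-vs-site-count correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import EditingMatrix

log = logging.getLogger(__name__)

#: accepted aliases -> canonical deaminase gene row
ADAR_ALIASES = {
    "ADAR": "ADAR",
    "ADAR1": "ADAR",
    "ADARB1": "ADARB1",
    "ADAR2": "ADARB1",
    "ADARB2": "ADARB2",
    "ADAR3": "ADARB2",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression (any normalized non-negative unit) plus
    per-sample condition and pairing metadata."""

    values: pd.DataFrame
    samples: pd.DataFrame  # index sample_id: condition, pair_id

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def adar_row(self, name: str) -> pd.Series:
        canonical = ADAR_ALIASES.get(name.upper())
        if canonical is None:
            raise KeyError(f"unknown ADAR alias {name!r}")
        for candidate in (canonical, name.upper()):
            if candidate in self.values.index:
                return self.values.loc[candidate]
        raise KeyError(f"gene {canonical!r} not present in the expression matrix")

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("gene_id")
        return cls(df[list(samples.index)], samples)


def mean_editing_level(matrix: EditingMatrix) -> pd.Series:
    """Per-sample mean editing level over the passing sites observed in that
    sample (not zero-filled, consistent with per-sample filtering)."""
    return matrix.level.mean(axis=0)


def site_count(matrix: EditingMatrix) -> pd.Series:
    """Per-sample number of passing sites."""
    return matrix.level.notna().sum(axis=0)


def global_adar_correlation(
    expr: ExpressionMatrix, matrix: EditingMatrix, adars=("ADAR", "ADARB1", "ADARB2")
) -> pd.DataFrame:
    """Spearman correlation of per-sample mean editing level with each ADAR's
    expression across all samples (ties mid-ranked).  Refuses < 3 samples."""
    level = mean_editing_level(matrix)
    shared = [s for s in expr.samples.index if s in level.index]
    if len(shared) < 3:
        raise ValueError(f"need at least 3 samples with editing observations, got {len(shared)}")
    rows = {}
    for name in adars:
        e = expr.adar_row(name).loc[shared]
        res = stats.spearmanr(e, level.loc[shared])
        rows[name] = {"rho": float(res.statistic), "p": float(res.pvalue), "n": len(shared)}
    return pd.DataFrame(rows).T.rename_axis("adar")


def adar_paired_ttests(expr: ExpressionMatrix, adars=("ADAR", "ADARB1", "ADARB2")) -> pd.DataFrame:
    """Paired tumor-vs-normal t-tests on log2(expression + 1) per ADAR gene."""
    meta = expr.samples
    rows = {}
    for name in adars:
        e = np.log2(expr.adar_row(name) + 1.0)
        wide = pd.DataFrame({"value": e, "condition": meta["condition"], "pair_id": meta["pair_id"]})
        piv = wide.pivot_table(index="pair_id", columns="condition", values="value").dropna()
        if len(piv) < 2:
            rows[name] = {"t": np.nan, "df": np.nan, "p": np.nan}
            continue
        res = stats.ttest_rel(piv["tumor"], piv["normal"])
        rows[name] = {"t": float(res.statistic), "df": len(piv) - 1, "p": float(res.pvalue)}
    return pd.DataFrame(rows).T.rename_axis("adar")


def per_site_adar_correlation(
    expr: ExpressionMatrix, matrix: EditingMatrix, adar: str = "ADAR", min_obs: int = 10
) -> pd.DataFrame:
    """Per-site Spearman correlation of editing level with ADAR expression,
    over the samples where the site passes; sites with fewer than
    ``min_obs`` observations or a constant level are reported missing."""
    e = expr.adar_row(adar)
    rows = []
    for site_id, levels in matrix.level.iterrows():
        obs = levels.dropna()
        obs = obs[[s for s in obs.index if s in e.index]]
        if len(obs) < min_obs or obs.nunique() < 2:
            rows.append({"site_id": site_id, "rho": np.nan, "p": np.nan, "n": len(obs)})
            continue
        res = stats.spearmanr(e.loc[obs.index], obs)
        rows.append({"site_id": site_id, "rho": float(res.statistic), "p": float(res.pvalue), "n": len(obs)})
    return pd.DataFrame(rows).set_index("site_id")


def stratify_by_adar1(
    expr: ExpressionMatrix, matrix: EditingMatrix, method: str = "spearman"
) -> dict:
    """Split pairs by tumor-vs-normal ADAR1 expression and correlate, within
    each stratum across tumor samples, mean editing level with passing-site
    count.  Strata with fewer than 3 pairs skip the correlation."""
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    e = expr.adar_row("ADAR")
    meta = expr.samples
    wide = pd.DataFrame({"value": e, "condition": meta["condition"], "pair_id": meta["pair_id"]})
    piv = wide.pivot_table(index="pair_id", columns="condition", values="value").dropna()
    up_pairs = piv.index[piv["tumor"] > piv["normal"]]
    down_pairs = piv.index[piv["tumor"] <= piv["normal"]]
    level = mean_editing_level(matrix)
    count = site_count(matrix)
    tumor_samples = meta.index[meta["condition"] == "tumor"]
    out = {}
    for stratum, pairs in (("upregulated", up_pairs), ("downregulated", down_pairs)):
        members = [s for s in tumor_samples if meta.loc[s, "pair_id"] in set(pairs)]
        entry = {"n_pairs": len(members), "rho": np.nan, "p": np.nan}
        if len(members) >= 3:
            x, y = level.loc[members], count.loc[members]
            if x.nunique() > 1 and y.nunique() > 1:
                fn = stats.spearmanr if method == "spearman" else stats.pearsonr
                res = fn(x, y)
                entry["rho"], entry["p"] = float(res.statistic), float(res.pvalue)
        else:
            log.info("ADAR1 %s stratum has %d pairs; correlation skipped", stratum, len(members))
        out[stratum] = entry
    return out
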