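"""Three-mode differential-editing classification and Fisher exact testing.

Sites are classified per condition-level sample coverage:

* ``shared`` — passing observations in at least ``min_shared_cov`` tumor
  samples AND at least ``min_shared_cov`` normal samples (the inclusive
  reading of "coverage over 10"; a strict ``>`` reading is selectable);
* ``tumor_specific`` / ``normal_specific`` — at least ``min_specific_cov``
  passing observations in one condition and none in the other;
* everything else is ``dropped`` with a recorded reason.

Differential editing of a shared site is tested with a two-sided Fisher
exact test on the 2x2 table of pooled read counts (tumor edited/unedited
vs normal edited/unedited), pooled over the samples where the site passes.
No multiplicity correction decides significance (p < 0.05), matching the
study design; a Benjamini-Hochberg adjusted column is emitted alongside.
A differentially edited site (DRE) is a significant shared site or any
condition-specific site.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .calling import EditingMatrix

log = logging.getLogger(__name__)

GROUP_SHARED = "shared"
GROUP_TUMOR = "tumor_specific"
GROUP_NORMAL = "normal_specific"
DROPPED = "dropped"


def classify_groups(
    matrix: EditingMatrix,
    min_shared_cov: int = 10,
    min_specific_cov: int = 4,
    shared_inclusive: bool = True,
) -> pd.DataFrame:
    """Assign every matrix site to shared / tumor_specific / normal_specific / dropped.

    Returns a frame indexed like the matrix with columns ``cov_tumor``,
    ``cov_normal``, ``group`` and ``drop_reason``; group labels partition
    the sites, so the four group counts always sum to ``len(matrix)``.
    """
    cov = matrix.sample_coverage()
    ct, cn = cov["tumor"].to_numpy(), cov["normal"].to_numpy()
    bar = min_shared_cov if shared_inclusive else min_shared_cov + 1
    log.info(
        "group classification: shared coverage >= %d per condition, specific >= %d", bar, min_specific_cov
    )
    group = np.full(len(cov), DROPPED, dtype=object)
    reason = np.full(len(cov), "", dtype=object)
    shared = (ct >= bar) & (cn >= bar)
    tumor = (~shared) & (cn == 0) & (ct >= min_specific_cov)
    normal = (~shared) & (ct == 0) & (cn >= min_specific_cov)
    group[shared] = GROUP_SHARED
    group[tumor] = GROUP_TUMOR
    group[normal] = GROUP_NORMAL
    dropped = group == DROPPED
    reason[dropped & (ct > 0) & (cn > 0)] = "shared_coverage_below_threshold"
    reason[dropped & ((ct == 0) | (cn == 0))] = "specific_coverage_below_threshold"
    reason[dropped & (ct == 0) & (cn == 0)] = "no_passing_observation"
    out = cov.rename(columns={"tumor": "cov_tumor", "normal": "cov_normal"})
    out["group"] = group
    out["drop_reason"] = reason
    return out


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

_REL_EPS = 1e-7  # relative tolerance for pmf ties, as in the classical two-sided rule


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Computed by summing, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding that of the observed table
    (with a small relative tolerance for floating-point ties).  A table with
    a zero margin is degenerate and returns p = 1.
    """
    a, b, c, d = (int(x) for x in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1 + _REL_EPS)].sum())
    return min(p, 1.0)


def fisher_differential(matrix: EditingMatrix, groups: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-site pooled 2x2 Fisher tests (tumor vs normal edited/unedited reads).

    Counts pool over samples with passing observations in each condition.
    Sites whose pooled table has a zero margin are flagged ``degenerate``
    with p = 1.  BH-adjusted q-values are computed over the shared-group
    tests (the only tests that decide DRE membership).
    """
    tum = matrix.condition_samples("tumor")
    nor = matrix.condition_samples("normal")
    edited_t = matrix.alt_count[tum].sum(axis=1, min_count=1).fillna(0).astype(int)
    unedited_t = matrix.ref_count[tum].sum(axis=1, min_count=1).fillna(0).astype(int)
    edited_n = matrix.alt_count[nor].sum(axis=1, min_count=1).fillna(0).astype(int)
    unedited_n = matrix.ref_count[nor].sum(axis=1, min_count=1).fillna(0).astype(int)
    pvals = np.ones(len(matrix.sites))
    degenerate = np.zeros(len(matrix.sites), dtype=bool)
    tables = np.column_stack([edited_t, unedited_t, edited_n, unedited_n])
    for i, (a, b, c, d) in enumerate(tables):
        n = a + b + c + d
        if n == 0 or a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            degenerate[i] = True
            pvals[i] = 1.0
        else:
            pvals[i] = fisher_two_sided(a, b, c, d)
    out = pd.DataFrame(
        {
            "edited_tumor": edited_t,
            "unedited_tumor": unedited_t,
            "edited_normal": edited_n,
            "unedited_normal": unedited_n,
            "mean_level_tumor": matrix.level[tum].mean(axis=1),
            "mean_level_normal": matrix.level[nor].mean(axis=1),
            "fisher_p": pvals,
            "degenerate": degenerate,
        },
        index=matrix.sites.index,
    )
    out["q_bh"] = np.nan
    shared = groups["group"] == GROUP_SHARED
    if shared.any():
        out.loc[shared, "q_bh"] = stats.false_discovery_control(out.loc[shared, "fisher_p"], method="bh")
    out["significant"] = (out["fisher_p"] < alpha) & ~out["degenerate"]
    return out


def build_dre_table(
    matrix: EditingMatrix,
    min_shared_cov: int = 10,
    min_specific_cov: int = 4,
    alpha: float = 0.05,
    shared_inclusive: bool = True,
    known_sites: set | None = None,
) -> pd.DataFrame:
    """Classification + Fisher tests joined into the full DRE table.

    ``is_dre`` marks significant shared sites and all condition-specific
    sites.  ``known`` is filled from an optional user-supplied set of
    (chrom, pos) keys (e.g. a REDIportal export) and is otherwise NA.
    """
    groups = classify_groups(matrix, min_shared_cov, min_specific_cov, shared_inclusive)
    fisher = fisher_differential(matrix, groups, alpha)
    out = pd.concat([matrix.sites, groups, fisher], axis=1)
    out["is_dre"] = (
        ((out["group"] == GROUP_SHARED) & out["significant"])
        | (out["group"] == GROUP_TUMOR)
        | (out["group"] == GROUP_NORMAL)
    )
    if known_sites is None:
        out["known"] = pd.NA
    else:
        out["known"] = [(c, int(p)) in known_sites for c, p in zip(out["chrom"], out["pos"])]
    out["fst"] = np.nan  # filled by the selection scan
    out["fst_raw"] = np.nan
    return out


# ---------------------------------------------------------------------------
# summaries and heatmap
# ---------------------------------------------------------------------------


def summarize_dre(matrix: EditingMatrix, dre_table: pd.DataFrame) -> dict:
    """Per-sample and per-gene DRE summaries with paired tumor/normal t-tests.

    Per sample: mean editing level over observed DREs and DRE count.  Per
    gene: DRE site count per condition.  Paired two-sided t-tests compare
    tumor vs normal per-sample quantities across pairs (df = n_pairs - 1);
    with fewer than two pairs the tests are skipped with a notice.
    """
    dre_ids = dre_table.index[dre_table["is_dre"]]
    level = matrix.level.loc[dre_ids]
    per_sample = pd.DataFrame(
        {
            "mean_level": level.mean(axis=0),
            "dre_count": level.notna().sum(axis=0),
            "condition": matrix.samples["condition"],
            "pair_id": matrix.samples["pair_id"],
        }
    )
    sub = dre_table[dre_table["is_dre"]]
    observed_t = level[matrix.condition_samples("tumor")].notna().any(axis=1)
    observed_n = level[matrix.condition_samples("normal")].notna().any(axis=1)
    per_gene = pd.DataFrame(
        {
            "n_dre": sub.groupby("gene_id").size(),
            "n_dre_tumor": observed_t.groupby(sub["gene_id"]).sum().astype(int),
            "n_dre_normal": observed_n.groupby(sub["gene_id"]).sum().astype(int),
        }
    ).fillna(0)

    tests = {}
    pairs = per_sample.pivot_table(index="pair_id", columns="condition", values="mean_level")
    counts = per_sample.pivot_table(index="pair_id", columns="condition", values="dre_count")
    if len(pairs) < 2 or {"tumor", "normal"} - set(pairs.columns):
        log.info("fewer than two complete pairs: paired t-tests skipped")
    else:
        for name, wide in (("mean_level", pairs), ("dre_count", counts)):
            wide = wide.dropna()
            t = stats.ttest_rel(wide["tumor"], wide["normal"])
            tests[name] = {"t": float(t.statistic), "df": len(wide) - 1, "p": float(t.pvalue)}
    return {"per_sample": per_sample, "per_gene": per_gene, "paired_tests": tests}


def dre_heatmap_matrix(
    matrix: EditingMatrix, dre_table: pd.DataFrame, fill_missing: float | None = None
) -> pd.DataFrame:
    """Editing-level matrix restricted to DREs, for clustering/plotting.

    Missing observations stay missing by default (zero-filling conflates
    "not edited" with "not covered"); pass ``fill_missing=0.0`` to zero-fill.
    """
    hm = matrix.level.loc[dre_table.index[dre_table["is_dre"]]].copy()
    if fill_missing is not None:
        hm = hm.fillna(fill_missing)
    return hm


def heatmap_cluster_purity(heatmap: pd.DataFrame, samples: pd.DataFrame) -> float:
    """Label purity of the leading 2-cluster cut (average linkage, Euclidean)
    of the sample profiles — how well DRE levels separate tumor from normal."""
    if heatmap.empty or heatmap.shape[1] < 2:
        return float("nan")
    data = heatmap.fillna(0.0).to_numpy().T
    labels = fcluster(linkage(data, method="average", metric="euclidean"), 2, criterion="maxclust")
    conditions = samples.loc[heatmap.columns, "condition"].to_numpy()
    correct = 0
    for cluster in (1, 2):
        members = conditions[labels == cluster]
        if len(members):
            correct += max((members == "tumor").sum(), (members == "normal").sum())
    return correct / len(conditions)
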