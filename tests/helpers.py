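"""Shared test utilities: independent oracles and hand-built matrices."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from editscan.calling import EditingMatrix


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by brute-force enumeration with exact-integer
    binomial coefficients (independent of the package implementation)."""
    n = a + b + c + d
    row = a + b
    col = a + c
    if n == 0 or row in (0, n) or col in (0, n):
        return 1.0
    denom = comb(n, col)
    p_obs = comb(row, a) * comb(n - row, col - a) / denom
    total = 0.0
    for x in range(max(0, row + col - n), min(row, col) + 1):
        px = comb(row, x) * comb(n - row, col - x) / denom
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def wc_oracle(freqs1, freqs2) -> float:
    """Weir-Cockerham two-population theta from per-sample frequencies,
    heterozygosity terms dropped: a literal transcription of the published
    variance-component definitions, coded independently."""
    p1s = [float(x) for x in freqs1]
    p2s = [float(x) for x in freqs2]
    n1, n2 = len(p1s), len(p2s)
    r = 2
    p1 = sum(p1s) / n1
    p2 = sum(p2s) / n2
    n_total = n1 + n2
    nbar = n_total / r
    nc = (n_total - (n1**2 + n2**2) / n_total) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / n_total
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = 0.0
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return 0.0 if a == 0 else float("nan")
    return a / denom


def toy_matrix(
    tumor_levels: np.ndarray,
    normal_levels: np.ndarray,
    depth: int = 50,
    site_meta: pd.DataFrame | None = None,
) -> EditingMatrix:
    """Hand-built EditingMatrix from per-site x per-sample level arrays.

    NaN entries mean "no passing observation".  Alt counts are
    round(level*depth), ref counts the remainder.
    """
    tumor_levels = np.atleast_2d(np.asarray(tumor_levels, dtype=float))
    normal_levels = np.atleast_2d(np.asarray(normal_levels, dtype=float))
    n_sites = tumor_levels.shape[0]
    n_t, n_n = tumor_levels.shape[1], normal_levels.shape[1]
    t_ids = [f"T{i + 1:02d}" for i in range(n_t)]
    n_ids = [f"N{i + 1:02d}" for i in range(n_n)]
    samples = pd.DataFrame(
        {
            "condition": ["tumor"] * n_t + ["normal"] * n_n,
            "pair_id": [f"P{i + 1:02d}" for i in range(n_t)] + [f"P{i + 1:02d}" for i in range(n_n)],
        },
        index=pd.Index(t_ids + n_ids, name="sample_id"),
    )
    site_ids = [f"chr1:{1000 + i}" for i in range(n_sites)]
    level = pd.DataFrame(
        np.hstack([tumor_levels, normal_levels]), index=site_ids, columns=t_ids + n_ids
    )
    level.index.name = "site_id"
    alt = np.round(level * depth)
    ref = depth - alt
    depth_df = level.notna() * depth
    depth_df = depth_df.where(level.notna())
    if site_meta is None:
        site_meta = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [1000 + i for i in range(n_sites)],
                "ref": "A",
                "alt": "G",
                "strand": "+",
                "edit_type": "A>G",
                "gene_id": "G001",
                "region": "intronic",
            },
            index=level.index,
        )
    return EditingMatrix(
        sites=site_meta,
        level=level,
        depth=depth_df,
        alt_count=alt,
        ref_count=ref,
        samples=samples,
    )


def site_ids_of(df: pd.DataFrame) -> pd.Series:
    return df["chrom"].astype(str) + ":" + df["pos"].astype(str)
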