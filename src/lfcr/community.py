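"""Alpha/beta diversity and compositional-shift summaries for ASV tables.

Tables are pandas DataFrames with one row per amplicon sequence variant, a
``taxonomy`` column of semicolon-delimited ranks (domain through species),
and one integer count column per sample named ``<community>_<temp>C``
(e.g. ``CF_30C``).  Shannon entropy is reported in nats; Bray-Curtis is
computed on raw counts by default, which equals the proportion-based value
only when read depths match - a normalise-first option covers unequal
depths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts sum to zero")
    return c / total


def shannon(counts) -> float:
    """Shannon diversity H = -sum(p ln p) in nats over non-zero proportions."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson diversity 1 - sum(p^2)."""
    p = _proportions(counts)
    return float(1.0 - (p ** 2).sum())


def bray_curtis(a, b, normalize: bool = False) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b).

    With ``normalize=True`` both vectors are converted to proportions
    first, removing read-depth differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both vectors must have positive totals")
    if normalize:
        a, b = _proportions(a), _proportions(b)
    return float(np.abs(a - b).sum() / (a + b).sum())


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "taxonomy"]


def rank_label(taxonomy: str, rank: str) -> str:
    """Rank label from a semicolon-delimited taxonomy string, or 'unclassified'."""
    idx = RANKS.index(rank)
    parts = [p.strip() for p in str(taxonomy).split(";")]
    if idx < len(parts) and parts[idx]:
        return parts[idx]
    return "unclassified"


def aggregate_rank(table: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Relative abundances summed at a taxonomic rank; columns sum to one."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    cols = sample_columns(table)
    if table.empty or not cols:
        raise ValueError("empty abundance table")
    labels = table["taxonomy"].map(lambda t: rank_label(t, rank))
    summed = table[cols].groupby(labels).sum()
    totals = summed.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total count")
    return summed / totals


def alpha_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format Shannon and Simpson diversity per sample."""
    rows = []
    for col in sample_columns(table):
        counts = table[col].to_numpy()
        rows.append({"sample": col, "metric": "shannon", "value": shannon(counts)})
        rows.append({"sample": col, "metric": "simpson", "value": simpson(counts)})
    return pd.DataFrame(rows)


def beta_table(table: pd.DataFrame, normalize: bool = False) -> pd.DataFrame:
    """Long-format pairwise Bray-Curtis dissimilarities between samples."""
    cols = sample_columns(table)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rows.append({"sample_a": a, "sample_b": b,
                         "bray_curtis": bray_curtis(table[a], table[b], normalize)})
    return pd.DataFrame(rows)


def shift_table(table: pd.DataFrame, warm_c: float = 30.0, cold_c: float = 10.0,
                min_abundance: float = 0.01, rank: str | None = None) -> pd.DataFrame:
    """Per-taxon change in relative abundance between two temperatures.

    For every community with samples at both temperatures, the delta is
    relabund(cold) - relabund(warm); taxa whose relative abundance stays
    below ``min_abundance`` in both conditions are dropped (the usual >= 1%
    display convention).  Optionally aggregates to a taxonomic rank first.
    """
    cols = sample_columns(table)
    if rank is not None:
        rel = aggregate_rank(table, rank)
    else:
        counts = table[cols]
        rel = counts / counts.sum(axis=0)
        rel.index = table.index
    suffix_w = f"_{warm_c:g}C"
    suffix_c = f"_{cold_c:g}C"
    communities = sorted({c[: -len(suffix_w)] for c in cols if c.endswith(suffix_w)})
    rows = []
    for community in communities:
        warm_col, cold_col = community + suffix_w, community + suffix_c
        if cold_col not in rel.columns:
            raise KeyError(f"missing sample {cold_col!r} for community {community!r}")
        for taxon in rel.index:
            r_w, r_c = rel.at[taxon, warm_col], rel.at[taxon, cold_col]
            if max(r_w, r_c) < min_abundance:
                continue
            rows.append({"community": community, "taxon": taxon,
                         "relabund_warm": r_w, "relabund_cold": r_c,
                         "delta": r_c - r_w})
    return pd.DataFrame(rows, columns=["community", "taxon", "relabund_warm",
                                       "relabund_cold", "delta"])
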