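"""Reference-ordered metric series and the 101-gene sliding-window landscape.

A landscape is a per-gene metric (GC%, GARP%, divergence …) arranged by the
gene's position in one reference genome and smoothed with a centered
window of a gene plus its 100 neighbors (50 each side, half-width w = 50),
sliding one gene at a time. Windows are truncated at the ends of the
ordered set (the mean runs over the available neighbors), and genes with
missing values are removed before windowing, so each window averages the
nearest *available* neighbors — every species is smoothed over the genes
it actually possesses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_HALF_WIDTH = 50


@dataclass
class ReferenceOrder:
    """The linear ranking of genes by position in one reference genome."""

    frame: pd.DataFrame  # columns: gene_symbol, chromosome, rank, midpoint

    @classmethod
    def from_species_table(cls, table, chromosome_order: list[str] | None = None) -> "ReferenceOrder":
        rows = [
            {
                "gene_symbol": r.gene_symbol,
                "chromosome": r.chromosome,
                "midpoint": (r.start + r.end) / 2.0,
            }
            for r in table.records
        ]
        df = pd.DataFrame(rows)
        if chromosome_order is None:
            chromosome_order = _natural_chromosome_order(df["chromosome"].unique())
        chrom_rank = {c: i for i, c in enumerate(chromosome_order)}
        df["_c"] = df["chromosome"].map(chrom_rank)
        if df["_c"].isna().any():
            bad = sorted(df.loc[df["_c"].isna(), "chromosome"].unique())
            raise ValueError(f"chromosomes missing from chromosome_order: {bad}")
        df = df.sort_values(["_c", "midpoint", "gene_symbol"], kind="mergesort")
        df = df.drop(columns="_c").reset_index(drop=True)
        df.insert(2, "rank", np.arange(1, len(df) + 1))
        return cls(frame=df)

    @property
    def symbols(self) -> list[str]:
        return self.frame["gene_symbol"].tolist()

    def rank_of(self) -> pd.Series:
        return pd.Series(
            self.frame["rank"].values, index=self.frame["gene_symbol"].values
        )

    def __len__(self) -> int:
        return len(self.frame)


def _natural_chromosome_order(names) -> list[str]:
    def key(name: str):
        s = str(name)
        digits = "".join(c for c in s if c.isdigit())
        return (0, int(digits)) if digits else (1, s)

    return sorted(map(str, names), key=key)


def order_genes(series: pd.Series, order: ReferenceOrder, drop_missing: bool = True) -> pd.DataFrame:
    """Arrange a gene-keyed metric series by reference rank.

    Returns a frame (gene_symbol, chromosome, rank, midpoint, value) sorted
    by rank; genes with NaN values are removed when ``drop_missing`` (the
    default, required before windowing). Keys absent from the reference
    order raise.
    """
    extra = sorted(set(series.index) - set(order.symbols))
    if extra:
        raise KeyError(f"genes absent from reference order: {extra[:10]}")
    df = order.frame.merge(
        series.rename("value"), left_on="gene_symbol", right_index=True, how="inner"
    )
    if drop_missing:
        df = df.dropna(subset=["value"])
    return df.sort_values("rank", kind="mergesort").reset_index(drop=True)


def sliding_window(values, w: int = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """Centered running mean over positions max(1, k−w)..min(n, k+w).

    Interior windows contain exactly 2w+1 values; end windows are
    truncated to the available range.
    """
    if w < 0:
        raise ValueError("window half-width must be ≥ 0")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window=2 * w + 1, center=True, min_periods=1).mean().to_numpy()


def smooth_landscape(
    series: pd.Series, order: ReferenceOrder, w: int = DEFAULT_HALF_WIDTH
) -> pd.DataFrame:
    """Order a metric series on the reference genome and smooth it.

    Returns the landscape table: gene_symbol, rank, chromosome, midpoint,
    raw_value, smoothed_value.
    """
    df = order_genes(series, order)
    df = df.rename(columns={"value": "raw_value"})
    df["smoothed_value"] = sliding_window(df["raw_value"].to_numpy(), w=w)
    return df[["gene_symbol", "rank", "chromosome", "midpoint", "raw_value", "smoothed_value"]]


def landscape_correlation(
    a: pd.Series,
    b: pd.Series,
    order: ReferenceOrder,
    w: int = DEFAULT_HALF_WIDTH,
    smoothed: bool = True,
) -> tuple[float, int]:
    """Pearson correlation between two landscapes on their common genes.

    The two series are restricted to genes with values in both, arranged on
    the shared reference order, window-smoothed (unless ``smoothed=False``,
    the per-gene mode), and correlated. Returns (r, n_common); r is NaN
    when fewer than 3 genes are shared or either side has zero variance.
    """
    common = a.dropna().index.intersection(b.dropna().index)
    if len(common) < 3:
        return float("nan"), len(common)
    df_a = order_genes(a.loc[common], order)
    va = df_a["value"].to_numpy()
    vb = b.loc[df_a["gene_symbol"]].to_numpy(dtype=float)
    if smoothed:
        va = sliding_window(va, w=w)
        vb = sliding_window(vb, w=w)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return float("nan"), len(common)
    r, _ = stats.pearsonr(va, vb)
    return float(r), len(common)


def landscape_axis(landscape: pd.DataFrame, mode: str = "rank") -> pd.DataFrame:
    """Attach a plotting axis to a landscape table.

    ``rank`` mode: x is the reference rank. ``physical`` mode: x is the
    gene midpoint offset onto a single concatenated coordinate axis, with
    chromosomes laid end to end; a boolean ``chromosome_start`` column
    marks the first gene of each chromosome.
    """
    df = landscape.copy()
    if mode == "rank":
        df["x"] = df["rank"]
    elif mode == "physical":
        if "midpoint" not in df.columns or df["midpoint"].isna().any():
            raise ValueError("physical axis mode requires midpoint coordinates")
        offset = 0.0
        xs = np.empty(len(df), dtype=float)
        for chrom, sub in df.groupby("chromosome", sort=False):
            xs[df["chromosome"] == chrom] = sub["midpoint"].to_numpy() + offset
            offset += float(sub["midpoint"].max())
        df["x"] = xs
    else:
        raise ValueError(f"unknown axis mode {mode!r}")
    df["chromosome_start"] = ~df["chromosome"].eq(df["chromosome"].shift())
    return df
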