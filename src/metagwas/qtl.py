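"""Post-processing of meta-GWAS hits: QTL windows and plot tables.

Significant SNPs are grouped into QTL by single-linkage chaining within a
trait and chromosome: position-sorted hits join one cluster whenever
consecutive hits are at most ``window_bp`` apart, so a run of hits spaced
just under the window chains into a single interval.  The Manhattan and QQ
tables are plain DataFrames ready for any plotting front end; a thin
matplotlib renderer is provided for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataFormatError

__all__ = [
    "QTLCluster",
    "cluster_qtl",
    "clusters_to_frame",
    "manhattan_table",
    "qq_table",
    "plot_manhattan",
    "plot_qq",
]


@dataclass
class QTLCluster:
    """A chromosome interval grouping significant SNPs for one trait."""

    qtl_id: str
    trait: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str] = field(default_factory=list)
    top_snp: str = ""
    top_neglog10p: float = np.nan

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def cluster_qtl(hits: pd.DataFrame, window_bp: int = 1_000_000) -> list[QTLCluster]:
    """Single-linkage chaining of hits into QTL per (trait, chromosome).

    ``hits`` needs columns snp_id, trait, chrom, pos, neglog10p.  Rows with a
    missing position raise.  QTL ids are assigned in (trait, chrom, start)
    order as QTL001, QTL002, ...
    """
    required = ["snp_id", "trait", "chrom", "pos", "neglog10p"]
    missing = [c for c in required if c not in hits.columns]
    if missing:
        raise DataFormatError(f"hits table lacks columns {missing}")
    if hits["pos"].isna().any():
        bad = hits.loc[hits["pos"].isna(), "snp_id"].tolist()
        raise DataFormatError(f"hits without map position: {bad[:5]}")
    clusters: list[QTLCluster] = []
    for (trait, chrom), grp in hits.groupby(["trait", "chrom"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window_bp)
        bounds = np.concatenate([[0], breaks + 1, [len(grp)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = grp.iloc[int(a):int(b)]
            top = members.loc[members["neglog10p"].idxmax()]
            clusters.append(
                QTLCluster(
                    qtl_id="",
                    trait=str(trait),
                    chrom=str(chrom),
                    start=int(members["pos"].min()),
                    end=int(members["pos"].max()),
                    snp_ids=members["snp_id"].astype(str).tolist(),
                    top_snp=str(top["snp_id"]),
                    top_neglog10p=float(top["neglog10p"]),
                )
            )
    clusters.sort(key=lambda c: (c.trait, c.chrom, c.start))
    for i, c in enumerate(clusters, start=1):
        c.qtl_id = f"QTL{i:03d}"
    return clusters


def clusters_to_frame(clusters: list[QTLCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "qtl_id": c.qtl_id, "trait": c.trait, "chrom": c.chrom,
                "start": c.start, "end": c.end, "n_snps": c.n_snps,
                "top_snp": c.top_snp, "top_neglog10p": c.top_neglog10p,
            }
            for c in clusters
        ]
    )


def manhattan_table(results: pd.DataFrame,
                    chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Rows (chrom, pos, cumulative genome coordinate, -log10 p, class).

    Cumulative offsets are running chromosome lengths; when lengths are not
    supplied the maximum observed position per chromosome is used.  Output is
    sorted by the cumulative coordinate.
    """
    required = ["chrom", "pos", "neglog10p"]
    missing = [c for c in required if c not in results.columns]
    if missing:
        raise DataFormatError(f"results table lacks columns {missing}")
    out = results.copy()
    if len(out) == 0:
        out["cum_pos"] = pd.Series(dtype=float)
        return out
    if chrom_lengths is None:
        chrom_lengths = out.groupby("chrom")["pos"].max().to_dict()
    offset, offsets = 0, {}
    for chrom in sorted(chrom_lengths):
        offsets[chrom] = offset
        offset += int(chrom_lengths[chrom])
    out["cum_pos"] = out["pos"] + out["chrom"].map(offsets)
    cols = ["chrom", "pos", "cum_pos", "neglog10p"]
    if "class" in out.columns:
        cols.append("class")
    return out[cols].sort_values("cum_pos").reset_index()


def qq_table(results: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Observed vs expected -log10 p plus the genomic inflation factor.

    Expected quantiles are ``-log10((i - 0.5) / m)``.  Zero p-values are
    clamped to the smallest positive float (flagged in the ``clamped``
    column).  Lambda-GC is median observed chi-square over the median of the
    reference chi-square at the modal df; when the table carries no
    chi2/df columns the chi-square is reconstructed from p at 1 df.
    """
    p = results["p"].dropna().to_numpy(dtype=float)
    m = len(p)
    if m < 1:
        raise DataFormatError("qq_table needs at least one p-value")
    clamped = p <= 0.0
    p = np.where(clamped, np.nextafter(0.0, 1.0), p)
    order = np.argsort(p)
    table = pd.DataFrame(
        {
            "observed_neglog10p": -np.log10(p[order]),
            "expected_neglog10p": -np.log10((np.arange(1, m + 1) - 0.5) / m),
            "clamped": clamped[order],
        }
    )
    if "chi2" in results.columns and "df" in results.columns:
        ok = results["chi2"].notna()
        chi2 = results.loc[ok, "chi2"].to_numpy()
        modal_df = int(results.loc[ok, "df"].mode().iloc[0])
    else:
        chi2 = stats.chi2.isf(p, df=1)
        modal_df = 1
    lambda_gc = float(np.median(chi2) / stats.chi2.ppf(0.5, df=modal_df))
    return table, lambda_gc


def plot_manhattan(table: pd.DataFrame, threshold: float | None = None,
                   path: str | None = None):
    """Render a Manhattan plot from :func:`manhattan_table` output."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    for i, (chrom, grp) in enumerate(table.groupby("chrom", sort=True)):
        ax.scatter(grp["cum_pos"], grp["neglog10p"], s=6,
                   color=["#30508c", "#7aa0d4"][i % 2], label=None)
    if threshold is not None:
        ax.axhline(threshold, color="red", ls="--", lw=0.8)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_qq(table: pd.DataFrame, lambda_gc: float | None = None,
            path: str | None = None):
    """Render a QQ plot from :func:`qq_table` output."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.8, 3.8))
    ax.scatter(table["expected_neglog10p"], table["observed_neglog10p"], s=6)
    lim = max(table["expected_neglog10p"].max(), table["observed_neglog10p"].max())
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    if lambda_gc is not None:
        ax.set_title(rf"$\lambda_{{GC}}$ = {lambda_gc:.3f}", fontsize=9)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
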