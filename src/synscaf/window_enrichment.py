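"""Fixed-window scans for over-represented functional gene categories.

Chromosomes are tiled into non-overlapping windows (default 0.5 Mb, last
window truncated).  For each (window, category) with at least one member a
one-sided Fisher exact test (hypergeometric upper tail) asks whether the
category is over-represented among the window's genes relative to the
genome, and p-values are adjusted across all tested pairs jointly with the
Bonferroni–Holm step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["Window", "EnrichmentResult", "make_windows", "enrich", "plot_significance_grid"]


@dataclass(frozen=True)
class Window:
    chromosome: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must be < end")


@dataclass(frozen=True)
class EnrichmentResult:
    window: Window
    category: str
    k: int  # category genes in window
    n: int  # genes in window
    K: int  # category genes genome-wide
    N: int  # genes genome-wide
    p: float
    p_adj: float


def make_windows(chrom_lengths: Mapping[str, int], size: int = 500_000) -> list[Window]:
    """ceil(L/size) windows per chromosome, the last truncated at L."""
    if size <= 0:
        raise ValueError("window size must be > 0")
    windows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom} has length < 1")
        for s in range(0, length, size):
            windows.append(Window(chrom, s, min(s + size, length)))
    return windows


def enrich(
    genes: Iterable[tuple[str, str, int, Sequence[str]]],
    windows: Sequence[Window],
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Test every (window, category) pair with >= 1 member gene.

    ``genes`` yields (gene_id, chromosome, start, categories); a gene belongs
    to the window containing its start.  The 2x2 table per pair is
    (k, n-k, K-k, N-n-K+k); p is the one-sided (enrichment) Fisher tail by
    default, switchable to "two-sided".  Holm adjustment spans all tested
    pairs as one family.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    win_index: dict[str, list[Window]] = {}
    for w in windows:
        win_index.setdefault(w.chromosome, []).append(w)
    for ws in win_index.values():
        ws.sort(key=lambda w: w.start)

    gene_window: dict[int, Window] = {}
    gene_cats: list[Sequence[str]] = []
    N = 0
    K: dict[str, int] = {}
    n_in: dict[Window, int] = {}
    k_in: dict[tuple[Window, str], int] = {}
    for gene_id, chrom, start, cats in genes:
        ws = win_index.get(chrom, [])
        window = None
        for w in ws:  # windows tile the chromosome; linear scan via bisect-able list
            if w.start <= start < w.end:
                window = w
                break
        if window is None:
            raise ValueError(f"gene {gene_id} at {chrom}:{start} outside all windows")
        N += 1
        n_in[window] = n_in.get(window, 0) + 1
        for c in cats:
            K[c] = K.get(c, 0) + 1
            k_in[(window, c)] = k_in.get((window, c), 0) + 1

    pairs = sorted(k_in, key=lambda t: (t[0].chromosome, t[0].start, t[1]))
    pvals = []
    for window, cat in pairs:
        k = k_in[(window, cat)]
        n = n_in[window]
        KK = K[cat]
        if alternative == "greater":
            p = float(hypergeom.sf(k - 1, N, KK, n))
        else:
            from scipy.stats import fisher_exact

            p = float(
                fisher_exact([[k, n - k], [KK - k, N - n - KK + k]], alternative="two-sided")[1]
            )
        pvals.append(min(1.0, p))
    if pvals:
        _, p_adj, _, _ = multipletests(pvals, method="holm")
    else:
        p_adj = np.array([])
    return [
        EnrichmentResult(
            window=w,
            category=c,
            k=k_in[(w, c)],
            n=n_in[w],
            K=K[c],
            N=N,
            p=p,
            p_adj=float(pa),
        )
        for (w, c), p, pa in zip(pairs, pvals, p_adj)
    ]


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.window.chromosome,
                r.window.start,
                r.window.end,
                r.category,
                r.k,
                r.n,
                r.K,
                r.N,
                r.p,
                r.p_adj,
            )
            for r in results
        ],
        columns=["chromosome", "start", "end", "category", "k", "n", "K", "N", "p", "p_adj"],
    )


def plot_significance_grid(
    results: Sequence[EnrichmentResult],
    windows: Sequence[Window],
    path: str | Path,
    alpha: float = 0.05,
) -> None:
    """Category x window grid of adjusted significance (darker = smaller p_adj)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = sorted({r.category for r in results})
    wkeys = [(w.chromosome, w.start) for w in sorted(windows, key=lambda w: (w.chromosome, w.start))]
    widx = {k: i for i, k in enumerate(wkeys)}
    cidx = {c: i for i, c in enumerate(cats)}
    grid = np.zeros((len(cats), len(wkeys)))
    for r in results:
        level = 0.0
        if r.p_adj <= alpha:
            level = 1.0
        if r.p_adj <= 0.01:
            level = 2.0
        if r.p_adj <= 0.001:
            level = 3.0
        grid[cidx[r.category], widx[(r.window.chromosome, r.window.start)]] = level
    fig, ax = plt.subplots(figsize=(10, max(2, 0.3 * len(cats))))
    ax.imshow(grid, aspect="auto", cmap="Reds", vmin=0, vmax=3)
    ax.set_yticks(range(len(cats)), cats)
    ax.set_xlabel("genomic window")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
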