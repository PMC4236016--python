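"""Theoretical vs experimental connectivity heatmaps.

The theoretical prediction for pattern alpha is the symmetric matrix whose
ij element is the signed product ``G_i,alpha * G_j,alpha``: two stable
transcripts (both G_i0 negative) give a positive product, a stable and a
deviating one an anti-correlated negative product.  Placed next to the
STRING combined-score heatmap over the *same genes in the same order*,
the block structure of the two maps can be compared directly — the
qualitative observation being that the most stable transcripts are also
the most functionally connected.

The pairing contract is strict: both heatmaps share one ordered gene
axis.  Missing connectivity cells (white dots) are excluded from any
correlation.  A rank correlation is used by default because the two
scales — dimensionless products vs probabilities — are incomparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import NA_TOKEN, ConnectivityMatrix
from .decomposition import SurprisalDecomposition
from .profiling import GeneSelection

__all__ = [
    "Heatmap",
    "HeatmapPair",
    "CellInfo",
    "product_heatmap",
    "connectivity_heatmap",
    "pair_heatmaps",
    "cell_info",
    "stability_scatter",
    "correlate_heatmaps",
    "render_heatmap_pair",
    "render_stability_scatter",
]


@dataclass(frozen=True)
class Heatmap:
    """A square symmetric matrix over one ordered gene axis.

    ``source`` tags provenance: ``theoretical`` (G-product) or
    ``string_db`` (combined scores, which may have missing cells).
    """

    gene_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    source: Literal["theoretical", "string_db"] = "theoretical"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.gene_names)
        if values.shape != (n, n):
            raise ValueError(f"heatmap shape {values.shape} does not match {n} genes")
        if not np.array_equal(values, values.T, equal_nan=True):
            raise ValueError("heatmap must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def save(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.values, index=list(self.gene_names), columns=list(self.gene_names)
        )
        frame.index.name = f"Gene:{self.source}"
        frame.to_csv(path, sep="\t", na_rep=NA_TOKEN)

    @classmethod
    def load(cls, path: str | Path) -> "Heatmap":
        frame = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[NA_TOKEN],
            float_precision="round_trip",
        )
        tag = str(frame.index.name or "")
        source = "string_db" if tag.endswith("string_db") else "theoretical"
        return cls(tuple(str(g) for g in frame.index), frame.to_numpy(dtype=float), source)


@dataclass(frozen=True)
class HeatmapPair:
    """A theoretical and an experimental heatmap on one shared gene axis."""

    theoretical: Heatmap
    experimental: Heatmap

    def __post_init__(self) -> None:
        if self.theoretical.gene_names != self.experimental.gene_names:
            raise ValueError("paired heatmaps must share an identical ordered gene axis")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return self.theoretical.gene_names


class CellInfo(NamedTuple):
    """The two crossing genes of a heatmap cell and its value (None = missing)."""

    gene_row: str
    gene_col: str
    value: float | None


def product_heatmap(
    d: SurprisalDecomposition,
    alpha: int,
    sel: GeneSelection | list[str] | tuple[str, ...],
) -> Heatmap:
    """Theoretical connectivity heatmap M_ij = G_i,alpha * G_j,alpha.

    The axis is the selection in its own order (for combined selections:
    stable block first, then the deviating block, reproducing the paired
    block structure).  Signed products are kept — sign encodes correlation
    vs anti-correlation within the pattern.
    """
    d._check_alpha(alpha)
    genes = list(sel.gene_names) if isinstance(sel, GeneSelection) else list(sel)
    index = {g: i for i, g in enumerate(d.gene_names)}
    missing = [g for g in genes if g not in index]
    if missing:
        raise KeyError(f"genes not in decomposition: {missing[:5]}")
    g = d.G[[index[x] for x in genes], alpha]
    return Heatmap(tuple(genes), np.outer(g, g), source="theoretical")


def connectivity_heatmap(c: ConnectivityMatrix) -> Heatmap:
    """Wrap a connectivity matrix as an experimental heatmap."""
    return Heatmap(c.gene_names, c.values, source="string_db")


def pair_heatmaps(theory: Heatmap, conn: ConnectivityMatrix | Heatmap) -> HeatmapPair:
    """Pair a theoretical heatmap with connectivity data on identical axes.

    The connectivity matrix is re-indexed to the theoretical gene order;
    the gene *sets* must match exactly.
    """
    exp = connectivity_heatmap(conn) if isinstance(conn, ConnectivityMatrix) else conn
    if set(theory.gene_names) != set(exp.gene_names):
        only_t = sorted(set(theory.gene_names) - set(exp.gene_names))
        only_e = sorted(set(exp.gene_names) - set(theory.gene_names))
        raise ValueError(
            f"gene sets differ; only in theoretical: {only_t[:5]}, only in experimental: {only_e[:5]}"
        )
    if exp.gene_names != theory.gene_names:
        pos = {g: i for i, g in enumerate(exp.gene_names)}
        perm = [pos[g] for g in theory.gene_names]
        exp = Heatmap(theory.gene_names, exp.values[np.ix_(perm, perm)], exp.source)
    return HeatmapPair(theoretical=theory, experimental=exp)


def cell_info(h: Heatmap, i: str, j: str) -> CellInfo:
    """Zoom in on one cell: the two crossing genes and the stored value."""
    index = {g: k for k, g in enumerate(h.gene_names)}
    for name in (i, j):
        if name not in index:
            raise KeyError(f"gene {name!r} not on the heatmap axis")
    v = h.values[index[i], index[j]]
    return CellInfo(i, j, None if math.isnan(v) else float(v))


class ScatterPoint(NamedTuple):
    gene: str
    g0: float
    g1: float


def stability_scatter(d: SurprisalDecomposition) -> list[ScatterPoint]:
    """Per-gene (G_i0, G_i1) points: steady-state weight vs participation in
    the main transformation pattern.

    Stable transcripts sit at large |G_i0| with G_i1 near zero — large
    steady-state weight, little involvement in the transformation; the
    deviating transcripts show the opposite signature.
    """
    if d.n_patterns < 2:
        raise ValueError("stability scatter needs at least two patterns (t >= 2)")
    return [
        ScatterPoint(g, float(a), float(b))
        for g, a, b in zip(d.gene_names, d.G[:, 0], d.G[:, 1])
    ]


def correlate_heatmaps(
    p: HeatmapPair, method: Literal["spearman", "pearson"] = "spearman"
) -> tuple[float, int]:
    """Correlation between the paired heatmaps over shared informative cells.

    Uses the upper-triangle off-diagonal cells where both maps carry a
    value; missing connectivity cells are excluded.  Returns the
    correlation and the number of cells used.  Rank correlation is the
    default since product values and probabilities live on incomparable
    scales.
    """
    n = p.theoretical.n_genes
    iu = np.triu_indices(n, k=1)
    a = p.theoretical.values[iu]
    b = p.experimental.values[iu]
    mask = ~np.isnan(a) & ~np.isnan(b)
    n_cells = int(mask.sum())
    if n_cells < 3:
        raise ValueError(f"need >= 3 mutually non-missing off-diagonal cells, have {n_cells}")
    if method == "spearman":
        rho = stats.spearmanr(a[mask], b[mask]).statistic
    elif method == "pearson":
        rho = stats.pearsonr(a[mask], b[mask]).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), n_cells


# -- rendering ---------------------------------------------------------


def render_heatmap_pair(p: HeatmapPair, path: str | Path, *, title: str = "") -> None:
    """Side-by-side render: diverging scale centred on zero for the signed
    products, sequential scale for probabilities, missing cells in white."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, axes = plt.subplots(1, 2, figsize=(12, 5.5))
    vmax = np.nanmax(np.abs(p.theoretical.values)) or 1.0
    sns.heatmap(
        p.theoretical.values, ax=axes[0], cmap="RdBu_r", vmin=-vmax, vmax=vmax,
        square=True, xticklabels=False, yticklabels=False,
        cbar_kws={"label": "G product"},
    )
    axes[0].set_title("Theoretical (G products)")
    sns.heatmap(
        p.experimental.values, ax=axes[1], cmap="Reds", vmin=0, vmax=1,
        square=True, xticklabels=False, yticklabels=False,
        cbar_kws={"label": "combined score"},
    )
    axes[1].set_facecolor("white")
    axes[1].set_title("STRING combined scores")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_stability_scatter(
    points: list[ScatterPoint], path: str | Path, *, title: str = ""
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter([p.g0 for p in points], [p.g1 for p in points], s=6, alpha=0.5)
    ax.set_xlabel(r"$G_{i0}$ (steady-state weight)")
    ax.set_ylabel(r"$G_{i1}$ (transformation pattern weight)")
    ax.axhline(0.0, color="grey", lw=0.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
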