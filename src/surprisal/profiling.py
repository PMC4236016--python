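"""Gene profiling: sorting participation weights and selecting sub-sets.

After the decomposition, each transcription pattern alpha assigns every
gene a participation weight G_i,alpha.  Profiling sorts those weights in
decreasing order and carves out the genes of interest — either by value
bounds (an upper bound for the high tail, a lower bound for the low tail)
or by extremes (e.g. the 100 most stable genes, i.e. the 100 most
negative G_i0).  Selections record their parameters so any downstream
heatmap can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from .decomposition import SurprisalDecomposition

__all__ = [
    "SortedProfile",
    "GeneSelection",
    "sort_pattern",
    "select_by_bounds",
    "select_extremes",
]

SelectionMode = Literal["most_negative", "most_positive", "largest_magnitude"]


@dataclass(frozen=True)
class SortedProfile:
    """Participation weights of one pattern, sorted in decreasing order.

    Ties are broken by gene name ascending, so the profile is a
    deterministic function of the decomposition.
    """

    pattern_index: int
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        values = [v for _, v in self.entries]
        if any(a < b for a, b in zip(values, values[1:])):
            raise ValueError("profile entries must be non-increasing")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.entries)


@dataclass(frozen=True)
class GeneSelection:
    """An ordered gene subset for one pattern, with its defining parameters.

    ``role`` records what the subset means (``stable``, ``deviating_high``,
    ``deviating_low`` or ``bounds``); ``params`` records the n or bounds
    that produced it, so the selection is reproducible.
    """

    pattern_index: int
    role: str
    genes: tuple[tuple[str, float], ...]
    params: tuple[tuple[str, float | str], ...] = ()

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def save(self, path: str | Path, *, with_values: bool = False) -> None:
        """Plain-text gene list (one name per line), or a TSV with values
        and selection parameters when ``with_values`` is set."""
        path = Path(path)
        if with_values:
            header = "# " + "; ".join(
                [f"pattern={self.pattern_index}", f"role={self.role}"]
                + [f"{k}={v}" for k, v in self.params]
            )
            frame = pd.DataFrame(list(self.genes), columns=["Gene", f"G{self.pattern_index}"])
            with path.open("w", encoding="utf-8") as fh:
                fh.write(header + "\n")
                frame.to_csv(fh, sep="\t", index=False)
        else:
            path.write_text("".join(f"{g}\n" for g in self.gene_names), encoding="utf-8")


def sort_pattern(d: SurprisalDecomposition, alpha: int) -> SortedProfile:
    """Sort G[:, alpha] in decreasing order (gene-name tiebreak)."""
    d._check_alpha(alpha)
    weights = d.pattern_weights(alpha)
    order = sorted(
        zip(d.gene_names, weights.tolist()), key=lambda gv: (-gv[1], gv[0])
    )
    return SortedProfile(pattern_index=alpha, entries=tuple(order))


def select_by_bounds(
    p: SortedProfile,
    upper: float,
    lower: float,
    *,
    inclusive: bool = False,
) -> tuple[GeneSelection, GeneSelection]:
    """Split a profile into the genes strictly above ``upper`` and strictly
    below ``lower`` (the two horizontal cut lines of the profile plot).

    Returns ``(high, low)`` selections in profile order.  Strict
    inequalities by default; ``inclusive`` admits genes exactly on a bound.
    """
    if upper < lower:
        raise ValueError(f"upper bound {upper} below lower bound {lower}")
    if inclusive:
        high = [(g, v) for g, v in p.entries if v >= upper]
        low = [(g, v) for g, v in p.entries if v <= lower]
    else:
        high = [(g, v) for g, v in p.entries if v > upper]
        low = [(g, v) for g, v in p.entries if v < lower]
    params = (("upper", float(upper)), ("lower", float(lower)))
    return (
        GeneSelection(p.pattern_index, "deviating_high", tuple(high), params),
        GeneSelection(p.pattern_index, "deviating_low", tuple(low), params),
    )


def select_extremes(
    d: SurprisalDecomposition,
    alpha: int,
    n: int,
    mode: SelectionMode = "most_negative",
) -> GeneSelection:
    """The n genes extreme in G[:, alpha] in the requested sense.

    ``most_negative`` on pattern 0 yields the most stable transcripts (the
    steady-state convention puts the most stable genes at the lowest G_i0);
    ``most_positive`` on a deviation pattern yields the genes contributing
    most, up-regulated; ``largest_magnitude`` ranks by |G|.  Deterministic
    under ties via the gene-name tiebreak.
    """
    d._check_alpha(alpha)
    if not 1 <= n <= d.n_genes:
        raise ValueError(f"n={n} out of range 1..{d.n_genes}")
    pairs = list(zip(d.gene_names, d.pattern_weights(alpha).tolist()))
    if mode == "most_negative":
        key = lambda gv: (gv[1], gv[0])
        role = "stable" if alpha == 0 else "deviating_low"
    elif mode == "most_positive":
        key = lambda gv: (-gv[1], gv[0])
        role = "deviating_high"
    elif mode == "largest_magnitude":
        key = lambda gv: (-abs(gv[1]), gv[0])
        role = "largest_magnitude"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    chosen = sorted(pairs, key=key)[:n]
    return GeneSelection(
        alpha, role, tuple(chosen), params=(("n", float(n)),) + (("mode", mode),)
    )
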