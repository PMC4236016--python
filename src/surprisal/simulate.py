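"""Synthetic expression matrices with planted surprisal structure.

The generator emulates a transformation time course at the scale of the
HPV16-keratinocyte study (thousands of genes, four stages): a dominant
steady-state log-component shared by all genes, one planted deviation
pattern carried by a designated group of transforming genes, and
multiplicative (log-additive Gaussian) noise.  The log matrix is built
directly in the model's own terms::

    ln X_i(T) = G_i0 * lam0(T) + G_i1 * lam1(T) + eps_i(T)

with orthonormal planted G columns, lam0 nearly constant across stages
(the balanced state persists through the whole course) and lam1 a
monotone ramp (progressive transformation).  A matching STRING-dialect
links fixture plants a dense high-score block on the stable genes so the
whole pipeline — decomposition, profiling, connectivity, paired heatmaps
— is testable without any download.

Defaults: 2000 genes x 4 stages; 100 planted-stable and 100 planted-
deviating genes (the sizes of the gene groups selected in practice);
deviation amplitude 1.5 log units (about a 4.5-fold change at the final
stage, a strong but realistic transformation effect); noise sd 0.05 log
units.  What the generator does *not* emulate: probe-level artifacts,
detection calls, batch effects, or heavy-tailed biological noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression import ExpressionMatrix

__all__ = ["PlantedTruth", "generate_planted_dataset", "generate_links_fixture"]

MEAN_LOG_LEVEL = 6.0  # ln signal ~ e^6 ~ 400, a typical scaled chip intensity


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted dataset.

    ``G_true`` holds the two orthonormal planted gene-weight columns
    (steady state, deviation); ``lam_true`` the corresponding 2 x t
    multiplier profiles; ``labels`` assigns each gene one of ``stable``,
    ``deviating`` or ``background``.  Stable and background genes carry
    exactly zero deviation weight.
    """

    G_true: np.ndarray = field(repr=False)
    lam_true: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    noise_sd: float
    seed: int

    @property
    def stable_genes(self) -> tuple[int, ...]:
        return tuple(i for i, l in enumerate(self.labels) if l == "stable")

    @property
    def deviating_genes(self) -> tuple[int, ...]:
        return tuple(i for i, l in enumerate(self.labels) if l == "deviating")


def generate_planted_dataset(
    m: int = 2000,
    t: int = 4,
    n_stable: int = 100,
    n_deviating: int = 100,
    deviation_amplitude: float = 1.5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a positive expression matrix with planted patterns.

    Parameters
    ----------
    m, t
        Genes and conditions (stages); ``m >= t >= 2``.
    n_stable, n_deviating
        Sizes of the planted groups; stable genes get the largest
        steady-state weights, deviating genes carry the whole deviation
        pattern (half up-, half down-regulated).
    deviation_amplitude
        Log-fold contribution of the deviation pattern for the typical
        (root-mean-square) deviating gene at the final stage, in
        natural-log units.
    noise_sd
        Standard deviation of the i.i.d. additive log noise
        (multiplicative on the expression scale).
    seed
        Mandatory reproducibility seed; recorded in the returned truth.
    """
    if t < 2:
        raise ValueError(f"need at least 2 conditions, got {t}")
    if m < t:
        raise ValueError(f"need m >= t, got m={m}, t={t}")
    if n_stable + n_deviating > m:
        raise ValueError(
            f"n_stable + n_deviating = {n_stable + n_deviating} exceeds m = {m}"
        )
    if min(n_stable, n_deviating) < 2:
        raise ValueError("need at least 2 genes in each planted group")
    if deviation_amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitudes must be non-negative")

    rng = np.random.default_rng(seed)
    labels = (
        ["stable"] * n_stable + ["deviating"] * n_deviating
        + ["background"] * (m - n_stable - n_deviating)
    )

    # steady-state weights: every gene participates; stable genes carry the
    # largest raw weights so they sit at the extreme of the G0 profile
    u = np.empty(m)
    u[:n_stable] = rng.uniform(1.4, 1.6, size=n_stable)
    u[n_stable:] = rng.uniform(0.8, 1.2, size=m - n_stable)
    g0 = u / np.linalg.norm(u)

    # deviation weights: supported only on the deviating genes, half up and
    # half down, rescaled so the column is exactly orthogonal to g0
    v = np.zeros(m)
    dev = slice(n_stable, n_stable + n_deviating)
    n_up = n_deviating // 2
    mags = rng.uniform(0.8, 1.2, size=n_deviating)
    signs = np.concatenate([np.ones(n_up), -np.ones(n_deviating - n_up)])
    v[dev] = signs * mags
    overlap_up = float(np.sum(np.clip(v, 0, None) * g0))
    overlap_dn = float(np.sum(np.clip(-v, 0, None) * g0))
    v[v < 0] *= overlap_up / overlap_dn
    assert abs(float(v @ g0)) < 1e-12
    g1 = v / np.linalg.norm(v)

    # multiplier profiles: lam0 nearly constant (balanced state persists
    # through all stages), lam1 a monotone 0 -> 1 ramp (progressive
    # transformation); signs follow the steady-state convention (G0 < 0)
    norm_u = np.linalg.norm(u)
    lam0 = -(MEAN_LOG_LEVEL * norm_u / np.mean(u)) * (
        1.0 + 0.01 * np.linspace(-1.0, 1.0, t)
    )
    g0 = -g0
    # centered monotone ramp: orthogonal to the constant steady-state profile,
    # so the planted pair (lam0, lam1) is itself a valid decomposition.  The
    # RMS weight of a deviating gene is exactly 1/sqrt(n_deviating), so the
    # typical deviating gene swings by deviation_amplitude log units at the
    # first and last stages
    lam1 = deviation_amplitude * np.sqrt(n_deviating) * np.linspace(-1.0, 1.0, t)

    log_values = np.outer(g0, lam0) + np.outer(g1, lam1)
    if noise_sd > 0:
        log_values = log_values + rng.normal(0.0, noise_sd, size=(m, t))

    gene_names = tuple(f"GENE{i:05d}" for i in range(m))
    condition_names = tuple(f"T{j}" for j in range(t))
    x = ExpressionMatrix(gene_names, condition_names, np.exp(log_values))
    truth = PlantedTruth(
        G_true=np.column_stack([g0, g1]),
        lam_true=np.vstack([lam0, lam1]),
        labels=tuple(labels),
        noise_sd=noise_sd,
        seed=seed,
    )
    return x, truth


def generate_links_fixture(
    truth: PlantedTruth,
    gene_names: tuple[str, ...] | list[str],
    path: str | Path,
    id_map_path: str | Path,
    within_stable_score: float = 0.9,
    background_score: float = 0.15,
    density: float = 0.8,
    seed: int = 0,
) -> None:
    """Write a STRING-dialect links file matching a planted dataset.

    Stable-stable gene pairs receive ``within_stable_score`` at the given
    ``density``; all other pairs appear sparsely (at a tenth of that
    density) with ``background_score`` — emulating the observation that
    the stable, balanced-state transcripts form a densely connected
    functional block while the rest of the genome is only weakly linked.
    Also writes the gene-name <-> protein-ID map consumed by the parser.
    """
    for name, p in (("within_stable_score", within_stable_score),
                    ("background_score", background_score)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")

    rng = np.random.default_rng(seed)
    gene_names = list(gene_names)
    protein_ids = {g: f"9606.SYN{i:07d}" for i, g in enumerate(gene_names)}
    stable = set(truth.stable_genes)

    raw_stable = round(within_stable_score * 1000)
    raw_background = round(background_score * 1000)
    n = len(gene_names)
    ii, jj = np.triu_indices(n, k=1)
    stable_mask = np.zeros(n, dtype=bool)
    stable_mask[list(stable)] = True
    in_block = stable_mask[ii] & stable_mask[jj]
    keep_p = np.where(in_block, density, density / 10.0)
    keep = rng.random(len(ii)) < keep_p
    lines = ["protein1 protein2 combined_score"]
    for i, j, blk in zip(ii[keep].tolist(), jj[keep].tolist(), in_block[keep].tolist()):
        raw = raw_stable if blk else raw_background
        a, b = protein_ids[gene_names[i]], protein_ids[gene_names[j]]
        lines.append(f"{a} {b} {raw}")
        lines.append(f"{b} {a} {raw}")  # STRING files list both directions

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    Path(id_map_path).write_text(
        "".join(f"{g}\t{p}\n" for g, p in protein_ids.items()), encoding="utf-8"
    )
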