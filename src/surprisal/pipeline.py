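"""Sequential orchestration of the four analysis stages.

The stages — decomposition, gene profiling, connectivity retrieval,
heatmap comparison — are chained so that each stage writes its output to
disk before the next runs.  Any stage can therefore be re-entered later
from the saved intermediates (cyclical use), and a failed run preserves
everything computed up to the failure.  A manifest of produced files with
SHA-256 checksums is written at the end; runs are byte-reproducible at a
fixed seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import (
    build_score_matrix,
    correlate_heatmaps,
    decompose,
    export_edge_list,
    generate_links_fixture,
    generate_planted_dataset,
    log_transform,
    pair_heatmaps,
    parse_string_links,
    product_heatmap,
    read_expression_csv,
    read_id_map,
    scale_to_target_intensity,
    select_extremes,
    stability_scatter,
    write_edge_list,
    write_expression_csv,
)
from .heatmaps import render_heatmap_pair, render_stability_scatter

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat configuration of a sequential run.

    Either ``input_csv`` points at an expression matrix, or ``simulate``
    is set and a planted dataset (plus links fixture, if no links file is
    given) is generated first.
    """

    out_dir: str
    input_csv: str | None = None
    simulate: bool = False
    scale_target: float | None = None
    method: str = "small_matrix"
    pattern: int = 1
    n_select: int = 100
    links_path: str | None = None
    id_map_path: str | None = None
    edge_threshold: float = 0.5
    seed: int = 0
    render: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Run decompose -> profile -> connectivity -> heatmaps sequentially.

    Returns the artifact manifest (relative path -> SHA-256).  Raises
    :class:`StageError` naming the failing stage; artifacts written before
    the failure are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # the config is recorded for provenance but kept out of the checksum
    # manifest: it embeds the (run-specific) output directory
    (out / "config.json").write_text(cfg.to_json() + "\n", encoding="utf-8")
    artifacts: list[Path] = []

    stage = "input"
    try:
        if cfg.simulate:
            x, truth = generate_planted_dataset(seed=cfg.seed)
            input_csv = out / "expression.csv"
            write_expression_csv(x, input_csv)
            artifacts.append(input_csv)
            if cfg.links_path is None:
                links_path = out / "links.txt"
                id_map_path = out / "id_map.tsv"
                generate_links_fixture(
                    truth, x.gene_names, links_path, id_map_path, seed=cfg.seed
                )
                artifacts += [links_path, id_map_path]
            else:
                links_path = Path(cfg.links_path)
                id_map_path = Path(cfg.id_map_path) if cfg.id_map_path else None
        else:
            if cfg.input_csv is None:
                raise ValueError("either input_csv or simulate must be given")
            input_csv = Path(cfg.input_csv)
            links_path = Path(cfg.links_path) if cfg.links_path else None
            id_map_path = Path(cfg.id_map_path) if cfg.id_map_path else None
        x = read_expression_csv(input_csv)
        if cfg.scale_target is not None:
            x = scale_to_target_intensity(x, cfg.scale_target)

        stage = "decompose"
        d = decompose(log_transform(x), method=cfg.method)  # type: ignore[arg-type]
        d.save(out)
        artifacts += [out / "gene_weights.tsv", out / "lagrange_multipliers.tsv",
                      out / "singular_values.tsv"]

        stage = "profile"
        stable = select_extremes(d, 0, cfg.n_select, "most_negative")
        deviating = select_extremes(d, cfg.pattern, cfg.n_select, "most_positive")
        for sel, name in ((stable, "stable"), (deviating, "deviating")):
            list_path = out / f"selection_{name}.txt"
            tsv_path = out / f"selection_{name}.tsv"
            sel.save(list_path)
            sel.save(tsv_path, with_values=True)
            artifacts += [list_path, tsv_path]

        scatter = stability_scatter(d)
        scatter_path = out / "stability_scatter.tsv"
        pd.DataFrame(scatter).to_csv(scatter_path, sep="\t", index=False)
        artifacts.append(scatter_path)
        if cfg.render:
            png = out / "stability_scatter.png"
            render_stability_scatter(scatter, png)
            artifacts.append(png)

        # combined heatmap axis: stable block first (ascending G0), then the
        # deviating block — the block structure of the paired comparison maps
        axis = list(stable.gene_names) + [
            g for g in deviating.gene_names if g not in set(stable.gene_names)
        ]

        conn = None
        if links_path is not None:
            stage = "connect"
            if not Path(links_path).exists():
                raise FileNotFoundError(f"links file not found: {links_path}")
            if id_map_path is None or not Path(id_map_path).exists():
                raise FileNotFoundError(f"id map not found: {id_map_path}")
            links = parse_string_links(links_path, read_id_map(id_map_path))
            conn = build_score_matrix(links, axis)
            conn_path = out / "connectivity.tsv"
            conn.save(conn_path)
            edges_path = out / "edges.tsv"
            write_edge_list(export_edge_list(conn, cfg.edge_threshold), edges_path)
            artifacts += [conn_path, edges_path]

        stage = "heatmap"
        theory = product_heatmap(d, 0, axis)
        theory_path = out / "heatmap_theoretical.tsv"
        theory.save(theory_path)
        artifacts.append(theory_path)
        if conn is not None:
            pair = pair_heatmaps(theory, conn)
            exp_path = out / "heatmap_string.tsv"
            pair.experimental.save(exp_path)
            artifacts.append(exp_path)
            rho, n_cells = correlate_heatmaps(pair)
            corr_path = out / "heatmap_correlation.json"
            corr_path.write_text(
                json.dumps({"spearman_rho": rho, "n_cells": n_cells}, indent=2) + "\n",
                encoding="utf-8",
            )
            artifacts.append(corr_path)
            if cfg.render:
                png = out / "heatmap_pair.png"
                render_heatmap_pair(pair, png)
                artifacts.append(png)
    except StageError:
        raise
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    manifest = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
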