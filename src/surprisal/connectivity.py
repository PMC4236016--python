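"""STRING functional-association scores: parsing, matrices, edge export.

STRING distributes protein links as a whitespace-separated flat file with
a header (``protein1 protein2 combined_score``) and integer scores 0-999.
The combined score is a benchmarked probability that the two proteins
belong to the same functional pathway, combining independent evidence
channels; higher when more than one type of information supports the
association.  We consume the combined score as given, normalizing the raw
integer to a probability by dividing by 1000 (a raw 999 is the printed
0.999), and translate protein IDs to gene names through a two-column map.

A :class:`ConnectivityMatrix` is the symmetric score matrix over an
ordered gene list.  Pairs STRING knows nothing about are *missing*, not
zero — missingness (rendered as white dots in the paired heatmaps) is a
distinct state carried as NaN and preserved through serialization as an
``NA`` token.  The diagonal is always missing: STRING has no self-links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LinkTable",
    "ConnectivityMatrix",
    "LinksParseError",
    "read_id_map",
    "parse_string_links",
    "build_score_matrix",
    "export_edge_list",
    "write_edge_list",
]

NA_TOKEN = "NA"


class LinksParseError(ValueError):
    """Malformed links file or identifier map."""


@dataclass(frozen=True)
class LinkTable:
    """Functional-association scores keyed by canonically ordered gene pairs.

    ``scores[(a, b)]`` with ``a < b`` (lexicographic) holds the combined
    score as a probability in [0, 1].  Self-links are never stored.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            if a >= b:
                raise LinksParseError(f"pair ({a!r}, {b!r}) not in canonical order")
            if not 0.0 <= s <= 1.0:
                raise LinksParseError(f"score {s} for ({a}, {b}) outside [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, a: str, b: str) -> float | None:
        if a == b:
            return None
        key = (a, b) if a < b else (b, a)
        return self.scores.get(key)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping protein IDs to gene names.

    Columns are ``gene_name<TAB>protein_id``; the returned dict maps
    protein ID -> gene name.  Duplicate gene names are an error (the
    downstream matrices require unique gene axes).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "protein"], dtype=str)
    if frame["gene"].duplicated().any():
        dup = frame["gene"][frame["gene"].duplicated()].iloc[0]
        raise LinksParseError(f"{path}: duplicate gene name in id map: {dup!r}")
    return dict(zip(frame["protein"], frame["gene"]))


def parse_string_links(path: str | Path, id_map: dict[str, str]) -> LinkTable:
    """Parse a STRING protein-links file into a gene-level link table.

    The header is located by column name, so both the minimal three-column
    file and wider detailed variants parse.  Raw integer scores become
    probabilities (score/1000).  Records whose proteins are not in
    ``id_map`` are dropped with a logged count; conflicting duplicate
    scores for a pair keep the maximum (higher confidence wins), with a
    warning.
    """
    path = Path(path)
    scores: dict[tuple[str, str], float] = {}
    n_unmapped = 0
    n_conflicts = 0
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise LinksParseError(f"{path}: empty file")
        header = header_line.split()
        try:
            i_a = header.index("protein1")
            i_b = header.index("protein2")
            i_s = header.index("combined_score")
        except ValueError as exc:
            raise LinksParseError(
                f"{path}: header must name protein1, protein2 and combined_score; got {header}"
            ) from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != len(header):
                raise LinksParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                raw = int(fields[i_s])
            except ValueError:
                raise LinksParseError(
                    f"{path}:{lineno}: non-integer combined_score {fields[i_s]!r}"
                ) from None
            if not 0 <= raw <= 999:
                raise LinksParseError(f"{path}:{lineno}: combined_score {raw} outside 0..999")
            gene_a = id_map.get(fields[i_a])
            gene_b = id_map.get(fields[i_b])
            if gene_a is None or gene_b is None:
                n_unmapped += 1
                continue
            if gene_a == gene_b:
                continue
            key = (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)
            prob = raw / 1000.0
            if key in scores and scores[key] != prob:
                n_conflicts += 1
                prob = max(prob, scores[key])
            scores[key] = max(prob, scores.get(key, 0.0))
    if n_unmapped:
        logger.info("%s: dropped %d records with unmapped protein IDs", path, n_unmapped)
    if n_conflicts:
        logger.warning(
            "%s: %d pairs had conflicting duplicate scores; kept the maximum", path, n_conflicts
        )
    return LinkTable(scores)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric combined-score matrix over an ordered gene list.

    ``values`` is square with NaN marking missing pairs (including the
    whole diagonal); symmetry of both values and missingness is exact.
    """

    gene_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.gene_names)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} genes")
        if not np.array_equal(values, values.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric (NaN-aware)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_names), columns=list(self.gene_names)
        )

    def save(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "Gene"
        frame.to_csv(path, sep="\t", na_rep=NA_TOKEN)

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityMatrix":
        frame = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[NA_TOKEN],
            float_precision="round_trip",
        )
        return cls(tuple(str(g) for g in frame.index), frame.to_numpy(dtype=float))


def build_score_matrix(links: LinkTable, genes: list[str] | tuple[str, ...]) -> ConnectivityMatrix:
    """Combined-score matrix over exactly the given genes in the given order.

    Pairs absent from the link table carry the missing marker (NaN), not
    zero — absence of evidence in STRING is lack of information.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    if len(set(genes)) != len(genes):
        dup = next(g for i, g in enumerate(genes) if g in genes[:i])
        raise ValueError(f"duplicate gene in list: {dup!r}")
    n = len(genes)
    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            s = links.get(genes[i], genes[j])
            if s is not None:
                values[i, j] = values[j, i] = s
    return ConnectivityMatrix(tuple(genes), values)


def export_edge_list(
    c: ConnectivityMatrix, threshold: float = 0.0
) -> list[tuple[str, str, float]]:
    """Edges (gene_a, gene_b, score) for every non-missing pair with score
    at or above ``threshold``; the score is the edge weight (it drives line
    thickness in downstream network renderings)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    edges: list[tuple[str, str, float]] = []
    n = c.n_genes
    for i in range(n):
        for j in range(i + 1, n):
            v = c.values[i, j]
            if not np.isnan(v) and v >= threshold:
                edges.append((c.gene_names[i], c.gene_names[j], float(v)))
    return edges


def write_edge_list(
    edges: list[tuple[str, str, float]], path: str | Path
) -> None:
    """TSV edge list (gene_a, gene_b, combined_score) loadable by graph tools."""
    frame = pd.DataFrame(edges, columns=["gene_a", "gene_b", "combined_score"])
    frame.to_csv(path, sep="\t", index=False)
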