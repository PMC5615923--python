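"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: intensity TSV (rows = proteins, columns = samples, empty cell =
missing) with a sample-metadata TSV; edge-list TSV (node_a, node_b,
confidence); term-gene and term-parent TSVs; promoter FASTA; MEME minimal
motif files (see :class:`~foxodep.enrichment.MotifModel`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .containers import IntensityMatrix

__all__ = [
    "read_intensities",
    "read_edges",
    "read_term_genes",
    "read_term_parents",
    "read_promoters",
]


def read_intensities(values_path: str | Path, samples_path: str | Path) -> IntensityMatrix:
    return IntensityMatrix.from_tsv(values_path, samples_path)


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read an edge list: TSV with header, or SIF (``.sif`` extension).

    SIF rows are ``source relation target [target ...]``; SIF carries no
    confidence, so edges get confidence 1.0.
    """
    path = Path(path)
    if path.suffix.lower() == ".sif":
        rows = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if len(parts) < 3:
                continue
            for target in parts[2:]:
                rows.append((parts[0], target, 1.0))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    edges = pd.read_csv(path, sep="\t")
    required = {"node_a", "node_b", "confidence"}
    if not required <= set(edges.columns):
        raise ValueError(f"{path}: edge table needs columns {sorted(required)}")
    return edges


def read_term_genes(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"term", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns ['term', 'gene']")
    out: dict[str, list[str]] = {}
    for term, gene in df.itertuples(index=False):
        out.setdefault(str(term), []).append(str(gene))
    return out


def read_term_parents(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"term", "parent"} <= set(df.columns):
        raise ValueError(f"{path}: needs columns ['term', 'parent']")
    out: dict[str, list[str]] = {}
    for term, parent in df.itertuples(index=False):
        term, parent = str(term), str(parent)
        if parent and parent.lower() != "nan":
            out.setdefault(term, []).append(parent)
        else:
            out.setdefault(term, [])
    return out


def read_promoters(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
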