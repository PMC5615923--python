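"""Core in-memory containers shared across the pipeline stages.

The central object is :class:`IntensityMatrix`: a protein-by-sample table of
log2 label-free quantification (LFQ) intensities with missing values encoded
as NaN, plus a sample-metadata table (genotype, tissue, replicate).  The four
genotype levels are, by convention:

* ``A`` — wild type,
* ``B`` — foxo-null mutant,
* ``C`` — median-neurosecretory-cell (mNSC) ablated (reduced insulin signalling),
* ``D`` — ablated, foxo-null double.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("A", "B", "C", "D")

SAMPLE_COLUMNS = ("genotype", "tissue", "replicate")


@dataclass
class IntensityMatrix:
    """Protein x sample log2 intensities with an explicit missingness mask.

    Parameters
    ----------
    values:
        DataFrame indexed by protein identifier, one column per sample;
        missing intensities are NaN.
    samples:
        DataFrame indexed by sample identifier with columns
        ``genotype``, ``tissue`` and ``replicate``.  Row order must match
        the column order of ``values``.
    imputed:
        Optional boolean DataFrame (same shape as ``values``) flagging cells
        filled in by imputation, kept for audit.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata rows must match intensity columns")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing required column {col!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein identifiers: {dups[:5]}")
        if self.imputed is not None and self.imputed.shape != self.values.shape:
            raise ValueError("imputed mask shape must match values")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator (True = missing)."""
        return self.values.isna()

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genotype_of(self) -> pd.Series:
        """Genotype label per sample, aligned with the value columns."""
        return self.samples["genotype"]

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            values=self.values.copy(),
            samples=self.samples.copy(),
            imputed=None if self.imputed is None else self.imputed.copy(),
        )

    # -- TSV dialect -------------------------------------------------------
    # intensity TSV: rows = proteins, columns = samples, empty cell = missing
    # metadata TSV: sample, genotype, tissue, replicate

    def to_tsv(self, values_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", na_rep="", index_label="protein")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(
        cls, values_path: str | Path, samples_path: str | Path
    ) -> "IntensityMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="protein")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(values=values, samples=samples)


@dataclass
class DependencyThreshold:
    """Tissue-specific equivalence margin ``t``.

    ``t`` is the minimum |log2 fold change| among proteins significant in the
    interaction contrast; an interaction CI inside [-t, t] is treated as
    evidence of no interaction (foxo-independence).
    """

    t: float
    tissue: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t <= 0:
            raise ValueError(f"equivalence threshold must be positive, got {self.t}")
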