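"""Perseus-style filtering and imputation of log2 LFQ matrices.

Two steps turn a raw matrix with missing values into a complete matrix ready
for linear modelling:

1. keep only proteins with at least ``min_valid`` observed values in at least
   one genotype category (default 4, against 6 replicates per genotype);
2. replace each remaining missing value, separately per sample column, with a
   draw from a normal distribution shifted into the low-intensity tail of
   that column: mean ``m - downshift * s`` and sd ``width * s``, where ``m``
   and ``s`` are the mean and sd of the column's *observed* values.  Defaults
   are width 0.3 and downshift 1.8 (in units of the observed column sd),
   modelling the assumption that values are missing because the protein sat
   below the detection limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix

__all__ = ["ImputationParams", "filter_min_valid", "impute_downshift"]


@dataclass
class ImputationParams:
    width: float = 0.3  # imputed sd, as a fraction of the observed column sd
    downshift: float = 1.8  # mean shift, in multiples of the observed column sd
    min_valid: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("width must be nonnegative")
        if self.downshift < 0:
            raise ValueError("downshift must be nonnegative")
        if self.min_valid < 0:
            raise ValueError("min_valid must be nonnegative")


def filter_min_valid(matrix: IntensityMatrix, min_valid: int = 4) -> IntensityMatrix:
    """Keep proteins observed at least ``min_valid`` times in some genotype.

    A genotype with fewer samples than ``min_valid`` simply cannot qualify.
    Protein order is preserved; ``min_valid=0`` is the identity filter.
    """
    if min_valid <= 0:
        return matrix.copy()
    observed = ~matrix.values.isna()
    counts = observed.T.groupby(matrix.samples["genotype"]).sum().T
    keep = (counts >= min_valid).any(axis=1)
    if not keep.any():
        warnings.warn("min-valid filter removed every protein", stacklevel=2)
    return IntensityMatrix(
        values=matrix.values.loc[keep].copy(),
        samples=matrix.samples.copy(),
        imputed=None if matrix.imputed is None else matrix.imputed.loc[keep].copy(),
    )


def impute_downshift(
    matrix: IntensityMatrix, params: ImputationParams | None = None
) -> IntensityMatrix:
    """Fill missing cells from a downshifted normal, per sample column.

    Observed cells are never altered; the returned matrix carries an
    ``imputed`` boolean mask for audit.  Reproducible for a fixed
    ``params.seed``.  A column that needs imputation but has fewer than two
    observed values raises, naming the column.
    """
    params = params or ImputationParams()
    rng = np.random.default_rng(params.seed)
    values = matrix.values.copy()
    imputed = pd.DataFrame(False, index=values.index, columns=values.columns)
    for col in values.columns:
        column = values[col]
        miss = column.isna()
        if not miss.any():
            continue
        obs = column[~miss]
        if len(obs) < 2:
            raise ValueError(
                f"column {col!r} has {len(obs)} observed values; "
                "need >= 2 to estimate imputation parameters"
            )
        m = float(obs.mean())
        s = float(obs.std(ddof=1))
        draws = rng.normal(m - params.downshift * s, params.width * s, int(miss.sum()))
        values.loc[miss, col] = draws
        imputed.loc[miss, col] = True
    return IntensityMatrix(values=values, samples=matrix.samples.copy(), imputed=imputed)
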