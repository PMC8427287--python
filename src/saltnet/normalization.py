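"""Median-of-ratios size-factor normalization and the correlation input.

The size factor of sample *j* is the median, over reference genes, of the
ratio of the gene's count in *j* to the gene's geometric mean across all
samples; genes with any zero count are excluded from the reference set.
The matrix handed to the correlation step is ``log2(count / s_j +
pseudocount)``, a variance-stabilizing transform on library-size-adjusted
abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SaltnetError


class NormalizationError(SaltnetError):
    """Size factors cannot be estimated for this matrix."""


@dataclass
class SizeFactors:
    """Per-sample scaling factors, all strictly positive."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        bad = [s for s, f in self.factors.items() if not f > 0]
        if bad:
            raise NormalizationError(f"non-positive size factors for samples {bad}")


def estimate_size_factors(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Raises
    ------
    NormalizationError
        If no gene has all-positive counts (the reference set would be
        empty); adding a pseudocount upstream or filtering samples is then
        required.
    """
    matrix = counts.values.to_numpy(dtype=float)
    reference = (matrix > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; cannot form the "
            "geometric-mean reference — consider adding a pseudocount"
        )
    ref = matrix[reference]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    return SizeFactors(
        factors={s: float(f) for s, f in zip(counts.sample_ids, factors)}
    )


def normalize_and_transform(
    counts: ExpressionMatrix, factors: SizeFactors, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Return ``log2(count / s_j + pseudocount)`` with metadata preserved."""
    if pseudocount <= 0:
        raise NormalizationError("pseudocount must be positive")
    missing = [s for s in counts.sample_ids if s not in factors.factors]
    if missing:
        raise NormalizationError(f"no size factor for sample(s) {missing}")
    s = np.array([factors.factors[c] for c in counts.sample_ids])
    values = np.log2(counts.values.to_numpy(dtype=float) / s + pseudocount)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=counts.values.index, columns=counts.values.columns),
        sample_state=dict(counts.sample_state),
        sample_stage=dict(counts.sample_stage),
        sample_replicate=dict(counts.sample_replicate),
    )
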