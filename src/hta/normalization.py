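"""Scaling normalization on the log scale.

Each array (sample column) is shifted additively so its mean log2
intensity equals the global target level G, the unweighted mean of all
per-sample means. On the raw-intensity scale this is scaling every array
to the global geometric mean. Per-feature differences between any two
samples are unchanged, so pairwise difference variances — and hence the
samplewise error-variance estimates — are invariant under this step.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import ExpressionMatrix

__all__ = ["NormalizationReport", "scaling_normalize"]


@dataclass
class NormalizationReport:
    """Per-sample additive offsets (log2) and the global target level."""

    offsets: pd.Series
    grand_mean: float

    def to_frame(self) -> pd.DataFrame:
        out = self.offsets.rename("offset").to_frame()
        out.index.name = "sample"
        out["grand_mean"] = self.grand_mean
        return out


def scaling_normalize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Align every sample's mean log2 intensity to the global mean level.

    Returns the shifted matrix and a report of the offsets applied. The
    operation is idempotent and a fixed point when column means are
    already equal.
    """
    col_means = matrix.frame.mean(axis=0)
    grand_mean = float(col_means.mean())
    offsets = grand_mean - col_means
    shifted = matrix.frame.add(offsets, axis=1)
    return (
        ExpressionMatrix(shifted),
        NormalizationReport(offsets=offsets, grand_mean=grand_mean),
    )
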