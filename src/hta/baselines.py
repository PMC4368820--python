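"""Reference methods: pooled two-sample t-test and the hybrid p + fold-change rule.

The t-test estimates error variance gene by gene through the common
sample standard deviation

    S_c = sqrt(((n1-1)S1^2 + (n2-1)S2^2) / (n1+n2-2)),

the pooled factor of the t denominator. The hybrid method (HM) selects
features passing both a significance cutoff and an absolute log2
fold-change cutoff, with strict inequalities on both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortDesign, DataError, ExpressionMatrix
from .model import bh_fdr

__all__ = ["PooledTTest", "TTestResults", "pooled_t_test", "hybrid_select"]


class PooledTTest:
    """Gene-wise pooled-variance two-sample t-test on a two-cohort contrast."""

    def __init__(self, matrix: ExpressionMatrix, design: CohortDesign) -> None:
        design.validate_against(matrix)
        self.matrix = matrix
        self.design = design

    @classmethod
    def from_files(cls, matrix_path, design_path) -> "PooledTTest":
        from .data import read_design, read_expression_matrix

        return cls(read_expression_matrix(matrix_path), read_design(design_path))

    def fit(self) -> "TTestResults":
        xt = self.matrix.values_for(self.design.test_samples)
        xc = self.matrix.values_for(self.design.control_samples)
        n1, n2 = xt.shape[1], xc.shape[1]
        df = n1 + n2 - 2
        diff = xt.mean(axis=1) - xc.mean(axis=1)
        s1 = xt.var(axis=1, ddof=1)
        s2 = xc.var(axis=1, ddof=1)
        sc = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / df)
        denom = sc * np.sqrt(1.0 / n1 + 1.0 / n2)
        degenerate = (sc == 0) & (diff == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / denom
        t[degenerate] = 0.0
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[degenerate] = 1.0
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        frame = pd.DataFrame(
            {
                "fc_hat": diff,
                "sc": sc,
                "t": t,
                "df": df,
                "p": p,
                "q": bh_fdr(p),
                "degenerate": degenerate,
            },
            index=pd.Index(self.matrix.feature_ids, name="feature"),
        )
        return TTestResults(model=self, frame=frame)


@dataclass
class TTestResults:
    """Per-feature pooled t statistics, p and BH q values."""

    model: PooledTTest
    frame: pd.DataFrame

    @property
    def fc_hat(self) -> pd.Series:
        return self.frame["fc_hat"]

    @property
    def pvalues(self) -> pd.Series:
        return self.frame["p"]

    @property
    def qvalues(self) -> pd.Series:
        return self.frame["q"]

    def selected(self, p_cut: float = 0.05) -> frozenset[str]:
        return frozenset(self.frame.index[self.frame["p"] < p_cut])

    def selected_fdr(self, q_cut: float = 0.05) -> frozenset[str]:
        return frozenset(self.frame.index[self.frame["q"] < q_cut])

    def ranking(self) -> list[str]:
        order = self.frame.assign(_abst=self.frame["t"].abs()).sort_values(
            by=["_abst", "p"], ascending=[False, True], kind="mergesort"
        )
        return list(order.index)

    def hybrid_selected(
        self, p_cut: float = 0.05, fc_cut: float = 1.0
    ) -> frozenset[str]:
        return hybrid_select(self.frame, self.frame["fc_hat"], p_cut, fc_cut)

    def summary(self) -> str:
        f = self.frame
        return "\n".join(
            [
                "Pooled two-sample t-test (gene-wise variance)",
                "=" * 45,
                f"features: {len(f)}   df={int(f['df'].iloc[0])}",
                f"selected p<0.05: {int((f['p'] < 0.05).sum())}    "
                f"selected FDR<0.05: {int((f['q'] < 0.05).sum())}",
            ]
        )


def pooled_t_test(matrix: ExpressionMatrix, design: CohortDesign) -> pd.DataFrame:
    """Convenience wrapper returning the per-feature result table."""
    return PooledTTest(matrix, design).fit().frame


def hybrid_select(
    tt_frame: pd.DataFrame, fc: pd.Series, p_cut: float = 0.05, fc_cut: float = 1.0
) -> frozenset[str]:
    """Hybrid-method selection: p < p_cut AND |fc| > fc_cut, both strict."""
    if not 0 < p_cut < 1:
        raise DataError(f"p_cut must lie in (0, 1), got {p_cut}")
    if fc_cut < 0:
        raise DataError(f"fc_cut must be >= 0, got {fc_cut}")
    fc = fc.reindex(tt_frame.index)
    keep = (tt_frame["p"] < p_cut) & (fc.abs() > fc_cut)
    return frozenset(tt_frame.index[keep])
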