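"""Heterogeneity-tolerant differential expression by samplewise error modelling.

The method treats technical error as homogeneous across genes but
heterogeneous across replicate arrays, and estimates one error variance
per array from the variances of per-feature log2 differences between
array pairs within a cohort. Under normal errors the difference variance
between arrays i and j decomposes as

    sigma2_{ij} = sigma2_i + sigma2_j,

so averaging the n-1 half-estimates gives the samplewise variance

    sigma2_i = (1/2) * (1/(n-1)) * sum_{j != i} sigma2_{ij}.

Each log2 measurement then carries a Gaussian with the measured value as
mean and its array's error variance as variance; multiplying a cohort's
Gaussians per gene yields the precision-weighted posterior of the cohort
mean. The difference of the two cohort posteriors gives the fold-change
distribution, and

    z = (mu_t - mu_c) / sqrt(sigma2_t + sigma2_c)

is referred to the standard normal. Because the estimation pools all
genes, the z-statistic is well calibrated even for triplicate cohorts
where gene-by-gene variance estimates are hopelessly noisy; and because
subtype-driven expression differences inflate gene-wise variances but not
array-pair difference variances uniformly, genes affected by molecular
heterogeneity are not deprioritized the way they are under a t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CohortDesign, DataError, ExpressionMatrix
from .normalization import NormalizationReport, scaling_normalize

__all__ = [
    "SampleErrorModel",
    "pairwise_difference_variance",
    "estimate_sample_error_variances",
    "degenerate_variance_floor",
    "cohort_posterior",
    "bh_fdr",
    "hta_test",
    "HTAModel",
    "HTAResults",
]

DEFAULT_VARIANCE_FLOOR = 1e-12


@dataclass
class SampleErrorModel:
    """Samplewise error variances for one cohort.

    Attributes
    ----------
    sigma2 : dict
        Sample id -> samplewise error variance (log2^2 units).
    pairwise : dict
        Unordered pair frozenset({i, j}) -> difference variance.
    floored : bool
        True if any variance was raised to the degeneracy floor.
    """

    sigma2: dict[str, float]
    pairwise: dict[frozenset, float] = field(default_factory=dict)
    floored: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sigma2)

    def sd(self) -> dict[str, float]:
        return {s: float(np.sqrt(v)) for s, v in self.sigma2.items()}

    def variances(self, sample_ids=None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else sample_ids
        return np.array([self.sigma2[s] for s in ids], dtype=float)


def pairwise_difference_variance(
    matrix: ExpressionMatrix, sample_i: str, sample_j: str, robust: bool = False
) -> float:
    """Variance across features of the per-feature log2 difference x_i - x_j.

    With ``robust=True`` a scaled-median-absolute-deviation variance is
    used instead of the plain sample variance, for heavy-tailed
    contamination of the non-DEG majority.
    """
    if sample_i == sample_j:
        raise DataError(f"pairwise variance needs two distinct samples, got {sample_i!r}")
    d = matrix.frame[sample_i].to_numpy(dtype=float) - matrix.frame[sample_j].to_numpy(
        dtype=float
    )
    if robust:
        return float(stats.median_abs_deviation(d, scale="normal") ** 2)
    return float(np.var(d, ddof=1))


def estimate_sample_error_variances(
    matrix: ExpressionMatrix, cohort, robust: bool = False
) -> SampleErrorModel:
    """Estimate one error variance per array by pairwise comparison.

    For every unordered pair within the cohort the variance of per-feature
    differences is computed; half of each pair variance estimates either
    member's variance, and the n-1 estimates per array are averaged.
    Additive per-array shifts cancel in the differences, so the estimates
    are identical before and after scaling normalization.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise DataError(f"cohort needs >= 2 samples for pairwise estimation, got {len(cohort)}")
    missing = set(cohort) - set(matrix.sample_ids)
    if missing:
        raise DataError(f"cohort samples absent from matrix: {sorted(missing)}")
    pairwise: dict[frozenset, float] = {}
    for i, j in combinations(cohort, 2):
        pairwise[frozenset((i, j))] = pairwise_difference_variance(
            matrix, i, j, robust=robust
        )
    n = len(cohort)
    sigma2 = {
        i: sum(pairwise[frozenset((i, j))] for j in cohort if j != i) / (2 * (n - 1))
        for i in cohort
    }
    return SampleErrorModel(sigma2=sigma2, pairwise=pairwise)


def degenerate_variance_floor(
    model: SampleErrorModel, floor: float = DEFAULT_VARIANCE_FLOOR
) -> SampleErrorModel:
    """Raise any samplewise variance below ``floor`` up to it.

    Zero variances arise only on degenerate input (identical arrays) and
    would otherwise give infinite precision; the flag records whether any
    replacement happened.
    """
    if not floor > 0:
        raise ValueError(f"variance floor must be positive, got {floor}")
    flo = {s: max(v, floor) for s, v in model.sigma2.items()}
    changed = any(flo[s] != model.sigma2[s] for s in flo)
    return SampleErrorModel(
        sigma2=flo, pairwise=dict(model.pairwise), floored=model.floored or changed
    )


def cohort_posterior(values, variances) -> tuple[float, float]:
    """Precision-weighted posterior of a cohort's true mean for one feature.

    Multiplying the per-measurement Gaussians N(x_i, sigma2_i) and
    renormalizing yields a Gaussian with variance 1/sum(1/sigma2_i) and
    mean var * sum(x_i/sigma2_i); the mean is a convex combination of the
    observations.
    """
    x = np.asarray(values, dtype=float)
    s2 = np.asarray(variances, dtype=float)
    if np.any(s2 <= 0):
        raise DataError("cohort posterior requires positive (floored) variances")
    w = 1.0 / s2
    var = 1.0 / w.sum()
    mu = var * float((w * x).sum())
    return float(mu), float(var)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cohort_stats(
    block: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, float]:
    """Vectorized posterior over all features of one cohort block."""
    w = 1.0 / variances
    var = 1.0 / w.sum()
    mu = var * block @ w
    return mu, float(var)


def hta_test(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    robust: bool = False,
    normalize: bool = True,
) -> pd.DataFrame:
    """Run the full z-test pipeline on one two-cohort contrast.

    Convenience wrapper around :class:`HTAModel`; returns the per-feature
    result table with columns fc_hat, var_fc, z, p, q.
    """
    return (
        HTAModel(
            matrix,
            design,
            variance_floor=variance_floor,
            robust=robust,
            normalize=normalize,
        )
        .fit()
        .frame
    )


class HTAModel:
    """Two-cohort differential-expression model with samplewise error variances.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log2 intensities, features x samples.
    design : CohortDesign
        Test/control assignment; each cohort needs >= 2 samples.
    variance_floor : float
        Lower bound applied to samplewise variances (log2^2 units).
    robust : bool
        Use a median-absolute-deviation pairwise variance instead of the
        plain sample variance.
    normalize : bool
        Apply scaling normalization before computing cohort posteriors.
        Error-variance estimation always runs on the matrix as given; the
        estimates are provably identical either way.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: CohortDesign,
        variance_floor: float = DEFAULT_VARIANCE_FLOOR,
        robust: bool = False,
        normalize: bool = True,
    ) -> None:
        design.validate_against(matrix)
        self.matrix = matrix
        self.design = design
        self.variance_floor = variance_floor
        self.robust = robust
        self.normalize = normalize

    @classmethod
    def from_files(cls, matrix_path, design_path, **kwargs) -> "HTAModel":
        from .data import read_design, read_expression_matrix

        return cls(read_expression_matrix(matrix_path), read_design(design_path), **kwargs)

    def fit(self) -> "HTAResults":
        # error variances are estimated pre-normalization; additive
        # per-array shifts cancel in pairwise differences so the order
        # cannot matter
        test_model = degenerate_variance_floor(
            estimate_sample_error_variances(
                self.matrix, self.design.test_samples, robust=self.robust
            ),
            self.variance_floor,
        )
        control_model = degenerate_variance_floor(
            estimate_sample_error_variances(
                self.matrix, self.design.control_samples, robust=self.robust
            ),
            self.variance_floor,
        )
        norm_report = None
        working = self.matrix
        if self.normalize:
            working, norm_report = scaling_normalize(self.matrix)

        mu_t, var_t = _cohort_stats(
            working.values_for(self.design.test_samples),
            test_model.variances(self.design.test_samples),
        )
        mu_c, var_c = _cohort_stats(
            working.values_for(self.design.control_samples),
            control_model.variances(self.design.control_samples),
        )
        fc_hat = mu_t - mu_c
        var_fc = var_t + var_c
        z = fc_hat / np.sqrt(var_fc)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        frame = pd.DataFrame(
            {
                "fc_hat": fc_hat,
                "var_fc": var_fc,
                "z": z,
                "p": p,
                "q": bh_fdr(p),
            },
            index=pd.Index(self.matrix.feature_ids, name="feature"),
        )
        return HTAResults(
            model=self,
            frame=frame,
            test_error_model=test_model,
            control_error_model=control_model,
            normalization=norm_report,
        )


@dataclass
class HTAResults:
    """Fitted results: per-feature estimates plus the error models used."""

    model: HTAModel
    frame: pd.DataFrame
    test_error_model: SampleErrorModel
    control_error_model: SampleErrorModel
    normalization: NormalizationReport | None = None

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
        """Features with raw p strictly below ``p_cut``."""
        return frozenset(self.frame.index[self.frame["p"] < p_cut])

    def selected_fdr(self, q_cut: float = 0.05) -> frozenset[str]:
        """Features with BH-adjusted q strictly below ``q_cut``."""
        return frozenset(self.frame.index[self.frame["q"] < q_cut])

    def ranking(self) -> list[str]:
        """Feature ids by descending |z|; ties broken by feature id."""
        order = self.frame.assign(_absz=self.frame["z"].abs()).sort_values(
            by=["_absz", "p"], ascending=[False, True], kind="mergesort"
        )
        return list(order.index)

    def summary(self) -> str:
        f = self.frame
        sds = {**self.test_error_model.sd(), **self.control_error_model.sd()}
        lines = [
            "Heterogeneity-tolerant differential expression (z-test)",
            "=" * 56,
            f"features: {len(f)}   test n={len(self.model.design.test_samples)}   "
            f"control n={len(self.model.design.control_samples)}",
            f"selected p<0.05: {int((f['p'] < 0.05).sum())}    "
            f"selected FDR<0.05: {int((f['q'] < 0.05).sum())}",
            "samplewise error SD (log2):",
        ]
        lines += [f"  {s}: {sd:.4f}" for s, sd in sds.items()]
        if self.normalization is not None:
            lines.append(
                f"scaling normalization target (grand mean log2): "
                f"{self.normalization.grand_mean:.4f}"
            )
        if self.test_error_model.floored or self.control_error_model.floored:
            lines.append("note: degenerate variances raised to floor")
        return "\n".join(lines)
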