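"""Biological measures of relative reliability for DE methods.

A method's output on a dataset is reduced to: the features it selects at
p < 0.05, the features it selects at FDR < 0.05, and the functions
overrepresented (Fisher p < 0.001) in the p < 0.05 selection. From these,
three measures are computed relative to a reference method (the
samplewise-error z-test by default), which scores exactly 1 on all three
by construction:

* relative specificity — detected-function count, divided by the
  reference's count (functionally coherent selections detect functions;
  random ones do not);
* relative sensitivity — specificity times the FDR < 0.05 gene count,
  normalized by the reference's product (proportional to true positives
  if relative specificity tracks absolute specificity);
* relative reproducibility — mean cross-dataset recurrence of detected
  function instances, normalized by the reference's.

Two further instruments: the detection rate of a designated list of
disease-specific functions, and an AUC comparing a method's function
ranking against the reference's derived function set, with AUC < 0.5
flagging a misanalyzed contrast. Validity of the function-count
specificity proxy is demonstrable by progressive degradation: permuting
the intensities of each array in the first i test-control pairs of the
i-th replicate destroys ranking specificity progressively, and detected
function counts decline with i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .baselines import PooledTTest
from .data import CohortDesign, DataError, ExpressionMatrix, GeneSetCollection
from .enrichment import DEFAULT_ENRICH_CUT, fisher_overrepresentation
from .model import HTAModel

__all__ = [
    "MethodOutput",
    "BmorrReport",
    "evaluate_method",
    "relative_specificity",
    "relative_sensitivity",
    "mean_recurrence",
    "relative_reproducibility",
    "detection_rate",
    "auc_vs_reference",
    "progressive_degradation",
    "degradation_curve",
    "bmorr_report",
    "METHODS",
]

METHODS = ("hta", "ttest", "hm")


@dataclass
class MethodOutput:
    """One method's reduced output on one dataset."""

    method: str
    dataset: str
    selected_p: frozenset[str]
    selected_fdr: frozenset[str]
    enrichment: pd.DataFrame  # all sets, ascending p; column 'detected'
    collection_id: int = 0

    @property
    def detected_functions(self) -> frozenset[str]:
        e = self.enrichment
        return frozenset(e.index[e["detected"]])

    @property
    def n_functions(self) -> int:
        return len(self.detected_functions)

    @property
    def n_genes_fdr(self) -> int:
        return len(self.selected_fdr)

    def function_pvalues(self) -> pd.Series:
        return self.enrichment["p"]


def evaluate_method(
    method: str,
    matrix: ExpressionMatrix,
    design: CohortDesign,
    collection: GeneSetCollection,
    dataset: str = "dataset",
    p_cut: float = 0.05,
    fdr_cut: float = 0.05,
    fc_cut: float = 1.0,
    enrich_cut: float = DEFAULT_ENRICH_CUT,
) -> MethodOutput:
    """Run one method on one contrast and reduce it for assessment.

    ``method`` is one of 'hta', 'ttest' or 'hm'. The hybrid method has a
    single joint selection (p < p_cut and |FC| > fc_cut) which serves both
    the function-derivation and the FDR-count roles, since it carries no
    FDR notion of its own.
    """
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "hta":
        res = HTAModel(matrix, design).fit()
        sel_p, sel_q = res.selected(p_cut), res.selected_fdr(fdr_cut)
    elif method == "ttest":
        res = PooledTTest(matrix, design).fit()
        sel_p, sel_q = res.selected(p_cut), res.selected_fdr(fdr_cut)
    else:
        res = PooledTTest(matrix, design).fit()
        joint = res.hybrid_selected(p_cut=p_cut, fc_cut=fc_cut)
        sel_p = sel_q = joint
    enr = fisher_overrepresentation(
        sel_p & collection.universe, collection, enrich_cut=enrich_cut
    )
    return MethodOutput(
        method=method,
        dataset=dataset,
        selected_p=sel_p,
        selected_fdr=sel_q,
        enrichment=enr,
        collection_id=id(collection),
    )


def _check_comparable(method: MethodOutput, reference: MethodOutput) -> None:
    if method.dataset != reference.dataset:
        raise DataError(
            f"outputs from different datasets: {method.dataset!r} vs "
            f"{reference.dataset!r}"
        )


def relative_specificity(method: MethodOutput, reference: MethodOutput) -> float:
    """Detected-function count ratio; NaN (flagged undefined) if the
    reference detected none."""
    _check_comparable(method, reference)
    if reference.n_functions == 0:
        return float("nan")
    return method.n_functions / reference.n_functions


def relative_sensitivity(method: MethodOutput, reference: MethodOutput) -> float:
    """(RSP x FDR-gene-count) ratio against the reference's product."""
    _check_comparable(method, reference)
    rsp = relative_specificity(method, reference)
    if reference.n_genes_fdr == 0 or np.isnan(rsp):
        return float("nan")
    return rsp * method.n_genes_fdr / reference.n_genes_fdr


def mean_recurrence(outputs: list[MethodOutput]) -> float:
    """Mean cross-dataset occurrence count over detected function instances.

    Each (function, dataset) detection is one instance; its value is the
    number of datasets in which that function was detected. NaN if the
    method detected nothing anywhere.
    """
    if len(outputs) < 2:
        raise DataError("reproducibility needs outputs on >= 2 datasets")
    counts: dict[str, int] = {}
    for out in outputs:
        for fn in out.detected_functions:
            counts[fn] = counts.get(fn, 0) + 1
    instances = [counts[fn] for out in outputs for fn in out.detected_functions]
    if not instances:
        return float("nan")
    return float(np.mean(instances))


def relative_reproducibility(
    method_outputs: list[MethodOutput], reference_outputs: list[MethodOutput]
) -> float:
    """Ratio of mean recurrence statistics; NaN if either is undefined."""
    m = mean_recurrence(method_outputs)
    r = mean_recurrence(reference_outputs)
    if np.isnan(m) or np.isnan(r) or r == 0:
        return float("nan")
    return m / r


def detection_rate(
    outputs: list[MethodOutput],
    disease_functions,
    collection: GeneSetCollection,
    per_dataset_average: bool = True,
) -> float:
    """Average fraction of disease-specific functions a method detects.

    With ``per_dataset_average`` (default) the fraction is computed per
    dataset and averaged; otherwise a function counts as detected if found
    in at least one dataset.
    """
    disease_functions = frozenset(disease_functions)
    unknown = disease_functions - set(collection.set_ids)
    if unknown:
        raise DataError(f"unknown disease function ids: {sorted(unknown)}")
    if not disease_functions:
        raise DataError("disease function list is empty")
    if per_dataset_average:
        rates = [
            len(out.detected_functions & disease_functions) / len(disease_functions)
            for out in outputs
        ]
        return float(np.mean(rates))
    union = frozenset().union(*(out.detected_functions for out in outputs))
    return len(union & disease_functions) / len(disease_functions)


def auc_vs_reference(
    function_pvalues: pd.Series,
    reference_set,
    all_functions,
) -> float:
    """Mann-Whitney AUC of a function ranking against a reference set.

    Functions are ranked by ascending enrichment p; functions absent from
    ``function_pvalues`` are tied at the bottom, and ties are midranked.
    A contrast is considered misanalyzed when the AUC falls below 0.5.
    """
    all_functions = list(all_functions)
    positives = frozenset(reference_set)
    if not positives or positives >= frozenset(all_functions):
        raise DataError("reference set must be nonempty and a proper subset")
    if not positives <= frozenset(all_functions):
        raise DataError("reference set must be drawn from the function universe")
    # higher score = better ranked; evaluated sets score -p in [-1, 0),
    # unevaluated sets share a score strictly below every evaluated one
    scores = np.full(len(all_functions), -2.0)
    for idx, fn in enumerate(all_functions):
        if fn in function_pvalues.index:
            scores[idx] = -float(function_pvalues[fn])
    ranks = rankdata(scores)
    is_pos = np.array([fn in positives for fn in all_functions])
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def progressive_degradation(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    seed: int,
) -> list[ExpressionMatrix]:
    """Build replicates with progressively destroyed gene ranking.

    The design must pair test and control samples positionally (equal
    cohort sizes, P pairs). Replicate i (i = 0..P) has the feature
    intensities of each array in its first i pairs independently permuted
    across features; replicate 0 is the original. Deterministic in
    ``seed``.
    """
    if len(design.test_samples) != len(design.control_samples):
        raise DataError("progressive degradation needs a paired design")
    pairs = list(zip(design.test_samples, design.control_samples))
    rng = np.random.default_rng(seed)
    nf = matrix.n_features
    replicates = [matrix]
    for i in range(1, len(pairs) + 1):
        frame = matrix.frame.copy()
        for t_id, c_id in pairs[:i]:
            for sid in (t_id, c_id):
                frame[sid] = frame[sid].to_numpy()[rng.permutation(nf)]
        replicates.append(ExpressionMatrix(frame))
    return replicates


def degradation_curve(
    replicates: list[ExpressionMatrix],
    design: CohortDesign,
    collection: GeneSetCollection,
    method: str = "ttest",
    p_cut: float = 0.05,
    top_fractions: tuple[float, ...] = (0.05, 0.10, 0.15),
    enrich_cut: float = DEFAULT_ENRICH_CUT,
) -> pd.DataFrame:
    """Detected-function counts per degradation replicate.

    Per replicate: count of functions detected on the method's p < p_cut
    selection, plus counts on fixed top-fraction slices of the method's
    ranking (ranking derangement, not selection shrinkage, is the point).
    """
    rows = []
    for idx, rep in enumerate(replicates):
        out = evaluate_method(
            method, rep, design, collection, dataset=f"replicate_{idx}",
            p_cut=p_cut, enrich_cut=enrich_cut,
        )
        if method == "hta":
            ranking = HTAModel(rep, design).fit().ranking()
        else:
            ranking = PooledTTest(rep, design).fit().ranking()
        row = {"replicate": idx, "n_functions": out.n_functions}
        for frac in top_fractions:
            top = frozenset(ranking[: max(1, int(round(frac * len(ranking))))])
            enr = fisher_overrepresentation(
                top & collection.universe, collection, enrich_cut=enrich_cut
            )
            row[f"n_functions_top_{int(round(frac * 100))}pct"] = int(
                enr["detected"].sum()
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("replicate")


@dataclass
class BmorrReport:
    """Relative reliability of methods against a reference across datasets."""

    per_dataset: pd.DataFrame  # method, dataset, F, Gq, RSP, RSE, AUC
    per_method: pd.DataFrame  # method, RR, DRF (DRF NaN if no disease list)
    reference: str = "hta"
    undefined_flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Relative reliability report (reference method: {self.reference})",
            "=" * 60,
            "Per dataset:",
            self.per_dataset.round(4).to_string(),
            "",
            "Per method (averages and cross-dataset measures):",
            self.per_method.round(4).to_string(),
        ]
        if self.undefined_flags:
            lines.append("flagged undefined: " + "; ".join(self.undefined_flags))
        return "\n".join(lines)


def bmorr_report(
    datasets: dict[str, tuple[ExpressionMatrix, CohortDesign]],
    methods,
    collection: GeneSetCollection,
    reference: str = "hta",
    disease_functions=None,
    p_cut: float = 0.05,
    fdr_cut: float = 0.05,
    fc_cut: float = 1.0,
    enrich_cut: float = DEFAULT_ENRICH_CUT,
) -> BmorrReport:
    """Run the full assessment: every method on every dataset.

    The reference method is always evaluated (and scores exactly 1 on the
    three relative measures). AUC against the reference's derived function
    set is reported per dataset for every non-reference method; undefined
    ratios are NaN with an entry in ``undefined_flags``.
    """
    methods = list(dict.fromkeys([*methods, reference]))
    outputs: dict[str, dict[str, MethodOutput]] = {m: {} for m in methods}
    for ds_name, (matrix, design) in datasets.items():
        for m in methods:
            outputs[m][ds_name] = evaluate_method(
                m, matrix, design, collection, dataset=ds_name,
                p_cut=p_cut, fdr_cut=fdr_cut, fc_cut=fc_cut, enrich_cut=enrich_cut,
            )

    flags: list[str] = []
    all_fns = collection.set_ids
    rows = []
    for ds_name in datasets:
        ref_out = outputs[reference][ds_name]
        for m in methods:
            out = outputs[m][ds_name]
            rsp = relative_specificity(out, ref_out)
            rse = relative_sensitivity(out, ref_out)
            if np.isnan(rsp):
                flags.append(f"RSP undefined for {m}/{ds_name} (reference found 0 functions)")
            auc = np.nan
            if m != reference and ref_out.n_functions and ref_out.n_functions < len(all_fns):
                auc = auc_vs_reference(
                    out.function_pvalues(), ref_out.detected_functions, all_fns
                )
            rows.append(
                {
                    "method": m,
                    "dataset": ds_name,
                    "F": out.n_functions,
                    "Gq": out.n_genes_fdr,
                    "RSP": rsp,
                    "RSE": rse,
                    "AUC": auc,
                    "misanalyzed": bool(auc < 0.5) if not np.isnan(auc) else False,
                }
            )
    per_dataset = pd.DataFrame(rows).set_index(["method", "dataset"])

    method_rows = []
    for m in methods:
        outs = list(outputs[m].values())
        ref_outs = list(outputs[reference].values())
        rr = np.nan
        if len(datasets) >= 2:
            rr = relative_reproducibility(outs, ref_outs)
            if np.isnan(rr):
                flags.append(f"RR undefined for {m} (no detections)")
        drf = np.nan
        if disease_functions:
            drf = detection_rate(outs, disease_functions, collection)
        sub = per_dataset.xs(m, level="method")
        method_rows.append(
            {
                "method": m,
                "RSP_mean": float(sub["RSP"].mean()),
                "RSE_mean": float(sub["RSE"].mean()),
                "RR": rr,
                "DRF": drf,
            }
        )
    per_method = pd.DataFrame(method_rows).set_index("method")
    return BmorrReport(
        per_dataset=per_dataset,
        per_method=per_method,
        reference=reference,
        undefined_flags=flags,
    )
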