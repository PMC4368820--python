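"""Synthetic two-cohort expression data with known ground truth.

Two data regimes are emulated. "Type I" cohorts behave like genetically
identical samples: every array is a common template plus per-array
additive Gaussian error on the log2 scale, so per-feature sample variance
is independent of fold-change. "Type II" cohorts carry molecular
heterogeneity: latent subtypes within the test cohort each shift a block
of features, producing expression variance that expands with absolute
fold-change — exactly the pattern that misleads gene-wise variance
estimators. True differential expression enters as per-feature log2
shifts applied to the whole test cohort (shared effects) or to single
subtypes (heterogeneous effects); shifted features are the ground-truth
DEGs.

A matching gene-set collection embeds functional structure: "signal"
sets draw their members mostly from the DEG pool, decoy sets from all
features, so enrichment and reliability assessment can be exercised end
to end. Each random ingredient (template, DEG placement, noise, subtype
structure, set membership) uses its own seeded substream, so e.g. setting
the subtype shifts to zero reproduces the type I matrix bit for bit, and
replicate datasets can share their planted biology while drawing
independent noise. All generators are deterministic functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    CohortDesign,
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    write_design,
    write_expression_matrix,
    write_gene_sets,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "simulate_type1",
    "simulate_type2",
    "simulate_study",
    "make_fixture_suite",
]

# substream tags: one independent generator per random ingredient
_TEMPLATE, _DEG, _SUBTYPE, _SETS, _NOISE = 1, 2, 3, 4, 5


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a realistic triplicate contrast.

    Error SDs are on the log2 scale; ``error_sd`` may be a scalar (even
    sample quality) or one value per sample (uneven quality). DEG effect
    magnitudes |delta| are drawn uniformly from ``effect_range`` — the
    lower end sits below common fold-change cutoffs on purpose, since
    modest coordinated shifts are biologically meaningful. Subtype shifts
    apply to the test cohort's latent subgroups only.
    """

    n_features: int = 10_000
    n_test: int = 3
    n_control: int = 3
    template_mean: float = 7.0
    template_sd: float = 2.0
    template_clip: tuple[float, float] = (2.0, 15.0)
    error_sd: float | tuple[float, ...] = 0.2
    deg_fraction: float = 0.1
    effect_range: tuple[float, float] = (0.3, 2.0)
    n_subtypes: int = 0
    subtype_block_size: int = 250
    subtype_shift_range: tuple[float, float] = (0.5, 2.0)
    n_sets: int = 50
    set_size: int = 20
    signal_set_fraction: float = 0.2
    signal_purity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 2 or self.n_test < 2 or self.n_control < 2:
            raise DataError("need >= 2 features and >= 2 samples per cohort")
        sds = np.atleast_1d(np.asarray(self.error_sd, dtype=float))
        if np.any(sds <= 0):
            raise DataError("error SDs must be positive")
        if sds.size not in (1, self.n_test + self.n_control):
            raise DataError(
                f"error_sd needs 1 or {self.n_test + self.n_control} values"
            )
        for frac in (self.deg_fraction, self.signal_set_fraction, self.signal_purity):
            if not 0 <= frac <= 1:
                raise DataError("fractions must lie in [0, 1]")
        if self.n_subtypes < 0 or self.n_subtypes > self.n_test:
            raise DataError("n_subtypes must lie in [0, n_test]")

    def sample_sds(self) -> np.ndarray:
        sds = np.atleast_1d(np.asarray(self.error_sd, dtype=float))
        if sds.size == 1:
            sds = np.repeat(sds, self.n_test + self.n_control)
        return sds


@dataclass
class GroundTruth:
    """What the generator planted: per-feature truth, subtype labels and sets."""

    truth: pd.DataFrame  # index feature; columns is_deg (bool), true_fc (log2)
    subtype_of: dict[str, int]  # test sample id -> subtype index (-1 if none)
    collection: GeneSetCollection
    signal_sets: frozenset[str] = field(default_factory=frozenset)

    @property
    def deg_features(self) -> frozenset[str]:
        return frozenset(self.truth.index[self.truth["is_deg"]])


@dataclass
class _PlantedBiology:
    """Noise-free structure shared by replicate datasets of one study."""

    features: list[str]
    template: np.ndarray
    delta: np.ndarray  # cohort-wide test-cohort shift per feature
    subtype_blocks: list[np.ndarray]  # feature indices per subtype
    subtype_betas: list[np.ndarray]  # per-feature shift per subtype
    subtype_cols: list[np.ndarray]  # test-sample column indices per subtype


def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def _plant(config: SyntheticConfig) -> _PlantedBiology:
    nf, nt = config.n_features, config.n_test
    features = [f"g{i:06d}" for i in range(nf)]
    template = np.clip(
        _rng(config, _TEMPLATE).normal(config.template_mean, config.template_sd, nf),
        *config.template_clip,
    )

    rng_deg = _rng(config, _DEG)
    n_deg = int(round(config.deg_fraction * nf))
    deg_idx = rng_deg.choice(nf, size=n_deg, replace=False)
    delta = np.zeros(nf)
    lo, hi = config.effect_range
    delta[deg_idx] = rng_deg.uniform(lo, hi, n_deg) * rng_deg.choice([-1.0, 1.0], n_deg)

    blocks: list[np.ndarray] = []
    betas: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    if config.n_subtypes > 0:
        rng_sub = _rng(config, _SUBTYPE)
        cols = [np.asarray(c) for c in np.array_split(np.arange(nt), config.n_subtypes)]
        non_deg = np.setdiff1d(np.arange(nf), deg_idx)
        need = config.n_subtypes * config.subtype_block_size
        if need > non_deg.size:
            raise DataError("not enough non-DEG features for the subtype blocks")
        pool = rng_sub.choice(non_deg, size=need, replace=False)
        slo, shi = config.subtype_shift_range
        for s in range(config.n_subtypes):
            block = pool[s * config.subtype_block_size : (s + 1) * config.subtype_block_size]
            beta = rng_sub.uniform(slo, shi, block.size) * rng_sub.choice(
                [-1.0, 1.0], block.size
            )
            blocks.append(block)
            betas.append(beta)
    return _PlantedBiology(features, template, delta, blocks, betas, cols)


def _ground_truth(config: SyntheticConfig, planted: _PlantedBiology) -> GroundTruth:
    true_fc = planted.delta.copy()
    test_ids = [f"t{i + 1}" for i in range(config.n_test)]
    subtype_of = {s: -1 for s in test_ids}
    for s, (block, beta, cols) in enumerate(
        zip(planted.subtype_blocks, planted.subtype_betas, planted.subtype_cols)
    ):
        # cohort-level true fold-change is the shift diluted by subtype share
        true_fc[block] += beta * (len(cols) / config.n_test)
        for col in cols:
            subtype_of[test_ids[col]] = s
    truth = pd.DataFrame(
        {"is_deg": true_fc != 0.0, "true_fc": true_fc},
        index=pd.Index(planted.features, name="feature"),
    )
    collection, signal = _make_collection(config, truth)
    return GroundTruth(
        truth=truth, subtype_of=subtype_of, collection=collection, signal_sets=signal
    )


def _realize(
    config: SyntheticConfig, planted: _PlantedBiology, rng_noise: np.random.Generator
) -> tuple[ExpressionMatrix, CohortDesign]:
    nf, nt, nc = config.n_features, config.n_test, config.n_control
    test_ids = [f"t{i + 1}" for i in range(nt)]
    control_ids = [f"c{i + 1}" for i in range(nc)]
    noise = rng_noise.normal(0.0, 1.0, size=(nf, nt + nc)) * config.sample_sds()
    values = planted.template[:, np.newaxis] + noise
    values[:, :nt] += planted.delta[:, np.newaxis]
    for block, beta, cols in zip(
        planted.subtype_blocks, planted.subtype_betas, planted.subtype_cols
    ):
        values[np.ix_(block, cols)] += beta[:, np.newaxis]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=planted.features, columns=test_ids + control_ids)
    )
    design = CohortDesign(test_samples=test_ids, control_samples=control_ids)
    return matrix, design


def _make_collection(
    config: SyntheticConfig, truth: pd.DataFrame
) -> tuple[GeneSetCollection, frozenset[str]]:
    rng = _rng(config, _SETS)
    features = np.asarray(truth.index)
    deg = np.asarray(truth.index[truth["is_deg"]])
    universe = frozenset(features)
    n_signal = int(round(config.signal_set_fraction * config.n_sets))
    if deg.size == 0:
        n_signal = 0
    sets: dict[str, frozenset[str]] = {}
    for i in range(config.n_sets):
        size = min(config.set_size, features.size)
        if i < n_signal:
            n_from_deg = min(int(round(config.signal_purity * size)), deg.size)
            members = list(rng.choice(deg, size=n_from_deg, replace=False))
            rest = rng.choice(
                np.setdiff1d(features, members), size=size - n_from_deg, replace=False
            )
            members += list(rest)
            name = f"SIGNAL_{i:03d}"
        else:
            members = list(rng.choice(features, size=size, replace=False))
            name = f"DECOY_{i:03d}"
        sets[name] = frozenset(members)
    signal = frozenset(n for n in sets if n.startswith("SIGNAL"))
    return GeneSetCollection(sets=sets, universe=universe), signal


def _simulate(config: SyntheticConfig) -> tuple[ExpressionMatrix, CohortDesign, GroundTruth]:
    planted = _plant(config)
    matrix, design = _realize(config, planted, _rng(config, _NOISE))
    return matrix, design, _ground_truth(config, planted)


def simulate_type1(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, CohortDesign, GroundTruth]:
    """Genetically identical cohorts: template + per-array Gaussian error.

    Requires heterogeneity disabled (``n_subtypes == 0``). With
    ``deg_fraction == 0`` this is pure null data.
    """
    if config.n_subtypes != 0:
        raise DataError("type I data has no subtypes; set n_subtypes=0")
    return _simulate(config)


def simulate_type2(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, CohortDesign, GroundTruth]:
    """Heterogeneous cohorts: type I plus latent subtype shift blocks.

    Subtype shifts inflate within-cohort variance on their block features
    in proportion to the induced fold-change, reproducing the
    variance-expansion pattern of genetically different samples. With
    ``subtype_shift_range == (0, 0)`` the output matrix is bit-identical
    to the type I output for the same seed.
    """
    if config.n_subtypes < 1:
        raise DataError("type II data needs >= 1 subtype; set n_subtypes >= 1")
    return _simulate(config)


def simulate_study(
    config: SyntheticConfig, n_datasets: int
) -> tuple[dict[str, tuple[ExpressionMatrix, CohortDesign]], GroundTruth]:
    """Replicate datasets of one study: shared biology, independent noise.

    All datasets share the template, the planted DEGs and subtype blocks,
    and the gene-set collection; only the technical noise differs. This
    is the substrate for cross-dataset reproducibility assessment.
    """
    if n_datasets < 1:
        raise DataError("need at least one dataset")
    planted = _plant(config)
    datasets = {}
    for j in range(n_datasets):
        rng_noise = np.random.default_rng([config.seed, _NOISE, j])
        datasets[f"dataset_{j}"] = _realize(config, planted, rng_noise)
    return datasets, _ground_truth(config, planted)


def make_fixture_suite(seed: int, out_dir) -> dict[str, dict]:
    """Write a standard battery of small datasets with a manifest.

    Produces: a type I null contrast, a type I contrast with DEGs, a
    type II contrast with two test-cohort subtypes, and a larger paired
    type II contrast for degradation runs, each with matrix, design,
    ground truth and a GMT. Returns the manifest mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = SyntheticConfig(n_features=2000, seed=seed)
    specs = {
        "type1_null": replace(base, deg_fraction=0.0, seed=seed),
        "type1_deg": replace(base, deg_fraction=0.1, seed=seed + 1),
        "type2_subtypes": replace(
            base, deg_fraction=0.05, n_subtypes=2, n_test=4, n_control=4,
            subtype_block_size=150, seed=seed + 2,
        ),
        "paired_degradation": replace(
            base, deg_fraction=0.1, n_subtypes=2, n_test=6, n_control=6,
            subtype_block_size=150, seed=seed + 3,
        ),
    }
    manifest: dict[str, dict] = {}
    for name, cfg in specs.items():
        matrix, design, gt = _simulate(cfg)
        paths = {
            "matrix": str(out / f"{name}.matrix.tsv"),
            "design": str(out / f"{name}.design.tsv"),
            "truth": str(out / f"{name}.truth.tsv"),
            "gmt": str(out / f"{name}.sets.gmt"),
        }
        write_expression_matrix(matrix, paths["matrix"])
        write_design(design, paths["design"])
        gt.truth.to_csv(paths["truth"], sep="\t")
        write_gene_sets(gt.collection, paths["gmt"])
        manifest[name] = {
            "paths": paths,
            "signal_sets": sorted(gt.signal_sets),
            "seed": cfg.seed,
        }
    with open(out / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return manifest
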