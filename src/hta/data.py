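"""Shared domain containers and delimited-text I/O.

The universal substrate is a log2 expression matrix (features x samples)
together with a two-cohort design. Gene-set collections are read from GMT
files. All readers validate invariants on construction so downstream code
can assume clean input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hta")

__all__ = [
    "ExpressionMatrix",
    "CohortDesign",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_gene_sets",
    "write_gene_sets",
    "write_de_results",
    "read_de_results",
]


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Log2 intensities, features in rows, samples in columns.

    Parameters
    ----------
    frame : pandas.DataFrame
        Numeric body; index holds feature ids, columns hold sample ids.
        Both must be unique, all values finite, and the shape at least 2x2.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise DataError(f"duplicate feature id: {dup!r}")
        if f.columns.has_duplicates:
            dup = f.columns[f.columns.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        if f.shape[0] < 2 or f.shape[1] < 2:
            raise DataError(
                f"expression matrix must be at least 2x2, got {f.shape[0]}x{f.shape[1]}"
            )
        values = f.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("expression matrix body must be numeric")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at feature {f.index[r]!r}, sample {f.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_features(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def values_for(self, sample_ids: list[str]) -> np.ndarray:
        """Return the (n_features, len(sample_ids)) value block."""
        return self.frame[list(sample_ids)].to_numpy(dtype=float)


@dataclass
class CohortDesign:
    """Assignment of sample columns to a test and a control cohort."""

    test_samples: list[str]
    control_samples: list[str]

    def __post_init__(self) -> None:
        t, c = list(self.test_samples), list(self.control_samples)
        if len(t) < 2 or len(c) < 2:
            raise DataError("each cohort needs at least 2 samples")
        if len(set(t)) != len(t) or len(set(c)) != len(c):
            raise DataError("duplicate sample id within a cohort")
        overlap = set(t) & set(c)
        if overlap:
            raise DataError(f"samples in both cohorts: {sorted(overlap)}")
        self.test_samples, self.control_samples = t, c

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = (set(self.test_samples) | set(self.control_samples)) - set(
            matrix.sample_ids
        )
        if missing:
            raise DataError(f"design samples absent from matrix: {sorted(missing)}")


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of annotatable feature ids."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            members = frozenset(members)
            if not members:
                raise DataError(f"gene set {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise DataError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )
            clean[name] = members
        self.sets = clean

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV with a sample-id header row and feature-id first column."""
    # pandas mangles duplicate header fields, so check the raw header first
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for sid in header:
        if sid in seen:
            raise DataError(f"{path}: duplicate sample id in header: {sid!r}")
        seen.add(sid)
    # keep_default_na=False so sentinel strings like "NA" are rejected as
    # parse errors rather than silently becoming missing values
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0, keep_default_na=False)
    body = frame.apply(pd.to_numeric, errors="coerce")
    bad = body.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{path}: non-numeric cell at feature {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r}: {frame.iat[r, c]!r}"
        )
    body.index = body.index.astype(str)
    body.columns = body.columns.astype(str)
    return ExpressionMatrix(body)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.frame.to_csv(path, sep="\t", index_label="feature", float_format="%.12g")


def read_design(path) -> CohortDesign:
    """Read a two-column TSV: sample_id, cohort in {test, control}."""
    table = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if table.shape[1] < 2:
        raise DataError(f"{path}: design needs columns sample_id and cohort")
    sample_col, cohort_col = table.columns[:2]
    groups: dict[str, list[str]] = {"test": [], "control": []}
    for _, row in table.iterrows():
        cohort = row[cohort_col].strip().lower()
        if cohort not in groups:
            raise DataError(
                f"{path}: unknown cohort label {row[cohort_col]!r} "
                f"for sample {row[sample_col]!r}"
            )
        groups[cohort].append(row[sample_col])
    return CohortDesign(test_samples=groups["test"], control_samples=groups["control"])


def write_design(design: CohortDesign, path) -> None:
    rows = [(s, "test") for s in design.test_samples]
    rows += [(s, "control") for s in design.control_samples]
    pd.DataFrame(rows, columns=["sample_id", "cohort"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path, universe) -> GeneSetCollection:
    """Read a GMT file, intersecting each set with `universe`.

    GMT dialect: one set per line, tab-separated fields
    ``set_id<TAB>description<TAB>member...``. Members outside the universe
    are dropped with a logged warning; sets emptied by the intersection are
    dropped entirely.
    """
    universe = frozenset(str(u) for u in universe)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line needs id, description and members"
                )
            name, members = fields[0], [m for m in fields[2:] if m]
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate set id {name!r}")
            kept = frozenset(members) & universe
            dropped = len(set(members)) - len(kept)
            if dropped:
                logger.warning(
                    "gene set %r: %d member(s) outside universe dropped", name, dropped
                )
            if kept:
                sets[name] = kept
            else:
                logger.warning("gene set %r empty after universe intersection", name)
    return GeneSetCollection(sets=sets, universe=universe)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, members in collection.sets.items():
            handle.write("\t".join([name, "na", *sorted(members)]) + "\n")


DE_COLUMNS = ["feature", "fc_hat", "var_fc", "z", "p", "q"]


def write_de_results(results: pd.DataFrame, path) -> None:
    """Write a differential-expression result table as TSV.

    Expects columns fc_hat, var_fc, z, p, q with feature ids in the index;
    values survive a read-back round trip to 12 significant digits.
    """
    out = results.reset_index()
    out.columns = DE_COLUMNS[: out.shape[1]]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_de_results(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", header=0)
    return table.set_index(table.columns[0])
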