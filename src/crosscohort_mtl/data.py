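"""Core in-memory containers for multi-cohort case-control expression data.

A *cohort* is one study's gene-expression matrix (genes x samples, log2
scale) together with aligned per-sample metadata (diagnosis, sex, age,
post-mortem interval, brain pH).  A :class:`MultiTaskData` bundles several
cohorts on a common, identically ordered gene set and exposes them as
classification *tasks* with labels coded -1 (control) / +1 (case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every cohort must provide (``ph`` may contain NaN)
META_COLUMNS = ("sample_id", "diagnosis", "sex", "age", "pmi", "ph")

#: label coding used throughout: case -> +1, control -> -1
LABEL_CODE = {"case": 1, "control": -1}


@dataclass
class CohortDataset:
    """One cohort: expression matrix plus aligned sample metadata.

    Parameters
    ----------
    cohort_id
        Short identifier, e.g. a GEO accession or synthetic cohort name.
    expr
        DataFrame of continuous expression values, index = gene symbols,
        columns = sample IDs (log2 scale by convention).
    meta
        DataFrame with one row per sample, columns ``sample_id``,
        ``diagnosis`` ('case'/'control'), ``sex`` ('m'/'f'), ``age`` (years),
        ``pmi`` (hours), ``ph`` (unitless, may be NaN).
    """

    cohort_id: str
    expr: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(
                f"cohort {self.cohort_id!r}: metadata missing columns {missing}"
            )
        expr_ids = list(self.expr.columns)
        meta_ids = list(self.meta["sample_id"])
        if set(expr_ids) != set(meta_ids):
            raise ValueError(
                f"cohort {self.cohort_id!r}: sample-ID mismatch between "
                f"expression and metadata"
            )
        if expr_ids != meta_ids:
            # align expression columns to metadata row order
            self.expr = self.expr.loc[:, meta_ids]
        if self.expr.index.duplicated().any():
            dups = sorted(set(self.expr.index[self.expr.index.duplicated()]))
            raise ValueError(
                f"cohort {self.cohort_id!r}: duplicate gene symbols {dups[:5]} "
                f"(run probe collapsing first)"
            )
        values = self.expr.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(
                f"cohort {self.cohort_id!r}: non-numeric expression values"
            )
        if np.isnan(values).any():
            raise ValueError(
                f"cohort {self.cohort_id!r}: missing expression values"
            )
        bad = set(self.meta["diagnosis"]) - {"case", "control"}
        if bad:
            raise ValueError(
                f"cohort {self.cohort_id!r}: unknown diagnosis values {bad}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    def labels(self) -> np.ndarray:
        """Diagnosis coded -1 (control) / +1 (case), in sample order."""
        return self.meta["diagnosis"].map(LABEL_CODE).to_numpy(dtype=float)

    def subset_samples(self, sample_ids: list[str]) -> "CohortDataset":
        """Restrict (and reorder) to the given sample IDs.

        Repeated IDs are allowed and produce repeated columns; bootstrap
        resampling relies on this, with a disambiguating suffix appended.
        """
        meta = self.meta.set_index("sample_id", drop=False).loc[sample_ids]
        new_ids = sample_ids
        if len(set(sample_ids)) != len(sample_ids):
            new_ids = [f"{s}#{k}" for k, s in enumerate(sample_ids)]
        expr = self.expr.loc[:, sample_ids].copy()
        expr.columns = new_ids
        meta = meta.copy()
        meta["sample_id"] = new_ids
        meta = meta.reset_index(drop=True)
        return CohortDataset(self.cohort_id, expr, meta)

    def equals(self, other: "CohortDataset", tol: float = 1e-12) -> bool:
        return (
            self.cohort_id == other.cohort_id
            and self.genes == other.genes
            and list(self.expr.columns) == list(other.expr.columns)
            and np.allclose(self.expr.to_numpy(), other.expr.to_numpy(), atol=tol)
            and self.meta.reset_index(drop=True).equals(
                other.meta.reset_index(drop=True)
            )
        )


@dataclass
class MultiTaskData:
    """Ordered cohorts on a shared gene set, viewed as classification tasks.

    ``X(i)`` returns task *i*'s samples-by-genes design matrix and ``Y(i)``
    its +/-1 labels; all tasks share ``gene_ids`` in identical order.
    """

    cohorts: list[CohortDataset]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("MultiTaskData needs at least one cohort")
        if not self.gene_ids:
            self.gene_ids = self.cohorts[0].genes
        for c in self.cohorts:
            if c.genes != self.gene_ids:
                raise ValueError(
                    f"cohort {c.cohort_id!r} gene order differs from the "
                    f"common gene set (intersect/reorder first)"
                )

    @property
    def t(self) -> int:
        return len(self.cohorts)

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    @property
    def n_i(self) -> list[int]:
        return [c.n_samples for c in self.cohorts]

    @property
    def cohort_ids(self) -> list[str]:
        return [c.cohort_id for c in self.cohorts]

    def X(self, i: int) -> np.ndarray:
        """Task *i* design matrix, samples x genes."""
        return self.cohorts[i].expr.to_numpy().T

    def Y(self, i: int) -> np.ndarray:
        return self.cohorts[i].labels()

    def tasks(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.X(i), self.Y(i)) for i in range(self.t)]

    def subset(self, indices: list[int]) -> "MultiTaskData":
        """New MultiTaskData restricted to the given cohort indices (ordered)."""
        return MultiTaskData([self.cohorts[i] for i in indices], self.gene_ids)

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Row-wise concatenation of all tasks (for single-task learners)."""
        X = np.vstack([self.X(i) for i in range(self.t)])
        Y = np.concatenate([self.Y(i) for i in range(self.t)])
        return X, Y
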