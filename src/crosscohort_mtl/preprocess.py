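"""Post-import preprocessing for multi-cohort expression data.

The pipeline order is fixed:

    collapse probes -> intersect genes -> 1:1 propensity matching (per
    cohort) -> concatenate -> quantile normalization -> covariate/batch
    adjustment -> split -> per-dataset z-scoring

Batch adjustment follows the parametric empirical-Bayes location-scale
scheme popularized by ComBat: per-gene linear model with nuisance
covariates (sex, pH, age, age^2, PMI) and the dataset indicator as batch;
shrunken per-dataset location and scale effects are removed, and the
fitted covariate contributions are subtracted as well.  Diagnosis is never
part of the design matrix, so case-control signal is protected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data import CohortDataset

logger = logging.getLogger("crosscohort_mtl")

#: covariates entering propensity and batch-adjustment design matrices
MATCH_COVARIATES = ("sex", "ph", "age", "pmi")


# -- probe collapsing and gene intersection -------------------------------

def collapse_probes(expr: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene symbol (probe -> gene collapsing).

    Keeps the first-occurrence row order and the column order unchanged.
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    return expr.groupby(level=0, sort=False).mean()


def intersect_genes(cohorts: list[CohortDataset]) -> list[CohortDataset]:
    """Restrict every cohort to the sorted common gene set."""
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to intersect")
    common: set[str] = set(cohorts[0].genes)
    for c in cohorts[1:]:
        common &= set(c.genes)
    if not common:
        raise ValueError("empty gene intersection across cohorts")
    genes = sorted(common)
    out = []
    for c in cohorts:
        out.append(CohortDataset(c.cohort_id, c.expr.loc[genes].copy(),
                                 c.meta.copy()))
    logger.info("intersect_genes: %d common genes across %d cohorts",
                len(genes), len(cohorts))
    return out


# -- propensity-score 1:1 matching ----------------------------------------

@dataclass
class MatchedDesign:
    """Greedy 1:1 case-control pairs with their propensity scores."""

    pairs: list[tuple[str, str]]          # (case sample_id, control sample_id)
    propensity: pd.Series                 # per-sample P(case | covariates)
    dropped_covariates: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> list[str]:
        out: list[str] = []
        for case, control in self.pairs:
            out.extend([case, control])
        return out


def _propensity_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    cols, dropped = [], []
    mat = []
    for cov in MATCH_COVARIATES:
        vals = meta[cov]
        if cov == "sex":
            vals = vals.map({"m": 1.0, "f": 0.0})
        vals = pd.to_numeric(vals)
        if vals.isna().any():
            dropped.append(cov)
            logger.info("propensity_match: dropping covariate %r (missing values)", cov)
            continue
        if float(vals.std()) == 0.0:
            dropped.append(cov)
            warnings.warn(f"propensity_match: constant covariate {cov!r} dropped")
            continue
        cols.append(cov)
        mat.append((vals - vals.mean()) / vals.std())
    if not cols:
        raise ValueError("no usable matching covariates")
    return np.column_stack(mat), cols, dropped


def propensity_match(cohort: CohortDataset,
                     caliper: float | None = None) -> MatchedDesign:
    """Greedy nearest-neighbor 1:1 matching on the propensity logit.

    The propensity is a logistic model of diagnosis on the matching
    covariates (pH is skipped when missing).  Subjects of the smaller
    diagnosis group are processed in order of descending propensity (ties
    broken by sample ID) and each is paired with the nearest unused subject
    of the larger group on the logit scale; anchoring on the minority class
    ensures every anchor finds a genuine nearest neighbor, so matching
    cannot select an extreme tail of the majority group.  ``caliper`` is a
    maximum pair distance expressed in SDs of the logit (``None`` disables
    it).
    """
    meta = cohort.meta
    y = (meta["diagnosis"] == "case").to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"cohort {cohort.cohort_id!r}: one diagnosis class absent")
    X, used, dropped = _propensity_design(meta)
    lr = LogisticRegression(C=np.inf, max_iter=2000)
    lr.fit(X, y)
    score = lr.predict_proba(X)[:, 1].clip(1e-12, 1 - 1e-12)
    propensity = pd.Series(score, index=meta["sample_id"].to_list(), name="propensity")
    logit = np.log(score / (1 - score))
    logit_s = pd.Series(logit, index=propensity.index)

    cases = meta.loc[y == 1, "sample_id"].to_list()
    controls = meta.loc[y == 0, "sample_id"].to_list()
    anchors, pool = (cases, controls) if len(cases) <= len(controls) else (controls, cases)
    anchors = sorted(anchors, key=lambda s: (-propensity[s], s))
    case_set = set(cases)
    max_dist = np.inf
    if caliper is not None:
        max_dist = caliper * float(np.std(logit))

    available = set(pool)
    pairs: list[tuple[str, str]] = []
    for anchor in anchors:
        if not available:
            break
        # nearest unused pool member on the logit scale, ties by sample_id
        best = min(available, key=lambda c: (abs(logit_s[c] - logit_s[anchor]), c))
        if abs(logit_s[best] - logit_s[anchor]) <= max_dist:
            pair = (anchor, best) if anchor in case_set else (best, anchor)
            pairs.append(pair)
            available.remove(best)
    return MatchedDesign(pairs=pairs, propensity=propensity, dropped_covariates=dropped)


def apply_matching(cohort: CohortDataset, design: MatchedDesign) -> CohortDataset:
    """Restrict a cohort to its matched case-control pairs."""
    return cohort.subset_samples(design.matched_ids())


def standardized_mean_difference(meta: pd.DataFrame, covariate: str) -> float:
    """Case-vs-control SMD of one covariate (pooled-SD denominator)."""
    vals = meta[covariate]
    if covariate == "sex":
        vals = vals.map({"m": 1.0, "f": 0.0})
    vals = pd.to_numeric(vals)
    case = vals[meta["diagnosis"] == "case"]
    ctrl = vals[meta["diagnosis"] == "control"]
    pooled = np.sqrt((case.var(ddof=1) + ctrl.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((case.mean() - ctrl.mean()) / pooled)


# -- quantile normalization ------------------------------------------------

def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean-of-order-statistics scale.

    Ties within a column receive the average of the reference values of the
    tied ranks, so tied inputs stay tied in the output.
    """
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile_normalize: NA cells in input")
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n_genes, n_samples = values.shape
    for j in range(n_samples):
        assigned = np.empty(n_genes)
        assigned[order[:, j]] = reference
        col = values[:, j]
        # average reference values across tied entries
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned, minlength=len(uniq))
        counts = np.bincount(inv, minlength=len(uniq))
        out[:, j] = (sums / counts)[inv]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# -- covariate / batch adjustment (parametric EB, ComBat-style) ------------

def _eb_posterior(gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior,
                  n_batch, sum_sq, tol=1e-6, max_iter=500):
    """Iterative joint posterior for per-batch location/scale effects."""
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (tau2 * n_batch * gamma_hat + delta * gamma_bar) / (
            tau2 * n_batch + delta
        )
        sum2 = sum_sq - 2.0 * gamma_new * n_batch * gamma_hat + n_batch * gamma_new ** 2
        delta_new = (0.5 * sum2 + b_prior) / (n_batch / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma) / np.maximum(np.abs(gamma), 1e-12)),
            np.max(np.abs(delta_new - delta) / np.maximum(np.abs(delta), 1e-12)),
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, delta


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m ** 2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def build_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Nuisance-covariate design: sex, ph, age, age^2, pmi (no intercept,
    no diagnosis).  pH is dropped, with a log line, when any sample lacks it."""
    cols: list[str] = []
    mats = []
    sex = meta["sex"].map({"m": 1.0, "f": 0.0}).to_numpy(dtype=float)
    mats.append(sex)
    cols.append("sex")
    ph = pd.to_numeric(meta["ph"])
    if ph.isna().any():
        logger.info("adjust_covariates: dropping pH (missing in >=1 sample)")
    else:
        mats.append(ph.to_numpy(dtype=float))
        cols.append("ph")
    age = pd.to_numeric(meta["age"]).to_numpy(dtype=float)
    mats.append(age)
    cols.append("age")
    mats.append(age ** 2)
    cols.append("age2")
    mats.append(pd.to_numeric(meta["pmi"]).to_numpy(dtype=float))
    cols.append("pmi")
    X = np.column_stack(mats)
    # center and scale for numerical stability of the per-gene regressions
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    return X, cols


def adjust_covariates(expr: pd.DataFrame, meta: pd.DataFrame,
                      keep_covariates: bool = False,
                      parametric_shrinkage: bool = True) -> pd.DataFrame:
    """Remove dataset (batch) location/scale effects and covariate effects.

    ``expr`` holds the concatenated cohorts (genes x samples); ``meta`` must
    align with its columns and provide a ``dataset`` indicator plus the
    nuisance covariates.  Per-gene linear effects of the covariates are
    estimated jointly with batch means; batch location/scale effects are
    shrunk toward their across-gene priors (parametric empirical Bayes)
    before removal.  With ``keep_covariates=True`` the fitted covariate
    contribution is added back (the classical ComBat output); the default
    removes it.
    """
    if "dataset" not in meta.columns:
        raise ValueError("metadata needs a 'dataset' indicator column")
    if list(meta["sample_id"]) != list(expr.columns):
        raise ValueError("metadata rows must align with expression columns")
    data = expr.to_numpy(dtype=float)
    p, N = data.shape
    batches = pd.Categorical(meta["dataset"])
    levels = list(batches.categories)
    n_batches = np.array([(batches == b).sum() for b in levels], dtype=float)
    B = len(levels)
    onehot = np.column_stack([(batches == b).astype(float) for b in levels])
    X_cov, cov_names = build_design(meta)
    design = np.column_stack([onehot, X_cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (batch + covariates)")

    # per-gene OLS of expression on batch indicators + covariates
    B_hat, *_ = np.linalg.lstsq(design, data.T, rcond=None)   # (B+k) x p
    grand_mean = (n_batches / N) @ B_hat[:B]                  # per gene
    resid = data.T - design @ B_hat
    var_pooled = (resid ** 2).sum(axis=0) / N                 # per gene
    var_pooled = np.maximum(var_pooled, 1e-12)
    cov_contrib = (X_cov @ B_hat[B:]).T                       # p x N
    stand_mean = grand_mean[:, None] + cov_contrib
    sd = np.sqrt(var_pooled)[:, None]
    Z = (data - stand_mean) / sd

    adjusted = np.empty_like(Z)
    for b_idx, level in enumerate(levels):
        mask = (batches == level)
        Zb = Z[:, np.asarray(mask)]
        nb = Zb.shape[1]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1) if nb > 1 else np.ones(p)
        delta_hat = np.maximum(delta_hat, 1e-12)
        if parametric_shrinkage and p > 1 and nb > 1:
            gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
            a_pr, b_pr = _aprior(delta_hat), _bprior(delta_hat)
            sum_sq = ((Zb - gamma_hat[:, None]) ** 2).sum(axis=1) + nb * gamma_hat ** 2
            gamma_star, delta_star = _eb_posterior(
                gamma_hat, delta_hat, gamma_bar, tau2, a_pr, b_pr,
                float(nb), sum_sq,
            )
        else:
            gamma_star, delta_star = gamma_hat, delta_hat
        adjusted[:, np.asarray(mask)] = (Zb - gamma_star[:, None]) / np.sqrt(
            np.maximum(delta_star, 1e-12)
        )[:, None]

    out = adjusted * sd + grand_mean[:, None]
    if keep_covariates:
        out = out + cov_contrib
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# -- per-dataset z-scoring -------------------------------------------------

def zscore_per_dataset(cohorts: list[CohortDataset]) -> list[CohortDataset]:
    """Standardize each gene to mean 0 / population SD 1 within each cohort.

    Genes with zero variance become all-zero rows (with a warning).
    """
    out = []
    for c in cohorts:
        if c.n_samples < 2:
            raise ValueError(f"cohort {c.cohort_id!r}: cannot z-score a single sample")
        vals = c.expr.to_numpy(dtype=float)
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        zero = sd[:, 0] == 0.0
        if zero.any():
            warnings.warn(
                f"cohort {c.cohort_id!r}: {int(zero.sum())} constant gene(s) set to 0"
            )
        sd[zero, :] = 1.0
        z = (vals - mean) / sd
        z[zero, :] = 0.0
        out.append(CohortDataset(c.cohort_id,
                                 pd.DataFrame(z, index=c.expr.index,
                                              columns=c.expr.columns),
                                 c.meta.copy()))
    return out


# -- full pipeline ---------------------------------------------------------

def concatenate(cohorts: list[CohortDataset]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise concatenation plus a combined metadata table with a
    ``dataset`` indicator."""
    expr = pd.concat([c.expr for c in cohorts], axis=1)
    metas = []
    for c in cohorts:
        m = c.meta.copy()
        m["dataset"] = c.cohort_id
        metas.append(m)
    meta = pd.concat(metas, ignore_index=True)
    return expr, meta


def split(expr: pd.DataFrame, meta: pd.DataFrame,
          cohorts: list[CohortDataset]) -> list[CohortDataset]:
    out = []
    for c in cohorts:
        ids = meta.loc[meta["dataset"] == c.cohort_id, "sample_id"].to_list()
        sub_meta = c.meta[c.meta["sample_id"].isin(ids)].reset_index(drop=True)
        out.append(CohortDataset(c.cohort_id, expr.loc[:, ids].copy(), sub_meta))
    return out


def run_pipeline(cohorts: list[CohortDataset], match: bool = True,
                 caliper: float | None = None,
                 adjust: bool = True) -> tuple[list[CohortDataset], dict]:
    """Run the fixed preprocessing order and return processed cohorts plus a
    stage log (matched designs, gene counts)."""
    info: dict = {}
    cohorts = [
        CohortDataset(c.cohort_id, collapse_probes(c.expr), c.meta.copy())
        for c in cohorts
    ]
    cohorts = intersect_genes(cohorts)
    info["n_common_genes"] = cohorts[0].n_genes
    if match:
        designs = {}
        matched = []
        for c in cohorts:
            d = propensity_match(c, caliper=caliper)
            designs[c.cohort_id] = d
            matched.append(apply_matching(c, d))
        cohorts = matched
        info["matched_designs"] = designs
    expr, meta = concatenate(cohorts)
    expr = quantile_normalize(expr)
    if adjust:
        expr = adjust_covariates(expr, meta)
    cohorts = split(expr, meta, cohorts)
    cohorts = zscore_per_dataset(cohorts)
    return cohorts, info
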