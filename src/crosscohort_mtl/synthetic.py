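"""Synthetic multi-cohort case-control expression data.

The generator emulates the statistical regime of multi-cohort brain
transcriptomics: a *weak* diagnostic signature shared across cohorts,
per-cohort perturbations of that signature, *dominant* per-cohort batch
offsets that outweigh the signal, linear covariate (age/sex/PMI/pH)
effects shared across cohorts, and configurable case/control imbalance for
exercising propensity matching.

Generative model, for cohort i and sample j with label y in {-1, +1}:

    x_j = b_i + y * w_i / 2 + Gamma @ z_j + e_j,   e_j ~ N(0, I_p)

where ``b_i`` is a per-cohort per-gene batch offset (SD ``sigma_batch``),
``w_i = w_star + task perturbation`` on the signature support (SD
``sigma_task``), ``Gamma`` holds global per-gene covariate loadings and
``z_j`` the sample's covariates.  The symmetric +/- w/2 coding makes a
logistic model with weights proportional to ``w_i`` Bayes-optimal, so
parameter-recovery tests are well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortDataset

#: covariates that can carry nuisance effects, in canonical order
COVARIATES = ("age", "sex", "pmi", "ph")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multi-cohort generator.

    Defaults describe the regime the analysis targets: five cohorts, a weak
    shared signature (``beta`` well below one noise SD per gene), moderate
    per-cohort signature deviation, and batch offsets whose SD is several
    times the signal.
    """

    t: int = 5                      # number of cohorts
    p: int = 300                    # number of genes
    n_per_cohort: int | list[int] = 60   # samples per cohort, pre-matching
    s: int = 20                     # signature support size
    beta: float = 0.8               # shared effect size, SD units per gene
    sigma_task: float = 0.3         # SD of per-cohort signature perturbation
    sigma_batch: float = 2.0        # SD of per-cohort per-gene offsets
    covariate_effects: dict[str, float] = field(default_factory=dict)
    n_cov_genes: int = 10           # genes loaded by each covariate effect
    case_fraction: float = 0.5
    batch_scale: bool = False       # per-cohort variance inflation, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s > self.p:
            raise ValueError(f"support size s={self.s} exceeds p={self.p}")
        if self.beta < 0 or self.sigma_task < 0 or self.sigma_batch < 0:
            raise ValueError("beta, sigma_task and sigma_batch must be >= 0")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie strictly in (0, 1)")
        unknown = set(self.covariate_effects) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates {unknown}")

    def sizes(self) -> list[int]:
        if isinstance(self.n_per_cohort, int):
            return [self.n_per_cohort] * self.t
        if len(self.n_per_cohort) != self.t:
            raise ValueError("n_per_cohort list length must equal t")
        return list(self.n_per_cohort)


@dataclass
class ImbalanceSpec:
    """Case-vs-control covariate shifts and group-size imbalance.

    ``age_shift``/``pmi_shift``/``ph_shift`` are added to case covariates;
    ``sex_shift`` is added to the case male probability; ``case_fraction``
    overrides the balanced default.  A zero spec reproduces ``generate``.
    """

    age_shift: float = 0.0
    sex_shift: float = 0.0
    pmi_shift: float = 0.0
    ph_shift: float = 0.0
    case_fraction: float | None = None

    def is_null(self) -> bool:
        return (
            self.age_shift == self.sex_shift == self.pmi_shift == self.ph_shift == 0.0
            and self.case_fraction is None
        )


@dataclass
class GroundTruth:
    """Latent quantities of one synthetic draw, for recovery tests."""

    support: np.ndarray          # indices of signature genes
    w_star: np.ndarray           # shared effect vector, length p, 0 off support
    w_task: np.ndarray           # p x t per-cohort effect vectors
    batch_offsets: np.ndarray    # p x t per-cohort per-gene offsets
    cov_loadings: dict[str, np.ndarray]   # covariate -> length-p loading
    cohort_cov_means: pd.DataFrame        # per-cohort covariate means used


def _draw_structure(cfg: SyntheticConfig, rng: np.random.Generator) -> GroundTruth:
    support = np.sort(rng.choice(cfg.p, size=cfg.s, replace=False))
    w_star = np.zeros(cfg.p)
    w_star[support] = cfg.beta * rng.choice([-1.0, 1.0], size=cfg.s)
    w_task = np.tile(w_star[:, None], (1, cfg.t))
    w_task[support, :] += rng.normal(0.0, cfg.sigma_task, size=(cfg.s, cfg.t))
    batch = rng.normal(0.0, cfg.sigma_batch, size=(cfg.p, cfg.t))
    loadings = {}
    for cov, coef in cfg.covariate_effects.items():
        vec = np.zeros(cfg.p)
        idx = rng.choice(cfg.p, size=min(cfg.n_cov_genes, cfg.p), replace=False)
        vec[idx] = coef
        loadings[cov] = vec
    means = pd.DataFrame(
        {
            "age": rng.uniform(40.0, 75.0, size=cfg.t),
            "pmi": rng.uniform(5.0, 40.0, size=cfg.t),
            "ph": rng.normal(6.3, 0.1, size=cfg.t),
            "male_frac": rng.uniform(0.55, 0.75, size=cfg.t),
        },
        index=[f"cohort{i+1}" for i in range(cfg.t)],
    )
    return GroundTruth(support, w_star, w_task, batch, loadings, means)


def _generate(cfg: SyntheticConfig, spec: ImbalanceSpec) -> tuple[list[CohortDataset], GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_structure(cfg, rng)
    case_frac = spec.case_fraction if spec.case_fraction is not None else cfg.case_fraction
    if not 0 < case_frac < 1:
        raise ValueError("case_fraction must lie strictly in (0, 1)")

    cohorts: list[CohortDataset] = []
    for i, n in enumerate(cfg.sizes()):
        cid = f"cohort{i+1}"
        n_case = int(round(case_frac * n))
        if n_case in (0, n):
            raise ValueError(f"{cid}: degenerate case/control split ({n_case}/{n})")
        y = np.concatenate([np.ones(n_case), -np.ones(n - n_case)])
        rng.shuffle(y)
        is_case = y > 0

        row = truth.cohort_cov_means.iloc[i]
        age = rng.normal(row["age"], 12.0, size=n)
        pmi = rng.normal(row["pmi"], 8.0, size=n).clip(min=0.5)
        ph = rng.normal(row["ph"], 0.25, size=n)
        p_male = np.full(n, row["male_frac"])
        age[is_case] += spec.age_shift
        pmi[is_case] += spec.pmi_shift
        ph[is_case] += spec.ph_shift
        p_male[is_case] = np.clip(p_male[is_case] + spec.sex_shift, 0.02, 0.98)
        sex_m = rng.random(n) < p_male

        x = truth.batch_offsets[:, i][:, None] + 0.5 * np.outer(truth.w_task[:, i], y)
        cov_values = {"age": age, "sex": sex_m.astype(float), "pmi": pmi, "ph": ph}
        for cov, vec in truth.cov_loadings.items():
            x = x + np.outer(vec, cov_values[cov])
        noise_sd = 1.0
        if cfg.batch_scale:
            noise_sd = float(np.exp(rng.normal(0.0, 0.25)))
        x = x + rng.normal(0.0, noise_sd, size=(cfg.p, n))

        sample_ids = [f"{cid}_s{j+1:03d}" for j in range(n)]
        expr = pd.DataFrame(x, index=[f"G{g+1:04d}" for g in range(cfg.p)],
                            columns=sample_ids)
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "diagnosis": np.where(is_case, "case", "control"),
                "sex": np.where(sex_m, "m", "f"),
                "age": np.round(age, 2),
                "pmi": np.round(pmi, 2),
                "ph": np.round(ph, 3),
            }
        )
        cohorts.append(CohortDataset(cid, expr, meta))
    return cohorts, truth


def generate(cfg: SyntheticConfig) -> tuple[list[CohortDataset], GroundTruth]:
    """Draw balanced multi-cohort data; deterministic given ``cfg.seed``."""
    return _generate(cfg, ImbalanceSpec())


def make_imbalanced(cfg: SyntheticConfig,
                    spec: ImbalanceSpec) -> tuple[list[CohortDataset], GroundTruth]:
    """Draw cohorts whose diagnosis is confounded with covariates.

    Cases receive the spec's covariate shifts and group sizes follow the
    spec's case fraction, producing the pre-matching imbalance that
    propensity matching is meant to repair.  A null spec reproduces
    :func:`generate` exactly.
    """
    return _generate(cfg, spec)
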