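"""Seeded synthetic cohorts with planted group-wise dependence structure.

The generator emulates the statistical shape the downstream analysis
assumes: ~17% lethal prevalence, group-dependent SIS correlation structure
(the lethal group carries a partial-correlation hub at item 11, the
nonlethal group a hub at item 9 with the method items 10 and 11
disconnected), male excess and higher mean age in the lethal group, and a
small MCAR missingness rate.

SIS items are drawn from a Gaussian copula: per group a latent multivariate
normal with the planted correlation matrix, discretised to {0,1,2} at the
fixed standard-normal 1/3 and 2/3 quantiles, so each item's marginal
distribution is identical across seeds in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_cohort import (
    CONFOUNDER_COLUMNS,
    CSSRS_COLUMN,
    DATA_COLUMNS,
    ID_COLUMN,
    SIS_COLUMNS,
    CohortTable,
    encode_date,
)

__all__ = [
    "GeneratorConfig",
    "PlantedTruth",
    "default_planted_networks",
    "pairwise_signal_config",
    "generate_cohort",
]

# latent-normal cut points giving balanced thirds for the 0/1/2 scores
_THRESHOLDS = stats.norm.ppf([1 / 3, 2 / 3])

# planted partial correlations, 1-based SIS item pairs; item 11 is the
# strict degree hub of the lethal group
_LETHAL_EDGES = {
    (10, 11): 0.35,  # ExFatal - ConMeth
    (11, 12): 0.35,  # ConMeth - SeriAtt
    (9, 11): 0.25,   # APurpo - ConMeth
    (1, 2): 0.30,    # sparse pairs elsewhere
    (3, 4): 0.30,
    (5, 6): 0.25,
    (13, 14): 0.25,
}
_NONLETHAL_EDGES = {
    (9, 13): 0.35,   # APurpo hub
    (9, 14): 0.35,
    (9, 15): 0.30,
    (1, 2): 0.30,
    (5, 6): 0.25,
    # items 10 and 11 are incident to no edge: method features disconnected
}


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted SIS dependence for one outcome group."""

    group: str
    true_edges: frozenset  # frozenset of (i, j) 1-based item pairs, i < j
    hub_item: int  # 1-based index of the planted hub item

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "true_edges": sorted(map(list, self.true_edges)),
            "hub_item": self.hub_item,
        }


def _corr_from_partial(edges: dict, p: int = 15) -> np.ndarray:
    """Correlation matrix whose inverse has support exactly on ``edges``.

    Builds a unit-diagonal precision matrix with -rho at each planted pair
    (diagonally dominant, hence positive definite), inverts it, and rescales
    to unit variances; rescaling preserves the support of the inverse.
    """
    theta = np.eye(p)
    for (i, j), rho in edges.items():
        theta[i - 1, j - 1] = theta[j - 1, i - 1] = -rho
    if np.linalg.eigvalsh(theta).min() <= 0:
        raise ValueError("planted precision matrix is not positive definite")
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def default_planted_networks():
    """Default (lethal, nonlethal) SIS correlation matrices and truths.

    The lethal matrix carries a partial-correlation hub at item 11
    (conception of the method's lethality) tied to items 10 and 12 plus a
    sparse chain elsewhere; the nonlethal matrix has a hub at item 9
    (alleged purpose) and leaves items 10 and 11 fully disconnected.
    """
    lethal_corr = _corr_from_partial(_LETHAL_EDGES)
    nonlethal_corr = _corr_from_partial(_NONLETHAL_EDGES)
    lethal_truth = PlantedTruth(
        "lethal", frozenset(_LETHAL_EDGES), hub_item=11
    )
    nonlethal_truth = PlantedTruth(
        "nonlethal", frozenset(_NONLETHAL_EDGES), hub_item=9
    )
    return (lethal_corr, nonlethal_corr), (lethal_truth, nonlethal_truth)


def _default_mean_shift() -> np.ndarray:
    shift = np.zeros(15)
    shift[[9, 10, 11]] = 0.6  # items 10-12 raised in the lethal group
    return shift


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator."""

    n_subjects: int = 1112
    prevalence: float = 0.171
    sis_corr_lethal: np.ndarray = None
    sis_corr_nonlethal: np.ndarray = None
    sis_mean_shift: np.ndarray = field(default_factory=_default_mean_shift)
    age_mean_lethal: float = 47.3
    age_mean_nonlethal: float = 42.3
    age_sd: float = 18.0
    male_prob_lethal: float = 0.563
    male_prob_nonlethal: float = 0.387
    missing_rate: float = 0.027
    seed: int = 0

    def __post_init__(self) -> None:
        (lethal, nonlethal), _ = default_planted_networks()
        if self.sis_corr_lethal is None:
            self.sis_corr_lethal = lethal
        if self.sis_corr_nonlethal is None:
            self.sis_corr_nonlethal = nonlethal
        self.sis_mean_shift = np.asarray(self.sis_mean_shift, dtype=float)
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        for name in ("sis_corr_lethal", "sis_corr_nonlethal"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (15, 15) or not np.allclose(mat, mat.T):
                raise ValueError(f"{name} must be a symmetric 15x15 matrix")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"{name} must have unit diagonal")
            if np.linalg.eigvalsh(mat).min() <= 0:
                raise ValueError(f"{name} is not positive definite")
            setattr(self, name, mat)


def pairwise_signal_config(n_subjects: int = 1112, prevalence: float = 0.171,
                           seed: int = 0) -> GeneratorConfig:
    """Config whose lethality signal lives only in SIS pairwise structure.

    Mean shifts and the age/sex group differences are zeroed, so item
    marginals and confounders are identical across groups, and the two
    groups share the same edge support with opposite-signed partial
    correlations — the outcome is detectable only through pairwise item
    patterns.  Used for ablation experiments that isolate the value of
    the relationship features.
    """
    edges = {(10, 11): 0.45, (11, 12): 0.45, (1, 2): 0.4, (2, 3): 0.4,
             (5, 6): 0.4, (13, 14): 0.4}
    return GeneratorConfig(
        n_subjects=n_subjects,
        prevalence=prevalence,
        sis_corr_lethal=_corr_from_partial(edges),
        sis_corr_nonlethal=_corr_from_partial({k: -v for k, v in edges.items()}),
        sis_mean_shift=np.zeros(15),
        age_mean_lethal=43.2,
        age_mean_nonlethal=43.2,
        male_prob_lethal=0.42,
        male_prob_nonlethal=0.42,
        seed=seed,
    )


# within-group C-SSRS grade probabilities (empirical cohort distribution)
_GRADE_P_LETHAL = np.array([0.80, 0.17, 0.03])  # grades 4, 5, 6
_GRADE_P_NONLETHAL = np.array([0.19, 0.42, 0.39])  # grades 1, 2, 3

_STUDY_START = encode_date("2013-05-01")
_STUDY_END = encode_date("2013-11-07")


def generate_cohort(config: GeneratorConfig):
    """Draw a seeded synthetic cohort.

    Returns ``(table, truths)`` where ``truths`` maps group name to its
    :class:`PlantedTruth`.  Identical configs (including the seed) give
    bitwise-identical tables.
    """
    root = np.random.default_rng(config.seed)
    # independent substreams so adding a component never shifts another
    r_label, r_sis, r_conf, r_grade, r_mask = root.spawn(5)

    n = config.n_subjects
    lethal = r_label.random(n) < config.prevalence

    # latent Gaussian SIS scores, group-wise correlation and mean shift
    z = np.empty((n, 15))
    for is_lethal, corr in ((True, config.sis_corr_lethal),
                            (False, config.sis_corr_nonlethal)):
        idx = np.flatnonzero(lethal == is_lethal)
        chol = np.linalg.cholesky(corr)
        draws = r_sis.standard_normal((idx.size, 15)) @ chol.T
        if is_lethal:
            draws = draws + config.sis_mean_shift
        z[idx] = draws
    sis = np.digitize(z, _THRESHOLDS).astype(float)  # {0,1,2}

    # confounders: age/sex carry the planted group shifts, the rest are
    # plausibility fillers with no outcome signal
    age_mean = np.where(lethal, config.age_mean_lethal, config.age_mean_nonlethal)
    age = np.clip(r_conf.normal(age_mean, config.age_sd), 18, 95).round()
    male_p = np.where(lethal, config.male_prob_lethal, config.male_prob_nonlethal)
    sex = np.where(r_conf.random(n) < male_p, 1.0, 2.0)
    visit = r_conf.uniform(_STUDY_START, _STUDY_END, n).round(3)
    stay_years = r_conf.integers(0, 15, n) / 366.0
    conf = {
        "sex": sex,
        "age": age,
        "marital_status": r_conf.integers(1, 7, n).astype(float),
        "religion": r_conf.integers(1, 6, n).astype(float),
        "monthly_income": np.exp(r_conf.normal(14.5, 0.8, n)).round(),
        "living_status": r_conf.integers(1, 5, n).astype(float),
        "education": r_conf.integers(1, 6, n).astype(float),
        "urbanicity": r_conf.integers(1, 4, n).astype(float),
        "er_visit_date": visit,
        "weekend_visit": r_conf.integers(1, 3, n).astype(float),
        "er_visit_time": r_conf.integers(0, 24, n).astype(float),
        "admission_route": r_conf.integers(1, 5, n).astype(float),
        "admission_transport": r_conf.integers(1, 6, n).astype(float),
        "discharge_date": (visit + stay_years).round(3),
    }

    grades = np.empty(n)
    n_lethal = int(lethal.sum())
    grades[lethal] = r_grade.choice([4, 5, 6], size=n_lethal, p=_GRADE_P_LETHAL)
    grades[~lethal] = r_grade.choice([1, 2, 3], size=n - n_lethal,
                                     p=_GRADE_P_NONLETHAL)

    df = pd.DataFrame({ID_COLUMN: [f"S{i:05d}" for i in range(n)]})
    for j, col in enumerate(SIS_COLUMNS):
        df[col] = sis[:, j]
    for col in CONFOUNDER_COLUMNS:
        df[col] = conf[col]
    df[CSSRS_COLUMN] = grades

    # MCAR masking over the SIS and confounder cells; the outcome grade is
    # never masked so every subject keeps a defined lethality label
    if config.missing_rate > 0:
        maskable = SIS_COLUMNS + CONFOUNDER_COLUMNS
        hit = r_mask.random((n, len(maskable))) < config.missing_rate
        vals = df[maskable].to_numpy()
        vals[hit] = np.nan
        df[maskable] = vals

    _, (lethal_truth, nonlethal_truth) = default_planted_networks()
    truths = {
        "lethal": replace(lethal_truth, true_edges=_support(config.sis_corr_lethal)),
        "nonlethal": replace(
            nonlethal_truth, true_edges=_support(config.sis_corr_nonlethal)
        ),
    }
    return CohortTable(df), truths


def _support(corr: np.ndarray, tol: float = 1e-8) -> frozenset:
    """Edges implied by the nonzero off-diagonal inverse-correlation entries."""
    theta = np.linalg.inv(corr)
    edges = set()
    for i in range(theta.shape[0]):
        for j in range(i + 1, theta.shape[0]):
            if abs(theta[i, j]) > tol:
                edges.add((i + 1, j + 1))
    return frozenset(edges)
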