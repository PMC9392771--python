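"""Design-matrix construction for the intron/exon stability GLM.

The stability model treats each sample's intronic and exonic observations as
two rows of one negative-binomial GLM. Writing ``p`` for pre-mRNA abundance,
``m`` for mature-mRNA abundance and ``gamma`` for stability, the generative
relations

    log m      = b * log p + log phi + log gamma
    log gamma  = X beta + alpha_0

become, after absorbing gene-length factors, a single linear predictor over
the 2n stacked observations with design matrix

    full:        [[ I_n ,   0 , 0 ],        (intronic rows)
                  [ b*I_n , 1 , X ]]        (exonic rows)

whose first column is then replaced by an all-ones intercept — a
span-equivalent reparameterization that leaves ``beta`` untouched. The
``b``-scaled identity block encodes the power-law coupling between
transcription and processing: the exonic signal inherits each sample's latent
pre-mRNA abundance raised to the exponent ``b``. The k trailing columns carry
the differential-stability coefficients ``beta`` (natural-log scale); they are
zero on the intronic block, so ``beta`` measures exonic excess beyond what the
b-scaled intronic signal predicts.

A simplified variant for large cohorts replaces the n sample-specific latent
abundances by a regression of log p on the same covariates
(``log p = X omega + rho``):

    simplified:  [[ 1 , X   , 0 , 0 ],
                  [ 1 , b*X , 1 , X ]]

Bias ("constant stability") designs drop the stability-effect columns and are
used only to profile the likelihood over ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# column roles
LATENT_PRE_MRNA = "latent_pre_mrna"
INTERCEPT = "intercept"
PRE_MRNA_EFFECT = "pre_mrna_effect"
STABILITY_INTERCEPT = "stability_intercept"
STABILITY_EFFECT = "stability_effect"

FULL = "full"
SIMPLIFIED = "simplified"


class DesignError(ValueError):
    """Raised for unbuildable or rank-deficient designs."""


@dataclass
class CovariateMatrix:
    """n x k sample-level covariate matrix with column names."""

    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DesignError("covariate matrix must be 2-D")
        self.names = list(self.names)
        if self.X.shape[1] != len(self.names):
            raise DesignError("covariate names do not match the number of columns")
        if self.X.shape[1] < 1:
            raise DesignError("need at least one covariate")
        if not np.all(np.isfinite(self.X)):
            raise DesignError("covariates contain missing or non-finite values")
        for j, name in enumerate(self.names):
            if np.ptp(self.X[:, j]) == 0:
                raise DesignError(
                    f"covariate {name!r} is constant across samples; "
                    "constant columns are absorbed by the intercept"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass
class ExpandedDesign:
    """2n x p design over stacked intronic-then-exonic observations."""

    matrix: np.ndarray
    column_roles: list[str]
    column_names: list[str]
    mode: str
    b: float
    n_samples: int

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def columns_with_role(self, role: str) -> list[int]:
        return [j for j, r in enumerate(self.column_roles) if r == role]


def _check_b(b: float) -> float:
    b = float(b)
    if not 0.0 <= b <= 1.0:
        raise DesignError(f"bias exponent b={b} outside [0, 1]")
    return b


def _check_rank(m: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(m) < m.shape[1]:
        raise DesignError(f"{what} design matrix is rank-deficient")


def build_covariates(
    samples: pd.DataFrame,
    variables: list[str],
    standardize: bool = False,
) -> CovariateMatrix:
    """Assemble the n x k covariate matrix from named sample-table columns.

    Columns are taken in the given order and passed through unscaled unless
    ``standardize`` is set (then centred and divided by their SD). Binary
    factors must already be 0/1-coded.
    """
    missing = [v for v in variables if v not in samples.columns]
    if missing:
        raise DesignError(f"sample table lacks columns: {missing}")
    cols = []
    for v in variables:
        col = pd.to_numeric(samples[v], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            raise DesignError(f"covariate {v!r} has missing or non-numeric values")
        if standardize:
            col = (col - col.mean()) / col.std(ddof=0)
        cols.append(col)
    return CovariateMatrix(X=np.column_stack(cols), names=list(variables))


def build_full_design(X: CovariateMatrix, b: float) -> ExpandedDesign:
    """Sample-specific latent abundance design (2n x (n+1+k)).

    Block structure ``[[I_n, 0, 0], [b I_n, 1, X]]`` with the first column
    replaced by an all-ones intercept, so the first sample's latent abundance
    becomes the model intercept.
    """
    b = _check_b(b)
    n, k = X.n, X.k
    if n < 2:
        raise DesignError("full design needs at least two samples")
    m = np.zeros((2 * n, n + 1 + k))
    m[:n, :n] = np.eye(n)
    m[n:, :n] = b * np.eye(n)
    m[n:, n] = 1.0
    m[n:, n + 1:] = X.X
    m[:, 0] = 1.0  # intercept substitution
    roles = (
        [INTERCEPT]
        + [LATENT_PRE_MRNA] * (n - 1)
        + [STABILITY_INTERCEPT]
        + [STABILITY_EFFECT] * k
    )
    names = (
        ["intercept"]
        + [f"log_p[{i}]" for i in range(1, n)]
        + ["c_prime"]
        + list(X.names)
    )
    _check_rank(m, "full")
    return ExpandedDesign(m, roles, names, FULL, b, n)


def build_simplified_design(X: CovariateMatrix, b: float) -> ExpandedDesign:
    """Condition-specific abundance design (2n x (2k+2)).

    Block structure ``[[1, X, 0, 0], [1, b X, 1, X]]``; the pre-mRNA columns
    regress latent abundance on the covariates instead of estimating one
    abundance per sample.
    """
    b = _check_b(b)
    n, k = X.n, X.k
    m = np.zeros((2 * n, 2 * k + 2))
    m[:, 0] = 1.0
    m[:n, 1:1 + k] = X.X
    m[n:, 1:1 + k] = b * X.X
    m[n:, 1 + k] = 1.0
    m[n:, 2 + k:] = X.X
    roles = [INTERCEPT] + [PRE_MRNA_EFFECT] * k + [STABILITY_INTERCEPT] + [STABILITY_EFFECT] * k
    names = (
        ["rho_prime"]
        + [f"omega[{v}]" for v in X.names]
        + ["c_prime"]
        + list(X.names)
    )
    _check_rank(m, "simplified")
    return ExpandedDesign(m, roles, names, SIMPLIFIED, b, n)


def build_bias_design(X: CovariateMatrix, b: float, mode: str = FULL) -> ExpandedDesign:
    """Constant-stability design used to profile the likelihood over b.

    Full mode: ``[[I_n, 0], [b I_n, 1]]`` (2n x (n+1)); simplified mode:
    ``[[1, X, 0], [1, b X, 1]]`` (2n x (k+2)). No stability-effect columns:
    each gene's stability is a single constant absorbed by the last column.
    """
    b = _check_b(b)
    n, k = X.n, X.k
    if mode == FULL:
        m = np.zeros((2 * n, n + 1))
        m[:n, :n] = np.eye(n)
        m[n:, :n] = b * np.eye(n)
        m[n:, n] = 1.0
        roles = [LATENT_PRE_MRNA] * n + [STABILITY_INTERCEPT]
        names = [f"log_p[{i}]" for i in range(n)] + ["c_prime"]
        mode_tag = "bias_full"
    elif mode == SIMPLIFIED:
        m = np.zeros((2 * n, k + 2))
        m[:, 0] = 1.0
        m[:n, 1:1 + k] = X.X
        m[n:, 1:1 + k] = b * X.X
        m[n:, 1 + k] = 1.0
        roles = [INTERCEPT] + [PRE_MRNA_EFFECT] * k + [STABILITY_INTERCEPT]
        names = ["rho_prime"] + [f"omega[{v}]" for v in X.names] + ["c_prime"]
        mode_tag = "bias_simplified"
    else:
        raise DesignError(f"unknown bias design mode {mode!r}")
    _check_rank(m, mode_tag)
    return ExpandedDesign(m, roles, names, mode_tag, b, n)


def build_deconvolution_covariates(stage, purity) -> CovariateMatrix:
    """Stage/impurity interaction design for attributing effects to malignant cells.

    Columns are ``[stage, impurity, stage:impurity]`` with
    ``impurity = 1 - purity``. In the fitted stability model the stage
    coefficient is the stage effect at zero impurity, i.e. the change
    attributable to the malignant cells themselves rather than to shifting
    cell composition.
    """
    stage = np.asarray(stage, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if np.any((purity < 0) | (purity > 1)):
        raise DesignError("purity values must lie in [0, 1]")
    impurity = 1.0 - purity
    X = np.column_stack([stage, impurity, stage * impurity])
    return CovariateMatrix(X=X, names=["stage", "impurity", "stage:impurity"])


def build_timecourse_design(cell, time) -> CovariateMatrix:
    """Cell-line x time interaction covariates for decay time-courses.

    Columns ``[cell, time, cell:time]`` for an ordinary NB GLM on mature-mRNA
    counts from a transcription-chase experiment: abundance decays
    exponentially, so log-abundance is linear in time and the ``cell:time``
    coefficient is the between-line difference in decay rate (differential
    stability, per hour, natural log).
    """
    cell = np.asarray(cell, dtype=float)
    time = np.asarray(time, dtype=float)
    for c in np.unique(cell):
        if len(np.unique(time[cell == c])) < 2:
            raise DesignError(
                f"cell line {c:g} has fewer than two distinct time points"
            )
    X = np.column_stack([cell, time, cell * time])
    return CovariateMatrix(X=X, names=["cell", "time", "cell:time"])
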