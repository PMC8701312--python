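"""Mass-univariate general linear modeling of CT_spc maps.

One design matrix is shared across vertices; ordinary least squares is
fitted independently at every vertex.  Continuous covariates are mean
centered over a declared centering population (all subjects by default; the
ASD-only subanalysis centers within ASD).  The quadratic age term is built
from the centered age and then itself centered, which keeps the design
well conditioned.  Group is coded TD=0 / ASD=1 and sex male=0 / female=1,
so with centered covariates the group coefficient is the adjusted ASD-TD
difference in CT_spc.

Model presets
-------------
``group_model``              intercept + group + sex + age + age^2 + fsiq + isi
``rbsr_model``               group_model + delta_rbsr
``rbsr_interaction_model``   rbsr_model + delta_rbsr x group

Step-up model selection admits a candidate term when the pooled
extra-sum-of-squares F over the whole cortex (per-vertex residual sums of
squares summed across vertices, degrees of freedom scaled by the vertex
count) is significant at the configured level, stopping at the first
non-admitted term.  The pooled test is exact for spatially independent
vertices and approximate under spatial smoothing; a conservative
whole-cortex mean-p summary is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUP_CODES = {"TD": 0.0, "ASD": 1.0}
SEX_CODES = {"male": 0.0, "female": 1.0}

MODEL_PRESETS = {
    "group_model": ("group", "sex", "age", "age2", "fsiq", "isi"),
    "rbsr_model": ("group", "sex", "age", "age2", "fsiq", "isi", "delta_rbsr"),
    "rbsr_interaction_model": ("group", "sex", "age", "age2", "fsiq", "isi",
                               "delta_rbsr", "delta_rbsr_x_group"),
}


@dataclass
class DesignMatrix:
    matrix: np.ndarray                  # (n_subjects, n_regressors)
    names: tuple[str, ...]
    centering: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def contrast(self, name: str) -> np.ndarray:
        c = np.zeros(len(self.names))
        c[self.names.index(name)] = 1.0
        return c


@dataclass
class GLMResult:
    beta: np.ndarray        # (n_regressors, n_vertices)
    sigma2: np.ndarray      # residual variance per vertex
    dof: int
    tmap: np.ndarray | None  # contrast t per vertex
    residuals: np.ndarray   # (n_subjects, n_vertices), kept for smoothness estimation
    design: DesignMatrix
    contrast: np.ndarray | None = None
    rss: np.ndarray | None = None


def build_design(frame: pd.DataFrame, covariates: Sequence[str] | str = "group_model",
                 centering_population: np.ndarray | None = None) -> DesignMatrix:
    """Construct the design matrix for a subject table.

    ``frame`` needs columns group, sex, age_t1, fsiq, isi and, for the
    behavioral models, delta_rbsr.  ``centering_population`` is a boolean
    row mask defining the population over which continuous covariates are
    mean centered (default: all rows).
    """
    if isinstance(covariates, str):
        covariates = MODEL_PRESETS[covariates]
    n = len(frame)
    pop = np.ones(n, dtype=bool) if centering_population is None \
        else np.asarray(centering_population, dtype=bool)
    if pop.sum() < 2:
        raise ValueError("centering population needs at least two subjects")

    centering: dict[str, float] = {}

    def centered(name: str, raw: np.ndarray) -> np.ndarray:
        mu = float(raw[pop].mean())
        centering[name] = mu
        return raw - mu

    age_c = centered("age", frame["age_t1"].to_numpy(dtype=np.float64))
    columns = {"intercept": np.ones(n)}
    for name in covariates:
        if name == "group":
            columns[name] = np.array([GROUP_CODES[g] for g in frame["group"]])
        elif name == "sex":
            columns[name] = np.array([SEX_CODES[s] for s in frame["sex"]])
        elif name == "age":
            columns[name] = age_c
        elif name == "age2":
            columns[name] = centered("age2", age_c**2)
        elif name in ("fsiq", "isi", "delta_rbsr"):
            columns[name] = centered(name, frame[name].to_numpy(dtype=np.float64))
        elif name == "delta_rbsr_x_group":
            group = np.array([GROUP_CODES[g] for g in frame["group"]])
            delta = frame["delta_rbsr"].to_numpy(dtype=np.float64) - \
                centering.get("delta_rbsr", frame["delta_rbsr"][pop].mean())
            columns[name] = delta * group
        else:
            columns[name] = centered(name, frame[name].to_numpy(dtype=np.float64))

    names = tuple(columns)
    X = np.column_stack(list(columns.values()))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise ValueError(f"design is rank deficient; collinear columns: {collinear}")
    return DesignMatrix(matrix=X, names=names, centering=centering)


def _collinear_columns(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Name the columns involved in a rank deficiency (QR pivot heuristic)."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * diag.max()
    return [names[i] for i in np.flatnonzero(bad)]


def fit_glm(Y: np.ndarray, design: DesignMatrix,
            contrast: np.ndarray | str | None = None) -> GLMResult:
    """OLS at every vertex with an optional contrast t-map.

    ``Y`` is (subjects, vertices); ``contrast`` is a weight vector over the
    design columns or a column name.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("rows of Y must match rows of the design")
    rank = design.rank
    dof = X.shape[0] - rank
    if dof < 1:
        raise ValueError(f"n={X.shape[0]} <= rank={rank}: no residual degrees of freedom")

    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    residuals = Y - X @ beta
    rss = np.einsum("ij,ij->j", residuals, residuals)
    sigma2 = rss / dof

    tmap = None
    cvec = None
    if contrast is not None:
        cvec = design.contrast(contrast) if isinstance(contrast, str) \
            else np.asarray(contrast, dtype=np.float64)
        xtx_inv = np.linalg.pinv(X.T @ X)
        cvar = float(cvec @ xtx_inv @ cvec)
        se = np.sqrt(sigma2 * cvar)
        with np.errstate(divide="ignore", invalid="ignore"):
            tmap = np.where(se > 0, (cvec @ beta) / np.where(se > 0, se, 1.0), 0.0)
    return GLMResult(beta=beta, sigma2=sigma2, dof=dof, tmap=tmap,
                     residuals=residuals, design=design, contrast=cvec, rss=rss)


# ---------------------------------------------------------------------------
# Step-up nested model selection


@dataclass
class SelectionStep:
    added: tuple[str, ...]
    f: float
    df1: float
    df2: float
    p: float
    admitted: bool
    f_per_vertex: np.ndarray | None = None


@dataclass
class SelectionResult:
    selected_index: int
    selected: DesignMatrix
    steps: list[SelectionStep]


def stepup_model_selection(Y: np.ndarray, designs: Sequence[DesignMatrix],
                           alpha: float = 0.05,
                           summary: str = "pooled-f") -> SelectionResult:
    """Admit terms of strictly nested designs while they improve the fit.

    At each step the extra-sum-of-squares F of the larger against the
    smaller model is computed per vertex; ``summary='pooled-f'`` pools the
    residual sums of squares across the cortex into a single nested F test,
    ``summary='mean-p'`` admits when the whole-cortex average per-vertex p
    falls below ``alpha`` (conservative).  Selection stops at the first term
    that is not admitted.
    """
    if summary not in ("pooled-f", "mean-p"):
        raise ValueError(f"unknown summary {summary!r}")
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    V = Y.shape[1]
    fits = [fit_glm(Y, d) for d in designs]
    steps: list[SelectionStep] = []
    selected = 0
    for k in range(1, len(designs)):
        small, big = designs[k - 1], designs[k]
        if not set(small.names) < set(big.names):
            raise ValueError(
                f"designs are not strictly nested at step {k}: "
                f"{small.names} vs {big.names}")
        q = big.rank - small.rank
        if q < 1:
            raise ValueError(f"candidate adds no rank at step {k} (redundant column)")
        rss_r, rss_f = fits[k - 1].rss, fits[k].rss
        dof_f = fits[k].dof
        with np.errstate(divide="ignore", invalid="ignore"):
            f_vertex = ((rss_r - rss_f) / q) / np.where(rss_f > 0, rss_f / dof_f, np.inf)
        f_vertex = np.clip(f_vertex, 0.0, None)
        if summary == "pooled-f":
            f_stat = ((rss_r.sum() - rss_f.sum()) / (q * V)) / (rss_f.sum() / (dof_f * V))
            df1, df2 = q * V, dof_f * V
            p = float(stats.f.sf(f_stat, df1, df2))
        else:
            p_vertex = stats.f.sf(f_vertex, q, dof_f)
            f_stat = float(np.mean(f_vertex))
            df1, df2 = float(q), float(dof_f)
            p = float(np.mean(p_vertex))
        admitted = p < alpha
        steps.append(SelectionStep(
            added=tuple(set(big.names) - set(small.names)), f=float(f_stat),
            df1=float(df1), df2=float(df2), p=p, admitted=admitted,
            f_per_vertex=f_vertex))
        if not admitted:
            break
        selected = k
    return SelectionResult(selected_index=selected, selected=designs[selected], steps=steps)
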