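"""Statistical comparisons on the measurement tables.

Two procedures mirror the analyses the pipeline feeds:

* a linear mixed model with a per-cell random intercept for the
  interphase-vs-mitosis comparison of centrosomal fluorescence, where the
  two centrosomes of a cell are nested, correlated measurements:
  ``y_ij = b0 + b1 * 1[mitosis] + u_i + e_ij`` with ``u_i ~ N(0, s_u^2)``
  and ``e_ij ~ N(0, s_e^2)``, fitted by REML (ML by flag), Wald inference
  on ``b1``;
* the Mann-Whitney U-test for group comparisons of ROI-level means
  (e.g. acetylated tubulin in transfected vs control cells), exact by
  enumeration for small tie-free samples, normal approximation with tie and
  continuity corrections otherwise.

A cluster bootstrap (resampling cells, never individual centrosomes)
summarizes the interphase/mitotic fold of stage means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import ConvergenceError, InputError, InsufficientDataError

__all__ = ["MixedModelFit", "RankTestResult", "FoldSummary",
           "fit_random_intercept", "mann_whitney", "stage_fold_summary"]

INTERPHASE = "interphase"
MITOSIS = "mitosis"

# exact Mann-Whitney p by enumeration up to this pooled size (no ties)
EXACT_MWU_LIMIT = 12


@dataclass
class MixedModelFit:
    """Random-intercept fit summary.

    ``beta0`` is the interphase mean, ``beta1`` the mitosis effect (mitotic
    minus interphase), ``sigma_u`` the between-cell SD, ``sigma_e`` the
    residual (within-cell) SD; ``beta1_p`` is the two-sided Wald p-value.
    ``sigma_u_boundary`` flags a fit at the sigma_u = 0 boundary.
    """

    beta0: float
    beta1: float
    sigma_u: float
    sigma_e: float
    beta1_se: float
    beta1_p: float
    n_cells: int
    n_obs: int
    method: str
    loglike: float
    sigma_u_boundary: bool = False

    def to_dict(self) -> dict:
        return {k: (bool(v) if isinstance(v, (bool, np.bool_)) else
                    (int(v) if isinstance(v, (int, np.integer)) else float(v)))
                if not isinstance(v, str) else v
                for k, v in self.__dict__.items()}


@dataclass
class RankTestResult:
    """Mann-Whitney U result; ``U`` is the statistic of the first group."""

    U: float
    p_two_sided: float
    method: str
    n1: int
    n2: int


@dataclass
class FoldSummary:
    """Interphase/mitotic ratio of stage means with a cluster-bootstrap
    percentile CI."""

    fold: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_cells: int


def _group_key(records: pd.DataFrame) -> pd.Series:
    return (records.image_id.astype(str) + "/" +
            records.cell_id.astype(str))


def fit_random_intercept(records: pd.DataFrame,
                         value_col: str = "mean_fluorescence",
                         reml: bool = True) -> MixedModelFit:
    """Fit the random-intercept model for the stage comparison.

    Requires every record to carry ``stage`` in {interphase, mitosis} and at
    least two cells per stage. Raises :class:`ConvergenceError` with the
    optimizer trace when the fit does not converge; a boundary estimate
    ``sigma_u = 0`` is permitted and flagged.
    """
    stages = set(records.stage)
    if not stages <= {INTERPHASE, MITOSIS}:
        raise InputError(f"records carry stages outside the comparison: "
                         f"{sorted(stages - {INTERPHASE, MITOSIS})}")
    groups = _group_key(records)
    for stage in (INTERPHASE, MITOSIS):
        n = groups[records.stage == stage].nunique()
        if n < 2:
            raise InsufficientDataError(
                f"stage {stage!r} has {n} cell(s); at least 2 are required")

    endog = records[value_col].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(records)),
                            (records.stage == MITOSIS).to_numpy(dtype=float)])
    result = None
    failures: list[str] = []
    # lbfgs handles the usual case; derivative-free optimizers rescue tiny
    # or boundary (sigma_u -> 0) datasets where the Hessian is singular
    for method in ("lbfgs", "powell", "nm"):
        model = sm.MixedLM(endog, exog, groups=groups.to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                candidate = model.fit(reml=reml, method=method)
            except np.linalg.LinAlgError as exc:
                failures.append(f"{method}: {exc}")
                continue
        if candidate.converged:
            result = candidate
            break
        failures.append(f"{method}: did not converge")
    if result is None:
        raise ConvergenceError(
            "random-intercept fit did not converge; optimizer trace: "
            + "; ".join(failures))

    sigma_u2 = float(np.asarray(result.cov_re)[0, 0])
    sigma_e2 = float(result.scale)
    sigma_u = float(np.sqrt(max(sigma_u2, 0.0)))
    boundary = sigma_u2 <= 1e-8 * max(sigma_e2, 1e-12)
    return MixedModelFit(
        beta0=float(result.fe_params[0]),
        beta1=float(result.fe_params[1]),
        sigma_u=sigma_u,
        sigma_e=float(np.sqrt(sigma_e2)),
        beta1_se=float(result.bse_fe[1]),
        beta1_p=float(result.pvalues[1]),
        n_cells=int(groups.nunique()),
        n_obs=int(len(records)),
        method="REML" if reml else "ML",
        loglike=float(result.llf),
        sigma_u_boundary=bool(boundary),
    )


def mann_whitney(group_a, group_b) -> RankTestResult:
    """Two-sided Mann-Whitney U-test.

    ``U`` is computed from rank sums with midranks for ties. The p-value is
    exact (full null permutation distribution; equals twice the smaller tail
    probability including the observed U, capped at 1) when the pooled size
    is at most ``EXACT_MWU_LIMIT`` and there are no ties; otherwise the
    normal approximation with tie correction and continuity correction is
    used. The method actually applied is reported in the result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[:a.size].sum() - a.size * (a.size + 1) / 2.0)

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_MWU_LIMIT and not has_ties:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="exact")
        p = float(p)
        method = "exact"
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=True)
        p = float(p)
        method = "normal_approx"
    return RankTestResult(U=u_a, p_two_sided=p, method=method,
                          n1=int(a.size), n2=int(b.size))


def stage_fold_summary(records: pd.DataFrame,
                       value_col: str = "mean_fluorescence",
                       n_boot: int = 1000, seed: int = 0) -> FoldSummary:
    """Interphase/mitotic ratio of mean centrosomal fluorescence.

    The CI is a percentile interval from a cluster bootstrap that resamples
    whole cells (with replacement, stratified by stage) — never individual
    centrosomes — respecting the nesting of the measurements.
    """
    for stage in (INTERPHASE, MITOSIS):
        if not (records.stage == stage).any():
            raise InputError(f"no {stage} records present")
    key = _group_key(records)
    values = records[value_col].to_numpy(dtype=float)

    def fold_of(idx_lists) -> float:
        means = {}
        for stage, idx in idx_lists.items():
            means[stage] = values[idx].mean()
        if means[MITOSIS] == 0:
            raise InputError("mitotic mean fluorescence is zero; fold undefined")
        return means[INTERPHASE] / means[MITOSIS]

    by_stage_cells: dict[str, list[np.ndarray]] = {}
    for stage in (INTERPHASE, MITOSIS):
        sel = records.stage == stage
        cells = key[sel].unique()
        by_stage_cells[stage] = [np.flatnonzero(key.to_numpy() == c)
                                 for c in cells]

    point = fold_of({s: np.concatenate(c) for s, c in by_stage_cells.items()})

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = {}
        for stage, cells in by_stage_cells.items():
            pick = rng.integers(0, len(cells), size=len(cells))
            idx[stage] = np.concatenate([cells[j] for j in pick])
        m_i = values[idx[INTERPHASE]].mean()
        m_m = values[idx[MITOSIS]].mean()
        boots[i] = np.inf if m_m == 0 else m_i / m_m
    lo, hi = np.percentile(boots, [2.5, 97.5])
    n_cells = int(key.nunique())
    return FoldSummary(fold=float(point), ci_low=float(lo), ci_high=float(hi),
                       n_boot=int(n_boot), n_cells=n_cells)
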