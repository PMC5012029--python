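"""Heritability estimation: relationship matrix, REML animal model,
parent-offspring regressions, cross-correlations, and the ANCOVA
sex-linkage test.

The animal model is y = Xb + Za + e with a ~ N(0, A*Va) and
e ~ N(0, I*Ve); the restricted likelihood is profiled on the heritability
ratio using a one-off eigendecomposition of the phenotyped submatrix of A,
which is cheap at the design sizes this package targets (~10^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import Pedigree
from .phenotype import TraitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RelationshipMatrix",
    "AnimalModelResult",
    "RegressionResult",
    "AncovaResult",
    "UnidentifiableModelError",
    "build_relationship_matrix",
    "reml_animal_model",
    "midparent_pairs",
    "single_parent_pairs",
    "parent_offspring_regression",
    "ancova_sex_linkage",
]


class UnidentifiableModelError(ValueError):
    """Raised when the additive variance cannot be separated from residual."""


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator (additive) relationship matrix with its id index."""

    ids: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id index")

    def loc(self, i: str, j: str) -> float:
        index = {v: k for k, v in enumerate(self.ids)}
        return float(self.values[index[i], index[j]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        index = {v: k for k, v in enumerate(self.ids)}
        idx = [index[i] for i in ids]
        return self.values[np.ix_(idx, idx)]


def build_relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular-method additive relationships.

    a_jj = 1 + 0.5 * a_{sire(j), dam(j)};
    a_ij = 0.5 * (a_{i, sire(j)} + a_{i, dam(j)}) for i processed before j;
    unknown parents contribute zero.
    """
    order = pedigree.topological_order()
    index = {ind_id: k for k, ind_id in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for j, ind_id in enumerate(order):
        ind = pedigree[ind_id]
        s = index.get(ind.sire_id) if ind.sire_id is not None else None
        d = index.get(ind.dam_id) if ind.dam_id is not None else None
        if s is not None and d is not None:
            A[j, j] = 1.0 + 0.5 * A[s, d]
        else:
            A[j, j] = 1.0
        for i in range(j):
            val = 0.0
            if s is not None:
                val += 0.5 * A[i, s]
            if d is not None:
                val += 0.5 * A[i, d]
            A[i, j] = A[j, i] = val
    return RelationshipMatrix(tuple(order), A)


# ---------------------------------------------------------------------------
# REML animal model


@dataclass
class AnimalModelResult:
    trait: str
    V_a: float
    V_e: float
    V_p: float
    h2: float
    se_h2: Optional[float]
    ci95: Tuple[Optional[float], Optional[float]]
    fixed_effects: Dict[str, float]
    n_records: int
    loglik: float
    converged: bool
    boundary: bool


def _design_matrix(
    frame: pd.DataFrame, fixed: Sequence[str]
) -> Tuple[np.ndarray, List[str]]:
    columns = [np.ones(len(frame))]
    names = ["intercept"]
    for factor in fixed:
        levels = sorted(frame[factor].astype(str).unique())
        for level in levels[1:]:  # first level is the reference
            columns.append((frame[factor].astype(str) == level).to_numpy(float))
            names.append(f"{factor}[{level}]")
    X = np.column_stack(columns)
    # drop linearly dependent columns via pivoted QR
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    keep = sorted(piv[: int((diag > tol).sum())])
    return X[:, keep], [names[k] for k in keep]


def _profile_restricted_loglik(
    theta: float,
    d: np.ndarray,
    yt: np.ndarray,
    Xt: np.ndarray,
) -> Tuple[float, float]:
    """Restricted log-likelihood profiled over total variance.

    V is proportional to theta*A + (1-theta)*I; returns (loglik, sigma2)
    where Va = theta*sigma2 and Ve = (1-theta)*sigma2.
    """
    n, p = Xt.shape
    w = theta * d + (1.0 - theta)
    if np.any(w <= 0):
        return -np.inf, np.nan
    wi = 1.0 / w
    XtWX = Xt.T @ (wi[:, None] * Xt)
    XtWy = Xt.T @ (wi * yt)
    yWy = float(yt @ (wi * yt))
    try:
        c = linalg.cho_factor(XtWX)
    except linalg.LinAlgError:
        return -np.inf, np.nan
    beta = linalg.cho_solve(c, XtWy)
    q = yWy - float(XtWy @ beta)
    if q <= 0:
        return -np.inf, np.nan
    sigma2 = q / (n - p)
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    ll = -0.5 * (
        float(np.sum(np.log(w)))
        + logdet_XtWX
        + (n - p) * math.log(sigma2)
        + (n - p)
    )
    return ll, sigma2


def _restricted_loglik_va_ve(
    va: float, ve: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> float:
    """Unprofiled restricted log-likelihood at (Va, Ve)."""
    n, p = Xt.shape
    w = va * d + ve
    if np.any(w <= 0):
        return -np.inf
    wi = 1.0 / w
    XtWX = Xt.T @ (wi[:, None] * Xt)
    XtWy = Xt.T @ (wi * yt)
    yWy = float(yt @ (wi * yt))
    try:
        c = linalg.cho_factor(XtWX)
    except linalg.LinAlgError:
        return -np.inf
    beta = linalg.cho_solve(c, XtWy)
    q = yWy - float(XtWy @ beta)
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return -0.5 * (float(np.sum(np.log(w))) + logdet_XtWX + q)


def reml_animal_model(
    pedigree: Pedigree,
    trait_records: Sequence[TraitRecord],
    trait: str,
    fixed: Sequence[str] = ("sex", "cohort", "generation"),
    values: Optional[Mapping[str, float]] = None,
) -> AnimalModelResult:
    """Univariate REML fit of the animal model for one colour trait.

    ``trait_records`` should come from ``prepare_trait_table`` with
    ``zero_policy='as_missing'``; records with missing transformed values
    (and unsexed individuals, when sex is a fixed factor) are dropped from
    the data but their relatives still link through the relationship
    matrix. ``values`` optionally overrides the response (id -> value),
    bypassing the trait table, for simulation studies.
    """
    if values is None:
        values = {
            r.id: r.transformed_value
            for r in trait_records
            if r.trait == trait and r.transformed_value is not None
        }
    rows = []
    for ind_id, y in values.items():
        ind = pedigree[ind_id]
        if "sex" in fixed and ind.sex not in ("male", "female"):
            continue
        rows.append(
            {
                "id": ind_id,
                "y": float(y),
                "sex": ind.sex,
                "cohort": ind.cohort or "unknown",
                "generation": ind.generation,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame) < 3:
        raise UnidentifiableModelError("fewer than 3 usable records")

    usable_fixed = [
        f for f in fixed if frame[f].astype(str).nunique() > 1
    ]
    X, names = _design_matrix(frame, usable_fixed)
    y = frame["y"].to_numpy(float)

    A = build_relationship_matrix(pedigree)
    A_obs = A.submatrix(frame["id"].tolist())
    off = A_obs[np.triu_indices_from(A_obs, k=1)]
    if int((off > 1e-9).sum()) < 2:
        raise UnidentifiableModelError(
            "additive variance is unidentifiable: fewer than two related "
            "pairs among phenotyped individuals"
        )

    d, U = linalg.eigh(A_obs)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    # profile over the heritability ratio with multi-start refinement
    grid = np.linspace(0.0, 0.999, 61)
    lls = np.array([_profile_restricted_loglik(t, d, yt, Xt)[0] for t in grid])
    starts = {0.1, 0.5, 0.9, float(grid[int(np.nanargmax(lls))])}
    best_theta, best_ll = 0.0, -np.inf
    for s in starts:
        lo, hi = max(0.0, s - 0.25), min(0.999, s + 0.25)
        res = optimize.minimize_scalar(
            lambda t: -_profile_restricted_loglik(t, d, yt, Xt)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun > best_ll:
            best_ll, best_theta = -res.fun, float(res.x)
    theta = best_theta
    ll, sigma2 = _profile_restricted_loglik(theta, d, yt, Xt)
    converged = math.isfinite(ll)
    boundary = theta < 1e-6 or theta > 0.999 - 1e-6
    va, ve = theta * sigma2, (1.0 - theta) * sigma2
    h2 = theta

    se_h2 = _se_h2(va, ve, d, yt, Xt)
    ci: Tuple[Optional[float], Optional[float]]
    if se_h2 is not None:
        ci = (h2 - 1.96 * se_h2, h2 + 1.96 * se_h2)
    else:
        ci = (None, None)

    # GLS fixed effects at the optimum
    w = np.clip(theta * d + (1.0 - theta), 1e-12, None)
    wi = 1.0 / w
    XtWX = Xt.T @ (wi[:, None] * Xt)
    beta = np.linalg.solve(XtWX, Xt.T @ (wi * yt))
    return AnimalModelResult(
        trait=trait,
        V_a=va,
        V_e=ve,
        V_p=va + ve,
        h2=h2,
        se_h2=se_h2,
        ci95=ci,
        fixed_effects=dict(zip(names, beta.tolist())),
        n_records=len(frame),
        loglik=ll,
        converged=converged,
        boundary=boundary,
    )


def _se_h2(
    va: float, ve: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> Optional[float]:
    """Delta-method SE of h2 from the observed information of (Va, Ve)."""
    vp = va + ve
    if vp <= 0:
        return None
    step_a = max(1e-8, 1e-4 * vp)
    step_e = max(1e-8, 1e-4 * vp)

    def ll(a: float, e: float) -> float:
        return _restricted_loglik_va_ve(max(a, 0.0), max(e, 1e-12), d, yt, Xt)

    try:
        H = np.empty((2, 2))
        f0 = ll(va, ve)
        H[0, 0] = (ll(va + step_a, ve) - 2 * f0 + ll(va - step_a, ve)) / step_a**2
        H[1, 1] = (ll(va, ve + step_e) - 2 * f0 + ll(va, ve - step_e)) / step_e**2
        H[0, 1] = H[1, 0] = (
            ll(va + step_a, ve + step_e)
            - ll(va + step_a, ve - step_e)
            - ll(va - step_a, ve + step_e)
            + ll(va - step_a, ve - step_e)
        ) / (4 * step_a * step_e)
        cov = np.linalg.inv(-H)
        grad = np.array([ve, -va]) / vp**2
        var = float(grad @ cov @ grad)
        if not math.isfinite(var) or var <= 0:
            return None
        return math.sqrt(var)
    except (np.linalg.LinAlgError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Parent-offspring regressions


@dataclass(frozen=True)
class RegressionResult:
    mode: str  # midparent | sire | dam
    parent_trait: str
    offspring_trait: str
    slope: float
    se_slope: float
    r2: float
    p: float
    n_pairs: int
    h2_reported: float
    doubled: bool = False


def _trait_values(
    trait_records: Sequence[TraitRecord], trait: str
) -> Dict[str, float]:
    """id -> transformed value for expressed records of one trait."""
    return {
        r.id: r.transformed_value
        for r in trait_records
        if r.trait == trait and r.expressed and r.transformed_value is not None
    }


def midparent_pairs(
    pedigree: Pedigree,
    trait_records: Sequence[TraitRecord],
    trait: str,
) -> List[Tuple[float, float, Tuple[str, str]]]:
    """(midparent, midoffspring, family) per sire x dam family.

    Requires both parents expressing the trait; midoffspring averages the
    family's expressing offspring over all its clutches. Families failing
    either condition are dropped (logged).
    """
    values = _trait_values(trait_records, trait)
    pairs = []
    dropped = 0
    for (sire_id, dam_id), kids in pedigree.families().items():
        if sire_id not in values or dam_id not in values:
            dropped += 1
            continue
        kid_values = [values[k] for k in kids if k in values]
        if not kid_values:
            dropped += 1
            continue
        midparent = 0.5 * (values[sire_id] + values[dam_id])
        pairs.append((midparent, float(np.mean(kid_values)), (sire_id, dam_id)))
    if dropped:
        logger.info("midparent_pairs: dropped %d families", dropped)
    return pairs


def single_parent_pairs(
    pedigree: Pedigree,
    trait_records: Sequence[TraitRecord],
    parent: str,
    parent_trait: str,
    offspring_trait: Optional[str] = None,
) -> List[Tuple[float, float, Tuple[str, str]]]:
    """(parent value, midoffspring value, family) for sire or dam mode.

    ``offspring_trait`` defaults to ``parent_trait``; setting it to the
    other colour yields the cross-correlation (reciprocal) pairs.
    """
    if parent not in ("sire", "dam"):
        raise ValueError("parent must be 'sire' or 'dam'")
    offspring_trait = offspring_trait or parent_trait
    parent_values = _trait_values(trait_records, parent_trait)
    offspring_values = _trait_values(trait_records, offspring_trait)
    pairs = []
    for (sire_id, dam_id), kids in pedigree.families().items():
        parent_id = sire_id if parent == "sire" else dam_id
        if parent_id not in parent_values:
            continue
        kid_values = [offspring_values[k] for k in kids if k in offspring_values]
        if not kid_values:
            continue
        pairs.append(
            (parent_values[parent_id], float(np.mean(kid_values)), (sire_id, dam_id))
        )
    return pairs


def parent_offspring_regression(
    pairs: Sequence[Tuple[float, float, object]],
    mode: str,
    parent_trait: str,
    offspring_trait: Optional[str] = None,
    double_single_parent: bool = False,
) -> RegressionResult:
    """OLS of offspring on parent values; the slope is the reported h2.

    The conventional x2 correction for single-parent modes is opt-in via
    ``double_single_parent``.
    """
    offspring_trait = offspring_trait or parent_trait
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], float)
    y = np.array([p[1] for p in pairs], float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: parent values have no variance")
    fit = stats.linregress(x, y)
    doubled = double_single_parent and mode in ("sire", "dam")
    h2 = fit.slope * (2.0 if doubled else 1.0)
    return RegressionResult(
        mode=mode,
        parent_trait=parent_trait,
        offspring_trait=offspring_trait,
        slope=float(fit.slope),
        se_slope=float(fit.stderr),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n_pairs=len(pairs),
        h2_reported=float(h2),
        doubled=doubled,
    )


# ---------------------------------------------------------------------------
# ANCOVA sex-linkage test


@dataclass(frozen=True)
class AncovaResult:
    trait: str
    F_interaction: float
    df_num: int
    df_den: int
    p: float
    clutch_variance: Optional[float]
    mixed: bool


def ancova_sex_linkage(
    pedigree: Pedigree,
    trait_records: Sequence[TraitRecord],
    trait: str,
) -> AncovaResult:
    """Test whether sire- and dam-offspring slopes differ for one trait.

    Each offspring contributes one row per expressing parent in the model
    offspring ~ parent_value * parent_sex. Because the same offspring value
    appears in both its sire and dam rows, a plain random-clutch-intercept
    GLS shrinks the interaction toward the (identically zero) within-
    offspring contrast; the Wald F for the interaction therefore comes from
    OLS with clutch-clustered robust covariance, which keeps the estimate
    consistent while accounting for non-independence within clutches. The
    clutch variance component is still estimated (REML random intercept)
    and reported; with a single clutch the test reduces to plain OLS.
    """
    values = _trait_values(trait_records, trait)
    rows = []
    for ind in pedigree:
        if ind.is_founder or ind.id not in values:
            continue
        for parent_id, parent_sex in ((ind.sire_id, "sire"), (ind.dam_id, "dam")):
            if parent_id is None or parent_id not in values:
                continue
            rows.append(
                {
                    "offspring": values[ind.id],
                    "parent": values[parent_id],
                    "parent_sex": parent_sex,
                    "clutch": ind.clutch_id or f"{ind.sire_id}x{ind.dam_id}",
                }
            )
    frame = pd.DataFrame(rows)
    if len(frame) < 6 or frame["parent_sex"].nunique() < 2:
        raise ValueError("need sire and dam pairs to test the interaction")
    if np.ptp(frame["parent"].to_numpy()) == 0:
        raise ValueError("degenerate predictor: parent values have no variance")

    frame["is_dam"] = (frame["parent_sex"] == "dam").astype(float)
    frame["interaction"] = frame["parent"] * frame["is_dam"]
    exog = frame[["parent", "is_dam", "interaction"]].to_numpy(float)
    exog = np.column_stack([np.ones(len(frame)), exog])
    endog = frame["offspring"].to_numpy(float)

    import statsmodels.api as sm

    mixed = frame["clutch"].nunique() > 1
    clutch_var: Optional[float] = None
    if mixed:
        try:
            refit = sm.MixedLM(endog, exog, groups=frame["clutch"]).fit(
                reml=True, method="powell", maxiter=2000
            )
            clutch_var = float(np.asarray(refit.cov_re)[0, 0])
        except Exception:  # singular random effect on degenerate inputs
            logger.warning("clutch variance component could not be estimated")
            mixed = False
    if mixed:
        n_clutches = frame["clutch"].nunique()
        fit = sm.OLS(endog, exog).fit(
            cov_type="cluster", cov_kwds={"groups": frame["clutch"]}
        )
        df_den = n_clutches - 1
    else:
        logger.info("single clutch: plain fixed-effects ANCOVA")
        fit = sm.OLS(endog, exog).fit()
        df_den = len(frame) - 4
    coef = float(np.asarray(fit.params)[3])
    se = float(np.asarray(fit.bse)[3])
    F = float((coef / se) ** 2) if se > 0 else math.inf
    p = float(stats.f.sf(F, 1, df_den))
    return AncovaResult(trait, F, 1, df_den, p, clutch_var, mixed)
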