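"""Regression battery linking assemblage lightness to climate.

For every (continent x family scope x body side x environmental variable)
combination an ordinary least-squares linear and quadratic model is fitted
and the relationship is classified by sign, significance and the difference
of the two models' r-squared values: a quadratic shape (U or hump) is
assumed only when quadratic r2 exceeds linear r2 by more than 0.1
(strictly), otherwise the shape is linear; combinations where neither model
reaches the significance level are "n.s.".  Spatial non-independence of
neighbouring cells is addressed by a generalized least-squares model with a
Gaussian correlation structure on Manhattan distances,
corr(i, j) = exp(-(d_ij / rho)^2), with the range rho estimated by maximum
likelihood.  Dorsal-ventral and between-family differences in species-level
lightness are assessed with Tukey HSD tests.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

SIDES = ("dorsal", "ventral")
SHAPES = ("linear", "U", "hump", "n.s.")


class ConvergenceError(RuntimeError):
    """The GLS likelihood optimization failed; no silent OLS fallback."""


@dataclass(frozen=True)
class ModelRecord:
    """One row of the model table: linear vs quadratic fit and its shape."""

    variable: str                 # INS | TMP | HUM
    family_scope: str             # family name or "all"
    side: str                     # dorsal | ventral
    n_cells: int
    linear_sign: str              # '+' | '-'
    linear_r2: float
    linear_p: float
    quad_sign: str                # sign of the x^2 coefficient
    quad_r2: float
    quad_p: float
    delta_r2: float
    shape: str                    # linear | U | hump | n.s.
    continent: str = ""
    status: str = "ok"            # "ok" | "absent"

    @staticmethod
    def absent(variable: str, family_scope: str, side: str,
               continent: str = "", n_cells: int = 0) -> "ModelRecord":
        return ModelRecord(variable=variable, family_scope=family_scope,
                           side=side, n_cells=n_cells, linear_sign="",
                           linear_r2=np.nan, linear_p=np.nan, quad_sign="",
                           quad_r2=np.nan, quad_p=np.nan, delta_r2=np.nan,
                           shape="", continent=continent, status="absent")


def fit_shape_models(y: np.ndarray, x: np.ndarray, alpha: float = 0.001,
                     delta_threshold: float = 0.1, *, variable: str = "",
                     family_scope: str = "all", side: str = "",
                     continent: str = "") -> ModelRecord:
    """Fit y ~ x and y ~ x + x^2 and classify the relationship's shape.

    Classification: "n.s." if neither model's overall F-test has p < alpha;
    otherwise U / hump (by the sign of the quadratic coefficient) when
    delta_r2 = quad_r2 - linear_r2 is strictly greater than
    ``delta_threshold``; otherwise linear, signed by the linear slope.
    Predictors are z-scored internally for numerical stability; r-squared,
    signs and p-values are invariant to this.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 10:
        raise ValueError(f"need >= 10 cells, got {len(y)}")
    # relative tolerance: an all-equal vector can carry ~1e-14 float fuzz
    if (np.std(x) <= 1e-12 * max(1.0, abs(x.mean()))
            or np.std(y) <= 1e-12 * max(1.0, abs(y.mean()))):
        raise ValueError("zero variance in x or y")

    z = (x - x.mean()) / x.std()
    lin = sm.OLS(y, sm.add_constant(z)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([z, z * z]))).fit()

    linear_r2 = float(lin.rsquared)
    quad_r2 = float(quad.rsquared)
    delta = quad_r2 - linear_r2
    if delta < -1e-8:
        raise AssertionError("nested models: quadratic r2 below linear r2")
    delta = max(delta, 0.0)

    lin_p = float(lin.f_pvalue)
    quad_p = float(quad.f_pvalue)
    lin_sign = "+" if lin.params[1] >= 0 else "-"
    quad_sign = "+" if quad.params[2] >= 0 else "-"

    if not (lin_p < alpha or quad_p < alpha):
        shape = "n.s."
    elif delta > delta_threshold:
        shape = "U" if quad.params[2] > 0 else "hump"
    else:
        shape = "linear"

    return ModelRecord(variable=variable, family_scope=family_scope, side=side,
                       n_cells=len(y), linear_sign=lin_sign,
                       linear_r2=linear_r2, linear_p=lin_p,
                       quad_sign=quad_sign, quad_r2=quad_r2, quad_p=quad_p,
                       delta_r2=delta, shape=shape, continent=continent)


# ---------------------------------------------------------------------------
# spatial GLS

def manhattan_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise |dx| + |dy| for (n, 2) coordinates."""
    d = np.abs(coords[:, None, :] - coords[None, :, :])
    return d.sum(axis=2)


def gaussian_correlation(dist: np.ndarray, rho: float) -> np.ndarray:
    """corr(i, j) = exp(-(d_ij / rho)^2)."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    return np.exp(-((dist / rho) ** 2))


@dataclass(frozen=True)
class GLSRecord:
    params: np.ndarray            # coefficients (intercept first)
    bse: np.ndarray               # standard errors
    rho_km: float                 # correlation range
    loglik: float
    n_cells_used: int
    subsampled: bool
    converged: bool


def _jitter_duplicates(coords: np.ndarray, cell_ids: list[str] | None,
                       amount: float = 1e-3) -> np.ndarray:
    """Deterministic ~1 m jitter (coords in km) for duplicated coordinates."""
    coords = coords.copy()
    _, inverse, counts = np.unique(coords, axis=0, return_inverse=True,
                                   return_counts=True)
    dup = counts[inverse] > 1
    if dup.any():
        keys = cell_ids if cell_ids is not None else [str(i) for i in
                                                      range(len(coords))]
        for i in np.flatnonzero(dup):
            h = zlib.crc32(keys[i].encode())
            coords[i, 0] += amount * (((h & 0xFFFF) / 0xFFFF) - 0.5)
            coords[i, 1] += amount * ((((h >> 16) & 0xFFFF) / 0xFFFF) - 0.5)
    return coords


def fit_gls_spatial(y: np.ndarray, x: np.ndarray, coords: np.ndarray,
                    correlation: str = "gaussian", metric: str = "manhattan",
                    max_n: int = 3000, seed: int = 0, quadratic: bool = False,
                    nugget: bool = False,
                    cell_ids: list[str] | None = None) -> GLSRecord:
    """GLS with Gaussian spatial error correlation on Manhattan distances.

    Mean model: y ~ x (plus x^2 when ``quadratic``).  The correlation range
    rho (km) is profiled out by maximum likelihood with a bounded scalar
    search over log rho.  When more than ``max_n`` cells are supplied a
    seeded random subsample is fitted and recorded.

    The Gaussian structure on a Manhattan metric is not a positive-definite
    kernel (on a regular lattice it is indefinite once rho exceeds the cell
    spacing), so the correlation matrix is evaluated by eigendecomposition
    with eigenvalues clipped to a small positive floor — i.e. the likelihood
    of the nearest positive-definite correlation with that structure.
    """
    if correlation != "gaussian" or metric != "manhattan":
        raise NotImplementedError("only gaussian correlation / manhattan metric")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(y) != len(x) or len(y) != len(coords):
        raise ValueError("y, x, coords length mismatch")

    subsampled = False
    if len(y) > max_n:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(y), size=max_n, replace=False))
        y, x, coords = y[idx], x[idx], coords[idx]
        if cell_ids is not None:
            cell_ids = [cell_ids[i] for i in idx]
        subsampled = True

    coords = _jitter_duplicates(coords, cell_ids)
    n = len(y)
    z = (x - x.mean()) / x.std()
    X = (sm.add_constant(np.column_stack([z, z * z])) if quadratic
         else sm.add_constant(z))
    dist = manhattan_distances(coords)

    def decompose(rho: float, nugget_var: float
                  ) -> tuple[np.ndarray, np.ndarray]:
        C = gaussian_correlation(dist, rho)
        C = (1 - nugget_var) * C + nugget_var * np.eye(n)
        w, V = np.linalg.eigh(C)
        w = np.maximum(w, 1e-10 * w[-1])   # nearest-PSD clip
        return w, V

    def solve(w: np.ndarray, V: np.ndarray, M: np.ndarray) -> np.ndarray:
        return V @ ((V.T @ M).T / w).T if M.ndim == 2 \
            else V @ ((V.T @ M) / w)

    def neg_loglik(rho: float, nugget_var: float) -> float:
        w, V = decompose(rho, nugget_var)
        logdet = float(np.sum(np.log(w)))
        Ci_X = solve(w, V, X)
        Ci_y = solve(w, V, y)
        XtCiX = X.T @ Ci_X
        beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
        r = y - X @ beta
        sigma2 = float(r @ solve(w, V, r)) / n
        if sigma2 <= 0:
            return 1e12
        return 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

    # profile likelihood is multimodal near singular fits: coarse log-grid
    # search over rho (and nugget when estimated), then local refinement
    off = dist[~np.eye(n, dtype=bool)]
    lo = max(float(off[off > 0].min()) * 0.1, 1e-6)
    hi = float(off.max()) * 3.0
    rho_grid = np.exp(np.linspace(np.log(lo), np.log(hi), 20))
    nugget_grid = [0.01, 0.05, 0.2, 0.5] if nugget else [1e-6]
    evals = [(neg_loglik(r, nv), r, nv)
             for r in rho_grid for nv in nugget_grid]
    best_fun, best_rho, nugget_var = min(evals, key=lambda t: t[0])
    if not np.isfinite(best_fun) or best_fun >= 1e12:
        raise ConvergenceError(
            f"GLS likelihood grid search failed: best fun={best_fun!r}, "
            f"rho_bounds_km=({lo:.3g}, {hi:.3g}), n={n}")
    res = minimize_scalar(
        lambda lr: neg_loglik(float(np.exp(lr)), nugget_var),
        bounds=(np.log(best_rho / 2.5), np.log(best_rho * 2.5)),
        method="bounded", options={"xatol": 1e-3, "maxiter": 60})
    if res.success and np.isfinite(res.fun) and res.fun <= best_fun:
        rho = float(np.exp(res.x))
        best_fun = float(res.fun)
    else:
        rho = float(best_rho)
    w, V = decompose(rho, nugget_var)
    Ci_X = solve(w, V, X)
    Ci_y = solve(w, V, y)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    r = y - X @ beta
    sigma2 = float(r @ solve(w, V, r)) / (n - X.shape[1])
    cov = sigma2 * np.linalg.inv(XtCiX)
    return GLSRecord(params=beta, bse=np.sqrt(np.diag(cov)), rho_km=rho,
                     loglik=-float(best_fun), n_cells_used=n,
                     subsampled=subsampled, converged=True)


# ---------------------------------------------------------------------------
# Tukey HSD side / family contrasts

@dataclass(frozen=True)
class SideContrast:
    """Dorsal vs ventral mean lightness within one family scope.

    ``difference`` is ventral minus dorsal: positive when the ventral side
    is the lighter one (countershading pattern).
    """

    continent: str
    family_scope: str
    mean_dorsal: float
    mean_ventral: float
    difference: float
    p_adj: float
    n_species: int


def tukey_hsd_pairwise(values: np.ndarray, groups: np.ndarray
                       ) -> dict[tuple[str, str], float]:
    """All-pairs Tukey(-Kramer) HSD adjusted p-values for a one-way layout.

    q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)) referred to the
    studentized-range distribution with k groups and N - k error df.
    """
    from scipy.stats import studentized_range

    labels = np.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    means, sizes, ss_within = [], [], 0.0
    for lab in labels:
        v = values[groups == lab]
        means.append(v.mean())
        sizes.append(len(v))
        ss_within += ((v - v.mean()) ** 2).sum()
    df_err = len(values) - k
    if df_err <= 0:
        raise ValueError("no within-group degrees of freedom")
    msw = ss_within / df_err
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(means[i] - means[j]) / se if se > 0 else np.inf
        p = 0.0 if np.isinf(q) else float(studentized_range.sf(q, k, df_err))
        out[(str(labels[i]), str(labels[j]))] = p
        out[(str(labels[j]), str(labels[i]))] = p
    return out


def tukey_side_family(traits: list, continent: str = "",
                      alpha: float = 0.05) -> list[SideContrast]:
    """Tukey HSD over family x side groups of species-level lightness.

    Each species contributes its dorsal and ventral value; all pairwise
    family x side comparisons are Tukey-adjusted and the within-family
    dorsal-ventral contrasts are reported, plus an across-family "all"
    contrast from a separate two-group test.  Groups with fewer than two
    species are excluded with a warning.
    """
    rows = []
    for t in traits:
        rows.append({"family": t.family, "side": "dorsal",
                     "value": t.lightness_dorsal})
        rows.append({"family": t.family, "side": "ventral",
                     "value": t.lightness_ventral})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no traits supplied")

    out: list[SideContrast] = []

    def run(sub: pd.DataFrame, scope: str) -> None:
        groups = sub.assign(g=sub["family"] + ":" + sub["side"]) \
            if scope != "all" else sub.assign(g=sub["side"])
        sizes = groups.groupby("g")["value"].size()
        small = sizes[sizes < 2].index.tolist()
        if small:
            warnings.warn(f"groups excluded (<2 members): {small}",
                          stacklevel=3)
            groups = groups[~groups["g"].isin(small)]
        if groups["g"].nunique() < 2:
            return
        padj = tukey_hsd_pairwise(groups["value"].to_numpy(),
                                  groups["g"].to_numpy(dtype=object))
        means = groups.groupby("g")["value"].mean()
        if scope == "all":
            want = [("dorsal", "ventral", "all")]
        else:
            fams = sorted(sub["family"].unique())
            want = [(f"{f}:dorsal", f"{f}:ventral", f) for f in fams]
        for g1, g2, label in want:
            if (g1, g2) not in padj:
                continue
            md = float(means[g1])
            mv = float(means[g2])
            out.append(SideContrast(
                continent=continent, family_scope=label,
                mean_dorsal=md, mean_ventral=mv, difference=mv - md,
                p_adj=padj[(g1, g2)],
                n_species=int(len(sub) // 2 if scope == "all"
                              else (sub["family"] == label).sum() // 2)))

    run(df, "all")
    run(df, "families")
    return out


# ---------------------------------------------------------------------------
# the full battery

def table1_battery(assemblages: dict[str, pd.DataFrame],
                   environments: dict[str, pd.DataFrame],
                   continents: list[str],
                   families: list[str],
                   sides: tuple[str, ...] = SIDES,
                   variables: tuple[str, ...] = ("INS", "TMP", "HUM"),
                   alpha: float = 0.001,
                   delta_threshold: float = 0.1) -> list[ModelRecord]:
    """One ModelRecord per (continent x scope x side x variable).

    ``assemblages[continent]`` is a long table (cell_id, side, family_scope,
    mean_lightness, n_species); ``environments[continent]`` is keyed by
    cell_id with INS/TMP/HUM columns.  Scopes are "all" plus each family.
    Combinations that cannot be fitted (absent family, too few cells) are
    recorded as absent, never silently skipped — the full design always
    yields ``len(continents) * (1 + len(families)) * len(sides) *
    len(variables)`` records.
    """
    records: list[ModelRecord] = []
    scopes = ["all"] + list(families)
    for cont in continents:
        asm = assemblages[cont]
        env = environments[cont]
        for scope in scopes:
            for side in sides:
                sub = asm[(asm["family_scope"] == scope)
                          & (asm["side"] == side)]
                merged = sub.merge(env, on="cell_id", how="inner")
                for var in variables:
                    data = merged[["mean_lightness", var]].dropna()
                    try:
                        records.append(fit_shape_models(
                            data["mean_lightness"].to_numpy(),
                            data[var].to_numpy(), alpha=alpha,
                            delta_threshold=delta_threshold, variable=var,
                            family_scope=scope, side=side, continent=cont))
                    except ValueError:   # too few cells or degenerate data
                        records.append(ModelRecord.absent(
                            var, scope, side, cont, n_cells=len(data)))
    return records


def records_to_frame(records: list[ModelRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "continent": r.continent, "family": r.family_scope, "side": r.side,
        "variable": r.variable, "n_cells": r.n_cells,
        "linear_sign": r.linear_sign, "linear_r2": r.linear_r2,
        "linear_p": r.linear_p, "quad_sign": r.quad_sign,
        "quad_r2": r.quad_r2, "quad_p": r.quad_p,
        "delta_r2": r.delta_r2, "shape": r.shape, "status": r.status,
    } for r in records])


def contrasts_to_frame(contrasts: list[SideContrast]) -> pd.DataFrame:
    return pd.DataFrame([{
        "continent": c.continent, "family_scope": c.family_scope,
        "mean_dorsal": c.mean_dorsal, "mean_ventral": c.mean_ventral,
        "difference": c.difference, "p_adj": c.p_adj,
        "n_species": c.n_species,
    } for c in contrasts])
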