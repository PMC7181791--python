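"""Face-centred central composite designs and quadratic response surfaces.

A face-centred CCD for k factors codes every factor to three levels
{-1, 0, +1} (axial distance alpha = 1, so axial points sit on the faces of
the factorial cube) and consists of:

* 2^k factorial corners, replicated ``r_f`` times,
* 2k axial points (one factor at ±1, the rest at 0), replicated ``r_a``,
* the centre point, replicated ``r_c``.

The response is fitted with the full quadratic model in coded units —
intercept, k linear, k(k-1)/2 two-way interaction and k pure quadratic
terms — by ordinary least squares, with a per-term partial (Type III)
ANOVA; for this balanced symmetric design partial and sequential sums of
squares coincide for the standard term ordering.  The fitted surface is
then maximised (or minimised) over the coded box [-1, 1]^k to predict the
optimal factor settings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import f as f_dist

__all__ = [
    "FactorSpec",
    "CCDDesign",
    "RSMFit",
    "OptimumPrediction",
    "DesignError",
    "generate_ccd",
    "encode",
    "decode",
    "quadratic_term_names",
    "quadratic_design_matrix",
    "fit_quadratic",
    "predict_optimum",
]


class DesignError(ValueError):
    """Invalid design request or rank-deficient model matrix."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its three natural-unit levels."""

    name: str
    low: float
    mid: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.mid < self.high:
            raise ValueError(f"{self.name}: need low < mid < high")
        span = self.high - self.low
        if abs(self.mid - 0.5 * (self.low + self.high)) > 1e-3 * span:
            raise ValueError(
                f"{self.name}: mid must be the midpoint of low and high "
                "(three-level face-centred design)"
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


def encode(natural_value: float | np.ndarray, factor: FactorSpec):
    """Natural units → coded units: (x - mid) / ((high - low) / 2)."""
    return (np.asarray(natural_value, dtype=float) - factor.mid) / factor.half_range


def decode(coded_value: float | np.ndarray, factor: FactorSpec):
    """Coded units → natural units (inverse of :func:`encode`)."""
    return factor.mid + np.asarray(coded_value, dtype=float) * factor.half_range


@dataclass
class CCDDesign:
    """Coded run matrix with replicate structure and point types."""

    factors: list[FactorSpec]
    coded: np.ndarray  # (n_runs, k) with entries in {-1, 0, +1}
    point_type: list[str]  # "factorial" | "axial" | "center"
    replicates: tuple[int, int, int]  # (r_f, r_a, r_c)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def k(self) -> int:
        return len(self.factors)

    def natural(self) -> np.ndarray:
        return np.column_stack(
            [decode(self.coded[:, j], f) for j, f in enumerate(self.factors)]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"run": np.arange(1, self.n_runs + 1)})
        df["point_type"] = self.point_type
        nat = self.natural()
        for j, f in enumerate(self.factors):
            df[f"{f.name}_coded"] = self.coded[:, j]
        for j, f in enumerate(self.factors):
            df[f"{f.name}_natural"] = nat[:, j]
        return df


def generate_ccd(
    factors: list[FactorSpec], r_f: int = 1, r_a: int = 1, r_c: int = 1
) -> CCDDesign:
    """Generate a face-centred CCD with the given replicate counts.

    Run order is deterministic: factorial block, axial block, centre block;
    lexicographic within each block with replicates adjacent.  Total runs:
    ``2**k * r_f + 2*k * r_a + r_c``.
    """
    k = len(factors)
    if k < 2:
        raise DesignError("a CCD needs at least 2 factors")
    if min(r_f, r_a, r_c) < 1:
        raise DesignError("replicate counts must be >= 1")
    rows: list[tuple[float, ...]] = []
    types: list[str] = []
    for corner in itertools.product((-1.0, 1.0), repeat=k):
        rows.extend([corner] * r_f)
        types.extend(["factorial"] * r_f)
    for j in range(k):
        for sign in (-1.0, 1.0):
            point = tuple(sign if i == j else 0.0 for i in range(k))
            rows.extend([point] * r_a)
            types.extend(["axial"] * r_a)
    rows.extend([(0.0,) * k] * r_c)
    types.extend(["center"] * r_c)
    return CCDDesign(
        factors=list(factors),
        coded=np.array(rows, dtype=float),
        point_type=types,
        replicates=(r_f, r_a, r_c),
    )


def quadratic_term_names(factors: list[FactorSpec]) -> list[str]:
    names = ["intercept"] + [f.name for f in factors]
    names += [
        f"{a.name}:{b.name}" for a, b in itertools.combinations(factors, 2)
    ]
    names += [f"{f.name}^2" for f in factors]
    return names


def quadratic_design_matrix(coded: np.ndarray) -> np.ndarray:
    """Full quadratic model matrix: 1, x_i, x_i x_j (i<j), x_i^2."""
    coded = np.asarray(coded, dtype=float)
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, i] for i in range(k)]
    cols += [
        coded[:, i] * coded[:, j] for i, j in itertools.combinations(range(k), 2)
    ]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class RSMFit:
    """OLS fit of the full quadratic surface with per-term ANOVA."""

    factors: list[FactorSpec]
    coefficients: pd.Series  # coded scale, indexed by term name
    standard_errors: pd.Series
    anova: pd.DataFrame  # per term: sum_sq, df, F, p (plus Residual row)
    r_squared: float
    df_resid: int
    mse_resid: float

    def predict(self, coded: np.ndarray) -> np.ndarray:
        X = quadratic_design_matrix(np.atleast_2d(coded))
        return X @ self.coefficients.to_numpy()


def fit_quadratic(design: CCDDesign, responses: np.ndarray) -> RSMFit:
    """Fit the full quadratic model in coded units by OLS.

    Per-term ANOVA uses partial (Type III) single-degree-of-freedom sums of
    squares, F = t² against the residual mean square.  Constant responses
    give all non-intercept coefficients 0 and R² = 0 by the zero-total-SS
    convention.  Rank deficiency raises :class:`DesignError` naming the
    aliased terms.
    """
    y = np.asarray(responses, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValueError(
            f"responses must have length {design.n_runs}, got {y.shape}"
        )
    X = quadratic_design_matrix(design.coded)
    names = quadratic_term_names(design.factors)
    p = X.shape[1]
    if design.n_runs <= p:
        raise DesignError("design leaves no residual degrees of freedom")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify aliased columns via the R diagonal of a pivoted QR proxy
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [names[i] for i in np.nonzero(diag < 1e-8 * diag.max())[0]]
        raise DesignError(f"rank-deficient model matrix; aliased terms: {aliased}")
    model = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    mse = float(model.mse_resid)
    df_resid = int(model.df_resid)
    terms = names[1:]
    if mse > 0:
        fvals = model.tvalues[terms] ** 2
        pvals = pd.Series(
            f_dist.sf(fvals.to_numpy(), 1, df_resid), index=terms
        )
        sums = fvals * mse
    else:  # zero residual variance: no valid F test
        fvals = pd.Series(np.nan, index=terms)
        pvals = pd.Series(np.nan, index=terms)
        sums = pd.Series(0.0, index=terms)
    anova = pd.DataFrame(
        {"sum_sq": sums, "df": 1, "F": fvals, "p": pvals}
    )
    anova.loc["Residual"] = [float(model.ssr), df_resid, np.nan, np.nan]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(model.rsquared)
    if not np.isfinite(r2):  # zero total SS convention
        r2 = 0.0
    return RSMFit(
        factors=list(design.factors),
        coefficients=pd.Series(model.params.to_numpy(), index=names),
        standard_errors=pd.Series(model.bse.to_numpy(), index=names),
        anova=anova,
        r_squared=r2,
        df_resid=df_resid,
        mse_resid=mse,
    )


@dataclass
class OptimumPrediction:
    """Response-optimising factor settings within the coded box."""

    coded_settings: dict[str, float]
    natural_settings: dict[str, float]
    predicted_response: float
    objective: str
    search_bounds: tuple[float, float] = (-1.0, 1.0)


def _quadratic_parts(fit: RSMFit) -> tuple[float, np.ndarray, np.ndarray]:
    """Decompose the fitted surface as c0 + b·x + x'Ax (A symmetric)."""
    k = len(fit.factors)
    coef = fit.coefficients
    c0 = float(coef["intercept"])
    b = np.array([coef[f.name] for f in fit.factors])
    A = np.zeros((k, k))
    for i in range(k):
        A[i, i] = coef[f"{fit.factors[i].name}^2"]
    for i, j in itertools.combinations(range(k), 2):
        half = 0.5 * coef[f"{fit.factors[i].name}:{fit.factors[j].name}"]
        A[i, j] = A[j, i] = half
    return c0, b, A


def predict_optimum(
    fit: RSMFit,
    factors: list[FactorSpec] | None = None,
    objective: str = "maximize",
) -> OptimumPrediction:
    """Optimise the fitted quadratic over the coded box [-1, 1]^k.

    Takes the interior stationary point when it lies in the box with the
    right curvature, and polishes a lattice of multistart points with
    bound-constrained L-BFGS-B otherwise, so boundary optima are found too.
    """
    if objective not in ("maximize", "minimize"):
        raise ValueError("objective must be 'maximize' or 'minimize'")
    factors = factors if factors is not None else fit.factors
    k = len(factors)
    c0, b, A = _quadratic_parts(fit)
    sign = -1.0 if objective == "maximize" else 1.0

    def neg_obj(x: np.ndarray) -> float:
        return sign * (c0 + b @ x + x @ A @ x)

    def neg_grad(x: np.ndarray) -> np.ndarray:
        return sign * (b + 2.0 * A @ x)

    starts = [np.array(s, dtype=float) for s in itertools.product((-1, 0, 1), repeat=k)]
    eigvals = np.linalg.eigvalsh(A)
    curvature_ok = np.all(eigvals < 0) if objective == "maximize" else np.all(eigvals > 0)
    if curvature_ok:
        stationary = np.linalg.solve(2.0 * A, -b)
        if np.all(np.abs(stationary) <= 1.0):
            starts.append(stationary)
    best_x, best_val = None, np.inf
    bounds = [(-1.0, 1.0)] * k
    for x0 in starts:
        res = minimize(
            neg_obj, x0, jac=neg_grad, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-12},
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
    coded = {f.name: float(np.clip(v, -1, 1)) for f, v in zip(factors, best_x)}
    natural = {
        f.name: float(decode(coded[f.name], f)) for f in factors
    }
    return OptimumPrediction(
        coded_settings=coded,
        natural_settings=natural,
        predicted_response=float(sign * best_val),
        objective=objective,
    )
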