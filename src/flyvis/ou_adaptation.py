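"""Hansen-type Ornstein-Uhlenbeck adaptive regression on a phylogeny.

A trait y evolves along the tree as dy = -alpha*(y - theta)*dt + sigma*dB,
pulled toward a primary optimum theta at rate alpha, with white noise sigma.
The process is reported in the (t_half, v_y) parametrization: phylogenetic
half-life t_half = ln(2)/alpha and stationary variance v_y = sigma^2/(2*alpha).

Starting the process at the ancestral optimum gives, for tips i and j with
shared time s_ij from the root and patristic distance d_ij,

    Cov[y_i, y_j] = v_y * (1 - exp(-2*alpha*s_ij)) * exp(-alpha*d_ij)

which reduces to the Brownian-motion covariance sigma^2 * s_ij as
alpha -> 0 (sigma^2 = 2*alpha*v_y held as the free parameter) and to white
noise v_y * I as alpha -> inf.  Both limits are handled analytically:
t_half = 0 is an i.i.d. GLS fit and t_half = inf a Brownian GLS fit.

The primary optimum is either constant, regime-dependent (through the
exponentially weighted regime history of each lineage), a linear function
of a Brownian predictor, or both.  With a randomly evolving predictor the
GLS slope on observed values is the *evolutionary* regression slope; the
inertia-free *optimal* slope is obtained by dividing by
rho(alpha*T) = 1 - (1 - exp(-alpha*T))/(alpha*T).

Estimation profiles the likelihood on a (t_half, v_y) grid with Nelder-Mead
refinement, reports a 2-logL support region for t_half, and ranks the four
model variants by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .io_fixtures import SpeciesTraitTable
from .regimes import RegimePainting
from .trees import UltrametricTree

LN2 = float(np.log(2.0))

PREDICTOR_KINDS = ("none", "bm", "regime", "regime_bm")


class OUFitError(ValueError):
    """Raised for invalid model specifications or degenerate fits."""


def rho(x):
    """Phylogenetic correction factor 1 - (1 - exp(-x))/x, in (0, 1).

    Ratio of the evolutionary to the optimal regression slope for a
    regression over total time x = alpha*T; rho(0) = 0 (pure inertia),
    rho(inf) = 1 (instantaneous adaptation).
    """
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    big = np.isinf(x)
    small = (~big) & (x <= 1e-8)
    mid = (~big) & (~small)
    out[big] = 1.0
    out[small] = x[small] / 2.0
    xm = np.minimum(x[mid], 700.0)
    out[mid] = 1.0 + np.expm1(-xm) / xm
    return float(out[0]) if scalar else out


# ----------------------------------------------------------------- covariance
def ou_covariance(tree: UltrametricTree, alpha: float, v_y: float) -> np.ndarray:
    """Tip covariance of a non-stationary OU process started at the root.

    For small alpha the expression is evaluated with expm1 so that it tends
    smoothly to the Brownian form sigma^2 * s_ij with sigma^2 = 2*alpha*v_y.
    """
    if alpha < 0 or v_y < 0:
        raise OUFitError(f"alpha and v_y must be >= 0 (got {alpha}, {v_y})")
    S = tree.shared_times()
    ti = np.diag(S)
    D = ti[:, None] + ti[None, :] - 2.0 * S
    if np.isinf(alpha):
        return v_y * np.eye(len(S))
    return v_y * (-np.expm1(-2.0 * alpha * S)) * np.exp(-alpha * D)


def bm_covariance(tree: UltrametricTree, sigma2: float) -> np.ndarray:
    """Brownian-motion tip covariance sigma^2 * shared time."""
    if sigma2 < 0:
        raise OUFitError("sigma2 must be >= 0")
    return sigma2 * tree.shared_times()


def regime_weights(
    tree: UltrametricTree,
    painting: RegimePainting,
    alpha: float,
    regimes: list[str] | None = None,
) -> np.ndarray:
    """Exponentially weighted time each lineage spent in each regime.

    W[i, k] sums exp(-alpha*(T - t_end)) - exp(-alpha*(T - t_start)) over
    the segments of lineage i painted with regime k, plus exp(-alpha*T)
    credited to the root's regime.  Rows sum to 1 for every alpha >= 0;
    alpha -> 0 puts all mass on the root regime, alpha -> inf on the
    terminal branch's regime.
    """
    if alpha < 0:
        raise OUFitError("alpha must be >= 0")
    if regimes is None:
        regimes = painting.regimes
    col = {r: k for k, r in enumerate(regimes)}
    tips = tree.tip_indices
    times = tree.times
    W = np.zeros((len(tips), len(regimes)))
    for i, tip in enumerate(tips):
        T = times[tip]
        if np.isinf(alpha):
            W[i, col[painting.branch_regime[int(tip)]]] = 1.0
            continue
        for node in tree.tip_lineage(int(tip)):
            if node not in painting.branch_regime:
                raise OUFitError(f"branch above node {node} is not painted")
            t0 = times[int(tree.parent[node])]
            t1 = times[node]
            W[i, col[painting.branch_regime[node]]] += np.exp(
                -alpha * (T - t1)
            ) - np.exp(-alpha * (T - t0))
        W[i, col[painting.root_regime]] += np.exp(-alpha * T)
    return W


# ------------------------------------------------------------------------ GLS
@dataclass
class GLSFit:
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    logL: float
    R2_phylo: float
    residuals: np.ndarray


def gls_fit(X: np.ndarray, V: np.ndarray, y: np.ndarray) -> GLSFit:
    """Generalized least squares with a fully specified covariance.

    beta = (X' V^-1 X)^-1 X' V^-1 y, SEs from the inverse information,
    exact multivariate-normal log-likelihood, and a phylogenetic R^2 of
    1 - (e' V^-1 e)/(e0' V^-1 e0) against the GLS intercept-only fit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    try:
        cho = scipy.linalg.cho_factor(V, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise OUFitError("covariance matrix is singular or not positive definite") from exc
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise OUFitError("design matrix is rank deficient")

    Vi_X = scipy.linalg.cho_solve(cho, X)
    Vi_y = scipy.linalg.cho_solve(cho, y)
    XtViX = X.T @ Vi_X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (X.T @ Vi_y)
    e = y - X @ beta
    quad = float(e @ scipy.linalg.cho_solve(cho, e))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    logL = -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)

    ones = np.ones((n, 1))
    Vi_1 = scipy.linalg.cho_solve(cho, ones)
    b0 = float((ones.T @ Vi_y).item() / (ones.T @ Vi_1).item())
    e0 = y - b0
    quad0 = float(e0 @ scipy.linalg.cho_solve(cho, e0))
    R2 = 1.0 - quad / quad0 if quad0 > 0 else (1.0 if quad == 0 else np.nan)
    return GLSFit(
        beta=beta,
        se=np.sqrt(np.diag(cov_beta)),
        cov_beta=cov_beta,
        logL=logL,
        R2_phylo=R2,
        residuals=e,
    )


# ------------------------------------------------------------------- fitting
@dataclass(frozen=True)
class OUModelSpec:
    """One of the four model variants for a given response trait.

    predictor: 'none' (intercept only), 'bm' (Brownian body-size
    predictor), 'regime' (fixed SAT/NON-SAT optima) or 'regime_bm' (both).
    """

    response: str
    predictor: str = "none"
    predictor_trait: str = "H_width"
    log_transform: bool = True
    measurement_error: bool = False

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTOR_KINDS:
            raise OUFitError(
                f"predictor must be one of {PREDICTOR_KINDS}, got {self.predictor!r}"
            )

    @property
    def has_regime(self) -> bool:
        return self.predictor in ("regime", "regime_bm")

    @property
    def has_bm(self) -> bool:
        return self.predictor in ("bm", "regime_bm")

    def label(self) -> str:
        return {
            "none": "-",
            "bm": "H_width",
            "regime": "B",
            "regime_bm": "B + H_width",
        }[self.predictor]


@dataclass
class OUFitResult:
    """Maximum-likelihood fit of one OU model variant."""

    spec: OUModelSpec
    t_half: float
    support_region: tuple[float, float]
    v_y: float
    alpha: float
    sigma2: float
    optima: dict[str, float]
    optima_se: dict[str, float]
    optimal_slope: float | None
    optimal_slope_se: float | None
    evolutionary_slope: float | None
    evolutionary_slope_se: float | None
    logL: float
    k_params: int
    n: int
    AICc: float
    R2_phylo: float
    grid_logL: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        def clean(v):
            if v is None:
                return None
            v = float(v)
            if np.isnan(v):
                return None
            if np.isinf(v):
                return "inf" if v > 0 else "-inf"
            return v

        return {
            "response": self.spec.response,
            "predictor": self.spec.label(),
            "t_half": clean(self.t_half),
            "support_region": [clean(self.support_region[0]), clean(self.support_region[1])],
            "v_y": clean(self.v_y),
            "alpha": clean(self.alpha),
            "sigma2": clean(self.sigma2),
            "optima": {k: clean(v) for k, v in self.optima.items()},
            "optima_se": {k: clean(v) for k, v in self.optima_se.items()},
            "optimal_slope": clean(self.optimal_slope),
            "optimal_slope_se": clean(self.optimal_slope_se),
            "evolutionary_slope": clean(self.evolutionary_slope),
            "evolutionary_slope_se": clean(self.evolutionary_slope_se),
            "logL": clean(self.logL),
            "k_params": self.k_params,
            "n": self.n,
            "AICc": clean(self.AICc),
            "R2_phylo": clean(self.R2_phylo),
        }


def _aicc(logL: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise OUFitError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0 (n={n}, k={k})")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def default_t_half_grid(depth: float, n: int = 60) -> np.ndarray:
    """{0} + log-spaced from depth/1000 to 10*depth + {inf}."""
    return np.concatenate(
        [[0.0], np.geomspace(1e-3, 10.0, n) * depth, [np.inf]]
    )


class _Problem:
    """Precomputed data for likelihood evaluation of one model."""

    def __init__(self, tree, traits: SpeciesTraitTable, painting, spec: OUModelSpec):
        self.tree = tree
        self.spec = spec
        self.painting = painting
        order = tree.tip_labels
        missing = [s for s in order if s not in traits.species]
        if missing:
            raise OUFitError(f"tree tips without trait data: {missing}")
        mean = traits.mean(spec.response).reindex(order).astype(float)
        if mean.isna().any():
            raise OUFitError(f"missing {spec.response} values for some species")
        self.y = np.log(mean.to_numpy()) if spec.log_transform else mean.to_numpy()
        self.x = None
        if spec.has_bm:
            xm = traits.mean(spec.predictor_trait).reindex(order).astype(float)
            if xm.isna().any():
                raise OUFitError(f"missing {spec.predictor_trait} values for some species")
            self.x = np.log(xm.to_numpy()) if spec.log_transform else xm.to_numpy()
        self.me = np.zeros(len(order))
        if spec.measurement_error:
            se = traits.se(spec.response).reindex(order).astype(float).to_numpy()
            se = np.nan_to_num(se, nan=0.0)
            self.me = (se / mean.to_numpy()) ** 2 if spec.log_transform else se**2
        self.S = tree.shared_times()
        ti = np.diag(self.S)
        self.D = ti[:, None] + ti[None, :] - 2.0 * self.S
        self.T = tree.depth
        self.n = len(order)
        self.regimes = painting.regimes if (spec.has_regime and painting) else []
        if spec.has_regime and painting is None:
            raise OUFitError("regime model requires a painting")

    def design(self, alpha: float) -> np.ndarray:
        cols = []
        if self.spec.has_regime:
            W = regime_weights(self.tree, self.painting, alpha, regimes=self.regimes)
            cols.append(W)
        else:
            cols.append(np.ones((self.n, 1)))
        if self.x is not None:
            cols.append(self.x[:, None])
        return np.hstack(cols)

    def covariance(self, t_half: float, v: float) -> np.ndarray:
        if t_half == 0.0:
            V = v * np.eye(self.n)
        elif np.isinf(t_half):
            V = v * self.S  # v plays the role of the BM rate sigma^2
        else:
            alpha = LN2 / t_half
            V = v * (-np.expm1(-2.0 * alpha * self.S)) * np.exp(-alpha * self.D)
        return V + np.diag(self.me)

    def loglik(self, t_half: float, v: float) -> tuple[float, GLSFit | None, np.ndarray | None]:
        alpha = np.inf if t_half == 0 else (0.0 if np.isinf(t_half) else LN2 / t_half)
        X = self.design(alpha)
        # at the Brownian limit regime weight columns collapse onto the root
        # regime; drop all-(near-)zero columns so the GLS stays well posed
        keep = np.ptp(X, axis=0) + np.abs(X).max(axis=0) > 1e-12
        Xr = X[:, keep]
        if np.linalg.matrix_rank(Xr) < Xr.shape[1]:
            return -np.inf, None, None
        V = self.covariance(t_half, v)
        try:
            fit = gls_fit(Xr, V, self.y)
        except OUFitError:
            return -np.inf, None, None
        return fit.logL, fit, keep


def fit_ou_model(
    tree: UltrametricTree,
    traits: SpeciesTraitTable,
    painting: RegimePainting | None,
    spec: OUModelSpec,
    *,
    t_half_grid: np.ndarray | None = None,
    v_grid: np.ndarray | None = None,
    n_t_half: int = 60,
    n_v: int = 15,
    refine: bool = True,
    support_cutoff: float = 2.0,
) -> OUFitResult:
    """Maximum-likelihood fit of one OU model variant by grid + refinement.

    The likelihood is profiled on a (t_half, v) grid -- v being the
    stationary variance for finite t_half and the Brownian rate at
    t_half = inf -- then polished by Nelder-Mead from the best interior
    cell.  The support region is the range of grid half-lives whose profile
    log-likelihood is within ``support_cutoff`` of the maximum.
    """
    prob = _Problem(tree, traits, painting, spec)
    if t_half_grid is None:
        t_half_grid = default_t_half_grid(prob.T, n_t_half)
    if v_grid is None:
        # scale the variance grid from the naive OLS residual variance
        X0 = prob.design(np.inf)
        resid = prob.y - X0 @ np.linalg.lstsq(X0, prob.y, rcond=None)[0]
        base = max(float(resid @ resid) / max(prob.n - X0.shape[1], 1), 1e-12)
        v_grid = base * np.geomspace(1e-2, 1e2, n_v)

    profile = np.full(len(t_half_grid), -np.inf)
    best = (-np.inf, None, None)  # logL, t_half, v
    for i, th in enumerate(t_half_grid):
        for v in v_grid:
            ll, _, _ = prob.loglik(th, v)
            if ll > profile[i]:
                profile[i] = ll
            if ll > best[0]:
                best = (ll, th, v)
    if not np.isfinite(best[0]):
        raise OUFitError(
            "likelihood is non-finite on the whole grid; "
            f"t_half range {t_half_grid[0]}..{t_half_grid[-1]}, "
            f"v range {v_grid[0]:.3g}..{v_grid[-1]:.3g}"
        )

    logL_best, th_best, v_best = best
    if refine and th_best not in (0.0, np.inf) and 0 < th_best:

        def neg(z):
            ll, _, _ = prob.loglik(float(np.exp(z[0])), float(np.exp(z[1])))
            return -ll if np.isfinite(ll) else 1e12

        res = scipy.optimize.minimize(
            neg,
            x0=[np.log(th_best), np.log(v_best)],
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
        )
        if -res.fun > logL_best:
            logL_best = -res.fun
            th_best, v_best = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    elif refine:
        # at the analytic endpoints only the variance is free: polish it 1-D
        def neg_v(z):
            ll, _, _ = prob.loglik(th_best, float(np.exp(z[0])))
            return -ll if np.isfinite(ll) else 1e12

        res = scipy.optimize.minimize(
            neg_v,
            x0=[np.log(v_best)],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 200},
        )
        if -res.fun > logL_best:
            logL_best = -res.fun
            v_best = float(np.exp(res.x[0]))

    in_region = t_half_grid[profile >= logL_best - support_cutoff]
    support = (
        (float(in_region.min()), float(in_region.max()))
        if len(in_region)
        else (th_best, th_best)
    )

    ll, fit, keep = prob.loglik(th_best, v_best)
    assert fit is not None
    alpha = np.inf if th_best == 0 else (0.0 if np.isinf(th_best) else LN2 / th_best)
    v_y = v_best if not np.isinf(th_best) else np.inf
    sigma2 = (
        v_best
        if np.isinf(th_best)
        else (np.inf if th_best == 0 else 2.0 * alpha * v_best)
    )

    # unpack coefficients back into the full design's slots
    n_reg = len(prob.regimes) if spec.has_regime else 1
    full_p = n_reg + (1 if spec.has_bm else 0)
    beta = np.full(full_p, np.nan)
    se = np.full(full_p, np.nan)
    beta[np.flatnonzero(keep)] = fit.beta
    se[np.flatnonzero(keep)] = fit.se

    optima: dict[str, float] = {}
    optima_se: dict[str, float] = {}
    if spec.has_regime:
        for j, r in enumerate(prob.regimes):
            optima[r] = float(beta[j])
            optima_se[r] = float(se[j])
    else:
        optima["intercept"] = float(beta[0])
        optima_se["intercept"] = float(se[0])

    evolutionary_slope = optimal_slope = None
    ev_se = opt_se = None
    if spec.has_bm:
        evolutionary_slope = float(beta[-1])
        ev_se = float(se[-1])
        r = rho(alpha * prob.T)
        optimal_slope = evolutionary_slope / r if r > 0 else np.inf * np.sign(evolutionary_slope)
        opt_se = ev_se / r if r > 0 else np.inf

    k = 2 + full_p
    return OUFitResult(
        spec=spec,
        t_half=float(th_best),
        support_region=support,
        v_y=float(v_y),
        alpha=float(alpha),
        sigma2=float(sigma2),
        optima=optima,
        optima_se=optima_se,
        optimal_slope=optimal_slope,
        optimal_slope_se=opt_se,
        evolutionary_slope=evolutionary_slope,
        evolutionary_slope_se=ev_se,
        logL=float(logL_best),
        k_params=k,
        n=prob.n,
        AICc=_aicc(logL_best, k, prob.n),
        R2_phylo=float(fit.R2_phylo),
        grid_logL={"t_half": list(map(float, t_half_grid)), "profile": list(map(float, profile))},
    )


# ------------------------------------------------------------ model selection
@dataclass
class ModelComparisonTable:
    """AICc ranking of model variants for one response trait."""

    fits: list[OUFitResult]
    delta: list[float]
    best_index: int
    supported: list[bool]  # delta < 4

    def to_records(self) -> list[dict]:
        out = []
        for i, fit in enumerate(self.fits):
            rec = fit.to_dict()
            rec["delta_AICc"] = self.delta[i]
            rec["best"] = i == self.best_index
            rec["equally_supported"] = self.supported[i]
            out.append(rec)
        return out


def compare_models(fits: list[OUFitResult], support_delta: float = 4.0) -> ModelComparisonTable:
    """Rank fits of the same response by AICc; flag best and delta < 4 rows."""
    if len(fits) < 2:
        raise OUFitError("model comparison needs at least two fits")
    responses = {f.spec.response for f in fits}
    if len(responses) > 1:
        raise OUFitError(f"cannot compare fits of different responses: {sorted(responses)}")
    aicc = np.array([f.AICc for f in fits])
    best = int(np.lexsort((np.array([f.k_params for f in fits]), aicc))[0])
    delta = aicc - aicc[best]
    return ModelComparisonTable(
        fits=list(fits),
        delta=[float(d) for d in delta],
        best_index=best,
        supported=[bool(d < support_delta) for d in delta],
    )


def fit_all_models(
    tree: UltrametricTree,
    traits: SpeciesTraitTable,
    painting: RegimePainting,
    response: str,
    *,
    log_transform: bool = True,
    measurement_error: bool = False,
    predictor_trait: str = "H_width",
    **fit_kwargs,
) -> ModelComparisonTable:
    """Fit the four model variants for one response and rank them by AICc."""
    fits = []
    for predictor in PREDICTOR_KINDS:
        spec = OUModelSpec(
            response=response,
            predictor=predictor,
            predictor_trait=predictor_trait,
            log_transform=log_transform,
            measurement_error=measurement_error,
        )
        fits.append(fit_ou_model(tree, traits, painting, spec, **fit_kwargs))
    return compare_models(fits)
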