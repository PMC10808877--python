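"""Per-trait models of pairwise cultural sharing.

For each cultural trait the 11 raw pair-level predictors (local TH/AI
dissimilarity, TH/AI path cost and length, topographic cost and length,
geodesic distance, relatedness, neighbourhood transmission) are screened
for collinearity, reduced to five varimax-rotated components with stable
semantics (temperature turnover, aridity turnover, travel cost, ancestry,
neighbour transmission), and used in a Bernoulli mixed model

    logit P(share_ij = 1) = b0 + sum_k b_k PC_k + u_i + u_j,
    u ~ N(0, sigma^2)  (one variance; a society's intercept is the same
    whether it appears as the first or second pair member)

estimated by a Laplace approximation to the marginal likelihood
(penalized IRLS over (beta, u) nested in a 1-D profile over log sigma).
Model-level filters (imbalance, non-convergence, < 50 datapoints),
Benjamini-Yekutieli FDR adjustment, AUC, and Moran's I residual
correlograms complete the per-trait pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats
from statsmodels.multivariate.factor_rotation import rotate_factors
from statsmodels.stats.multitest import multipletests

from .cost_paths import geodesic_km_matrix

__all__ = [
    "RAW_PREDICTORS",
    "COMPONENT_NAMES",
    "ComponentScores",
    "FitResult",
    "Correlogram",
    "vif",
    "varimax_components",
    "fit_mixed_logit",
    "model_filters",
    "adjust_fdr",
    "auc",
    "morans_correlogram",
    "fit_trait",
]

logger = logging.getLogger(__name__)

RAW_PREDICTORS = [
    "th_dissim",
    "th_cost",
    "ai_dissim",
    "ai_cost",
    "th_len",
    "ai_len",
    "topo_cost",
    "topo_len",
    "geodesic_km",
    "relatedness",
    "neighbor_transmission",
]

COMPONENT_NAMES = [
    "temp_turnover",
    "aridity_turnover",
    "travel_cost",
    "ancestry",
    "neighbor_transmission",
]

# which raw variables define each component's semantics; used to label the
# rotated components by their dominant loading block
_COMPONENT_BLOCKS = {
    "temp_turnover": ["th_dissim", "th_cost"],
    "aridity_turnover": ["ai_dissim", "ai_cost"],
    "travel_cost": ["topo_cost", "topo_len", "th_len", "ai_len", "geodesic_km"],
    "ancestry": ["relatedness"],
    "neighbor_transmission": ["neighbor_transmission"],
}


def vif(design: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    Perfectly collinear columns report +inf.
    """
    x = np.asarray(design, dtype=float)
    names = (
        list(design.columns)
        if isinstance(design, pd.DataFrame)
        else [f"x{j}" for j in range(x.shape[1])]
    )
    n, p = x.shape
    if n <= p:
        raise ValueError("need more rows than columns")
    xs = x - x.mean(axis=0)
    out = np.empty(p)
    for j in range(p):
        yj = xs[:, j]
        xj = np.delete(xs, j, axis=1)
        ss_tot = yj @ yj
        if ss_tot <= 0:
            out[j] = np.nan
            continue
        beta, *_ = np.linalg.lstsq(xj, yj, rcond=None)
        resid = yj - xj @ beta
        r2 = 1.0 - (resid @ resid) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names, name="vif")


@dataclass
class ComponentScores:
    """Varimax-rotated component scores with labeled semantics."""

    scores: pd.DataFrame  # n_pairs x components, named per semantics
    loadings: pd.DataFrame  # raw predictors x components
    explained_variance: float  # fraction retained by the rotated subspace


def _label_components(loadings: pd.DataFrame) -> list[str]:
    """Assign semantic names to rotated components by loading blocks."""
    comps = loadings.columns
    score = np.zeros((len(COMPONENT_NAMES), len(comps)))
    for a, name in enumerate(COMPONENT_NAMES):
        block = _COMPONENT_BLOCKS[name]
        score[a] = loadings.loc[block].abs().mean(axis=0).to_numpy()
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-score)
    labels = [""] * len(comps)
    for a, c in zip(rows, cols):
        labels[c] = COMPONENT_NAMES[a]
    return labels


def varimax_components(
    raw: pd.DataFrame, n_components: int = 5
) -> ComponentScores:
    """Reduce the raw barrier predictors to varimax-rotated components.

    Correlation PCA retains ``n_components`` axes, an orthogonal varimax
    rotation redistributes them toward simple structure, and each rotated
    component is sign-anchored so its largest-|loading| raw variable loads
    positively (higher score = higher barrier). Scores are standardized
    (zero mean, unit variance) and mutually uncorrelated.
    """
    x = raw[RAW_PREDICTORS] if set(RAW_PREDICTORS) <= set(raw.columns) else raw
    cols = list(x.columns)
    if n_components > len(cols):
        raise ValueError("more components than predictors")
    arr = x.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("raw predictor matrix contains non-finite values")
    n = arr.shape[0]
    sd = arr.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = [c for c, s in zip(cols, sd) if s <= 0]
        raise ValueError(f"zero-variance predictors: {bad}")
    xs = (arr - arr.mean(axis=0)) / sd

    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    load = (vt[:n_components].T * s[:n_components]) / np.sqrt(n - 1)
    t_std = u[:, :n_components] * np.sqrt(n - 1)  # standardized PC scores
    evr = float((s[:n_components] ** 2).sum() / (s**2).sum())

    load_rot, rot = rotate_factors(load, "varimax")
    scores = t_std @ rot

    # sign anchor: dominant raw variable loads positively
    for c in range(n_components):
        dom = int(np.argmax(np.abs(load_rot[:, c])))
        if load_rot[dom, c] < 0:
            load_rot[:, c] *= -1
            scores[:, c] *= -1

    load_df = pd.DataFrame(
        load_rot, index=cols, columns=[f"PC{c + 1}" for c in range(n_components)]
    )
    if n_components == len(COMPONENT_NAMES) and set(
        sum(_COMPONENT_BLOCKS.values(), [])
    ) <= set(cols):
        labels = _label_components(load_df)
        load_df.columns = labels
        score_df = pd.DataFrame(scores, index=raw.index, columns=labels)
        score_df = score_df[COMPONENT_NAMES]
        load_df = load_df[COMPONENT_NAMES]
    else:
        score_df = pd.DataFrame(scores, index=raw.index, columns=load_df.columns)
    return ComponentScores(score_df, load_df, evr)


@dataclass
class FitResult:
    """A fitted per-trait sharing model."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    sigma2: float  # society random-intercept variance
    converged: bool
    loglik: float
    n_pairs: int
    share_fraction: float
    fitted: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    auc: float = np.nan
    p_adjusted: pd.Series | None = None
    included: bool = True
    exclusion_reason: str = ""


def _penalized_irls(
    y: np.ndarray,
    x: np.ndarray,
    a_idx: np.ndarray,
    b_idx: np.ndarray,
    q: int,
    sigma2: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Joint (beta, u) mode of the penalized Bernoulli log-likelihood."""
    n, p = x.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    u = np.zeros(q)
    tau = 1.0 / sigma2

    def eta_of(beta, u):
        return x @ beta + u[a_idx] + u[b_idx]

    def pen_ll(beta, u):
        eta = eta_of(beta, u)
        # log-likelihood of the Bernoulli terms minus the Gaussian penalty
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * tau * (u @ u))

    ll = pen_ll(beta, u)
    converged = False
    for _ in range(max_iter):
        eta = eta_of(beta, u)
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        r = y - mu

        xtwx = (x * w[:, None]).T @ x
        xtwz = np.zeros((p, q))
        np.add.at(xtwz.T, a_idx, x * w[:, None])
        np.add.at(xtwz.T, b_idx, x * w[:, None])
        ztwz = np.zeros((q, q))
        np.add.at(ztwz, (a_idx, a_idx), w)
        np.add.at(ztwz, (b_idx, b_idx), w)
        np.add.at(ztwz, (a_idx, b_idx), w)
        np.add.at(ztwz, (b_idx, a_idx), w)
        ztwz[np.diag_indices(q)] += tau

        g_beta = x.T @ r
        g_u = np.zeros(q)
        np.add.at(g_u, a_idx, r)
        np.add.at(g_u, b_idx, r)
        g_u -= tau * u

        h = np.block([[xtwx, xtwz], [xtwz.T, ztwz]])
        g = np.concatenate([g_beta, g_u])
        try:
            step = linalg.solve(h, g, assume_a="pos")
        except linalg.LinAlgError:
            step = np.linalg.lstsq(h, g, rcond=None)[0]

        scale = 1.0
        for _ in range(30):
            nb = beta + scale * step[:p]
            nu = u + scale * step[p:]
            nll = pen_ll(nb, nu)
            if nll >= ll - 1e-12:
                break
            scale *= 0.5
        beta, u, prev = nb, nu, ll
        ll = nll
        if abs(ll - prev) < tol * (abs(prev) + 1.0):
            converged = True
            break

    # final Hessian pieces at the mode for the Laplace determinant / SEs
    eta = eta_of(beta, u)
    mu = special.expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    ztwz = np.zeros((q, q))
    np.add.at(ztwz, (a_idx, a_idx), w)
    np.add.at(ztwz, (b_idx, b_idx), w)
    np.add.at(ztwz, (a_idx, b_idx), w)
    np.add.at(ztwz, (b_idx, a_idx), w)
    ztwz[np.diag_indices(q)] += tau
    return beta, u, ll, converged, ztwz, w


def _laplace_loglik(ll_pen, u, ztwz, sigma2, q):
    sign, logdet = np.linalg.slogdet(ztwz)
    if sign <= 0:
        return -np.inf
    return ll_pen - 0.5 * q * np.log(sigma2) - 0.5 * logdet


def fit_mixed_logit(
    share: np.ndarray | pd.Series,
    design: pd.DataFrame,
    id_a: np.ndarray | pd.Series,
    id_b: np.ndarray | pd.Series,
    add_intercept: bool = True,
    sigma2_bounds: tuple[float, float] = (1e-6, 25.0),
) -> FitResult:
    """Bernoulli model of pair sharing with crossed society intercepts.

    Both pair members contribute the same random intercept wherever they
    appear; the single variance ``sigma2`` is profiled by maximizing the
    Laplace-approximate marginal likelihood over log(sigma2). Wald SEs for
    the fixed effects come from the beta block of the inverse joint
    Hessian at the optimum. Returns fitted probabilities (conditional on
    the estimated intercepts) and response residuals for diagnostics.
    """
    y = np.asarray(share, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("sharing flags must be binary")
    x = design.to_numpy(dtype=float)
    names = list(design.columns)
    if add_intercept:
        x = np.column_stack([np.ones(len(y)), x])
        names = ["intercept"] + names
    ids = np.concatenate([np.asarray(id_a), np.asarray(id_b)])
    societies, codes = np.unique(ids, return_inverse=True)
    a_idx = codes[: len(y)]
    b_idx = codes[len(y) :]
    q = societies.size
    n, p = x.shape

    state: dict[float, tuple] = {}

    def negloglik(log_s2: float) -> float:
        s2 = float(np.exp(log_s2))
        beta, u, ll, conv, ztwz, w = _penalized_irls(y, x, a_idx, b_idx, q, s2)
        lap = _laplace_loglik(ll, u, ztwz, s2, q)
        state[log_s2] = (s2, beta, u, conv, ztwz, w, lap)
        return -lap

    lo, hi = np.log(sigma2_bounds[0]), np.log(sigma2_bounds[1])
    res = optimize.minimize_scalar(
        negloglik, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
    )
    s2, beta, u, conv, ztwz, w, lap = state[res.x]

    # SEs: beta block of the inverse of the full (beta, u) Hessian
    xtwx = (x * w[:, None]).T @ x
    xtwz = np.zeros((p, q))
    np.add.at(xtwz.T, a_idx, x * w[:, None])
    np.add.at(xtwz.T, b_idx, x * w[:, None])
    try:
        inner = linalg.solve(ztwz, xtwz.T, assume_a="pos")
        beta_info = xtwx - xtwz @ inner
        cov = linalg.inv(beta_info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except linalg.LinAlgError:
        se = np.full(p, np.nan)
        conv = False

    zstat = np.where(se > 0, beta / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    eta = x @ beta + u[a_idx] + u[b_idx]
    fitted = special.expit(eta)
    share_fraction = float(y.mean())

    return FitResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2=s2,
        converged=bool(conv and res.success),
        loglik=float(lap),
        n_pairs=n,
        share_fraction=share_fraction,
        fitted=fitted,
        residuals=y - fitted,
        auc=auc(y, fitted),
    )


def model_filters(
    n_pairs: int,
    share_fraction: float,
    converged: bool,
    min_n: int = 50,
    balance: tuple[float, float] = (0.10, 0.90),
) -> tuple[bool, str]:
    """Include/exclude a trait model and give the reason.

    A model is excluded when the sharing percentage is above 90% or below
    10% (imbalance), when the fit did not converge, or when fewer than 50
    datapoints remain.
    """
    if n_pairs < min_n:
        return False, f"fewer than {min_n} datapoints"
    if not converged:
        return False, "did not converge"
    if share_fraction > balance[1] or share_fraction < balance[0]:
        return False, "imbalanced sharing fraction"
    return True, ""


def adjust_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Yekutieli step-up adjusted p-values (any dependence)."""
    arr = np.asarray(pvalues, dtype=float)
    adj = multipletests(arr, method="fdr_by")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index)
    return adj


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class Correlogram:
    """Moran's I by distance bin on pair midpoints."""

    table: pd.DataFrame  # bin_center_km, morans_i, p_value, n_pairs, flagged


def _morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    r = values - values.mean()
    denom = r @ r
    s0 = weights.sum()
    if denom <= 0 or s0 <= 0:
        return np.nan
    return float(len(values) / s0 * (r @ weights @ r) / denom)


def morans_correlogram(
    residuals: np.ndarray,
    midpoints: pd.DataFrame,
    n_bins: int = 10,
    n_perm: int = 199,
    upper_quantile: float = 0.9,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
) -> Correlogram:
    """Spatial autocorrelogram of model residuals.

    Pair coordinates are the midpoints of the two societies; bins are
    equal-count up to the ``upper_quantile`` of midpoint distances unless
    explicit ``bin_edges`` are given. Within-bin binary weights feed
    Moran's I; p-values come from residual permutations (one-sided,
    positive autocorrelation). Bins with degenerate variance are flagged.
    """
    r = np.asarray(residuals, dtype=float)
    dist = geodesic_km_matrix(
        midpoints["lat"].to_numpy(), midpoints["lon"].to_numpy()
    )
    iu = np.triu_indices(len(r), k=1)
    dvals = dist[iu]
    if bin_edges is None:
        top = np.quantile(dvals, upper_quantile)
        inside = dvals[dvals <= top]
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(inside, qs))
    rng = np.random.default_rng(seed)
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        w = ((dist > lo) & (dist <= hi)).astype(float)
        np.fill_diagonal(w, 0.0)
        n_in = int(w.sum() / 2)
        obs = _morans_i(r, w)
        if not np.isfinite(obs) or n_in == 0:
            rows.append(
                {
                    "bin_center_km": (lo + hi) / 2,
                    "morans_i": np.nan,
                    "p_value": np.nan,
                    "n_pairs": n_in,
                    "flagged": True,
                }
            )
            continue
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(r)
            if _morans_i(perm, w) >= obs:
                count += 1
        rows.append(
            {
                "bin_center_km": (lo + hi) / 2,
                "morans_i": obs,
                "p_value": (count + 1) / (n_perm + 1),
                "n_pairs": n_in,
                "flagged": False,
            }
        )
    return Correlogram(pd.DataFrame(rows))


def fit_trait(
    pair_data: pd.DataFrame,
    trait: str,
    min_n: int = 50,
    n_components: int = 5,
) -> tuple[FitResult | None, ComponentScores | None]:
    """Full per-trait pipeline: screen, reduce, fit, filter.

    ``pair_data`` carries ``id_a``, ``id_b``, the 11 raw predictors and a
    ``share`` column (the per-trait flag, NaN = missing); rows with any
    missing value are dropped first.
    """
    cols = ["id_a", "id_b", "share"] + RAW_PREDICTORS
    data = pair_data[cols].dropna()
    n = len(data)
    if n < min_n:
        logger.info("trait %s: %d complete pairs (<%d), skipped", trait, n, min_n)
        fr = FitResult(
            params=pd.Series(dtype=float),
            se=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float),
            sigma2=np.nan,
            converged=False,
            loglik=np.nan,
            n_pairs=n,
            share_fraction=float(data["share"].mean()) if n else np.nan,
            included=False,
            exclusion_reason=f"fewer than {min_n} datapoints",
        )
        return fr, None
    try:
        comps = varimax_components(data[RAW_PREDICTORS], n_components)
    except ValueError as err:
        logger.warning("trait %s: component reduction failed (%s)", trait, err)
        fr = FitResult(
            params=pd.Series(dtype=float),
            se=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float),
            sigma2=np.nan,
            converged=False,
            loglik=np.nan,
            n_pairs=n,
            share_fraction=float(data["share"].mean()),
            included=False,
            exclusion_reason=str(err),
        )
        return fr, None
    fit = fit_mixed_logit(
        data["share"].to_numpy(),
        comps.scores,
        data["id_a"].to_numpy(),
        data["id_b"].to_numpy(),
    )
    included, reason = model_filters(
        fit.n_pairs, fit.share_fraction, fit.converged, min_n=min_n
    )
    fit.included = included
    fit.exclusion_reason = reason
    return fit, comps
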