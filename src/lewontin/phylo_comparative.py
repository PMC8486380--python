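"""Phylogenetic comparative methods for the diversity-census-size relationship.

Implements the Brownian-motion (BM) machinery used throughout the analysis:

* the phylogenetic covariance matrix of a chronogram (shared root-to-MRCA
  path lengths, scaled to unit tree height);
* a Bayesian phylogenetic mixed-effects regression
  ``y = alpha + beta x + u + e`` with ``u ~ MVN(0, sigma_p^2 C)`` and
  ``e ~ N(0, sigma_r^2 I)``, whose variance components give the
  phylogenetic signal ``lambda = sigma_p^2 / (sigma_p^2 + sigma_r^2)``;
* ordinary least squares with case-resampling bootstrap intervals;
* Felsenstein's phylogenetic independent contrasts and node-height tests
  (robust regression of |standardized contrast| on node age, which detects
  shifts in the rate of trait evolution through time);
* maximum-likelihood BM ancestral state estimates (GLS closed form);
* a lognormal mixed-effects model of recombination map length on census
  size, with social taxa excluded.

The mixed model is sampled with a differential-evolution ensemble sampler over
(alpha, beta, sigma_p, sigma_r) after marginalizing the phylogenetic effect,
using an eigendecomposition of C so each likelihood evaluation is O(n).
Priors are weakly informative on standardized data: normal(0, 10) for the
coefficients and half-normal(0, 1) for both standard deviations.
Convergence requires split-Rhat < 1.01 and effective sample size > 1000 for
every parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import dendropy
import emcee
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError, InvalidTreeError

__all__ = [
    "PhyloCovariance",
    "SamplerConfig",
    "PhyloMMFit",
    "ContrastSet",
    "OLSFit",
    "NodeHeightResult",
    "phylo_covariance",
    "repair_ultrametric",
    "fit_phylo_mm",
    "fit_phylo_mm_subset",
    "ols_diversity_nc",
    "pic",
    "node_height_test",
    "ancestral_states",
    "bm_loglik_pruning",
    "bm_loglik_dense",
    "fit_map_length_model",
]

logger = logging.getLogger(__name__)

ULTRAMETRY_RTOL = 1e-6


def _label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            raise InvalidTreeError(f"branch without length above node {_label(node)!r}")
        depths[node] = depths[node.parent_node] + length
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = _node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def check_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRY_RTOL) -> float:
    """Return the tree height; raise InvalidTreeError if tips are uneven."""
    depths = _node_depths(tree)
    tip_depths = np.array([depths[leaf] for leaf in tree.leaf_node_iter()])
    height = tip_depths.max()
    if height <= 0:
        raise InvalidTreeError("tree has zero height")
    if (height - tip_depths.min()) / height > rtol:
        raise InvalidTreeError(
            "tree is not ultrametric; consider repair_ultrametric() to extend "
            "tips within tolerance"
        )
    return float(height)


def repair_ultrametric(tree: dendropy.Tree, tol: float = 1e-3) -> dendropy.Tree:
    """Extend tip branches to the deepest tip, if deviations are small.

    Deviations up to ``tol`` (relative to tree height) are treated as
    rounding slop in the input chronogram and absorbed into terminal
    branches; anything larger is rejected.
    """
    clone = tree.clone(depth=1)
    depths = _node_depths(clone)
    tips = list(clone.leaf_node_iter())
    height = max(depths[t] for t in tips)
    worst = max(height - depths[t] for t in tips)
    if worst / height > tol:
        raise InvalidTreeError(
            f"tip depth deviation {worst / height:.2e} exceeds repair tolerance {tol:.0e}"
        )
    for t in tips:
        t.edge.length = (t.edge.length or 0.0) + (height - depths[t])
    return clone


@dataclass
class PhyloCovariance:
    """BM covariance of tips on a unit-height tree, with its label order."""

    matrix: np.ndarray
    labels: list[str]
    height: float  # original tree height (e.g. Myr) before unit scaling


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Shared-path covariance C with C_ij = depth(MRCA(i,j)) / height.

    The diagonal is exactly 1 after scaling; off-diagonals lie in [0, 1].
    Tip order is sorted tip labels.
    """
    height = check_ultrametric(tree)
    depths = _node_depths(tree)
    labels = sorted(_label(leaf) for leaf in tree.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    # Postorder: tips below each internal node get that node's depth as the
    # covariance for all cross-child pairs.
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[_label(node)]]
            continue
        children = node.child_nodes()
        sets = [tipsets[c] for c in children]
        d = depths[node] / height
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                ia = np.array(sets[a])[:, None]
                ib = np.array(sets[b])[None, :]
                C[ia, ib] = d
                C[ib.T, ia.T] = d
        tipsets[node] = [i for s in sets for i in s]
    np.fill_diagonal(C, 1.0)
    return PhyloCovariance(matrix=C, labels=labels, height=height)


@dataclass
class SamplerConfig:
    """Ensemble-sampler settings for the mixed-effects model."""

    n_walkers: int = 32
    n_burn: int = 1500
    n_steps: int = 2000
    rhat_max: float = 1.01
    ess_min: float = 1000.0


@dataclass
class PhyloMMFit:
    """Posterior summaries and diagnostics of a phylogenetic mixed model."""

    summary: pd.DataFrame          # rows: parameters; cols: mean, sd, q5, q50, q95
    draws: pd.DataFrame            # flattened posterior draws
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    flags: list[str] = field(default_factory=list)
    n_obs: int = 0

    def credible_interval(self, name: str, prob: float = 0.90) -> tuple[float, float]:
        lo = (1 - prob) / 2
        vals = self.draws[name].to_numpy()
        return float(np.quantile(vals, lo)), float(np.quantile(vals, 1 - lo))


def _log_prob_factory(y_t, X_t, eigvals, reduced: bool):
    """Vectorized log posterior over (coefs..., sigma_p, sigma_r).

    Data are pre-rotated by the eigenvectors of C, so the marginal
    covariance is diagonal: d_i = sigma_p^2 lam_i + sigma_r^2.
    """
    n_coef = X_t.shape[1]

    def log_prob(params: np.ndarray) -> np.ndarray:
        params = np.atleast_2d(params)
        coefs = params[:, :n_coef]
        if reduced:
            sp = np.zeros(len(params))
            sr = params[:, n_coef]
        else:
            sp = params[:, n_coef]
            sr = params[:, n_coef + 1]
        bad = (sr <= 0) | (sp < 0)
        sp = np.where(bad, 1.0, sp)
        sr = np.where(bad, 1.0, sr)
        # priors: coef ~ N(0, 10), sigma ~ half-N(0, 1)
        lp = -0.5 * np.sum(coefs**2, axis=1) / 100.0 - 0.5 * (sp**2 + sr**2)
        d = sp[:, None] ** 2 * eigvals[None, :] + sr[:, None] ** 2
        resid = y_t[None, :] - coefs @ X_t.T
        ll = -0.5 * (np.sum(resid**2 / d, axis=1) + np.sum(np.log(d), axis=1))
        out = lp + ll
        out[bad] = -np.inf
        return out

    return log_prob


def _run_sampler(y_t, X_t, eigvals, config: SamplerConfig, seed: int, reduced: bool):
    n_coef = X_t.shape[1]
    ndim = n_coef + (1 if reduced else 2)
    log_prob = _log_prob_factory(y_t, X_t, eigvals, reduced)
    rng = np.random.RandomState(seed & 0x7FFFFFFF)
    # initialize near a least-squares solution
    coef0, *_ = np.linalg.lstsq(X_t, y_t, rcond=None)
    resid_sd = max(np.std(y_t - X_t @ coef0), 1e-3)
    p0 = np.empty((config.n_walkers, ndim))
    p0[:, :n_coef] = coef0[None, :] + 0.1 * resid_sd * rng.standard_normal(
        (config.n_walkers, n_coef)
    )
    for j in range(n_coef, ndim):
        p0[:, j] = np.abs(resid_sd * (0.7 + 0.3 * rng.standard_normal(config.n_walkers))) + 1e-3
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        config.n_walkers, ndim, log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = rng.get_state()
    sampler.run_mcmc(p0, config.n_burn + config.n_steps, progress=False)
    chain = sampler.get_chain(discard=config.n_burn)  # (steps, walkers, ndim)
    return np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)


def _diagnostics(chains: dict[str, np.ndarray], config: SamplerConfig):
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for name, arr in chains.items():
        data = az.convert_to_dataset(arr[None] if arr.ndim == 1 else arr)
        rhat[name] = float(az.rhat(data)["x"].values)
        ess[name] = float(az.ess(data)["x"].values)
    converged = all(r < config.rhat_max for r in rhat.values()) and all(
        e > config.ess_min for e in ess.values()
    )
    return rhat, ess, converged


def _summarize(draws: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for name in draws.columns:
        v = draws[name].to_numpy()
        rows[name] = {
            "mean": v.mean(),
            "sd": v.std(ddof=1),
            "q5": np.quantile(v, 0.05),
            "q50": np.quantile(v, 0.50),
            "q95": np.quantile(v, 0.95),
        }
    return pd.DataFrame(rows).T


def fit_phylo_mm(
    y,
    x=None,
    C: PhyloCovariance | np.ndarray | None = None,
    config: SamplerConfig | None = None,
    seed: int = 0,
    reduced: bool = False,
) -> PhyloMMFit:
    """Bayesian phylogenetic mixed-effects regression.

    Model: ``y = alpha + beta x + u + e`` with ``u ~ MVN(0, sigma_p^2 C)``
    and ``e ~ N(0, sigma_r^2 I)``; with ``x=None`` the slope is omitted.
    Inputs are centered and scaled internally; ``alpha`` and ``beta`` are
    reported on the original scale, the variance components on the
    standardized scale (their ratio, lambda, is scale-free). The
    phylogenetic signal ``lambda = sigma_p^2 / (sigma_p^2 + sigma_r^2)`` is
    computed draw-wise.

    ``reduced=True`` drops the phylogenetic term entirely (sigma_p = 0),
    the fallback for subsets where the full model fails to converge.
    """
    config = config or SamplerConfig()
    y = np.asarray(y, float)
    n = len(y)
    if np.any(~np.isfinite(y)):
        raise InvalidArgumentError("y contains missing values; drop them first")
    if C is None:
        raise InvalidArgumentError("a phylogenetic covariance C is required")
    Cm = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    if Cm.shape != (n, n):
        raise InvalidArgumentError(f"C has shape {Cm.shape}, expected ({n}, {n})")

    flags: list[str] = []
    off_diag = np.abs(Cm - np.diag(np.diag(Cm))).max()
    if off_diag < 1e-8 and not reduced:
        flags.append("unidentifiable-lambda")
        logger.warning("C is numerically the identity; lambda is unidentifiable")

    y_mean, y_sd = y.mean(), y.std(ddof=1)
    if y_sd == 0:
        raise InvalidArgumentError("y is constant")
    ys = (y - y_mean) / y_sd
    if x is not None:
        x = np.asarray(x, float)
        if np.any(~np.isfinite(x)):
            raise InvalidArgumentError("x contains missing values; drop them first")
        x_mean, x_sd = x.mean(), x.std(ddof=1)
        if x_sd == 0:
            flags.append("degenerate-design")
            x_sd = 1.0
        xs = (x - x_mean) / x_sd
        X = np.column_stack([np.ones(n), xs])
    else:
        X = np.ones((n, 1))

    eigvals, Q = np.linalg.eigh(Cm)
    eigvals = np.clip(eigvals, 0.0, None)
    y_t = Q.T @ ys
    X_t = Q.T @ X

    chain = _run_sampler(y_t, X_t, eigvals, config, seed, reduced)
    n_coef = X.shape[1]
    alpha_s = chain[:, :, 0]
    beta_s = chain[:, :, 1] if x is not None else None
    if reduced:
        sp = np.zeros_like(chain[:, :, n_coef])
        sr = chain[:, :, n_coef]
    else:
        sp = chain[:, :, n_coef]
        sr = chain[:, :, n_coef + 1]
    lam = np.where(sp**2 + sr**2 > 0, sp**2 / (sp**2 + sr**2), 0.0)

    # back-transform coefficients to the original scale
    if x is not None:
        beta = beta_s * y_sd / x_sd
        alpha = y_mean + alpha_s * y_sd - beta * x_mean
    else:
        beta = None
        alpha = y_mean + alpha_s * y_sd

    chains = {"alpha": alpha, "sigma_p2": sp**2, "sigma_r2": sr**2, "lambda": lam}
    if beta is not None:
        chains["beta"] = beta
    if reduced:
        chains.pop("sigma_p2")
        chains.pop("lambda")
    rhat, ess, converged = _diagnostics(chains, config)

    draws = pd.DataFrame({k: v.reshape(-1) for k, v in chains.items()})
    if reduced:
        draws["sigma_p2"] = 0.0
        draws["lambda"] = 0.0
        flags.append("reduced")
    if not reduced and draws["sigma_r2"].mean() < 2.5e-3:
        flags.append("degenerate-residual")
    if not converged:
        logger.warning("sampler did not meet convergence criteria: rhat=%s", rhat)

    return PhyloMMFit(
        summary=_summarize(draws),
        draws=draws,
        rhat=rhat,
        ess=ess,
        converged=converged,
        flags=flags,
        n_obs=n,
    )


def fit_phylo_mm_subset(
    taxa: pd.DataFrame,
    tree: dendropy.Tree,
    phylum: str | None,
    y_col: str = "pi",
    x_col: str = "N_c",
    log10_transform: bool = True,
    config: SamplerConfig | None = None,
    seed: int = 0,
) -> PhyloMMFit:
    """Fit the mixed model on one phylum's taxa (or all taxa, phylum=None).

    The subtree spanning the subset is extracted and rescaled to unit
    height. If the full model fails the convergence criteria, the model is
    automatically refit without the phylogenetic term and flagged
    ``"reduced"``.
    """
    subset = taxa if phylum is None else taxa[taxa["phylum"] == phylum]
    tip_labels = {_label(leaf) for leaf in tree.leaf_node_iter()}
    subset = subset[subset["species"].isin(tip_labels)]
    subset = subset.dropna(subset=[y_col, x_col])
    if len(subset) < 10:
        raise InsufficientDataError(
            f"subset {phylum!r} has {len(subset)} taxa with complete data; need >= 10"
        )
    keep = sorted(subset["species"])
    sub_tree = tree.extract_tree_with_taxa_labels(keep)
    cov = phylo_covariance(sub_tree)
    ordered = subset.set_index("species").loc[cov.labels]
    y = ordered[y_col].to_numpy(float)
    x = ordered[x_col].to_numpy(float)
    if log10_transform:
        y, x = np.log10(y), np.log10(x)
    fit = fit_phylo_mm(y, x, cov, config=config, seed=seed)
    if not fit.converged:
        logger.warning("subset %r failed convergence; refitting reduced model", phylum)
        fit = fit_phylo_mm(y, x, cov, config=config, seed=seed, reduced=True)
    return fit


@dataclass
class OLSFit:
    slope: float
    intercept: float
    adj_r2: float
    percent_per_decade: float
    slope_ci: tuple[float, float]
    percent_per_decade_ci: tuple[float, float]
    n_boot: int


def ols_diversity_nc(pi, N_c, n_boot: int = 1000, seed: int = 0) -> OLSFit:
    """OLS of log10 diversity on log10 census size, with bootstrap intervals.

    The slope b is also reported as a percent increase in diversity per
    order of magnitude of census size, ``(10^b - 1) * 100``. Confidence
    intervals are nonparametric case-resampling bootstrap percentiles.
    """
    pi = np.asarray(pi, float)
    N_c = np.asarray(N_c, float)
    if len(pi) < 3:
        raise InsufficientDataError("need >= 3 observations")
    if np.any(pi <= 0) or np.any(N_c <= 0):
        raise InvalidArgumentError("pi and N_c must be > 0")
    y = np.log10(pi)
    X = sm.add_constant(np.log10(N_c))
    res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    rng = np.random.default_rng(seed)
    n = len(y)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        Xi = X[idx]
        if np.ptp(Xi[:, 1]) == 0:
            boot[i] = np.nan
            continue
        boot[i] = np.linalg.lstsq(Xi, y[idx], rcond=None)[0][1]
    boot = boot[np.isfinite(boot)]
    lo, hi = np.quantile(boot, [0.025, 0.975])
    return OLSFit(
        slope=slope,
        intercept=float(res.params[0]),
        adj_r2=float(res.rsquared_adj),
        percent_per_decade=float((10.0**slope - 1.0) * 100.0),
        slope_ci=(float(lo), float(hi)),
        percent_per_decade_ci=(
            float((10.0**lo - 1.0) * 100.0),
            float((10.0**hi - 1.0) * 100.0),
        ),
        n_boot=len(boot),
    )


@dataclass
class ContrastSet:
    """Standardized independent contrasts with their node ages (n-1 rows)."""

    table: pd.DataFrame  # columns: node, contrast, age, child1, child2


def _pic_recursion(tree: dendropy.Tree, trait: dict[str, float]):
    """Felsenstein's pruning pass.

    Returns (rows, root_estimate, root_variance, loglik_terms) where
    loglik_terms are the per-contrast (raw difference, variance-multiplier)
    pairs used by the BM likelihood.
    """
    depths = _node_depths(tree)
    height = max(depths[leaf] for leaf in tree.leaf_node_iter())
    est: dict[dendropy.Node, float] = {}
    extra: dict[dendropy.Node, float] = {}
    rows = []
    terms = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            key = _label(node)
            if key not in trait:
                raise InvalidArgumentError(f"missing trait value for tip {key!r}")
            est[node] = float(trait[key])
            extra[node] = 0.0
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise InvalidTreeError(
                f"node {_label(node)!r} has {len(children)} children; tree must be binary"
            )
        c1, c2 = children
        v1 = (c1.edge.length or 0.0) + extra[c1]
        v2 = (c2.edge.length or 0.0) + extra[c2]
        raw = est[c1] - est[c2]
        var = v1 + v2
        rows.append(
            {
                "node": _label(node),
                "contrast": raw / np.sqrt(var),
                "age": height - depths[node],
                "child1": _label(c1),
                "child2": _label(c2),
            }
        )
        terms.append((raw, var))
        est[node] = (est[c1] / v1 + est[c2] / v2) / (1.0 / v1 + 1.0 / v2)
        extra[node] = v1 * v2 / (v1 + v2)
    root = tree.seed_node
    return rows, est[root], extra[root], terms


def pic(tree: dendropy.Tree, trait: dict[str, float]) -> ContrastSet:
    """Standardized phylogenetic independent contrasts.

    Under constant-rate BM with rate sigma^2 the contrasts are iid
    N(0, sigma^2); node ages are in the tree's time units, tips at age 0.
    """
    rows, _, _, _ = _pic_recursion(tree, trait)
    return ContrastSet(table=pd.DataFrame(rows))


@dataclass
class NodeHeightResult:
    slope: float
    p_value: float
    contrasts: ContrastSet
    method: str


def _huber_fit(age: np.ndarray, abs_contrast: np.ndarray):
    X = sm.add_constant(age)
    rlm = sm.RLM(abs_contrast, X, M=sm.robust.norms.HuberT(t=1.345))
    res = rlm.fit(scale_est="mad")
    return float(res.params[1]), float(res.bse[1])


def node_height_test(
    tree: dendropy.Tree,
    trait: dict[str, float],
    method: str = "huber",
    n_perm: int = 999,
    seed: int = 0,
) -> NodeHeightResult:
    """Regress |standardized contrast| on node age to detect rate shifts.

    A negative slope means larger contrasts at younger nodes, i.e. the rate
    of trait evolution increases toward the present. The default p-value is
    a Wald test on the Huber M-estimate (tuning constant 1.345, MAD scale);
    ``method='permutation'`` instead permutes node ages across contrasts
    ``n_perm`` times and compares |slope|, which conditions on the observed
    contrast magnitudes and tests only their association with age.
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 4:
        raise InsufficientDataError("node-height test needs >= 4 tips")
    contrasts = pic(tree, trait)
    age = contrasts.table["age"].to_numpy()
    ac = np.abs(contrasts.table["contrast"].to_numpy())
    if np.ptp(ac) == 0 or np.ptp(age) == 0:
        return NodeHeightResult(0.0, 1.0, contrasts, method)
    slope, bse = _huber_fit(age, ac)
    if method == "huber":
        if bse == 0:
            p = 1.0 if slope == 0 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(slope) / bse))
        return NodeHeightResult(slope, p, contrasts, method)
    if method != "permutation":
        raise InvalidArgumentError("method must be 'huber' or 'permutation'")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        s_perm, _ = _huber_fit(rng.permutation(age), ac)
        if abs(s_perm) >= abs(slope):
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return NodeHeightResult(slope, p, contrasts, method)


def _shared_depth_to_tips(tree: dendropy.Tree, labels: list[str]):
    """For every node, the root-to-MRCA(node, tip) depth for each tip."""
    depths = _node_depths(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    below: dict[dendropy.Node, set[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {index[_label(node)]}
        else:
            below[node] = set().union(*(below[c] for c in node.child_nodes()))
    out: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        c = np.empty(n)
        anc = node
        remaining = set(range(n))
        while anc is not None:
            # tips first reached at this ancestor have it as their MRCA with
            # the node; tips below the node itself share the node's depth
            members = below[anc] & remaining
            if members:
                c[list(members)] = depths[anc]
            remaining -= below[anc]
            anc = anc.parent_node
        out[node] = c
    return out, depths


def ancestral_states(tree: dendropy.Tree, trait: dict[str, float]) -> dict[str, float]:
    """Maximum-likelihood BM ancestral values for every internal node.

    GLS closed form: the root value is the GLS mean
    ``(1' C^-1 y) / (1' C^-1 1)`` and each internal node's estimate is the
    conditional expectation given the tips under the BM covariance.
    """
    labels = sorted(_label(leaf) for leaf in tree.leaf_node_iter())
    missing = [s for s in labels if s not in trait]
    if missing:
        raise InvalidArgumentError(f"missing trait values for tips: {missing}")
    y = np.array([trait[s] for s in labels], float)
    cov = phylo_covariance(tree)
    shared, depths = _shared_depth_to_tips(tree, labels)
    C = cov.matrix * cov.height  # back to time units
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(labels))
    mu = float(ones @ Cinv @ y / (ones @ Cinv @ ones))
    resid = Cinv @ (y - mu)
    out: dict[str, float] = {}
    for i, node in enumerate(tree.preorder_internal_node_iter()):
        # unlabeled internal nodes get stable preorder keys; the root is node_0000
        key = _label(node) if _label(node) is not None else f"node_{i:04d}"
        out[key] = float(mu + shared[node] @ resid)
    return out


def bm_loglik_pruning(tree: dendropy.Tree, trait: dict[str, float], sigma2: float, root_value: float) -> float:
    """Exact BM log-likelihood via the contrasts (pruning) recursion.

    Factorizes the joint tip density into independent contrast terms plus a
    root term; agrees with the dense multivariate-normal likelihood.
    """
    if sigma2 <= 0:
        raise InvalidArgumentError("sigma2 must be > 0")
    _, root_est, root_var, terms = _pic_recursion(tree, trait)
    ll = 0.0
    for raw, var in terms:
        ll += stats.norm.logpdf(raw, 0.0, np.sqrt(sigma2 * var))
    ll += stats.norm.logpdf(root_est, root_value, np.sqrt(sigma2 * root_var))
    return float(ll)


def bm_loglik_dense(tree: dendropy.Tree, trait: dict[str, float], sigma2: float, root_value: float) -> float:
    """BM log-likelihood via the dense MVN over the tip covariance matrix."""
    cov = phylo_covariance(tree)
    y = np.array([trait[s] for s in cov.labels], float)
    C = cov.matrix * cov.height
    return float(
        stats.multivariate_normal.logpdf(y, mean=root_value * np.ones(len(y)), cov=sigma2 * C)
    )


def fit_map_length_model(
    taxa: pd.DataFrame,
    tree: dendropy.Tree,
    config: SamplerConfig | None = None,
    seed: int = 0,
) -> tuple[PhyloMMFit, dict]:
    """Lognormal phylogenetic mixed model of map length on census size.

    Fits ``log10 L = a_L + b_L log10 N_c + u + e`` on the non-social taxa
    with complete data present in the tree. Social taxa (which have
    adaptively longer maps) are excluded before fitting and listed in the
    returned metadata. Point predictions of L on the natural scale should
    use the half-variance lognormal correction, provided in the metadata as
    ``predict(log10_Nc)``.
    """
    required = {"species", "map_length_M", "N_c"}
    if required - set(taxa.columns):
        raise InvalidArgumentError(f"missing columns: {sorted(required - set(taxa.columns))}")
    social_col = taxa["social"] if "social" in taxa else pd.Series(False, index=taxa.index)
    social_excluded = sorted(taxa.loc[social_col.astype(bool), "species"])
    usable = taxa[~social_col.astype(bool)].dropna(subset=["map_length_M", "N_c"])
    if np.any(usable["map_length_M"] <= 0):
        raise InvalidArgumentError("map lengths must be > 0")
    tip_labels = {_label(leaf) for leaf in tree.leaf_node_iter()}
    dropped_from_tree = sorted(set(usable["species"]) - tip_labels)
    usable = usable[usable["species"].isin(tip_labels)]
    logger.info(
        "map-length model: %d taxa (%d social excluded, %d absent from tree)",
        len(usable), len(social_excluded), len(dropped_from_tree),
    )
    sub_tree = tree.extract_tree_with_taxa_labels(sorted(usable["species"]))
    cov = phylo_covariance(sub_tree)
    ordered = usable.set_index("species").loc[cov.labels]
    y = np.log10(ordered["map_length_M"].to_numpy(float))
    x = np.log10(ordered["N_c"].to_numpy(float))
    fit = fit_phylo_mm(y, x, cov, config=config, seed=seed)

    a = fit.summary.loc["alpha", "mean"]
    b = fit.summary.loc["beta", "mean"]
    total_var = fit.summary.loc["sigma_p2", "mean"] + fit.summary.loc["sigma_r2", "mean"]
    # variance components are on the standardized-y scale; rescale to log10 L
    total_var = total_var * np.var(y, ddof=1)

    def predict(log10_nc):
        """E[L] under the lognormal model, with half-variance correction."""
        mean_log10 = a + b * np.asarray(log10_nc, float)
        return 10.0**mean_log10 * np.exp(0.5 * total_var * np.log(10.0) ** 2)

    meta = {
        "social_excluded": social_excluded,
        "n_social_excluded": len(social_excluded),
        "dropped_from_tree": dropped_from_tree,
        "n_fit": len(usable),
        "predict": predict,
    }
    return fit, meta
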