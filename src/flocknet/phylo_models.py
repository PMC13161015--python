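"""Phylogenetic comparative models: Pagel's λ, PGLS, and a Bayesian
phylogenetic linear model pooled over a sample of trees.

Under Brownian motion on a rooted tree with branch lengths, a continuous
trait across species is multivariate normal with covariance proportional to
C, the matrix of shared root-to-tip path lengths.  Pagel's λ multiplies the
off-diagonal entries of C by a factor in [0, 1], interpolating between
phylogenetic independence (λ = 0) and the full Brownian expectation (λ = 1);
it is estimated here by profile maximum likelihood.  PGLS is generalized
least squares with error covariance σ²C(λ).  The Bayesian phylogenetic
linear model adds a phylogenetic random intercept,

    y = Xβ + u + ε,   u ~ N(0, σ²_phylo C),   ε ~ N(0, σ²_resid I),

sampled by a Gibbs/Metropolis-within-Gibbs scheme on the marginalized
likelihood (u integrated out via an eigendecomposition of C, which makes
every iteration O(n p²)).  Priors are weakly informative: N(0, 10²) on each
coefficient and half-Cauchy(0, 5) on both standard deviations.  Topological
uncertainty is handled by refitting on each tree of a sample and
concatenating the posterior draws into one pooled posterior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "read_newick",
    "read_newick_trees",
    "phylo_vcv",
    "lambda_transform",
    "LambdaResult",
    "pagel_lambda_ml",
    "PglsFit",
    "pgls_fit",
    "BayesFit",
    "bayes_phylo_lm",
    "fit_all_models",
]


class PhylogenyError(ValueError):
    """Invalid tree input."""


class Phylogeny:
    """A rooted tree with branch lengths whose tips are species ids.

    Thin wrapper around a :class:`dendropy.Tree` adding validation, a cached
    phylogenetic variance-covariance matrix, and Newick round-tripping.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise PhylogenyError("duplicate tip labels")
        if len(labels) < 2:
            raise PhylogenyError("tree must have at least 2 tips")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # the root edge may be absent
            if edge.length is None:
                raise PhylogenyError("missing branch lengths")
            if edge.length < 0:
                raise PhylogenyError("negative branch length")
        self.species: list[str] = labels
        self._vcv_cache: tuple[list[str], np.ndarray] | None = None

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.species)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        except Exception as exc:
            raise PhylogenyError(f"cannot parse Newick: {exc}") from exc
        return cls(t)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def vcv(self, species: list[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Phylogenetic VCV: C[i, j] = shared root-to-tip path length.

        Diagonal entries are root-to-tip distances.  Optionally restricted to
        (and ordered by) a subset of species; dropping tips does not change
        the remaining entries, so the cached full matrix is simply subset.
        """
        if self._vcv_cache is None:
            self._vcv_cache = _build_vcv(self._tree)
        labels, C = self._vcv_cache
        if species is None:
            return list(labels), C.copy()
        idx = {sp: k for k, sp in enumerate(labels)}
        missing = [sp for sp in species if sp not in idx]
        if missing:
            raise PhylogenyError(f"species not in tree: {missing[:5]}")
        sel = [idx[sp] for sp in species]
        return list(species), C[np.ix_(sel, sel)]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


def _build_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): k for k, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    depth: dict[int, float] = {id(tree.seed_node): float(tree.seed_node.edge.length or 0.0)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length)
    tips_below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[id(node)]
            tips_below[id(node)] = np.array([k])
            C[k, k] = depth[id(node)]
        else:
            groups = [tips_below.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    C[np.ix_(groups[a], groups[b])] = d
                    C[np.ix_(groups[b], groups[a])] = d
            tips_below[id(node)] = np.concatenate(groups)
    return labels, C


def read_newick_trees(path: str | Path) -> list[Phylogeny]:
    """Read every tree in a Newick file (one per line or ;-separated)."""
    try:
        tl = dendropy.TreeList.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise PhylogenyError(f"{path}: cannot parse Newick: {exc}") from exc
    if len(tl) == 0:
        raise PhylogenyError(f"{path}: no trees found")
    return [Phylogeny(t) for t in tl]


def read_newick(path: str | Path):
    """Read a Newick file; returns one Phylogeny, or a list if it holds several."""
    trees = read_newick_trees(path)
    return trees[0] if len(trees) == 1 else trees


def phylo_vcv(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Convenience alias for ``tree.vcv()``."""
    return tree.vcv()


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel λ transform: off-diagonals scaled by λ, diagonal unchanged."""
    out = lam * C
    np.fill_diagonal(out, np.diagonal(C))
    return out


# ---------------------------------------------------------------------------
# GLS core
# ---------------------------------------------------------------------------


class _ProfileGLS:
    """Profile log-likelihood over Pagel's λ for y = Xβ + e, e ~ N(0, σ²C(λ)).

    For ultrametric trees (constant diagonal h), C(λ) = λC + (1−λ)hI shares
    C's eigenvectors, so one eigendecomposition serves every λ; otherwise a
    Cholesky factorization is done per λ evaluation.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, C: np.ndarray):
        self.y = y
        self.X = X
        self.C = C
        self.n, self.p = X.shape
        d = np.diagonal(C)
        self.h = float(d[0])
        self._ultrametric = self.h > 0 and np.allclose(d, self.h, rtol=1e-8)
        if self._ultrametric:
            w, U = np.linalg.eigh(C)
            self._w = w
            self._yt = U.T @ y
            self._Xt = U.T @ X

    def fit(self, lam: float) -> dict:
        if self._ultrametric:
            v = lam * self._w + (1.0 - lam) * self.h
            v = np.maximum(v, 1e-12)
            yt, Xt = self._yt, self._Xt
            logdet = float(np.log(v).sum())
        else:
            Cl = lambda_transform(self.C, lam)
            L = np.linalg.cholesky(Cl)
            yt = linalg.solve_triangular(L, self.y, lower=True)
            Xt = linalg.solve_triangular(L, self.X, lower=True)
            v = np.ones(self.n)
            logdet = 2.0 * float(np.log(np.diagonal(L)).sum())
        Wi = 1.0 / v
        XtWX = Xt.T @ (Xt * Wi[:, None])
        XtWy = Xt.T @ (yt * Wi)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        rss = float((r * r * Wi).sum())
        sigma2_ml = max(rss / self.n, 1e-300)  # guard exact fits
        ll = -0.5 * (
            self.n * np.log(2 * np.pi * sigma2_ml) + logdet + self.n
        )
        return {
            "lambda": lam,
            "beta": beta,
            "sigma2_ml": sigma2_ml,
            "rss_gls": rss,
            "loglik": ll,
            "XtWX": XtWX,
        }

    def loglik(self, lam: float) -> float:
        return self.fit(lam)["loglik"]

    def maximize(self, xatol: float = 1e-6) -> dict:
        res = optimize.minimize_scalar(
            lambda l: -self.loglik(l), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": xatol},
        )
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"lambda optimization failed: {res.message}")
        cands = [0.0, float(res.x), 1.0]
        fits = [self.fit(l) for l in cands]
        best = max(fits, key=lambda f: f["loglik"])
        return best


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diagonal(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[k] for k in piv[rank:]]
        raise ValueError(f"design matrix is rank-deficient; aliased columns: {aliased}")


@dataclass
class LambdaResult:
    """Pagel's λ profile-ML estimate for one trait."""

    lam: float
    loglik: float
    loglik_lambda0: float
    p_value: float  # LRT vs λ=0, boundary-aware (halved χ²₁ tail)
    sigma2: float
    mean: float
    n: int


def pagel_lambda_ml(y: pd.Series | np.ndarray, tree: Phylogeny) -> LambdaResult:
    """Maximum-likelihood Pagel's λ for a continuous trait.

    ``y`` may be a Series indexed by species id (aligned to the tree) or an
    array ordered like ``tree.species``.  The likelihood-ratio test against
    λ = 0 accounts for the boundary by halving the χ²₁ tail probability.
    """
    yv, _, C, _ = _align(y, None, tree)
    if len(yv) < 4:
        raise ValueError("Pagel's lambda requires at least 4 species")
    prof = _ProfileGLS(yv, np.ones((len(yv), 1)), C)
    best = prof.maximize()
    ll0 = prof.loglik(0.0)
    lr = max(0.0, 2.0 * (best["loglik"] - ll0))
    p = 1.0 if lr == 0 else 0.5 * float(stats.chi2.sf(lr, df=1))
    return LambdaResult(
        lam=float(best["lambda"]),
        loglik=float(best["loglik"]),
        loglik_lambda0=float(ll0),
        p_value=p,
        sigma2=float(best["sigma2_ml"]),
        mean=float(best["beta"][0]),
        n=len(yv),
    )


@dataclass
class PglsFit:
    """PGLS estimates: β with t-based uncertainty, λ̂, and residuals."""

    params: pd.DataFrame = field(repr=False)  # estimate, se, t, p, lower95, upper95
    lam: float = 0.0
    sigma2: float = 0.0
    loglik: float = 0.0
    n: int = 0
    residuals: pd.Series | None = field(default=None, repr=False)

    @property
    def coef(self) -> pd.Series:
        return self.params["estimate"]


def _align(y, X, tree: Phylogeny, extra_index=None):
    """Align response, design and VCV on the common complete-case species set.

    Returns (y array, X DataFrame or None, C, species list) ordered by the
    tree's tip order.
    """
    tree_sp = tree.species
    if isinstance(y, pd.Series):
        ok = y.index[np.isfinite(y.to_numpy(dtype=float))]
        common = [sp for sp in tree_sp if sp in set(ok)]
        if X is not None:
            Xdf = pd.DataFrame(X)
            xin = Xdf.dropna().index
            common = [sp for sp in common if sp in set(xin)]
            Xa = Xdf.loc[common]
        else:
            Xa = None
        ya = y.loc[common].to_numpy(dtype=float)
        _, C = tree.vcv(common)
        return ya, Xa, C, common
    ya = np.asarray(y, dtype=float)
    if len(ya) != tree.n_tips:
        raise ValueError("array response must match the tree's tip count/order")
    Xa = pd.DataFrame(X, index=tree_sp) if X is not None else None
    _, C = tree.vcv(tree_sp)
    return ya, Xa, C, list(tree_sp)


def pgls_fit(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame | np.ndarray | None,
    tree: Phylogeny,
    lambda_mode: str = "ML",
    lam: float | None = None,
    add_intercept: bool = True,
) -> PglsFit:
    """Phylogenetic generalized least squares with λ-transformed covariance.

    β̂ = (XᵀC(λ)⁻¹X)⁻¹ XᵀC(λ)⁻¹ y with λ estimated by profile ML (default)
    or fixed.  Standard errors use σ̂² = RSS_GLS/(n−p); t statistics and
    two-sided p-values follow, with 95% confidence limits from the t
    distribution.
    """
    yv, Xa, C, species = _align(y, X, tree)
    if Xa is None:
        Xm = np.empty((len(yv), 0))
        names: list[str] = []
    else:
        Xm = Xa.to_numpy(dtype=float)
        names = [str(c) for c in Xa.columns]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(yv)), Xm])
        names = ["Intercept"] + names
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"too few species (n={n}) for {p} coefficients")
    _check_full_rank(Xm, names)
    prof = _ProfileGLS(yv, Xm, C)
    if lambda_mode == "ML":
        best = prof.maximize()
    elif lambda_mode == "fixed":
        if lam is None:
            raise ValueError("lambda_mode='fixed' requires lam")
        best = prof.fit(float(lam))
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")
    sigma2 = best["rss_gls"] / (n - p)
    cov = sigma2 * np.linalg.inv(best["XtWX"])
    se = np.sqrt(np.diagonal(cov))
    beta = best["beta"]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)
    tcrit = stats.t.ppf(0.975, df=n - p)
    params = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "t": tstat,
            "p": pval,
            "lower95": beta - tcrit * se,
            "upper95": beta + tcrit * se,
        },
        index=names,
    )
    resid = pd.Series(yv - Xm @ beta, index=species, name="residual")
    return PglsFit(
        params=params,
        lam=float(best["lambda"]),
        sigma2=float(sigma2),
        loglik=float(best["loglik"]),
        n=n,
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# Bayesian phylogenetic linear model
# ---------------------------------------------------------------------------


def _half_cauchy_logpdf_logscale(log_s: float, scale: float) -> float:
    # density of s ~ half-Cauchy(scale) expressed in log s (Jacobian included)
    s = np.exp(log_s)
    return float(np.log(2.0 / (np.pi * scale * (1.0 + (s / scale) ** 2))) + log_s)


def _run_chain(
    yt: np.ndarray,
    Xt: np.ndarray,
    w: np.ndarray,
    n_iter: int,
    burn: int,
    thin: int,
    rng: np.random.Generator,
    beta_prior_sd: float,
    hc_scale: float,
) -> dict[str, np.ndarray]:
    """One collapsed MCMC chain on the eigenbasis-transformed model.

    yt = Xt β + e with independent errors of variance σ²_p w_i + σ²_e.
    The variance components move by two 1-D Metropolis steps in rotated
    coordinates — the overall scale on the log scale, and the phylogenetic
    share ρ = σ²_p/(σ²_p+σ²_e) by a reflected random walk on [0, 1] (with
    the Jacobian of the reparametrization in the acceptance ratio, so the
    half-Cauchy priors on the SDs are respected) — each with its own
    proposal SD adapted during burn-in only.  Their target is the
    β-*marginalized* posterior (β integrated out analytically under its
    Gaussian prior), which decouples the walk from β and keeps the
    autocorrelation low; β is then drawn exactly from its Gaussian
    conditional.  The bounded ρ walk is what prevents the sampler from
    taking long excursions into the flat log-variance tail when one
    component is near zero.
    """
    n, p = Xt.shape
    var_y = float(np.var(yt)) or 1.0
    log_sp = np.log(np.sqrt(var_y / 2))
    log_se = np.log(np.sqrt(var_y / 2))
    prop_sds = np.array([0.4, 0.25])  # log-scale move, rho-share move
    accepted = np.zeros(2)
    window = 0
    prior_prec = 1.0 / beta_prior_sd**2
    keep = max(0, (n_iter - burn) // thin)
    out_beta = np.empty((keep, p))
    out_sp2 = np.empty(keep)
    out_se2 = np.empty(keep)
    kidx = 0
    eye_p = np.eye(p)

    def marginal(lsp: float, lse: float):
        """Log posterior of the variances with β integrated out, plus the
        factor (A, b) needed to draw β conditionally."""
        v = np.exp(2 * lsp) * w + np.exp(2 * lse)
        Wi = 1.0 / v
        A = Xt.T @ (Xt * Wi[:, None]) + prior_prec * eye_p
        b = Xt.T @ (yt * Wi)
        L = np.linalg.cholesky(A)
        half = linalg.solve_triangular(L, b, lower=True)
        quad = float((yt * yt * Wi).sum()) - float(half @ half)
        logdet_A = 2.0 * float(np.log(np.diagonal(L)).sum())
        lp = -0.5 * (float(np.log(v).sum()) + logdet_A + quad)
        lp += _half_cauchy_logpdf_logscale(lsp, hc_scale)
        lp += _half_cauchy_logpdf_logscale(lse, hc_scale)
        return lp, L, b

    def reflect01(x: float) -> float:
        # reflect into (0, 1); symmetric proposal
        x = x % 2.0
        return 2.0 - x if x > 1.0 else x

    cur, L, b = marginal(log_sp, log_se)
    for it in range(n_iter):
        # scale move: both log-SDs shifted together
        d = prop_sds[0] * rng.standard_normal()
        prop, Lp, bp = marginal(log_sp + d, log_se + d)
        if np.log(rng.uniform()) < prop - cur:
            log_sp += d
            log_se += d
            cur, L, b = prop, Lp, bp
            accepted[0] += 1
        # share move: reflected walk on rho = sigma2_p / (sigma2_p + sigma2_e);
        # target includes the |d(log sd_p, log sd_e)/d(log tot, rho)| Jacobian
        sp2 = np.exp(2 * log_sp)
        se2 = np.exp(2 * log_se)
        tot = sp2 + se2
        rho = sp2 / tot
        rho_p = reflect01(rho + prop_sds[1] * rng.standard_normal())
        rho_p = min(max(rho_p, 1e-12), 1.0 - 1e-12)
        lsp_p = 0.5 * np.log(rho_p * tot)
        lse_p = 0.5 * np.log((1.0 - rho_p) * tot)
        prop, Lp, bp = marginal(lsp_p, lse_p)
        log_jac_cur = -np.log(rho * (1.0 - rho))
        log_jac_prop = -np.log(rho_p * (1.0 - rho_p))
        if np.log(rng.uniform()) < (prop + log_jac_prop) - (cur + log_jac_cur):
            log_sp, log_se = lsp_p, lse_p
            cur, L, b = prop, Lp, bp
            accepted[1] += 1
        mean = linalg.cho_solve((L, True), b)
        beta = mean + linalg.solve_triangular(L.T, rng.standard_normal(p), lower=False)
        window += 1
        if it < burn and window == 50:  # adapt toward ~40% acceptance
            rates = accepted / window
            prop_sds = np.clip(prop_sds * np.exp(rates - 0.4), 0.02, 2.5)
            accepted[:] = 0
            window = 0
        if it >= burn and (it - burn) % thin == 0:
            out_beta[kidx] = beta
            out_sp2[kidx] = np.exp(2 * log_sp)
            out_se2[kidx] = np.exp(2 * log_se)
            kidx += 1
    return {"beta": out_beta[:kidx], "sigma2_phylo": out_sp2[:kidx], "sigma2_resid": out_se2[:kidx]}


@dataclass
class BayesFit:
    """Pooled posterior over trees for the phylogenetic mixed model."""

    summary: pd.DataFrame = field(repr=False)  # mean, lower95, upper95, rhat, n_eff
    draws: dict[str, np.ndarray] = field(repr=False)
    n_trees: int = 0
    n: int = 0
    max_rhat: float = np.nan
    flagged: bool = False


def _rhat_ess(chains: np.ndarray) -> tuple[float, float]:
    """Split-Rhat and bulk ESS for an array of shape (n_chains, n_draws)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(az.rhat(chains))
        e = float(az.ess(chains))
    return r, e


def bayes_phylo_lm(
    y: pd.Series,
    X: pd.DataFrame,
    trees: list[Phylogeny] | Phylogeny,
    n_chains: int = 2,
    n_iter: int = 4000,
    burn: int = 2000,
    thin: int = 1,
    seed: int = 0,
    beta_prior_sd: float = 10.0,
    hc_scale: float = 5.0,
    add_intercept: bool = True,
) -> BayesFit:
    """Bayesian phylogenetic linear model, posteriors pooled over a tree sample.

    Fits y = Xβ + u + ε with u ~ N(0, σ²_phylo C) per tree and concatenates
    post-burn-in draws across trees into a single pooled posterior.  Reports
    posterior means, central 95% credible intervals, the maximum split-Rhat
    over trees (computed per tree across chains) and total effective sample
    size.  Rhat above 1.1 flags the fit with a warning but does not raise.
    """
    if isinstance(trees, Phylogeny):
        trees = [trees]
    if n_iter <= burn:
        raise ValueError("n_iter must exceed burn")
    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.spawn(len(trees))
    names: list[str] | None = None
    all_draws: dict[str, list[np.ndarray]] = {}
    rhats: list[float] = []
    esss: dict[str, float] = {}
    n_used = 0
    n_dropped_total = 0
    for tree, tseed in zip(trees, tree_seeds):
        in_tree = y.index.intersection(tree.species)
        n_dropped_total += len(y.index) - len(in_tree)
        yv, Xa, C, species = _align(y.loc[in_tree], X.loc[X.index.intersection(in_tree)], tree)
        Xm = Xa.to_numpy(dtype=float)
        cnames = [str(c) for c in Xa.columns]
        if add_intercept:
            Xm = np.column_stack([np.ones(len(yv)), Xm])
            cnames = ["Intercept"] + cnames
        _check_full_rank(Xm, cnames)
        if names is None:
            names = cnames
        n_used = len(yv)
        w, U = np.linalg.eigh(C)
        w = np.maximum(w, 0.0)
        yt = U.T @ yv
        Xt = U.T @ Xm
        chain_seeds = tseed.spawn(n_chains)
        chains = [
            _run_chain(
                yt, Xt, w, n_iter, burn, thin,
                np.random.Generator(np.random.PCG64(cs)),
                beta_prior_sd, hc_scale,
            )
            for cs in chain_seeds
        ]
        params: dict[str, np.ndarray] = {}
        for k, nm in enumerate(cnames):
            params[nm] = np.stack([c["beta"][:, k] for c in chains])
        params["sigma2_phylo"] = np.stack([c["sigma2_phylo"] for c in chains])
        params["sigma2_resid"] = np.stack([c["sigma2_resid"] for c in chains])
        for nm, arr in params.items():
            r, e = _rhat_ess(arr)
            rhats.append(r)
            esss[nm] = esss.get(nm, 0.0) + e
            all_draws.setdefault(nm, []).append(arr.reshape(-1))
    if n_dropped_total:
        logger.info("bayes_phylo_lm: %d species-tree pairs dropped (absent from tree)", n_dropped_total)
    draws = {nm: np.concatenate(v) for nm, v in all_draws.items()}
    rows = []
    for nm in list(names) + ["sigma2_phylo", "sigma2_resid"]:
        d = draws[nm]
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append(
            {
                "parameter": nm,
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "lower95": float(lo),
                "upper95": float(hi),
                "n_eff": esss[nm],
            }
        )
    summary = pd.DataFrame(rows).set_index("parameter")
    max_rhat = float(np.nanmax(rhats)) if rhats else np.nan
    summary["rhat_max"] = max_rhat
    flagged = bool(max_rhat > 1.1)
    if flagged:
        warnings.warn(f"MCMC convergence suspect: max Rhat = {max_rhat:.3f}")
    return BayesFit(
        summary=summary,
        draws=draws,
        n_trees=len(trees),
        n=n_used,
        max_rhat=max_rhat,
        flagged=flagged,
    )


def fit_all_models(
    responses: dict[str, pd.Series],
    predictors: pd.DataFrame,
    trees: list[Phylogeny] | Phylogeny,
    method: str = "bayes",
    seed: int = 0,
    standardize_predictors: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit one phylogenetic model per response variable.

    ``responses`` maps response names (e.g. ``log_propensity``,
    ``connectivity``, ``z_strength``) to species-indexed Series; the same
    predictor table is used for every model, standardized to mean 0 / SD 1
    over each model's complete cases (so effect sizes are comparable).
    Returns a long table shaped like a coefficients table: one row per
    (response, parameter) with mean, 95% interval bounds and diagnostics.
    """
    if isinstance(trees, Phylogeny):
        trees = [trees]
    ss = np.random.SeedSequence(seed)
    out = []
    for (name, y), rs in zip(responses.items(), ss.spawn(len(responses))):
        common = y.dropna().index.intersection(predictors.dropna().index)
        ya = y.loc[common]
        Xa = predictors.loc[common].astype(float)
        if standardize_predictors:
            Xa = (Xa - Xa.mean()) / Xa.std(ddof=1)
        if method == "bayes":
            fit = bayes_phylo_lm(ya, Xa, trees, seed=int(rs.generate_state(1)[0]), **fit_kwargs)
            tab = fit.summary.reset_index().rename(columns={"rhat_max": "rhat"})
        elif method == "pgls":
            fit = pgls_fit(ya, Xa, trees[0], **fit_kwargs)
            tab = fit.params.reset_index().rename(
                columns={"index": "parameter", "estimate": "mean"}
            )
            tab["rhat"] = np.nan
            tab["n_eff"] = np.nan
        else:
            raise ValueError(f"unknown method {method!r}")
        tab.insert(0, "response", name)
        tab["n_species"] = len(common)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
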