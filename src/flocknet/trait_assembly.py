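"""Predictor construction: size correction, beak PCA, plumage color classes,
standardization and collinearity diagnostics.

Continuous traits that scale with body size (beak dimensions, eye axial
diameter, maximum song frequency) are size-corrected by phylogenetic
regression on body mass — the residuals of a PGLS fit with λ estimated
jointly by maximum likelihood — on the log scale (log10 by default, the
standard treatment in acoustic and morphometric allometry).  The four
size-corrected beak measurements are summarized by a PCA on their
correlation matrix; the sign of PC1 is fixed so that large, thick beaks
score negative.

Plumage is described by the proportion of the body covered by 12
human-visible color categories, grouped into five classes by pigmentary or
structural origin: structural (blue + purple), carotenoid-based (yellow +
orange + red), melanin-based (black + grey + brown + rufous), green
(green + olive) and white.  Because structural and melanin-based coloration
are typically negatively correlated, the default predictor set excludes
structural coloration (configurable).

Collinearity among the final predictors is assessed with pairwise Pearson
and Spearman correlations and generalized variance inflation factors,
reported on the Df-adjusted scale GVIF^(1/(2·Df)); values below 2 indicate
low collinearity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .phylo_models import Phylogeny, pgls_fit

logger = logging.getLogger(__name__)

__all__ = [
    "COLOR_CATEGORIES",
    "COLOR_CLASS_MAP",
    "group_colors",
    "phylo_residuals",
    "beak_pca",
    "residual_song_frequency",
    "collinearity_check",
    "standardize",
    "destandardize",
    "build_predictor_table",
]

#: The 12 plumage color categories (proportion of body covered by each).
COLOR_CATEGORIES = (
    "blue", "purple",
    "yellow", "orange", "red",
    "black", "grey", "brown", "rufous",
    "green", "olive",
    "white",
)

#: Grouping of the 12 categories into five classes by color origin.
COLOR_CLASS_MAP = {
    "structural": ("blue", "purple"),
    "carotenoid": ("yellow", "orange", "red"),
    "melanin": ("black", "grey", "brown", "rufous"),
    "green": ("green", "olive"),
    "white": ("white",),
}

BEAK_COLUMNS = ("beak_depth", "beak_width", "beak_nares", "beak_culmen")


def group_colors(traits: pd.DataFrame) -> pd.DataFrame:
    """Sum the 12 color-category proportions into the five color classes.

    The classes conserve mass: their sum equals the sum of the 12 inputs.
    """
    missing = [c for c in COLOR_CATEGORIES if c not in traits.columns]
    if missing:
        raise ValueError(f"missing color category column(s): {missing}")
    out = pd.DataFrame(index=traits.index)
    for cls, cats in COLOR_CLASS_MAP.items():
        out[cls] = traits[list(cats)].sum(axis=1)
    return out


def phylo_residuals(
    y: pd.Series,
    x: pd.Series,
    tree: Phylogeny,
) -> pd.Series:
    """Residuals of the phylogenetic GLS regression of y on x.

    λ is estimated jointly by maximum likelihood.  The residuals satisfy the
    GLS orthogonality condition Xᵀ C(λ̂)⁻¹ r = 0; on a star tree they reduce
    to ordinary least-squares residuals.  Complete cases only; requires at
    least 3 species.
    """
    common = y.dropna().index.intersection(x.dropna().index)
    if len(common) < 3:
        raise ValueError("phylogenetic residuals require at least 3 species")
    if x.loc[common].std(ddof=1) < 1e-12:
        # degenerate regressor: residuals are deviations from the GLS mean
        fit = pgls_fit(y.loc[common], None, tree, lambda_mode="ML")
    else:
        fit = pgls_fit(y.loc[common], x.loc[common].to_frame(name="x"), tree, lambda_mode="ML")
    return fit.residuals.rename(y.name)


@dataclass
class BeakPCA:
    """Beak-shape PCA results (correlation-matrix PCA of residual traits)."""

    scores: pd.DataFrame = field(repr=False)  # PC1..PC4 per species
    loadings: pd.DataFrame = field(repr=False)  # variables × components
    variance_proportions: np.ndarray = field(repr=False)


def beak_pca(residuals: pd.DataFrame) -> BeakPCA:
    """PCA summarizing beak shape from the four size-corrected beak traits.

    Performed on the correlation matrix (columns standardized), since the
    residual traits are on different scales.  The sign of PC1 is fixed so
    that larger/thicker beaks (positive depth/width residuals) score
    negative: if the mean PC1 loading of beak depth and width is positive,
    PC1 is flipped.
    """
    cols = [c for c in BEAK_COLUMNS if c in residuals.columns]
    if len(cols) != 4:
        raise ValueError(f"expected the 4 beak columns {BEAK_COLUMNS}, got {list(residuals.columns)}")
    X = residuals[list(cols)].dropna()
    sd = X.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant beak column(s): {list(sd.index[sd == 0])}")
    Z = (X - X.mean()) / sd
    pca = PCA(n_components=4)
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T  # variables × components
    if loadings[[0, 1], 0].mean() > 0:  # depth, width
        loadings[:, 0] *= -1
        scores[:, 0] *= -1
    comp_names = [f"PC{k + 1}" for k in range(4)]
    return BeakPCA(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=cols, columns=comp_names),
        variance_proportions=pca.explained_variance_ratio_,
    )


def residual_song_frequency(
    freq: pd.Series,
    body_mass: pd.Series,
    tree: Phylogeny,
    log: bool = True,
) -> pd.Series:
    """Size-corrected maximum song frequency.

    Residuals of the phylogenetic regression of log10 frequency on log10
    body mass (song frequency scales negatively with mass); set
    ``log=False`` for the linear-scale variant.
    """
    if log:
        freq = np.log10(freq).rename(freq.name)
        body_mass = np.log10(body_mass)
    return phylo_residuals(freq, body_mass, tree)


def _gvif_from_corr(R: np.ndarray, groups: list[list[int]]) -> list[float]:
    """GVIF per predictor group from the determinant ratio of correlation
    submatrices: GVIF_g = det(R_g) det(R_-g) / det(R)."""
    detR = np.linalg.det(R)
    out = []
    all_idx = np.arange(R.shape[0])
    for g in groups:
        rest = np.setdiff1d(all_idx, g)
        det_g = np.linalg.det(R[np.ix_(g, g)])
        det_rest = np.linalg.det(R[np.ix_(rest, rest)]) if rest.size else 1.0
        if detR <= np.finfo(float).eps * 100:
            out.append(np.inf)
        else:
            out.append(float(det_g * det_rest / detR))
    return out


def collinearity_check(P: pd.DataFrame, flag_threshold: float = 2.0) -> dict:
    """Pairwise correlations and generalized VIFs for a predictor table.

    Returns a dict with ``pearson`` and ``spearman`` correlation matrices
    and a ``gvif`` table (GVIF, Df, GVIF^(1/(2Df)), flag).  Perfectly
    collinear predictors get infinite GVIF and are flagged, not fatal.
    Complete cases only; each column is one predictor (Df = 1).
    """
    X = P.dropna()
    if X.shape[1] < 2:
        raise ValueError("collinearity check needs at least 2 predictors")
    pearson = X.corr(method="pearson")
    spearman = X.corr(method="spearman")
    R = pearson.to_numpy()
    gvifs = _gvif_from_corr(R, [[k] for k in range(X.shape[1])])
    adj = [g ** 0.5 if np.isfinite(g) else np.inf for g in gvifs]  # Df = 1
    tab = pd.DataFrame(
        {
            "gvif": gvifs,
            "df": 1,
            "gvif_adj": adj,
            "flag": [a >= flag_threshold for a in adj],
        },
        index=X.columns,
    )
    if tab["flag"].any():
        logger.warning("collinearity flagged for: %s", list(tab.index[tab["flag"]]))
    return {"pearson": pearson, "spearman": spearman, "gvif": tab, "n": len(X)}


def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise (x − mean)/SD over complete cases; returns (z, params).

    ``params`` stores the means and SDs, so the transform is invertible via
    :func:`destandardize`; applying it to already-standardized columns is
    idempotent up to floating point.
    """
    mean = df.mean()
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant column(s): {list(sd.index[sd == 0])}")
    z = (df - mean) / sd
    return z, pd.DataFrame({"mean": mean, "sd": sd})


def destandardize(z: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    return z * params["sd"] + params["mean"]


def build_predictor_table(
    traits: pd.DataFrame,
    tree: Phylogeny,
    exclude: tuple[str, ...] = ("structural",),
    log_allometry: bool = True,
) -> pd.DataFrame:
    """Assemble the model predictor table from raw traits.

    Expects columns ``body_mass``, the four beak measurements, optionally
    ``eye_ad`` (NaN where unmeasured), ``max_song_freq`` and the 12 color
    categories.  Produces the five color-class proportions, ``beak_pc1``
    (shape axis, thick beaks negative), ``res_eye_size`` and
    ``res_max_freq`` (phylogenetic size-corrected residuals), minus any
    classes named in ``exclude``.  Standardized variants (``z_`` prefix,
    mean 0 / SD 1 over each column's complete cases) are appended.
    """
    tf = lambda s: np.log10(s) if log_allometry else s  # noqa: E731
    colors = group_colors(traits)
    mass = traits["body_mass"]
    beak_resid = pd.DataFrame(
        {
            c: phylo_residuals(tf(traits[c]).rename(c), tf(mass), tree)
            for c in BEAK_COLUMNS
        }
    )
    pca = beak_pca(beak_resid)
    out = colors.copy()
    out["beak_pc1"] = pca.scores["PC1"]
    if "eye_ad" in traits.columns and traits["eye_ad"].notna().sum() >= 3:
        out["res_eye_size"] = phylo_residuals(
            tf(traits["eye_ad"]).rename("eye_ad"), tf(mass), tree
        )
        n_sub = int(traits["eye_ad"].notna().sum())
        logger.info("residual eye size available for %d of %d species", n_sub, len(traits))
    out["res_max_freq"] = residual_song_frequency(
        traits["max_song_freq"], mass, tree, log=log_allometry
    )
    out = out.drop(columns=[c for c in exclude if c in out.columns])
    for c in list(out.columns):
        col = out[c]
        sd = col.std(ddof=1)
        out[f"z_{c}"] = (col - col.mean()) / sd if sd > 0 else np.nan
    return out
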