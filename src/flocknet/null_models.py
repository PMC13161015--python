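"""Fixed-fixed null models for flock matrices and standardized effect sizes.

The null hypothesis of random flock assembly is represented by the uniform
distribution over binary matrices sharing the observed matrix's row sums
(flock sizes) and column sums (species occurrence frequencies).  Samples are
drawn with the curveball trade algorithm: repeatedly pick two flocks and
randomly re-deal the species that occur in exactly one of them, which
preserves both margins at every step and has the uniform distribution as its
stationary law.  Each replicate runs an independent chain of
``trades_factor × fill`` trades from the observed matrix (fill = number of
ones), after which one sample is taken.

Observed metrics are standardized against the null ensemble as

    z = (observed − mean of null values) / SD of null values,

computed per species, per metric, per locality; a zero null SD yields a
missing z (a zero-variance null carries no standardization information) and
such cases are tallied.  z-scores are averaged across localities per species
afterwards, mirroring the averaging of the observed metrics.

Seeds: one master seed per ensemble; per-replicate seeds are derived with
``numpy.random.SeedSequence(master).spawn`` so any single replicate is
reproducible in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cooccurrence_networks import METRICS, metrics_from_weights
from .flock_data import FlockMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullEnsemble",
    "randomize_fixed_fixed",
    "null_distribution",
    "z_scores",
    "average_z_scores",
    "is_margin_unique",
]

try:  # jitted trade kernel; the numpy fallback is stream-incompatible but equivalent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _curveball_trades_py(occ: np.ndarray, n_trades: int, seed: int) -> np.ndarray:
    """Pure-numpy curveball chain; modifies and returns ``occ`` (int8)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    n_rows = occ.shape[0]
    for _ in range(n_trades):
        i, j = rng.integers(0, n_rows, size=2)
        if i == j:
            continue
        ri, rj = occ[i], occ[j]
        excl = np.flatnonzero(ri != rj)
        k = excl.size
        if k == 0:
            continue
        ci = int(ri[excl].sum())
        if ci == 0 or ci == k:
            continue
        rng.shuffle(excl)
        take = excl[:ci]
        rest = excl[ci:]
        ri[take] = 1
        rj[take] = 0
        ri[rest] = 0
        rj[rest] = 1
    return occ


if _HAVE_NUMBA:

    @njit(cache=False)
    def _curveball_trades_nb(occ, n_trades, seed):  # pragma: no cover - jitted
        np.random.seed(seed)
        n_rows, n_cols = occ.shape
        excl = np.empty(n_cols, np.int64)
        for _ in range(n_trades):
            i = np.random.randint(n_rows)
            j = np.random.randint(n_rows)
            if i == j:
                continue
            k = 0
            ci = 0
            for c in range(n_cols):
                a = occ[i, c]
                b = occ[j, c]
                if a != b:
                    excl[k] = c
                    k += 1
                    if a == 1:
                        ci += 1
            if k == 0 or ci == 0 or ci == k:
                continue
            # partial Fisher-Yates: the first ci entries go to row i
            for s in range(ci):
                r = s + np.random.randint(k - s)
                tmp = excl[s]
                excl[s] = excl[r]
                excl[r] = tmp
            for s in range(k):
                c = excl[s]
                if s < ci:
                    occ[i, c] = 1
                    occ[j, c] = 0
                else:
                    occ[i, c] = 0
                    occ[j, c] = 1
        return occ


def _curveball(occ: np.ndarray, n_trades: int, seed: int) -> np.ndarray:
    if _HAVE_NUMBA:
        return _curveball_trades_nb(occ, n_trades, np.uint32(seed))
    return _curveball_trades_py(occ, n_trades, seed)


def _swap_randomize(occ: np.ndarray, n_attempts: int, seed: int) -> np.ndarray:
    """Classic checkerboard-swap chain (alternative sampler, slower mixing)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    n_rows, n_cols = occ.shape
    for _ in range(n_attempts):
        r = rng.integers(0, n_rows, size=2)
        c = rng.integers(0, n_cols, size=2)
        if r[0] == r[1] or c[0] == c[1]:
            continue
        a, b = occ[r[0], c[0]], occ[r[0], c[1]]
        c_, d = occ[r[1], c[0]], occ[r[1], c[1]]
        if a == d and b == c_ and a != b:
            occ[r[0], c[0]], occ[r[0], c[1]] = b, a
            occ[r[1], c[0]], occ[r[1], c[1]] = d, c_
    return occ


def is_margin_unique(occ: np.ndarray) -> bool:
    """True iff ``occ`` is the only binary matrix with its row/column sums.

    A binary matrix admits an alternative with the same margins iff it
    contains a 2×2 checkerboard submatrix, i.e. two rows i, j such that i has
    a 1 where j has a 0 in some column and vice versa in another.
    """
    A = occ.astype(np.int64)
    B = A @ (1 - A).T  # B[i, j] = #cols where row i has 1 and row j has 0
    swappable = (B > 0) & (B.T > 0)
    np.fill_diagonal(swappable, False)
    return not swappable.any()


def randomize_fixed_fixed(
    m: FlockMatrix,
    seed: int,
    trades_factor: int = 5,
    method: str = "curveball",
) -> FlockMatrix:
    """Draw one margin-preserving randomization of a flock matrix.

    Row sums (flock sizes) and column sums (species occurrence counts) of
    the result equal those of ``m`` exactly.  If the margins determine the
    matrix uniquely, the input is returned unchanged with a warning.
    """
    occ = m.occ.copy()
    if is_margin_unique(occ):
        warnings.warn(
            f"locality {m.locality_id!r}: margins determine the matrix uniquely; "
            "returning the observed matrix"
        )
        return FlockMatrix(m.locality_id, list(m.flock_ids), list(m.species_ids), occ)
    fill = int(occ.sum())
    n_steps = trades_factor * fill
    if method == "curveball":
        occ = _curveball(occ, n_steps, seed)
    elif method == "swap":
        occ = _swap_randomize(occ, n_steps, seed)
    else:
        raise ValueError(f"unknown randomization method {method!r}")
    return FlockMatrix(m.locality_id, list(m.flock_ids), list(m.species_ids), occ)


@dataclass
class NullEnsemble:
    """Per-species null means and SDs of the network metrics for one locality."""

    locality_id: str
    n_reps: int
    seed: int
    species_ids: list[str] = field(repr=False)
    null_mean: pd.DataFrame = field(repr=False)  # species × metric
    null_sd: pd.DataFrame = field(repr=False)  # species × metric (ddof=1)


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return np.array([child.generate_state(1)[0] for child in ss.spawn(n)], dtype=np.uint32)


def null_distribution(
    m: FlockMatrix,
    n_reps: int = 500,
    seed: int = 0,
    trades_factor: int = 5,
    method: str = "curveball",
) -> NullEnsemble:
    """Null distribution of all species-level metrics at one locality.

    Each of ``n_reps`` replicates randomizes the matrix (fixed-fixed),
    projects it to the co-occurrence graph, and computes connectivity,
    strength and weighted closeness for every species.  Means and sample
    SDs over replicates are returned.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    S = m.n_species
    unique = is_margin_unique(m.occ)
    fill = int(m.occ.sum())
    n_steps = trades_factor * fill
    seeds = _replicate_seeds(seed, n_reps)
    vals = np.empty((n_reps, S, len(METRICS)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            occ = m.occ.copy()
            if not unique:
                if method == "curveball":
                    occ = _curveball(occ, n_steps, int(seeds[r]))
                else:
                    occ = _swap_randomize(occ, n_steps, int(seeds[r]))
            W = occ.astype(np.int64).T @ occ.astype(np.int64)
            np.fill_diagonal(W, 0)
            mets = metrics_from_weights(W)
            for k, name in enumerate(METRICS):
                vals[r, :, k] = mets[name]
    mean = pd.DataFrame(vals.mean(axis=0), index=m.species_ids, columns=METRICS)
    sd = pd.DataFrame(vals.std(axis=0, ddof=1), index=m.species_ids, columns=METRICS)
    return NullEnsemble(
        locality_id=m.locality_id,
        n_reps=n_reps,
        seed=seed,
        species_ids=list(m.species_ids),
        null_mean=mean,
        null_sd=sd,
    )


def z_scores(observed: pd.DataFrame, nulls: NullEnsemble) -> pd.DataFrame:
    """Standardize observed metrics against a locality's null ensemble.

    ``observed`` is a tidy per-locality metric table (as produced by
    :func:`flocknet.cooccurrence_networks.locality_metrics`).  Returns a long
    table with one row per (species, metric): observed value, null mean,
    null SD, and z; z is NaN where the null SD is zero.
    """
    obs = observed[observed["locality_id"] == nulls.locality_id]
    missing = set(obs["species_id"]) - set(nulls.species_ids)
    if missing:
        raise ValueError(
            f"species {sorted(missing)} present in observed metrics but not in "
            f"null ensemble for locality {nulls.locality_id!r}"
        )
    rows = []
    n_degenerate = 0
    for _, rec in obs.iterrows():
        sp = rec["species_id"]
        for metric in METRICS:
            mu = float(nulls.null_mean.loc[sp, metric])
            sd = float(nulls.null_sd.loc[sp, metric])
            if sd > 0:
                z = (float(rec[metric]) - mu) / sd
            else:
                z = np.nan
                n_degenerate += 1
            rows.append(
                {
                    "species_id": sp,
                    "locality_id": nulls.locality_id,
                    "metric": metric,
                    "observed": float(rec[metric]),
                    "null_mean": mu,
                    "null_sd": sd,
                    "z": z,
                }
            )
    if n_degenerate:
        logger.info(
            "locality %s: %d zero-variance null cells -> z set missing",
            nulls.locality_id,
            n_degenerate,
        )
    return pd.DataFrame(rows)


def average_z_scores(z_tables: list[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Average per-locality z-scores per species and metric (NaNs excluded).

    Returns a wide table indexed by species with one column per metric
    (``z_connectivity`` etc.) plus ``n_localities``.
    """
    df = pd.concat(z_tables, ignore_index=True) if isinstance(z_tables, list) else z_tables
    wide = (
        df.groupby(["species_id", "metric"])["z"]
        .mean()  # NaN-skipping; species with only degenerate cells stay as NaN
        .unstack("metric")
        .rename(columns={m: f"z_{m}" for m in METRICS})
    )
    wide.columns.name = None
    wide["n_localities"] = df.groupby("species_id")["locality_id"].nunique()
    return wide
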