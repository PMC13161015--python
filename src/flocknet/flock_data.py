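"""Reading, validation and filtering of per-locality flock occurrence matrices.

A *flock matrix* is one locality's binary flock × species table: rows are
individually surveyed mixed-species flocks, columns are species, and a 1
means the species was recorded in that flock.  Two filters mirror standard
practice for this kind of compilation: flocks must contain a minimum number
of species (default 3) to count as a mixed-species flock, and species
recorded in fewer than a minimum number of flocks across the whole dataset
(default 3) are treated as anecdotal and excluded.  Because the two filters
interact (dropping a rare species can push a flock below the size threshold),
:func:`filter_species` iterates both rules to a fixed point.

*Flocking propensity* is the proportion of flocks in which a species was
detected, pooled across localities; it is reported together with its natural
logarithm, the transform used downstream to reduce skewness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FlockDataError",
    "FlockMatrix",
    "read_flock_tables",
    "filter_flocks",
    "filter_species",
    "flocking_propensity",
]


class FlockDataError(ValueError):
    """Malformed or degenerate flock occurrence data."""


@dataclass
class FlockMatrix:
    """One locality's binary flock × species occurrence table.

    Attributes
    ----------
    locality_id : str
        Identifier of the locality (study site).
    flock_ids : list of str
        Row labels, one per surveyed flock.
    species_ids : list of str
        Column labels, one per species.
    occ : ndarray of shape (n_flocks, n_species)
        Binary occurrence matrix; ``occ[f, s] == 1`` iff species ``s`` was
        recorded in flock ``f``.
    """

    locality_id: str
    flock_ids: list[str] = field(repr=False)
    species_ids: list[str] = field(repr=False)
    occ: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.occ = np.asarray(self.occ)
        if self.occ.ndim != 2:
            raise FlockDataError(
                f"locality {self.locality_id!r}: occurrence matrix must be 2-D"
            )
        nf, ns = self.occ.shape
        if nf != len(self.flock_ids) or ns != len(self.species_ids):
            raise FlockDataError(
                f"locality {self.locality_id!r}: matrix shape {self.occ.shape} does "
                f"not match {len(self.flock_ids)} flocks × {len(self.species_ids)} species"
            )
        vals = np.unique(self.occ)
        if not np.isin(vals, (0, 1)).all():
            bad = [v for v in vals if v not in (0, 1)]
            raise FlockDataError(
                f"locality {self.locality_id!r}: non-binary cell value(s) {bad}"
            )
        self.occ = self.occ.astype(np.int8)
        if len(set(self.flock_ids)) != len(self.flock_ids):
            raise FlockDataError(f"locality {self.locality_id!r}: duplicate flock ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise FlockDataError(f"locality {self.locality_id!r}: duplicate species ids")

    @property
    def n_flocks(self) -> int:
        return self.occ.shape[0]

    @property
    def n_species(self) -> int:
        return self.occ.shape[1]

    def flock_sizes(self) -> np.ndarray:
        """Number of species per flock (row sums)."""
        return self.occ.sum(axis=1)

    def species_counts(self) -> pd.Series:
        """Number of flocks each species occurs in at this locality."""
        return pd.Series(self.occ.sum(axis=0), index=self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occ, index=self.flock_ids, columns=self.species_ids)

    @classmethod
    def from_frame(cls, locality_id: str, df: pd.DataFrame) -> "FlockMatrix":
        return cls(
            locality_id=locality_id,
            flock_ids=[str(i).strip() for i in df.index],
            species_ids=[str(c).strip() for c in df.columns],
            occ=df.to_numpy(),
        )


def read_flock_tables(path: str | Path) -> list[FlockMatrix]:
    """Read one CSV per locality from a directory.

    Each CSV must have flock ids in the first column and species ids as the
    header row; cells are 0/1.  The file stem becomes the locality id.
    Ids are whitespace-trimmed; matching across files is exact string match.

    Raises
    ------
    FlockDataError
        On empty files, non-binary cells (named by file and row), or
        duplicate ids.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv"))
    if not files:
        raise FlockDataError(f"no CSV files found in {path}")
    out: list[FlockMatrix] = []
    for f in files:
        try:
            df = pd.read_csv(f, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FlockDataError(f"{f.name}: cannot parse CSV ({exc})") from exc
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise FlockDataError(f"{f.name}: no flocks")
        arr = df.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FlockDataError(
                f"{f.name}: non-binary cell value {arr[r, c]!r} at "
                f"flock {df.index[r]!r}, species {df.columns[c]!r}"
            )
        try:
            out.append(FlockMatrix.from_frame(f.stem, df))
        except FlockDataError as exc:
            raise FlockDataError(f"{f.name}: {exc}") from exc
    return out


def filter_flocks(m: FlockMatrix, min_species: int = 3) -> FlockMatrix:
    """Drop flocks (rows) with fewer than ``min_species`` species.

    The column set is unchanged.  Raises :class:`FlockDataError` if no
    flock survives.
    """
    keep = m.flock_sizes() >= min_species
    if not keep.any():
        raise FlockDataError(
            f"locality {m.locality_id!r}: no flocks survive filter "
            f"(min_species={min_species})"
        )
    return FlockMatrix(
        locality_id=m.locality_id,
        flock_ids=[fid for fid, k in zip(m.flock_ids, keep) if k],
        species_ids=list(m.species_ids),
        occ=m.occ[keep],
    )


def filter_species(
    ms: list[FlockMatrix],
    min_flocks: int = 3,
    min_species: int = 3,
) -> tuple[list[FlockMatrix], set[str]]:
    """Exclude species recorded in fewer than ``min_flocks`` flocks overall.

    Occurrence counts are pooled across *all* localities.  After removing a
    species' columns, flocks are re-checked against the ``min_species`` rule
    and the two filters iterate to a fixed point, so both constraints hold
    simultaneously in the result.  Localities whose flocks are all removed
    are dropped with a warning.

    Returns the filtered matrices and the set of retained species ids.
    """
    mats = list(ms)
    while True:
        counts: dict[str, int] = {}
        for m in mats:
            for sp, c in zip(m.species_ids, m.occ.sum(axis=0)):
                counts[sp] = counts.get(sp, 0) + int(c)
        retained = {sp for sp, c in counts.items() if c >= min_flocks}
        changed = False
        nxt: list[FlockMatrix] = []
        for m in mats:
            keep_cols = np.array([sp in retained for sp in m.species_ids], dtype=bool)
            if not keep_cols.all():
                changed = True
            if not keep_cols.any():
                warnings.warn(
                    f"locality {m.locality_id!r}: all species filtered out; "
                    "locality dropped"
                )
                continue
            occ = m.occ[:, keep_cols]
            sp_ids = [sp for sp, k in zip(m.species_ids, keep_cols) if k]
            keep_rows = occ.sum(axis=1) >= min_species
            if not keep_rows.all():
                changed = True
            if not keep_rows.any():
                warnings.warn(
                    f"locality {m.locality_id!r}: no flocks survive re-check; "
                    "locality dropped"
                )
                continue
            nxt.append(
                FlockMatrix(
                    locality_id=m.locality_id,
                    flock_ids=[fid for fid, k in zip(m.flock_ids, keep_rows) if k],
                    species_ids=sp_ids,
                    occ=occ[keep_rows],
                )
            )
        mats = nxt
        if not changed:
            break
    if not mats:
        warnings.warn("species filter removed every locality")
    final_species = {sp for m in mats for sp in m.species_ids}
    dropped = len({sp for m in ms for sp in m.species_ids}) - len(final_species)
    logger.info("filter_species: dropped %d species, kept %d", dropped, len(final_species))
    return mats, final_species


def flocking_propensity(
    ms: list[FlockMatrix],
    denominator: str = "global",
) -> pd.DataFrame:
    """Per-species flocking propensity pooled across localities.

    Parameters
    ----------
    ms : list of FlockMatrix
        Filtered matrices (flock and species filters already applied).
    denominator : {"global", "range"}
        ``"global"`` divides each species' occurrence count by the total
        number of flocks in the whole dataset; ``"range"`` divides by the
        number of flocks at the localities where the species was recorded.

    Returns
    -------
    DataFrame
        Indexed by ``species_id`` with columns ``n_flocks_present``,
        ``n_flocks_total``, ``propensity`` and ``log_propensity`` (natural
        log).  Species absent everywhere are excluded.
    """
    if denominator not in ("global", "range"):
        raise ValueError(f"unknown denominator {denominator!r}")
    present: dict[str, int] = {}
    loc_flocks: dict[str, int] = {}
    occurs_at: dict[str, set[str]] = {}
    for m in ms:
        loc_flocks[m.locality_id] = m.n_flocks
        for sp, c in zip(m.species_ids, m.occ.sum(axis=0)):
            if c > 0:
                present[sp] = present.get(sp, 0) + int(c)
                occurs_at.setdefault(sp, set()).add(m.locality_id)
    total = sum(loc_flocks.values())
    rows = []
    for sp in sorted(present):
        denom = (
            total
            if denominator == "global"
            else sum(loc_flocks[l] for l in occurs_at[sp])
        )
        p = present[sp] / denom
        rows.append(
            {
                "species_id": sp,
                "n_flocks_present": present[sp],
                "n_flocks_total": denom,
                "propensity": p,
                "log_propensity": float(np.log(p)),
            }
        )
    return pd.DataFrame(rows).set_index("species_id")
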