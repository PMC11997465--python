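"""Observed dispersion metrics: MPD, MNTD (phylogenetic) and MFD (functional).

All three are means over a quadrat's co-occurring species of entries of a
pairwise species distance matrix — patristic distances for MPD/MNTD, trait
distances for MFD.  Each comes in an occurrence-based form (every present
species counts once) and an abundance-weighted form (pairs weighted by the
product of raw abundances; conspecific pairs excluded).  A quadrat with fewer
than two species has no pairwise structure: the metrics return NaN, the
pipeline's undefined marker.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import ValidationError

WEIGHTINGS = ("abundance", "occurrence")

#: default per-trait transform before z-scoring; seed mass spans several
#: orders of magnitude, so it is analysed on a log10 scale
DEFAULT_TRANSFORMS = {"seed_mass_g": "log10"}

_TRANSFORMS = {
    "identity": lambda x: x,
    "log10": np.log10,
    "log": np.log,
    "sqrt": np.sqrt,
}


def _present(abundances: Mapping[str, float] | pd.Series) -> pd.Series:
    ab = pd.Series(abundances, dtype=float)
    if (ab < 0).any():
        raise ValidationError("abundances must be nonnegative")
    return ab[ab > 0]


def _submatrix(dm: DistanceMatrix, species: Sequence[str]) -> np.ndarray:
    ids = set(dm.ids)
    missing = [s for s in species if s not in ids]
    if missing:
        raise ValidationError(
            f"species absent from distance matrix: {sorted(missing)}")
    idx = [dm.index(s) for s in species]
    return dm.data[np.ix_(idx, idx)]


def mpd(dm: DistanceMatrix, abundances: Mapping[str, float] | pd.Series,
        weighting: str = "abundance") -> float:
    """Mean pairwise distance among the species present in a quadrat.

    occurrence: mean of d(i, j) over unordered pairs of present species;
    abundance: sum of f_i f_j d(i, j) over pairs, divided by sum of f_i f_j,
    with f the raw abundances.  Returns NaN when richness < 2.
    """
    _check_weighting(weighting)
    ab = _present(abundances)
    if len(ab) < 2:
        return float("nan")
    sub = _submatrix(dm, list(ab.index))
    if weighting == "occurrence":
        k = len(ab)
        return float(sub.sum() / (k * (k - 1)))
    w = np.outer(ab.to_numpy(), ab.to_numpy())
    np.fill_diagonal(w, 0.0)
    return float((sub * w).sum() / w.sum())


def mntd(dm: DistanceMatrix, abundances: Mapping[str, float] | pd.Series,
         weighting: str = "abundance") -> float:
    """Mean distance from each present species to its nearest co-occurring
    neighbour; abundance weighting weights each species' nearest-neighbour
    distance by its abundance.  Returns NaN when richness < 2."""
    _check_weighting(weighting)
    ab = _present(abundances)
    if len(ab) < 2:
        return float("nan")
    sub = _submatrix(dm, list(ab.index)).copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if weighting == "occurrence":
        return float(nearest.mean())
    f = ab.to_numpy()
    return float((f * nearest).sum() / f.sum())


def mfd(tdm: DistanceMatrix, abundances: Mapping[str, float] | pd.Series,
        weighting: str = "abundance") -> float:
    """Mean functional trait distance: the MPD kernel on a trait distance
    matrix."""
    return mpd(tdm, abundances, weighting)


def _check_weighting(weighting: str) -> None:
    if weighting not in WEIGHTINGS:
        raise ValidationError(
            f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")


def read_traits(path) -> pd.DataFrame:
    """Trait CSV ``species_id,<trait>,...`` indexed by species."""
    df = pd.read_csv(path)
    if df.columns[0] != "species_id":
        raise ValidationError(
            f"first trait column must be 'species_id', got {df.columns[0]!r}")
    return df.set_index("species_id")


def trait_distance(traits: pd.DataFrame,
                   trait_set: Optional[Sequence[str]] = None,
                   transforms: Optional[Mapping[str, str]] = None,
                   pool: Optional[Sequence[str]] = None,
                   metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise species distance in standardized trait space.

    Each requested trait is transformed (defaults: log10 for seed mass,
    identity otherwise), then z-scored across the standardization population
    (``pool``; defaults to all species in the table — the population the null
    model draws from, not the quadrat).  Distance is Euclidean in the
    standardized space; for a single trait this is |z_i − z_j|.  ``metric=
    "gower"`` gives mean per-trait range-normalised absolute difference on
    the transformed values, as a robustness alternative.
    """
    if pool is not None:
        missing = sorted(set(pool) - set(traits.index))
        if missing:
            raise ValidationError(f"species missing from trait table: {missing}")
        traits = traits.loc[sorted(pool)]
    cols = list(trait_set) if trait_set is not None else list(traits.columns)
    unknown = [c for c in cols if c not in traits.columns]
    if unknown:
        raise ValidationError(f"unknown traits requested: {unknown}")
    tf = dict(DEFAULT_TRANSFORMS)
    if transforms:
        tf.update(transforms)

    block = np.empty((len(traits), len(cols)))
    for j, col in enumerate(cols):
        x = traits[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            bad = traits.index[np.isnan(x)].tolist()
            raise ValidationError(f"missing {col!r} values for species: {bad}")
        fn = _TRANSFORMS[tf.get(col, "identity")]
        x = fn(x)
        block[:, j] = x

    if metric == "euclidean":
        sd = block.std(axis=0, ddof=1)
        if (sd == 0).any():
            zero = [cols[j] for j in np.where(sd == 0)[0]]
            raise ValidationError(
                f"zero-variance traits cannot be standardized: {zero}")
        z = (block - block.mean(axis=0)) / sd
        d = squareform(pdist(z, metric="euclidean"))
    elif metric == "gower":
        rng = block.max(axis=0) - block.min(axis=0)
        if (rng == 0).any():
            zero = [cols[j] for j in np.where(rng == 0)[0]]
            raise ValidationError(f"zero-range traits: {zero}")
        d = np.zeros((len(traits), len(traits)))
        for j in range(block.shape[1]):
            d += np.abs(block[:, j][:, None] - block[:, j][None, :]) / rng[j]
        d /= block.shape[1]
    else:
        raise ValidationError(f"unknown trait distance metric {metric!r}")
    return DistanceMatrix(d, ids=list(traits.index))
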