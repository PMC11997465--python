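"""Randomization null models and standardized effect sizes (NRI, NTI, FD-SES).

Two null models are provided:

``independent_swap``
    Checkerboard swaps on the quadrat × species matrix.  Each successful swap
    exchanges the occupied/empty pattern of a 2 × 2 submatrix whose occupancy
    is a checkerboard, moving abundance values within their species column.
    Per-quadrat species richness, per-species occurrence frequency, and each
    species' abundance multiset are preserved exactly.

``taxa_labels``
    Species labels of the distance matrix are permuted uniformly at random
    over the members of the chosen species pool, so a quadrat's occupants
    become a uniform draw from the pool while its richness and abundance
    vector are kept.

The standardized effect size of an observed metric against ``n_rand`` null
draws is (obs − null mean)/null sd.  NRI and NTI flip the sign, so positive
values mean phylogenetic clustering and negative values overdispersion;
FD-SES is unsigned, so positive values mean trait divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import CommunityMatrix, SpeciesPool
from .errors import ValidationError

NULL_MODELS = ("independent_swap", "taxa_labels")
#: metric → (reported index name, SES sign)
INDEX_FOR_METRIC = {"MPD": ("NRI", -1.0), "MNTD": ("NTI", -1.0),
                    "MFD": ("FD_SES", 1.0)}


@dataclass(frozen=True)
class NullSpec:
    """Randomization settings: which null, how many draws, burn-in, seed."""

    model: str = "taxa_labels"
    n_rand: int = 999
    swap_burnin: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in NULL_MODELS:
            raise ValidationError(
                f"null model must be one of {NULL_MODELS}, got {self.model!r}")
        if self.n_rand < 1:
            raise ValidationError("n_rand must be >= 1")
        if self.swap_burnin < 1:
            raise ValidationError("swap_burnin must be >= 1")


@dataclass
class SESResult:
    """One quadrat × index × weighting standardized effect size."""

    quadrat_key: tuple
    index: str
    weighting: str
    obs: float
    null_mean: float
    null_sd: float
    ses: float
    p_rank: float
    n_rand: int
    model: str
    seed: int


def results_to_frame(results: Sequence[SESResult]) -> pd.DataFrame:
    """Tidy table: one SESResult per row."""
    rows = []
    for r in results:
        plot, row, col, layer = r.quadrat_key
        rows.append({"plot_id": plot, "grid_row": row, "grid_col": col,
                     "layer": layer, "index": r.index,
                     "weighting": r.weighting, "obs": r.obs,
                     "null_mean": r.null_mean, "null_sd": r.null_sd,
                     "ses": r.ses, "p_rank": r.p_rank, "n_rand": r.n_rand,
                     "model": r.model, "seed": r.seed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# randomization engines


def _swap_array(ab: np.ndarray, burnin: int, rng: np.random.Generator,
                attempt_budget: Optional[int] = None) -> int:
    """Perform ``burnin`` successful checkerboard swaps on ``ab`` in place.

    Returns the number of successful swaps (may be < burnin if the attempt
    budget is exhausted, e.g. on a nested matrix with no checkerboard).
    """
    n_q, n_s = ab.shape
    if attempt_budget is None:
        attempt_budget = max(200 * burnin, 10_000)
    successes = 0
    attempts = 0
    # draw candidate quadruples in batches; apply sequentially
    batch = 4096
    while successes < burnin and attempts < attempt_budget:
        qs = rng.integers(0, n_q, size=(batch, 2))
        ss = rng.integers(0, n_s, size=(batch, 2))
        for (i1, i2), (j1, j2) in zip(qs, ss):
            attempts += 1
            if i1 == i2 or j1 == j2:
                continue
            a = ab[i1, j1]
            b = ab[i2, j2]
            c = ab[i1, j2]
            d = ab[i2, j1]
            if a > 0 and b > 0 and c == 0 and d == 0:
                ab[i2, j1] = a
                ab[i1, j1] = 0.0
                ab[i1, j2] = b
                ab[i2, j2] = 0.0
                successes += 1
            elif a == 0 and b == 0 and c > 0 and d > 0:
                ab[i1, j1] = d
                ab[i2, j1] = 0.0
                ab[i2, j2] = c
                ab[i1, j2] = 0.0
                successes += 1
            if successes >= burnin or attempts >= attempt_budget:
                break
    return successes


def independent_swap(cm: CommunityMatrix, burnin: int = 1000,
                     seed: int = 0) -> CommunityMatrix:
    """Randomize a community matrix by ``burnin`` successful checkerboard
    swaps, preserving quadrat richness and species occurrence frequency.

    If no checkerboard can be found within the attempt budget (e.g. a
    perfectly nested matrix), the input is returned with a warning.
    """
    if cm.n_quadrats < 2 or len(cm.species) < 2:
        raise ValidationError("independent swap needs >= 2 quadrats and species")
    rng = np.random.default_rng(seed)
    ab = cm.abundance_array()
    done = _swap_array(ab, burnin, rng)
    if done < burnin:
        warnings.warn(
            f"only {done}/{burnin} checkerboard swaps possible within the "
            "attempt budget; matrix may admit no (further) swaps", stacklevel=2)
    out = cm.data.copy()
    out[cm.species] = ab
    return CommunityMatrix(out)


def taxa_label_shuffle(dm: DistanceMatrix, pool: SpeciesPool,
                       seed: int | np.random.Generator = 0) -> DistanceMatrix:
    """Permute distance-matrix labels uniformly over the pool members.

    Labels outside the pool are untouched; matrix values are unchanged, so
    the eigenvalues (and every label-free property) are invariant.
    """
    ids = list(dm.ids)
    absent = sorted(pool.members - set(ids))
    if absent:
        raise ValidationError(f"pool members absent from matrix: {absent}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    positions = [i for i, lab in enumerate(ids) if lab in pool.members]
    perm = rng.permutation(len(positions))
    new_ids = list(ids)
    for p, q in zip(positions, perm):
        new_ids[p] = ids[positions[q]]
    return DistanceMatrix(dm.data, ids=new_ids)


# ---------------------------------------------------------------------------
# vectorized metric kernels (rows = null replicates)


def _gather(D: np.ndarray, S: np.ndarray) -> np.ndarray:
    """(R, k, k) pairwise submatrices for R index rows S of length k."""
    return D[S[:, :, None], S[:, None, :]]


def _mpd_rows(sub: np.ndarray, f: Optional[np.ndarray]) -> np.ndarray:
    R, k, _ = sub.shape
    if f is None:
        return sub.sum(axis=(1, 2)) / (k * (k - 1))
    w = np.outer(f, f)
    np.fill_diagonal(w, 0.0)
    return (sub * w).sum(axis=(1, 2)) / w.sum()


def _mntd_rows(sub: np.ndarray, f: Optional[np.ndarray]) -> np.ndarray:
    R, k, _ = sub.shape
    s = sub.copy()
    s[:, np.arange(k), np.arange(k)] = np.inf
    nearest = s.min(axis=2)
    if f is None:
        return nearest.mean(axis=1)
    return (nearest * f).sum(axis=1) / f.sum()


_ROW_KERNELS = {"MPD": _mpd_rows, "MNTD": _mntd_rows, "MFD": _mpd_rows}


# ---------------------------------------------------------------------------
# SES engine


def ses_engine(cm: CommunityMatrix, dm: DistanceMatrix, metric: str,
               weighting: str = "abundance",
               null: NullSpec = NullSpec(),
               pool: Optional[SpeciesPool] = None) -> list[SESResult]:
    """Standardized effect sizes of one metric for every quadrat.

    For each quadrat the observed metric is compared with ``null.n_rand``
    null draws: ``independent_swap`` re-randomizes the community matrix with
    a fresh swap chain per replicate and recomputes; ``taxa_labels`` permutes
    the distance-matrix labels over the pool per replicate.  null_sd uses the
    n−1 denominator; p_rank = (#(null ≤ obs) + 1)/(n_rand + 1), ties counted
    conservatively.  Quadrats with richness < 2, or with null_sd = 0, get a
    NaN SES.
    """
    table = compute_ses_table(cm, dm, metrics=[metric], weightings=[weighting],
                              null=null, pool=pool)
    return table


def compute_ses_table(cm: CommunityMatrix, dm: DistanceMatrix,
                      metrics: Sequence[str] = ("MPD", "MNTD"),
                      weightings: Sequence[str] = ("abundance", "occurrence"),
                      null: NullSpec = NullSpec(),
                      pool: Optional[SpeciesPool] = None) -> list[SESResult]:
    """SES for several metrics and weightings, sharing one set of null draws.

    Sharing draws across metrics/weightings is statistically harmless (each
    SES is a marginal summary) and markedly faster.
    """
    for m in metrics:
        if m not in INDEX_FOR_METRIC:
            raise ValidationError(f"unknown metric {m!r}")
    ids = list(dm.ids)
    col_of = {lab: i for i, lab in enumerate(ids)}
    observed = [s for s in cm.species if cm.data[s].sum() > 0]
    missing = sorted(set(observed) - set(ids))
    if missing:
        raise ValidationError(f"community species absent from distance "
                              f"matrix: {missing}")
    if pool is None:
        pool = SpeciesPool("plot", frozenset(
            s for s in cm.species if cm.data[s].sum() > 0))
    absent = sorted(pool.members - set(ids))
    if absent:
        raise ValidationError(f"pool members absent from matrix: {absent}")

    D = dm.data
    ab = cm.abundance_array()
    keys = cm.quadrat_keys()
    # zero-total species may be absent from dm (e.g. a pool-restricted trait
    # matrix); they are never occupants, so their slot is never dereferenced
    sp_cols = np.array([col_of.get(s, -1) for s in cm.species])
    R = null.n_rand
    results: list[SESResult] = []

    if null.model == "taxa_labels":
        pool_positions = np.array(sorted(col_of[s] for s in pool.members))
        n_pool = len(pool_positions)
        seedseq = np.random.SeedSequence(null.seed)
        children = seedseq.spawn(cm.n_quadrats)
        for qi, key in enumerate(keys):
            f_full = ab[qi]
            present = np.where(f_full > 0)[0]
            k = len(present)
            if k < 2 or k > n_pool:
                results.extend(_undefined(key, metrics, weightings, null))
                continue
            rng = np.random.default_rng(children[qi])
            obs_idx = sp_cols[present][None, :]
            # uniform k-subsets of the pool = first k slots of a uniform
            # label permutation
            draws = np.argsort(rng.random((R, n_pool)), axis=1)[:, :k]
            S = pool_positions[draws]
            sub_obs = _gather(D, obs_idx)
            sub_null = _gather(D, S)
            f = f_full[present]
            for metric in metrics:
                kern = _ROW_KERNELS[metric]
                for weighting in weightings:
                    fv = None if weighting == "occurrence" else f
                    obs = float(kern(sub_obs, fv)[0])
                    nulls = kern(sub_null, fv)
                    results.append(_make_result(
                        key, metric, weighting, obs, nulls, null))
    else:  # independent_swap
        seedseq = np.random.SeedSequence(null.seed)
        children = seedseq.spawn(R)
        n_q = len(keys)
        nulls_store = {(m, w): np.empty((n_q, R))
                       for m in metrics for w in weightings}
        for r in range(R):
            rng = np.random.default_rng(children[r])
            ab_r = ab.copy()
            done = _swap_array(ab_r, null.swap_burnin, rng)
            if done < null.swap_burnin and r == 0:
                warnings.warn(
                    f"swap chain reached only {done}/{null.swap_burnin} "
                    "successful swaps", stacklevel=2)
            for qi in range(n_q):
                f_full = ab_r[qi]
                present = np.where(f_full > 0)[0]
                if len(present) < 2:
                    for kw in nulls_store:
                        nulls_store[kw][qi, r] = np.nan
                    continue
                sub = _gather(D, sp_cols[present][None, :])
                f = f_full[present]
                for metric in metrics:
                    kern = _ROW_KERNELS[metric]
                    for weighting in weightings:
                        fv = None if weighting == "occurrence" else f
                        nulls_store[(metric, weighting)][qi, r] = kern(sub, fv)[0]
        for qi, key in enumerate(keys):
            f_full = ab[qi]
            present = np.where(f_full > 0)[0]
            if len(present) < 2:
                results.extend(_undefined(key, metrics, weightings, null))
                continue
            sub_obs = _gather(D, sp_cols[present][None, :])
            f = f_full[present]
            for metric in metrics:
                kern = _ROW_KERNELS[metric]
                for weighting in weightings:
                    fv = None if weighting == "occurrence" else f
                    obs = float(kern(sub_obs, fv)[0])
                    nulls = nulls_store[(metric, weighting)][qi]
                    nulls = nulls[~np.isnan(nulls)]
                    results.append(_make_result(
                        key, metric, weighting, obs, nulls, null))
    return results


def _make_result(key, metric, weighting, obs, nulls, null: NullSpec
                 ) -> SESResult:
    index, sign = INDEX_FOR_METRIC[metric]
    mean = float(np.mean(nulls))
    sd = float(np.std(nulls, ddof=1)) if len(nulls) > 1 else 0.0
    if sd == 0.0 or np.isnan(obs):
        ses = float("nan")
    else:
        ses = sign * (obs - mean) / sd
    p = (np.count_nonzero(nulls <= obs) + 1) / (len(nulls) + 1)
    return SESResult(key, index, weighting, obs, mean, sd, ses, float(p),
                     null.n_rand, null.model, null.seed)


def _undefined(key, metrics, weightings, null: NullSpec) -> list[SESResult]:
    nan = float("nan")
    return [SESResult(key, INDEX_FOR_METRIC[m][0], w, nan, nan, nan, nan, nan,
                      null.n_rand, null.model, null.seed)
            for m in metrics for w in weightings]
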