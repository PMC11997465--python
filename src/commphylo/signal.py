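"""Blomberg's K phylogenetic-signal statistic with a permutation test.

K compares the observed ratio of the among-species trait variance to the
variance of phylogenetically independent contrasts-style GLS residuals with
its Brownian-motion expectation on the same tree.  K = 1 is the Brownian
expectation; K < 1 means relatives resemble each other less than Brownian
motion predicts.  Significance comes from permuting trait values across the
tips: signal makes the observed K larger than permuted K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import ValidationError
from .phylo import Phylogeny, phylo_vcv


@dataclass
class KResult:
    """Blomberg's K with its permutation p-value for one trait."""

    trait_name: str
    K: float
    p_perm: float
    n_species: int
    n_perm: int
    transform: str = "identity"


class _KEngine:
    """Precomputed Cholesky machinery so permutations reuse one factorization."""

    def __init__(self, V: np.ndarray):
        n = V.shape[0]
        try:
            self.chol = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            ridge = 1e-10 * np.trace(V) / n
            warnings.warn(
                f"Brownian covariance is singular (e.g. zero-length tips); "
                f"adding ridge {ridge:.3g} to the diagonal", stacklevel=3)
            self.chol = cho_factor(V + ridge * np.eye(n), lower=True)
        ones = np.ones(n)
        self.Vinv_1 = cho_solve(self.chol, ones)
        self.sum_Vinv = float(ones @ self.Vinv_1)
        # Brownian expectation of MSE0/MSE on this tree
        self.expected_ratio = (np.trace(V) - n / self.sum_Vinv) / (n - 1)
        self.n = n

    def k(self, x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            raise ValidationError(
                "trait is constant across tips; K is undefined")
        a_hat = float(x @ self.Vinv_1) / self.sum_Vinv
        resid = x - a_hat
        mse0 = float(resid @ resid) / (self.n - 1)
        mse = float(resid @ cho_solve(self.chol, resid)) / (self.n - 1)
        if mse == 0.0:
            raise ValidationError(
                "trait is constant across tips; K is undefined")
        return (mse0 / mse) / self.expected_ratio


def _trait_vector(phy: Phylogeny, trait: Mapping[str, float] | pd.Series,
                  labels: list[str]) -> np.ndarray:
    t = pd.Series(trait, dtype=float)
    missing = sorted(set(labels) - set(t.index))
    if missing:
        raise ValidationError(f"trait missing for tips: {missing}")
    x = t.loc[labels].to_numpy()
    if np.isnan(x).any():
        raise ValidationError("trait contains missing values")
    return x


def blomberg_k(phy: Phylogeny, trait: Mapping[str, float] | pd.Series) -> float:
    """Blomberg's K for one continuous trait on a rooted, dated tree.

    With V the Brownian tip covariance, the GLS phylogenetic mean is
    â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1); MSE0 = (x−â)ᵀ(x−â)/(n−1) and
    MSE = (x−â)ᵀV⁻¹(x−â)/(n−1); K is the ratio MSE0/MSE divided by its
    Brownian expectation (tr V − n/(1ᵀV⁻¹1))/(n−1).
    """
    if phy.n_tips < 3:
        raise ValidationError("K needs at least 3 tips")
    V = phylo_vcv(phy)
    labels = list(V.ids)
    x = _trait_vector(phy, trait, labels)
    return _KEngine(V.data).k(x)


def k_permutation_test(phy: Phylogeny, trait: Mapping[str, float] | pd.Series,
                       n_perm: int = 999, seed: int = 0,
                       trait_name: str = "trait",
                       transform: str = "identity") -> KResult:
    """One-sided permutation test of K (signal = larger-than-null K).

    Tip values are permuted uniformly; p = (#(K_perm ≥ K_obs) + 1)/(n_perm+1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if phy.n_tips < 3:
        raise ValidationError("K needs at least 3 tips")
    V = phylo_vcv(phy)
    labels = list(V.ids)
    x = _trait_vector(phy, trait, labels)
    eng = _KEngine(V.data)
    k_obs = eng.k(x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        k_p = eng.k(rng.permutation(x))
        if k_p >= k_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return KResult(trait_name, k_obs, p, phy.n_tips, n_perm, transform)


def signal_table(phy: Phylogeny, traits: pd.DataFrame,
                 transforms: Optional[Mapping[str, str]] = None,
                 n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """K and permutation p per trait column; mirrors a trait-signal table
    (``trait,range_min,range_max,K,n,p``).

    ``transforms`` names a per-trait transform applied before K (K is not
    invariant to nonlinear transforms, so it is recorded); the reported
    range is of the raw values.
    """
    from .dispersion import DEFAULT_TRANSFORMS, _TRANSFORMS

    tf = dict(DEFAULT_TRANSFORMS)
    if transforms:
        tf.update(transforms)
    rows = []
    for i, col in enumerate(traits.columns):
        raw = traits[col]
        name = tf.get(col, "identity")
        vals = pd.Series(_TRANSFORMS[name](raw.to_numpy(dtype=float)),
                         index=raw.index)
        res = k_permutation_test(phy, vals, n_perm=n_perm, seed=seed + i,
                                 trait_name=col, transform=name)
        rows.append({"trait": col, "range_min": float(raw.min()),
                     "range_max": float(raw.max()), "K": res.K,
                     "n": res.n_species, "p": res.p_perm,
                     "transform": name})
    return pd.DataFrame(rows)
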