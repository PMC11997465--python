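"""Per-scale tests of SES against zero and across-scale letter groups.

SES values have expectation zero under the null, so the per-scale verdict
(clustered / overdispersed / random) comes from a one-sample two-tailed
t-test of the quadrat SES values against zero.  Scale dependence is assessed
by comparing scales with one-way ANOVA + Tukey HSD and summarised as a
compact letter display: scales sharing a letter do not differ significantly.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UntestableError, ValidationError

DIRECTIONS = ("clustered", "overdispersed", "random")


@dataclass
class TTestReport:
    """One-sample t-test of SES values against zero for one group."""

    n: int
    n_excluded: int
    mean: float
    sd: float
    t_stat: float
    df: int
    p_two_tailed: float
    direction: str
    alpha: float


def ttest_vs_zero(values: Sequence[float], alpha: float = 0.05,
                  positive_means: str = "clustered") -> TTestReport:
    """Two-tailed one-sample t-test of SES values against an expectation of 0.

    NaN (undefined) values are dropped and counted.  The direction label is
    assigned by the sign of the mean when p < alpha, else "random";
    ``positive_means`` names the verdict for a significantly positive mean
    ("clustered" for NRI/NTI, "divergent" for FD-SES).
    """
    x = np.asarray(list(values), dtype=float)
    excluded = int(np.isnan(x).sum())
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise UntestableError(f"need >= 2 defined values, have {n}")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise UntestableError("zero variance; t-test undefined")
    res = stats.ttest_1samp(x, popmean=0.0)
    mean = float(x.mean())
    if res.pvalue < alpha:
        negative = {"clustered": "overdispersed",
                    "divergent": "convergent"}[positive_means]
        direction = positive_means if mean > 0 else negative
    else:
        direction = "random"
    return TTestReport(n=n, n_excluded=excluded, mean=mean, sd=sd,
                       t_stat=float(res.statistic), df=n - 1,
                       p_two_tailed=float(res.pvalue), direction=direction,
                       alpha=alpha)


# ---------------------------------------------------------------------------
# across-scale comparison


def _pairwise_tukey(groups: Mapping, alpha: float) -> dict[tuple, bool]:
    """Tukey-HSD significant-difference indicator per group pair."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = list(groups)
    data = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    tags = np.concatenate([[str(g)] * len(groups[g]) for g in labels])
    res = pairwise_tukeyhsd(data, tags, alpha=alpha)
    sig: dict[tuple, bool] = {}
    tbl = res.summary().data[1:]
    by_str = {str(g): g for g in labels}
    for row in tbl:
        g1, g2 = by_str[str(row[0])], by_str[str(row[1])]
        reject = bool(row[-1]) if isinstance(row[-1], (bool, np.bool_)) \
            else str(row[-1]) == "True"
        sig[(g1, g2)] = sig[(g2, g1)] = reject
    return sig


def _pairwise_dunn(groups: Mapping, alpha: float) -> dict[tuple, bool]:
    """Dunn's rank-based post-hoc with Holm correction (Kruskal–Wallis
    alternative for non-normal SES distributions)."""
    labels = list(groups)
    data = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    ranks = stats.rankdata(data)
    n_total = len(data)
    # tie correction term
    _, counts = np.unique(data, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12 * (n_total - 1))
    offsets = np.cumsum([0] + [len(groups[g]) for g in labels])
    mean_rank = {g: ranks[offsets[i]:offsets[i + 1]].mean()
                 for i, g in enumerate(labels)}
    sizes = {g: len(groups[g]) for g in labels}
    pairs = list(itertools.combinations(labels, 2))
    pvals = []
    for g1, g2 in pairs:
        se = np.sqrt((n_total * (n_total + 1) / 12 - tie_term)
                     * (1 / sizes[g1] + 1 / sizes[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        pvals.append(2 * stats.norm.sf(abs(z)))
    # Holm step-down
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank_i, idx in enumerate(order):
        running = max(running, (m - rank_i) * pvals[idx])
        adj[idx] = min(1.0, running)
    sig: dict[tuple, bool] = {}
    for (g1, g2), p in zip(pairs, adj):
        sig[(g1, g2)] = sig[(g2, g1)] = bool(p < alpha)
    return sig


def compact_letter_display(labels: Sequence, means: Mapping,
                           sig: Mapping[tuple, bool]) -> dict:
    """Compact letter display exactly encoding the significance graph.

    One letter per maximal clique of the "not significantly different"
    graph: two groups share a letter iff they are not significantly
    different (every edge lies in a maximal clique; non-adjacent groups
    share none).  Letters are ordered by the best group mean in each clique,
    with ties broken lexicographically.
    """
    import networkx as nx

    g_nd = nx.Graph()
    g_nd.add_nodes_from(labels)
    for a, b in itertools.combinations(labels, 2):
        if not sig[(a, b)]:
            g_nd.add_edge(a, b)
    cliques = [frozenset(c) for c in nx.find_cliques(g_nd)]
    cliques.sort(key=lambda c: (-max(means[g] for g in c),
                                sorted(str(g) for g in c)))
    ordered = sorted(labels, key=lambda g: (-means[g], str(g)))
    out: dict = {g: "" for g in labels}
    for letter, s in zip(_letters(), cliques):
        for g in ordered:
            if g in s:
                out[g] += letter
    return out


def _letters():
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def across_scale_letters(groups: Mapping[object, Sequence[float]],
                         alpha: float = 0.05,
                         method: str = "tukey") -> dict:
    """Letter labels per scale from pairwise post-hoc comparisons.

    One-way ANOVA + Tukey HSD by default (``method="dunn"`` for
    Kruskal–Wallis/Dunn).  A group with fewer than 2 defined values is
    lettered "–" and excluded from the comparison.
    """
    clean: dict = {}
    lettered: dict = {}
    for g, vals in groups.items():
        x = np.asarray(list(vals), dtype=float)
        x = x[~np.isnan(x)]
        if len(x) < 2 or x.std(ddof=1) == 0.0:
            lettered[g] = "–"
        else:
            clean[g] = x
    if len(clean) == 0:
        return lettered
    if len(clean) == 1:
        lettered[next(iter(clean))] = "a"
        return lettered
    if method == "tukey":
        sig = _pairwise_tukey(clean, alpha)
    elif method == "dunn":
        sig = _pairwise_dunn(clean, alpha)
    else:
        raise ValidationError(f"unknown post-hoc method {method!r}")
    means = {g: float(v.mean()) for g, v in clean.items()}
    lettered.update(compact_letter_display(list(clean), means, sig))
    return lettered


def anova_oneway(groups: Mapping[object, Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F and p across groups (NaN dropped)."""
    arrays = [np.asarray(list(v), dtype=float) for v in groups.values()]
    arrays = [a[~np.isnan(a)] for a in arrays]
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# report assembly


def assemble_report(ses_frame: pd.DataFrame, alpha: float = 0.05,
                    posthoc: str = "tukey",
                    metadata: Optional[Mapping] = None
                    ) -> dict[str, pd.DataFrame]:
    """Scale report + letters from a tidy SES table.

    The SES table needs columns ``layer, pool, index, weighting, scale, ses``
    (missing grouping columns are tolerated and filled with "—").  Returns
    ``{"scale_report": ..., "metadata": ...}``; the scale report has one row
    per (layer, pool, index, weighting, scale) with the t-test against zero,
    the verdict, and the across-scale letter.  Quadrats pooled across plots.
    """
    df = ses_frame.copy()
    for col in ("layer", "pool", "index", "weighting", "scale"):
        if col not in df.columns:
            df[col] = "—"
    rows = []
    group_cols = ["layer", "pool", "index", "weighting"]
    for gkey, gdf in df.groupby(group_cols, sort=True):
        scales = {s: sdf["ses"].to_numpy() for s, sdf in gdf.groupby("scale")}
        testable = {s: v for s, v in scales.items()
                    if len(v[~np.isnan(v)]) >= 2}
        if len(testable) >= 2:
            letters = across_scale_letters(scales, alpha=alpha, method=posthoc)
        else:
            letters = {s: "a" if s in testable else "–" for s in scales}
        for scale, vals in sorted(scales.items()):
            base = dict(zip(group_cols, gkey))
            base["scale"] = scale
            positive = "divergent" if base["index"] == "FD_SES" else "clustered"
            try:
                rep = ttest_vs_zero(vals, alpha=alpha,
                                    positive_means=positive)
                base.update(n_quadrats=rep.n, n_excluded=rep.n_excluded,
                            mean_ses=rep.mean, sd_ses=rep.sd,
                            t_stat=rep.t_stat, df=rep.df,
                            p_two_tailed=rep.p_two_tailed,
                            direction=rep.direction)
            except UntestableError as exc:
                base.update(n_quadrats=int((~np.isnan(vals)).sum()),
                            n_excluded=int(np.isnan(vals).sum()),
                            mean_ses=float(np.nanmean(vals)) if len(vals) else
                            float("nan"), sd_ses=float("nan"),
                            t_stat=float("nan"), df=0,
                            p_two_tailed=float("nan"),
                            direction=f"untestable ({exc})")
            base["letter_group"] = letters.get(scale, "–")
            rows.append(base)
    report = pd.DataFrame(rows)
    meta = pd.DataFrame(sorted((metadata or {}).items()),
                        columns=["key", "value"])
    return {"scale_report": report, "metadata": meta}
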