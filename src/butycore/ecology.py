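"""Cross-sample and cross-dataset ecology statistics.

Community-level analyses of the butyrate-producer abundance tables:
prevalence cores, Bray–Curtis dissimilarity on square-root-transformed
abundances, complete-linkage community typing, PERMANOVA, Spearman
co-occurrence networks with multi-dataset support, case/control group
comparisons (linear model for pathway totals, FDR-corrected
Mann–Whitney U for taxa and groups at >= 25% prevalence), and
fixed-effect meta-analysis across datasets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests


class EcologyError(Exception):
    pass


@dataclass
class NetworkEdge:
    """A co-occurrence edge supported by several datasets."""

    taxon_a: str
    taxon_b: str
    support: int
    rhos: tuple[float, ...]

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.rhos))


@dataclass
class GroupComparison:
    """Case-vs-control contrast for one feature."""

    feature: str
    mean_case: float
    mean_control: float
    difference: float  # absolute difference (case - control)
    se: float  # standard error of the difference
    p: float
    q: float = float("nan")
    test: str = ""

    @property
    def relative_difference_pct(self) -> float:
        if self.mean_control == 0:
            return float("nan")
        return 100.0 * self.difference / self.mean_control


# ---------------------------------------------------------------------------

def prevalence_core(table: pd.DataFrame, threshold: float) -> list[str]:
    """Taxa detected (abundance > 0) in strictly more than ``threshold``
    fraction of samples.  ``table`` is samples x taxa."""
    if not 0 < threshold <= 1:
        raise EcologyError("threshold must be in (0, 1]")
    if table.empty:
        return []
    frac = (table > 0).mean(axis=0)
    return sorted(frac.index[frac > threshold])


def braycurtis_sqrt(table: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity on square-root-transformed abundances.

    BC(i,j) = sum |sqrt(x_ik) - sqrt(x_jk)| / sum (sqrt(x_ik) + sqrt(x_jk)).
    A pair of all-zero samples is assigned dissimilarity 1 with warning.
    """
    x = np.sqrt(np.asarray(table, dtype=float))
    if (x < 0).any():
        raise EcologyError("abundances must be nonnegative")
    n = x.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                warnings.warn(f"all-zero sample pair ({i}, {j}); dissimilarity set to 1",
                              stacklevel=2)
                d = 1.0
            else:
                d = np.abs(x[i] - x[j]).sum() / denom
            dm[i, j] = dm[j, i] = d
    return pd.DataFrame(dm, index=table.index, columns=table.index)


def cluster_communities(
    dm: pd.DataFrame, k: int | None = None, *, k_max: int = 10
) -> pd.Series:
    """Community types from complete-linkage clustering of a
    dissimilarity matrix; with ``k=None`` the number of clusters is
    chosen by silhouette maximum over 2..k_max."""
    n = len(dm)
    if n < 3:
        return pd.Series(np.ones(n, dtype=int), index=dm.index, name="community_type")
    z = linkage(squareform(dm.values, checks=False), method="complete")
    if k is not None:
        labels = fcluster(z, t=k, criterion="maxclust")
    else:
        best, labels = -np.inf, None
        for kk in range(2, min(k_max, n - 1) + 1):
            lab = fcluster(z, t=kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(dm.values, lab, metric="precomputed")
            if s > best:
                best, labels = s, lab
        if labels is None:
            labels = np.ones(n, dtype=int)
    return pd.Series(labels, index=dm.index, name="community_type")


def permanova(
    dm: pd.DataFrame,
    grouping: Sequence,
    *,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA: pseudo-F from between/within sums of squared
    dissimilarities, P from label permutation.

    P = (1 + #{perm F >= observed}) / (1 + n_perm).
    """
    groups = np.asarray(grouping)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise EcologyError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        raise EcologyError("every group needs n >= 2")
    d2 = np.asarray(dm, dtype=float) ** 2
    n = d2.shape[0]

    def pseudo_f(g: np.ndarray) -> float:
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for lab in labels:
            idx = np.flatnonzero(g == lab)
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = sst - ssw
        a = len(labels)
        return (ssa / (a - 1)) / (ssw / (n - a))

    f_obs = pseudo_f(groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(groups)) >= f_obs:
            exceed += 1
    return float(f_obs), (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------

def cooccurrence_network(
    tables: Sequence[pd.DataFrame],
    *,
    rho_min: float = 0.4,
    alpha: float = 0.05,
    min_support: int = 3,
    prevalence_min: float = 0.5,
) -> list[NetworkEdge]:
    """Multi-dataset Spearman co-occurrence network.

    Per dataset: taxa present in > ``prevalence_min`` of samples are
    kept; Spearman correlations of all pairs are tested; a pair
    qualifies when P < alpha, BH-FDR Q < alpha (within dataset) and
    rho > rho_min.  An edge is reported when the pair qualifies in at
    least ``min_support`` datasets.  Edge order is independent of
    dataset and taxon ordering.
    """
    if len(tables) < min_support:
        warnings.warn("fewer datasets than min_support: empty network", stacklevel=2)
        return []
    qualified: dict[tuple[str, str], list[float]] = {}
    for table in tables:
        frac = (table > 0).mean(axis=0)
        taxa = sorted(frac.index[frac > prevalence_min])
        pairs = list(itertools.combinations(taxa, 2))
        if not pairs:
            continue
        results = []
        for a, b in pairs:
            rho, p = stats.spearmanr(table[a], table[b])
            results.append((a, b, float(rho), float(p)))
        pvals = np.array([r[3] for r in results])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (a, b, rho, p), q in zip(results, qvals):
            if p < alpha and q < alpha and rho > rho_min:
                qualified.setdefault((a, b), []).append(rho)
    edges = [
        NetworkEdge(a, b, support=len(rhos), rhos=tuple(rhos))
        for (a, b), rhos in sorted(qualified.items())
        if len(rhos) >= min_support
    ]
    return edges


def network_to_graph(edges: Iterable[NetworkEdge]):
    """Edge list as a networkx graph (support and mean rho as attributes)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(e.taxon_a, e.taxon_b, support=e.support, mean_rho=e.mean_rho)
    return g


def edges_to_frame(edges: Iterable[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"taxon_a": e.taxon_a, "taxon_b": e.taxon_b,
             "support": e.support, "mean_rho": e.mean_rho}
            for e in edges
        ],
        columns=["taxon_a", "taxon_b", "support", "mean_rho"],
    )


# ---------------------------------------------------------------------------

def _two_group_linear(case: np.ndarray, control: np.ndarray) -> tuple[float, float, float]:
    """Difference of means, its SE and P from a two-group linear model
    (equivalent to the pooled-variance t-test)."""
    import statsmodels.api as sm

    y = np.concatenate([control, case])
    x = sm.add_constant(np.concatenate([np.zeros(len(control)), np.ones(len(case))]))
    fit = sm.OLS(y, x).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def compare_groups(
    case: pd.DataFrame,
    control: pd.DataFrame,
    *,
    pathway_features: Sequence[str] = (),
    prevalence_min: float = 0.25,
    fdr_method: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[GroupComparison]:
    """Case-vs-control contrasts on a feature table (samples x features).

    Pathway-total features are tested with a two-group linear model
    (difference, SE, P); all other features (taxa, enzyme groups,
    family groups) present in >= ``prevalence_min`` of pooled samples
    are tested with Mann–Whitney U and BH-FDR corrected jointly.
    Relative differences are in percent of the control mean.
    """
    if len(case) < 2 or len(control) < 2:
        raise EcologyError("both groups need n >= 2")
    fdr = fdr_method or (lambda p: multipletests(p, method="fdr_bh")[1])
    out: list[GroupComparison] = []
    rank_results: list[GroupComparison] = []
    common = [f for f in case.columns if f in control.columns]
    pooled = pd.concat([case[common], control[common]], ignore_index=True)
    prevalence = (pooled > 0).mean(axis=0)
    for feat in common:
        x, y = case[feat].to_numpy(float), control[feat].to_numpy(float)
        mean_case, mean_control = float(np.mean(x)), float(np.mean(y))
        if mean_control == 0:
            warnings.warn(f"zero control mean for {feat}; relative difference undefined",
                          stacklevel=2)
        if feat in pathway_features:
            diff, se, p = _two_group_linear(x, y)
            out.append(GroupComparison(feat, mean_case, mean_control, diff, se, p,
                                       test="linear"))
        else:
            if prevalence[feat] < prevalence_min:
                continue
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            se = float(np.sqrt(np.var(x, ddof=1) / len(x) + np.var(y, ddof=1) / len(y)))
            rank_results.append(
                GroupComparison(feat, mean_case, mean_control,
                                mean_case - mean_control, se, p, test="mannwhitney")
            )
    if rank_results:
        qs = fdr(np.array([r.p for r in rank_results]))
        for r, q in zip(rank_results, qs):
            r.q = float(q)
    if out:
        qs = fdr(np.array([r.p for r in out]))
        for r, q in zip(out, qs):
            r.q = float(q)
    return out + rank_results


def comparisons_to_frame(results: Iterable[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature": r.feature, "mean_case": r.mean_case,
             "mean_control": r.mean_control, "difference": r.difference,
             "relative_difference_pct": r.relative_difference_pct,
             "se": r.se, "p": r.p, "q": r.q, "test": r.test}
            for r in results
        ]
    )


def meta_analyze(
    per_dataset: Sequence[Sequence[GroupComparison]],
) -> list[GroupComparison]:
    """Fixed-effect inverse-variance pooling of absolute differences
    across datasets, per feature.

    The pooled relative difference is re-expressed against the
    weighted control mean (weights = dataset sample proxies, default
    inverse-variance).  Features with a missing/zero SE in any dataset
    where they appear are pooled over the remaining datasets; fewer than
    two usable datasets skips the feature.
    """
    by_feature: dict[str, list[GroupComparison]] = {}
    for results in per_dataset:
        for r in results:
            by_feature.setdefault(r.feature, []).append(r)
    pooled = []
    for feat, results in sorted(by_feature.items()):
        usable = [r for r in results if np.isfinite(r.se) and r.se > 0]
        if len(usable) < 2:
            continue
        w = np.array([1 / r.se**2 for r in usable])
        diffs = np.array([r.difference for r in usable])
        controls = np.array([r.mean_control for r in usable])
        cases = np.array([r.mean_case for r in usable])
        pooled_diff = float(np.sum(w * diffs) / w.sum())
        pooled_se = float(np.sqrt(1 / w.sum()))
        z = pooled_diff / pooled_se
        p = 2 * stats.norm.sf(abs(z))
        pooled.append(
            GroupComparison(
                feature=feat,
                mean_case=float(np.sum(w * cases) / w.sum()),
                mean_control=float(np.sum(w * controls) / w.sum()),
                difference=pooled_diff, se=pooled_se, p=float(p),
                test="meta_fixed",
            )
        )
    return pooled
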