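"""Shared statistical machinery.

Multiple-testing adjustments delegate to statsmodels; the empirical-Bayes
variance moderation (scaled inverse-chi-square prior fitted by moment
matching on log variances) and Dunn's rank-based pairwise test are written
here because no installed package exposes them with the contracts the
pipeline needs.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from scipy.cluster.hierarchy import linkage, to_tree
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="holm")[1]


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(p, dtype=float) * len(p), 1.0)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation (moderated t)


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature sample variances toward a pooled prior.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    variances by matching the first two moments of log(s^2), then returns
    the posterior variances (d0*s0^2 + df*s^2)/(d0 + df) together with the
    prior df d0 and prior variance s0^2. d0 = inf when the observed
    variances are (numerically) exchangeable with a single value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.nanmean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1)
    resid = e_var - special.polygamma(1, df / 2.0)
    if resid <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(float(resid))
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    post[~ok] = np.nan
    return post, float(d0), s0_2


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    correction: str = "holm",
    min_group_size: int = 3,
) -> tuple[float, dict[tuple[str, str], float]]:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post hoc z tests.

    Groups with fewer than ``min_group_size`` observations are excluded
    (with a warning). Pairwise p-values are adjusted by Holm step-down
    (default) or Bonferroni. Returns (omnibus_p, {pair: adjusted_p}).
    """
    import warnings

    kept = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < min_group_size:
            warnings.warn(f"group {name!r} has <{min_group_size} values; excluded")
            continue
        kept[name] = vals
    if len(kept) < 2:
        raise ValueError("need at least two groups with enough observations")

    names = list(kept)
    omnibus_p = float(stats.kruskal(*kept.values()).pvalue)

    # Dunn: z tests on mean ranks of the pooled sample, with tie correction
    pooled = np.concatenate([kept[n] for n in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for n in names:
        k = len(kept[n])
        mean_ranks[n] = ranks[pos : pos + k].mean()
        sizes[n] = k
        pos += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))

    pairs, raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term)
                * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se
            pairs.append((a, b))
            raw.append(2.0 * stats.norm.sf(abs(z)))
    raw = np.asarray(raw)
    if correction == "holm":
        adj = holm_adjust(raw)
    elif correction == "bonferroni":
        adj = bonferroni_adjust(raw)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return omnibus_p, dict(zip(pairs, adj))


# ---------------------------------------------------------------------------
# Complete-linkage clustering + Newick export


def complete_linkage(matrix: np.ndarray) -> np.ndarray:
    """Agglomerative clustering with complete (full) linkage, Euclidean."""
    return linkage(np.asarray(matrix, dtype=float), method="complete", metric="euclidean")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    def render_root(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:0;"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right});"

    return render_root(tree)


# ---------------------------------------------------------------------------
# Set algebra for target overlaps


def venn_partition(sets: dict[str, set]) -> dict[frozenset, int]:
    """Exact Venn partition: counts of elements in every nonempty combination.

    The key is the frozenset of set names an element belongs to (exactly).
    Partition counts sum to the size of the union.
    """
    union = set().union(*sets.values()) if sets else set()
    out: dict[frozenset, int] = {}
    for el in union:
        key = frozenset(name for name, s in sets.items() if el in s)
        out[key] = out.get(key, 0) + 1
    return out
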