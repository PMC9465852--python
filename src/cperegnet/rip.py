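"""RIP-Seq enrichment testing and CPEB target calling.

Gene-level counts from CPEB immunoprecipitations are compared against the
input library and against a not-injected (NI) control IP. The count model
is a self-contained negative-binomial Wald test: median-of-ratios size
factors, per-gene method-of-moments dispersion shrunk 50/50 (on the log
scale) toward a log-linear mean-dispersion trend, and a Wald test on the
log2 fold change with a t reference distribution. Log fold changes are
additionally shrunk with a normal prior whose scale is estimated from
high-count genes, so that low-information genes shrink most.

A gene is a CPEB target when it is at least ``fc_input``-fold enriched over
input and ``fc_ni``-fold over the NI IP, both at BH-adjusted p <= alpha
(defaults 4x, 2x, 0.05). Preferential targets of CPEB1 versus the CPEB2-4
subfamily are assigned from the pairwise CPEB1-vs-CPEBX contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleSheet
from .stats import bh_adjust, complete_linkage, linkage_to_newick, venn_partition

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (geometric-mean reference)."""
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts; cannot normalize")
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    ok = np.isfinite(log_geo)
    if not ok.any():
        raise ValueError("no gene has nonzero counts in every sample")
    with np.errstate(divide="ignore"):
        ratios = np.log(mat[ok]) - log_geo[ok, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass(frozen=True)
class ContrastResults:
    """Per-gene enrichment statistics for one two-group contrast."""

    contrast: tuple[str, str]  # (numerator condition, denominator condition)
    table: pd.DataFrame  # gene-indexed: base_mean, log2fc, log2fc_shrunk, se, p, padj

    def summary(self) -> pd.Series:
        t = self.table
        tested = t["p"].notna()
        return pd.Series(
            {
                "contrast": f"{self.contrast[0]} vs {self.contrast[1]}",
                "n_genes": len(t),
                "n_tested": int(tested.sum()),
                "n_padj_lt_0.05": int((t["padj"] < 0.05).sum()),
                "median_log2fc": float(t.loc[tested, "log2fc"].median()),
            }
        )


def _nb_wald(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    sf: pd.Series,
    min_total_count: int = 10,
) -> pd.DataFrame:
    cond_b, cond_a = contrast
    samples_b, samples_a = sheet.samples(cond_b), sheet.samples(cond_a)
    for cond, smp in ((cond_b, samples_b), (cond_a, samples_a)):
        if len(smp) == 0:
            raise ValueError(f"contrast condition {cond!r} absent from sample sheet")
        if len(smp) < 2:
            raise ValueError(f"condition {cond!r} has <2 replicates")

    qa = counts[samples_a].to_numpy(float) / sf[samples_a].to_numpy()
    qb = counts[samples_b].to_numpy(float) / sf[samples_b].to_numpy()
    na, nb = qa.shape[1], qb.shape[1]

    raw_total = counts[samples_a + samples_b].sum(axis=1).to_numpy()
    tested = raw_total >= min_total_count
    n_dropped = int((~tested).sum())
    if n_dropped:
        logger.info("excluding %d gene(s) with total count < %d", n_dropped, min_total_count)

    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    var_a, var_b = qa.var(axis=1, ddof=1), qb.var(axis=1, ddof=1)
    grand_mu = (na * mu_a + nb * mu_b) / (na + nb)

    # method-of-moments dispersion per gene, pooled across the two groups
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mu_a) / mu_a**2
        alpha_b = (var_b - mu_b) / mu_b**2
    alpha_raw = ((na - 1) * np.nan_to_num(alpha_a) + (nb - 1) * np.nan_to_num(alpha_b)) / (
        na + nb - 2
    )

    # log-linear mean-dispersion trend over genes with usable estimates
    fit_ok = tested & (alpha_raw > 1e-6) & (grand_mu > 0)
    if fit_ok.sum() >= 10:
        x = np.log(grand_mu[fit_ok])
        yv = np.log(alpha_raw[fit_ok])
        slope, intercept = np.polyfit(x, yv, 1)
    else:  # degenerate input: flat trend at the median dispersion
        slope, intercept = 0.0, np.log(max(np.median(alpha_raw[tested]), 1e-4))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_trend = np.exp(intercept + slope * np.log(np.maximum(grand_mu, 1e-8)))
    alpha_trend = np.clip(alpha_trend, 1e-8, 10.0)
    # 50/50 shrink on the log scale; floor the raw estimate so a lucky
    # underdispersed gene cannot drive its Wald SE to zero
    alpha_floor = np.maximum(alpha_raw, alpha_trend / 10.0)
    alpha = np.exp(0.5 * np.log(alpha_floor) + 0.5 * np.log(alpha_trend))

    pseudo = 0.5
    log2fc = np.log2(mu_b + pseudo) - np.log2(mu_a + pseudo)
    se = (
        np.sqrt(
            (1.0 / (mu_a + pseudo) + alpha) / na + (1.0 / (mu_b + pseudo) + alpha) / nb
        )
        / _LN2
    )
    df_resid = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df_resid)
    p = np.where(tested, p, np.nan)

    out = pd.DataFrame(
        {
            "base_mean": grand_mu,
            "log2fc": log2fc,
            "se": se,
            "stat": tstat,
            "p": p,
            "padj": bh_adjust(p),
            "tested": tested,
        },
        index=counts.index,
    )
    return out


def shrink_lfc(table: pd.DataFrame, prior_sd: float | None = None) -> pd.DataFrame:
    """Add a ``log2fc_shrunk`` column: normal-prior posterior mode.

    shrunk = lfc * prior_var / (prior_var + se^2), so genes with noisier
    estimates shrink more, the sign is preserved, and |shrunk| <= |raw|.
    When ``prior_sd`` is None it is estimated from the high-count half of
    the tested genes (observed lfc variance minus mean sampling variance,
    floored at 0.25).
    """
    t = table.copy()
    if prior_sd is None:
        tested = t[t["tested"]] if "tested" in t else t
        if len(tested) == 0:
            prior_var = 1.0
        else:
            high = tested[tested["base_mean"] >= tested["base_mean"].median()]
            prior_var = max(
                float(np.var(high["log2fc"])) - float(np.mean(high["se"] ** 2)), 0.25**2
            )
    else:
        prior_var = float(prior_sd) ** 2
    t["log2fc_shrunk"] = t["log2fc"] * prior_var / (prior_var + t["se"] ** 2)
    return t


def nb_test(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    sf: pd.Series | None = None,
    min_total_count: int = 10,
    prior_sd: float | None = None,
) -> ContrastResults:
    """Negative-binomial Wald test of ``contrast = (numerator, denominator)``."""
    if sf is None:
        sf = size_factors(counts)
    table = _nb_wald(counts, sheet, contrast, sf, min_total_count)
    table = shrink_lfc(table, prior_sd)
    return ContrastResults(contrast, table)


# ---------------------------------------------------------------------------
# Target calling


@dataclass(frozen=True)
class TargetSet:
    """Called targets of one CPEB with the thresholds that produced them."""

    cpeb: str
    genes: frozenset
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def call_targets(
    res_input: ContrastResults,
    res_ni: ContrastResults,
    fc_input: float = 4.0,
    fc_ni: float = 2.0,
    alpha: float = 0.05,
    cpeb: str = "",
) -> TargetSet:
    """Call targets: >= fc_input-fold over input AND >= fc_ni-fold over the
    NI control IP, both on the shrunk log2 fold change at padj <= alpha."""
    ti, tn = res_input.table, res_ni.table
    if not ti.index.equals(tn.index):
        raise ValueError("mismatched gene universes between the two contrasts")
    sel = (
        (ti["log2fc_shrunk"] >= np.log2(fc_input))
        & (ti["padj"] <= alpha)
        & (tn["log2fc_shrunk"] >= np.log2(fc_ni))
        & (tn["padj"] <= alpha)
    )
    return TargetSet(
        cpeb=cpeb or res_input.contrast[0],
        genes=frozenset(ti.index[sel.fillna(False)]),
        provenance={"fc_input": fc_input, "fc_ni": fc_ni, "alpha": alpha},
    )


def preferential_targets(
    union_targets: set,
    res_1vX: dict[str, ContrastResults],
    lfc_thresh: float = 2.0,
    alpha: float = 0.05,
) -> tuple[set, set, set]:
    """Partition the target union into CPEB1-preferential, CPEB2-4-
    preferential, and shared sets.

    A gene is CPEB1-preferential when shrunk log2FC > lfc_thresh with
    padj < alpha in CPEB1 versus ANY of CPEB2/3/4 (``res_1vX`` keys), and
    CPEB2-4-preferential by the reciprocal (< -lfc_thresh). A gene
    qualifying for both under the disjunction is assigned to the side with
    the larger absolute shrunk fold change (logged).
    """
    best_pos: dict = {}
    best_neg: dict = {}
    for res in res_1vX.values():
        t = res.table
        sig = (t["padj"] < alpha).fillna(False)
        pos = sig & (t["log2fc_shrunk"] > lfc_thresh)
        neg = sig & (t["log2fc_shrunk"] < -lfc_thresh)
        for g in t.index[pos]:
            best_pos[g] = max(best_pos.get(g, 0.0), float(t.at[g, "log2fc_shrunk"]))
        for g in t.index[neg]:
            best_neg[g] = min(best_neg.get(g, 0.0), float(t.at[g, "log2fc_shrunk"]))

    cpeb1_pref, cpeb24_pref = set(), set()
    for g in union_targets:
        in_pos, in_neg = g in best_pos, g in best_neg
        if in_pos and in_neg:
            logger.warning(
                "gene %s preferential in both directions; assigning by |shrunk lfc|", g
            )
            if best_pos[g] >= -best_neg[g]:
                cpeb1_pref.add(g)
            else:
                cpeb24_pref.add(g)
        elif in_pos:
            cpeb1_pref.add(g)
        elif in_neg:
            cpeb24_pref.add(g)
    shared = set(union_targets) - cpeb1_pref - cpeb24_pref
    return cpeb1_pref, cpeb24_pref, shared


def overlap_sets(target_sets: dict[str, TargetSet]) -> pd.DataFrame:
    """Exact Venn partition over the target sets (all nonempty combinations)."""
    part = venn_partition({name: set(ts.genes) for name, ts in target_sets.items()})
    rows = [
        {"combination": "&".join(sorted(key)), "degree": len(key), "count": n}
        for key, n in sorted(part.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["combination", "degree", "count"])


# ---------------------------------------------------------------------------
# Enrichment heatmap + clustering


def enrichment_heatmap_values(
    res_input: dict[str, ContrastResults],
    res_ni: dict[str, ContrastResults],
    genes: list | None = None,
    center: str = "per_contrast",
) -> pd.DataFrame:
    """Combined enrichment score per gene and CPEB.

    The score is the Euclidean norm (modulus) of the two mean-centered
    shrunk log2 fold changes (vs input and vs the NI IP). Centering is per
    contrast by default (subtract the mean over genes); ``center='per_gene'``
    subtracts each gene's mean across the two contrasts instead.
    """
    if center not in ("per_contrast", "per_gene"):
        raise ValueError(f"unknown centering {center!r}")
    out = {}
    for cpeb in res_input:
        ti, tn = res_input[cpeb].table, res_ni[cpeb].table
        if genes is not None:
            ti, tn = ti.loc[genes], tn.loc[genes]
        a, b = ti["log2fc_shrunk"].to_numpy(), tn["log2fc_shrunk"].to_numpy()
        if center == "per_contrast":
            a, b = a - a.mean(), b - b.mean()
        else:
            m = (a + b) / 2.0
            a, b = a - m, b - m
        out[cpeb] = np.hypot(a, b)
    idx = genes if genes is not None else next(iter(res_input.values())).table.index
    return pd.DataFrame(out, index=pd.Index(idx, name="gene"))


def cluster_targets(matrix: pd.DataFrame) -> tuple[np.ndarray, str]:
    """Complete-linkage clustering of the enrichment matrix rows.

    Returns the scipy linkage matrix (merge heights non-decreasing) and a
    Newick rendering of the dendrogram.
    """
    Z = complete_linkage(matrix.to_numpy(float))
    return Z, linkage_to_newick(Z, [str(i) for i in matrix.index])


# ---------------------------------------------------------------------------
# Model-style facade


class RIPEnrichment:
    """Model object over a RIP-Seq count matrix and its sample sheet.

    ``fit()`` runs the IP-vs-input and IP-vs-NI contrasts for every CPEB IP
    condition present in the sheet and returns :class:`RIPResults`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        sheet: SampleSheet,
        min_total_count: int = 10,
    ):
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.sheet = sheet
        self.min_total_count = min_total_count
        self.size_factors = size_factors(counts)

    def fit(
        self, fc_input: float = 4.0, fc_ni: float = 2.0, alpha: float = 0.05
    ) -> "RIPResults":
        conds = set(self.sheet.table["condition"])
        ip_conds = sorted(c for c in conds if c.endswith("_ip") and c != "ni_ip")
        res_input, res_ni, targets = {}, {}, {}
        for c in ip_conds:
            res_input[c] = nb_test(
                self.counts, self.sheet, (c, "input"), self.size_factors, self.min_total_count
            )
            res_ni[c] = nb_test(
                self.counts, self.sheet, (c, "ni_ip"), self.size_factors, self.min_total_count
            )
            targets[c] = call_targets(
                res_input[c], res_ni[c], fc_input, fc_ni, alpha, cpeb=c
            )
        return RIPResults(self, res_input, res_ni, targets, alpha)


@dataclass
class RIPResults:
    """Fitted contrasts and called target sets for every CPEB IP."""

    model: RIPEnrichment
    res_input: dict[str, ContrastResults]
    res_ni: dict[str, ContrastResults]
    targets: dict[str, TargetSet]
    alpha: float

    @property
    def union_targets(self) -> set:
        out: set = set()
        for ts in self.targets.values():
            out |= set(ts.genes)
        return out

    def overlap(self) -> pd.DataFrame:
        return overlap_sets(self.targets)

    def heatmap(self, center: str = "per_contrast") -> pd.DataFrame:
        genes = sorted(self.union_targets)
        return enrichment_heatmap_values(self.res_input, self.res_ni, genes, center)

    def preferential(self, lfc_thresh: float = 2.0) -> tuple[set, set, set]:
        res_1vX = {
            x: nb_test(
                self.model.counts,
                self.model.sheet,
                ("cpeb1_ip", x),
                self.model.size_factors,
                self.model.min_total_count,
            )
            for x in ("cpeb2_ip", "cpeb3_ip", "cpeb4_ip")
            if x in self.targets
        }
        if not res_1vX:
            raise ValueError("preferential analysis needs CPEB2-4 IP conditions")
        return preferential_targets(self.union_targets, res_1vX, lfc_thresh, self.alpha)

    def summary(self) -> pd.DataFrame:
        rows = []
        for c, ts in self.targets.items():
            rows.append(
                {
                    "cpeb": c,
                    "n_targets": len(ts),
                    "n_tested": int(self.res_input[c].table["p"].notna().sum()),
                }
            )
        return pd.DataFrame(rows)

    def plot_heatmap(self, center: str = "per_contrast", ax=None):
        """Clustered heatmap of the combined enrichment scores of the
        target union (rows ordered by the complete-linkage dendrogram)."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import leaves_list

        heat = self.heatmap(center)
        if len(heat) >= 2:
            Z = complete_linkage(heat.to_numpy(float))
            heat = heat.iloc[leaves_list(Z)]
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(heat.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(heat.shape[1]), heat.columns, rotation=45)
        ax.set_ylabel(f"{len(heat)} target genes")
        plt.colorbar(im, ax=ax, label="|centered log2FC| (input, NI)")
        return ax
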