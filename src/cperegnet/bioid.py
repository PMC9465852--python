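"""BioID proximome hit calling from log10(iBAQ) intensity matrices.

Label-free proximity-labeling intensities are missing not at random: low-
abundance proteins drop out of the matrix. The pipeline is therefore

1. percentile (quantile) normalization of each sample onto the mean of the
   sorted per-sample distributions, to minimize batch effects;
2. restricted kNN imputation (k = 10): only proteins with one or two
   missing values are imputed, each hole with the column average over the
   k nearest rows by Euclidean distance on co-present columns;
3. two hit routes, mutually exclusive per protein:
   * tested - at most 2 missing values per condition before imputation; a
     moderated t test (empirical-Bayes pooled variance) of the bait
     condition against the BirA-alone control; hit when the fold change is
     positive and BH-adjusted p < 0.05;
   * rescued - 3 to 4 missing values (of 4) in the control against 1 or
     none in the bait condition, provided the protein's mean detected
     intensity exceeds the 25th percentile of all detected values in the
     bait samples. The rescue rule operates on raw missingness, before any
     imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleSheet
from .stats import bh_adjust, squeeze_variances

_LOG10_2 = np.log10(2.0)


def percentile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-map each sample onto the pooled reference distribution.

    The reference is the mean of the per-sample quantile functions
    evaluated on a common grid; each present value is replaced by the
    reference value at its own within-sample percentile rank. Missing
    cells stay missing and within-sample order is preserved.
    """
    mat = matrix.to_numpy(float)
    n_present = (~np.isnan(mat)).sum(axis=0)
    if (n_present < 2).any():
        bad = matrix.columns[n_present < 2].tolist()
        raise ValueError(f"sample(s) {bad} have fewer than 2 present values")

    grid = np.linspace(0.0, 1.0, int(n_present.max()))
    ref = np.zeros_like(grid)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        ref += np.quantile(col[~np.isnan(col)], grid)
    ref /= mat.shape[1]

    out = np.full_like(mat, np.nan)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        ok = ~np.isnan(col)
        ranks = sps.rankdata(col[ok], method="average")
        pr = (ranks - 1.0) / (ok.sum() - 1.0)
        out[ok, j] = np.interp(pr, grid, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def knn_impute(matrix: pd.DataFrame, k: int = 10, max_missing: int = 2) -> pd.DataFrame:
    """Impute rows with 1..max_missing missing cells from their k nearest rows.

    Distance between rows is Euclidean over co-present columns, rescaled by
    the fraction of columns co-present (the NaN-Euclidean convention), so
    rows with fewer shared columns are not spuriously close. Rows with no
    missing values, or with more than ``max_missing``, are returned
    untouched; present values are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mat = matrix.to_numpy(float)
    n_rows, n_cols = mat.shape
    missing = np.isnan(mat)
    n_missing = missing.sum(axis=1)
    out = mat.copy()

    to_impute = np.flatnonzero((n_missing >= 1) & (n_missing <= max_missing))
    for i in to_impute:
        x = mat[i]
        co = ~missing & ~np.isnan(x)[None, :]  # co-present columns per candidate row
        n_co = co.sum(axis=1)
        diff = np.where(co, mat - x[None, :], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d2 = (diff**2).sum(axis=1) * (n_cols / n_co)
        d2[i] = np.inf
        d2[n_co == 0] = np.inf
        for j in np.flatnonzero(np.isnan(x)):
            cand = np.flatnonzero(~missing[:, j] & np.isfinite(d2))
            if len(cand) == 0:
                warnings.warn(f"no donor rows for cell ({matrix.index[i]}, col {j})")
                continue
            if len(cand) < k:
                warnings.warn(
                    f"only {len(cand)} donor rows (<k={k}) for row {matrix.index[i]}"
                )
            nearest = cand[np.argsort(d2[cand], kind="stable")[:k]]
            out[i, j] = mat[nearest, j].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def rescue_rule(
    matrix: pd.DataFrame,
    sheet: SampleSheet,
    protein,
    condition: str = "cpeb_birA",
    control: str = "birA_control",
    abundance_pct: float = 25.0,
) -> tuple[bool, float]:
    """Evaluate the missingness rescue rule on the raw matrix for one protein.

    True iff the control has >= n-1 missing of n replicates, the condition
    has <= 1 missing, and the protein's mean detected condition intensity
    exceeds the ``abundance_pct`` percentile of all detected values pooled
    across the condition's samples. Also returns the abundance percentile.
    """
    ctrl = matrix.loc[protein, sheet.samples(control)].to_numpy(float)
    cond = matrix.loc[protein, sheet.samples(condition)].to_numpy(float)
    pooled = matrix[sheet.samples(condition)].to_numpy(float)
    detected = pooled[~np.isnan(pooled)]

    cond_present = cond[~np.isnan(cond)]
    if len(cond_present) == 0:
        return False, np.nan
    mean_cond = cond_present.mean()
    percentile = float(100.0 * (detected < mean_cond).mean())

    n_ctrl_missing = int(np.isnan(ctrl).sum())
    n_cond_missing = int(np.isnan(cond).sum())
    eligible = (n_ctrl_missing >= len(ctrl) - 1) and (n_cond_missing <= 1)
    floor = float(np.percentile(detected, abundance_pct))
    return bool(eligible and mean_cond > floor), percentile


def moderated_test(
    matrix: pd.DataFrame,
    sheet: SampleSheet,
    condition: str = "cpeb_birA",
    control: str = "birA_control",
    batch_adjust: bool = False,
    proteins=None,
) -> pd.DataFrame:
    """Per-protein moderated t test of condition vs control.

    Per-protein linear model on present values (difference of means; with
    ``batch_adjust`` the replicate index enters as a covariate), with
    empirical-Bayes variance moderation: residual variances are shrunk
    toward a scaled inverse-chi-square prior fitted by moment matching on
    the log variances of proteins with the modal residual df. The fold
    change is reported in log2 units (intensities are log10).
    """
    cond_samples = sheet.samples(condition)
    ctrl_samples = sheet.samples(control)
    sub = matrix if proteins is None else matrix.loc[proteins]

    effects, s2s, dfs, index = [], [], [], []
    for protein, row in sub.iterrows():
        y1 = row[cond_samples].to_numpy(float)
        y0 = row[ctrl_samples].to_numpy(float)
        if batch_adjust:
            # paired-by-replicate design: condition effect adjusted for replicate
            reps1 = sheet.table.set_index("sample_id").loc[cond_samples, "replicate"]
            reps0 = sheet.table.set_index("sample_id").loc[ctrl_samples, "replicate"]
            y = np.concatenate([y1, y0])
            ok = ~np.isnan(y)
            cond_ind = np.concatenate([np.ones(len(y1)), np.zeros(len(y0))])
            reps = np.concatenate([reps1.to_numpy(), reps0.to_numpy()])
            rep_levels = np.unique(reps)
            X = np.column_stack(
                [np.ones(len(y)), cond_ind]
                + [(reps == r).astype(float) for r in rep_levels[1:]]
            )
            Xo, yo = X[ok], y[ok]
            if np.linalg.matrix_rank(Xo) < Xo.shape[1]:
                raise ValueError("singular design: covariate 'replicate' aliased")
            beta, res, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
            df = len(yo) - Xo.shape[1]
            if df < 1:
                continue
            resid = yo - Xo @ beta
            s2 = float(resid @ resid / df)
            xtx_inv = np.linalg.inv(Xo.T @ Xo)
            v_eff = float(xtx_inv[1, 1])
            effect = float(beta[1])
        else:
            y1p, y0p = y1[~np.isnan(y1)], y0[~np.isnan(y0)]
            if len(y1p) < 2 or len(y0p) < 2:
                continue
            df = len(y1p) + len(y0p) - 2
            s2 = float(
                ((len(y1p) - 1) * y1p.var(ddof=1) + (len(y0p) - 1) * y0p.var(ddof=1)) / df
            )
            v_eff = 1.0 / len(y1p) + 1.0 / len(y0p)
            effect = float(y1p.mean() - y0p.mean())
        effects.append((effect, v_eff))
        s2s.append(s2)
        dfs.append(df)
        index.append(protein)

    if not index:
        return pd.DataFrame(
            columns=["log2fc", "t", "p", "padj"], index=pd.Index([], name="protein")
        )

    s2s = np.asarray(s2s)
    dfs = np.asarray(dfs, dtype=float)
    df_mode = float(sps.mode(dfs, keepdims=False).mode)
    _, d0, s0_2 = squeeze_variances(s2s[dfs == df_mode], df_mode)
    if np.isinf(d0):
        s2_post = np.full_like(s2s, s0_2)
        df_total = np.full_like(dfs, np.inf)
    else:
        s2_post = (d0 * s0_2 + dfs * s2s) / (d0 + dfs)
        df_total = d0 + dfs

    eff = np.array([e for e, _ in effects])
    v_eff = np.array([v for _, v in effects])
    tstat = eff / np.sqrt(s2_post * v_eff)
    p = 2.0 * sps.t.sf(np.abs(tstat), df_total)
    return pd.DataFrame(
        {
            "log2fc": eff / _LOG10_2,
            "t": tstat,
            "p": p,
            "padj": bh_adjust(p),
        },
        index=pd.Index(index, name="protein"),
    )


@dataclass(frozen=True)
class ProximomeResults:
    """Hit table with per-protein route, statistics and abundance."""

    table: pd.DataFrame  # protein-indexed: route, log2fc, p, padj, abundance_percentile, hit

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["hit"]]

    def summary(self) -> pd.Series:
        t = self.table
        return pd.Series(
            {
                "n_proteins": len(t),
                "n_hits": int(t["hit"].sum()),
                "n_tested_hits": int((t["hit"] & (t["route"] == "tested")).sum()),
                "n_rescued_hits": int((t["hit"] & (t["route"] == "rescued")).sum()),
            }
        )


class ProximomeAnalysis:
    """Model object: raw log10-intensity matrix + sample sheet in, hits out."""

    def __init__(
        self,
        matrix: pd.DataFrame,
        sheet: SampleSheet,
        condition: str = "cpeb_birA",
        control: str = "birA_control",
        k: int = 10,
        max_missing: int = 2,
        alpha: float = 0.05,
        abundance_pct: float = 25.0,
        batch_adjust: bool = False,
    ):
        self.matrix = matrix
        self.sheet = sheet
        self.condition = condition
        self.control = control
        self.k = k
        self.max_missing = max_missing
        self.alpha = alpha
        self.abundance_pct = abundance_pct
        self.batch_adjust = batch_adjust

    def fit(self) -> ProximomeResults:
        raw = self.matrix
        cond_samples = self.sheet.samples(self.condition)
        ctrl_samples = self.sheet.samples(self.control)
        miss_cond = raw[cond_samples].isna().sum(axis=1)
        miss_ctrl = raw[ctrl_samples].isna().sum(axis=1)

        # routing on raw missingness; the two routes are mutually exclusive
        testable = (miss_cond <= self.max_missing) & (miss_ctrl <= self.max_missing)

        normalized = percentile_normalize(raw)
        imputed = knn_impute(normalized, k=self.k, max_missing=self.max_missing)

        tested = moderated_test(
            imputed,
            self.sheet,
            self.condition,
            self.control,
            batch_adjust=self.batch_adjust,
            proteins=raw.index[testable],
        )

        rows = []
        for protein in raw.index:
            rescued, pct = rescue_rule(
                raw, self.sheet, protein, self.condition, self.control, self.abundance_pct
            )
            if testable.loc[protein] and protein in tested.index:
                r = tested.loc[protein]
                hit = bool((r["log2fc"] > 0) and (r["padj"] < self.alpha))
                rows.append(
                    {
                        "protein": protein,
                        "route": "tested",
                        "log2fc": r["log2fc"],
                        "p": r["p"],
                        "padj": r["padj"],
                        "abundance_percentile": pct,
                        "hit": hit,
                    }
                )
            else:
                rows.append(
                    {
                        "protein": protein,
                        "route": "rescued" if rescued else "none",
                        "log2fc": np.nan,
                        "p": np.nan,
                        "padj": np.nan,
                        "abundance_percentile": pct,
                        "hit": bool(rescued),
                    }
                )
        table = pd.DataFrame(rows).set_index("protein")
        return ProximomeResults(table)


def call_proximome(matrix: pd.DataFrame, sheet: SampleSheet, **kwargs) -> ProximomeResults:
    """Functional wrapper around :class:`ProximomeAnalysis`."""
    return ProximomeAnalysis(matrix, sheet, **kwargs).fit()


def rank_compare(scores_a: pd.Series, scores_b: pd.Series) -> pd.DataFrame:
    """Compare two states by dense enrichment rank (ties share a rank).

    Rank 1 is the most enriched protein; a protein absent from one state is
    ranked last+1 there. ``delta = rank_a - rank_b`` (positive: higher in
    state B).
    """
    rank_a = scores_a.rank(method="dense", ascending=False)
    rank_b = scores_b.rank(method="dense", ascending=False)
    proteins = sorted(set(scores_a.index) | set(scores_b.index))
    last_a = rank_a.max() if len(rank_a) else 0
    last_b = rank_b.max() if len(rank_b) else 0
    out = pd.DataFrame(
        {
            "rank_a": [rank_a.get(p, last_a + 1) for p in proteins],
            "rank_b": [rank_b.get(p, last_b + 1) for p in proteins],
        },
        index=pd.Index(proteins, name="protein"),
    )
    out["delta"] = out["rank_a"] - out["rank_b"]
    return out
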