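"""Phospho-site occupancy from PSM counts.

For each phosphorylation site the number of position-specific
phosphorylated peptide-spectrum matches (N_phos) and non-phosphorylated
PSMs (N_nonphos) is counted, pooled across search engines (Andromeda,
Amanda, Sequest by default), and the occupancy ratio

    r = N_phos / (N_phos + N_nonphos)

is computed per condition (prophase-I arrest vs progesterone-treated).
Phospho PSMs with localization probability <= 0.75 are excluded. The ratio
error is the binomial standard error sqrt(r (1-r) / N); gains are sites
with strictly larger occupancy after progesterone, with errors propagated
in quadrature. Proline-directed sites are S/T residues immediately
followed by P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

KNOWN_ENGINES = ("Andromeda", "Amanda", "Sequest")


@dataclass(frozen=True)
class PhosphoConfig:
    loc_prob_min: float = 0.75
    engines: tuple[str, ...] = KNOWN_ENGINES
    pooling: str = "sum"  # or "dedupe_by_spectrum"

    def __post_init__(self) -> None:
        if not 0 <= self.loc_prob_min <= 1:
            raise ValueError("loc_prob_min must be in [0,1]")
        if self.pooling not in ("sum", "dedupe_by_spectrum"):
            raise ValueError(f"unknown pooling {self.pooling!r}")


SITE_KEYS = ["protein", "position", "residue"]


def aggregate_psms(psm_table: pd.DataFrame, config: PhosphoConfig = PhosphoConfig()) -> pd.DataFrame:
    """Pool PSM-level rows into per-(site, condition) counts.

    Phospho PSMs at localization probability <= ``loc_prob_min`` are
    excluded from N_phos. Counts are summed across engines, or deduplicated
    by spectrum id when ``pooling='dedupe_by_spectrum'``. Unknown engine
    labels are included with a warning.
    """
    cols = SITE_KEYS + ["is_phospho", "loc_prob", "condition", "engine"]
    missing = [c for c in cols if c not in psm_table.columns]
    if missing:
        raise ValueError(f"PSM table missing columns {missing}")
    t = psm_table.copy()

    unknown = set(t["engine"]) - set(config.engines)
    if unknown:
        warnings.warn(f"unknown engine label(s) {sorted(unknown)}; included")

    if config.pooling == "dedupe_by_spectrum":
        if "spectrum_id" not in t.columns:
            raise ValueError("dedupe_by_spectrum pooling requires a spectrum_id column")
        t = t.drop_duplicates(subset=SITE_KEYS + ["condition", "spectrum_id"])

    is_phos = t["is_phospho"].astype(bool)
    localized = is_phos & (t["loc_prob"] > config.loc_prob_min)
    t = t.assign(
        n_phos=localized.astype(int),
        n_nonphos=(~is_phos).astype(int),
    )
    # phospho PSMs failing the localization filter count toward neither tally
    out = (
        t.groupby(SITE_KEYS + ["condition"], as_index=False)[["n_phos", "n_nonphos"]]
        .sum()
        .sort_values(SITE_KEYS + ["condition"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def occupancy(n_phos: int, n_nonphos: int) -> tuple[float, float]:
    """Occupancy ratio r = N_phos/(N_phos+N_nonphos) and its binomial SE."""
    total = n_phos + n_nonphos
    if total < 1:
        raise ValueError("occupancy undefined for zero total PSM count")
    r = n_phos / total
    return r, float(np.sqrt(r * (1.0 - r) / total))


def occupancy_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add r and r_err columns to an aggregated count table; zero-total
    rows are flagged (``defined`` False) rather than raising."""
    t = counts.copy()
    total = t["n_phos"] + t["n_nonphos"]
    t["defined"] = total >= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(total >= 1, t["n_phos"] / total.replace(0, np.nan), np.nan)
        t["r"] = r
        t["r_err"] = np.sqrt(r * (1.0 - r) / total.replace(0, np.nan))
    return t


def gain_sites(occ: pd.DataFrame, cond_before: str = "PI", cond_after: str = "prog") -> pd.DataFrame:
    """Sites with a relative gain of occupancy after treatment.

    A site is reported iff r_after > r_before (strict). A site present in
    only one condition is treated as r = 0 in the other and flagged.
    Errors are propagated in quadrature. Output sorted by position.
    """
    before = occ[occ["condition"] == cond_before].set_index(SITE_KEYS)
    after = occ[occ["condition"] == cond_after].set_index(SITE_KEYS)
    sites = before.index.union(after.index)
    rows = []
    for site in sites:
        rb = before["r"].get(site, np.nan)
        ra = after["r"].get(site, np.nan)
        flagged = bool(np.isnan(rb) or np.isnan(ra))
        eb = before["r_err"].get(site, 0.0)
        ea = after["r_err"].get(site, 0.0)
        rb0 = 0.0 if np.isnan(rb) else rb
        ra0 = 0.0 if np.isnan(ra) else ra
        if ra0 > rb0:
            rows.append(
                {
                    "protein": site[0],
                    "position": site[1],
                    "residue": site[2],
                    "r_before": rb0,
                    "r_after": ra0,
                    "gain": ra0 - rb0,
                    "gain_err": float(np.hypot(np.nan_to_num(eb), np.nan_to_num(ea))),
                    "single_condition": flagged,
                }
            )
    return (
        pd.DataFrame(
            rows,
            columns=[
                "protein",
                "position",
                "residue",
                "r_before",
                "r_after",
                "gain",
                "gain_err",
                "single_condition",
            ],
        )
        .sort_values("position", kind="mergesort")
        .reset_index(drop=True)
    )


def proline_directed(protein_seq: str, position: int) -> bool:
    """True iff the S/T at 1-based ``position`` is immediately followed by P."""
    if not 1 <= position <= len(protein_seq):
        raise ValueError(f"position {position} outside sequence of length {len(protein_seq)}")
    if protein_seq[position - 1] not in "ST":
        return False
    if position == len(protein_seq):
        warnings.warn("site at sequence end has no +1 residue; not proline-directed")
        return False
    return protein_seq[position] == "P"


@dataclass(frozen=True)
class PhosphoResults:
    """Per-site occupancies per condition plus the gain table."""

    occupancies: pd.DataFrame
    gains: pd.DataFrame

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n_sites": int(self.occupancies.groupby(SITE_KEYS).ngroups),
                "n_gain_sites": len(self.gains),
                "median_gain": float(self.gains["gain"].median()) if len(self.gains) else np.nan,
            }
        )


class PhosphoOccupancy:
    """Model object: PSM-level table in, per-site occupancy results out."""

    def __init__(self, psm_table: pd.DataFrame, config: PhosphoConfig = PhosphoConfig()):
        self.psm_table = psm_table
        self.config = config

    def fit(self) -> PhosphoResults:
        counts = aggregate_psms(self.psm_table, self.config)
        occ = occupancy_table(counts)
        gains = gain_sites(occ) if len(occ) else pd.DataFrame()
        return PhosphoResults(occ, gains)
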