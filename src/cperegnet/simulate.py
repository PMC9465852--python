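"""Synthetic data generators with ground truth.

Each generator emulates the statistical structure of one assay in the
study design so every downstream caller can be scored against known truth:

* 3' UTR sets with planted CPE/PAS architectures and log-normal lengths
  (target median 1489 nt vs 531 nt for non-targets);
* RIP-Seq negative-binomial count matrices with planted IP enrichment
  (default 150 of 2,000 genes at 8x over input / 4x over the not-injected
  control IP, 6 replicates per condition);
* BioID log10-intensity matrices with Gaussian noise and logistic
  missing-not-at-random dropout, with planted hits reachable by both the
  tested and the rescued route;
* PSM tables with binomial phospho counts at planted occupancies;
* three-ROI FRAP traces following single-exponential recovery with
  acquisition bleaching and Gaussian noise.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .frap import FRAPTrace
from .io import DEFAULT_SEED, SampleSheet, UTRRecord
from .motifs import CPE_CANONICAL, CPE_G, PAS_CANONICAL

# ---------------------------------------------------------------------------
# 3' UTR sets


@dataclass(frozen=True)
class UTRTruth:
    """Ground truth of a generated UTR set."""

    records: pd.DataFrame  # record_id, is_target, length
    plantings: pd.DataFrame  # record_id, motif_class, start, end, matched_seq


#: Planting probabilities per motif class: (target rate, non-target rate).
DEFAULT_MOTIF_RATES: dict[str, tuple[float, float]] = {
    CPE_CANONICAL: (1.0, 0.0),
    CPE_G: (0.6, 0.0),
    PAS_CANONICAL: (1.0, 0.6),
}

_PLANT_SEQS = {
    CPE_CANONICAL: ("UUUUAU", "UUUUAAU"),
    CPE_G: ("UUUUGUA",),
    PAS_CANONICAL: ("AAUAAA", "AUUAAA"),
}


def _random_seq(rng: np.random.Generator, n: int, u_rich: bool) -> np.ndarray:
    bases = np.array(list("ACGU"))
    if u_rich:
        p = np.array([0.65 / 3, 0.65 / 3, 0.65 / 3, 0.35])
    else:
        p = np.full(4, 0.25)
    return rng.choice(bases, size=n, p=p)


def gen_utr_set(
    n_targets: int,
    n_nontargets: int,
    motif_rates: dict[str, tuple[float, float]] | None = None,
    length_medians: tuple[float, float] = (1489.0, 531.0),
    sigma_log: float = 0.6,
    max_pas_to_end: int = 60,
    u_rich: bool = False,
    seed: int = DEFAULT_SEED,
) -> tuple[list[UTRRecord], UTRTruth]:
    """Generate UTRs with planted CPE/PAS motifs and a truth table.

    Lengths are log-normal with the given medians (targets, non-targets).
    Planted motifs are inserted at uniform random non-overlapping
    positions; a planted PAS always ends within ``max_pas_to_end`` nt of
    the 3' end, as the architecture rule requires. Raises if a planting
    collision cannot be resolved in 100 attempts.
    """
    if motif_rates is None:
        motif_rates = DEFAULT_MOTIF_RATES
    for cls, (rt, rn) in motif_rates.items():
        if not (0 <= rt <= 1 and 0 <= rn <= 1):
            raise ValueError(f"rates for {cls} must be in [0,1]")
    if min(length_medians) <= 0:
        raise ValueError("length medians must be > 0")

    rng = np.random.default_rng(seed)
    records: list[UTRRecord] = []
    rec_rows, plant_rows = [], []

    labels = [True] * n_targets + [False] * n_nontargets
    for idx, is_target in enumerate(labels):
        rid = f"utr_{idx:05d}"
        median = length_medians[0] if is_target else length_medians[1]
        length = max(80, int(round(rng.lognormal(np.log(median), sigma_log))))
        seq = _random_seq(rng, length, u_rich)

        occupied: list[tuple[int, int]] = []  # 0-based [start, end) intervals
        for cls, (rate_t, rate_n) in motif_rates.items():
            rate = rate_t if is_target else rate_n
            if rng.random() >= rate:
                continue
            motif = str(rng.choice(_PLANT_SEQS[cls]))
            m = len(motif)
            for attempt in range(100):
                if cls == PAS_CANONICAL:
                    # end within the PAS window of the 3' end
                    max_dist = min(max_pas_to_end - m, length - m)
                    dist = int(rng.integers(0, max(max_dist, 0) + 1))
                    s0 = length - dist - m
                else:
                    # keep CPEs upstream of the PAS window
                    hi = max(length - max_pas_to_end - m, 1)
                    s0 = int(rng.integers(0, hi))
                if all(s0 + m <= a or s0 >= b for a, b in occupied):
                    break
            else:
                raise RuntimeError(
                    f"could not place {cls} in {rid} without collision in 100 attempts"
                )
            occupied.append((s0, s0 + m))
            seq[s0 : s0 + m] = list(motif)
            plant_rows.append(
                {
                    "record_id": rid,
                    "motif_class": cls,
                    "start": s0 + 1,
                    "end": s0 + m,
                    "matched_seq": motif,
                }
            )
        records.append(UTRRecord(rid, "".join(seq)))
        rec_rows.append({"record_id": rid, "is_target": is_target, "length": length})

    truth = UTRTruth(
        records=pd.DataFrame(rec_rows, columns=["record_id", "is_target", "length"]),
        plantings=pd.DataFrame(
            plant_rows, columns=["record_id", "motif_class", "start", "end", "matched_seq"]
        ),
    )
    return records, truth


# ---------------------------------------------------------------------------
# RIP-Seq counts

RIP_IP_CONDITIONS = ("cpeb1_ip", "cpeb2_ip", "cpeb3_ip", "cpeb4_ip")


@dataclass(frozen=True)
class RIPTruth:
    """Per-gene true enrichment (log2, relative to input) and NB parameters."""

    baseline: pd.Series  # gene -> mean expression in input
    dispersion: pd.Series  # gene -> NB dispersion alpha
    lfc: pd.DataFrame  # gene x condition true log2 enrichment vs input

    @property
    def genes(self) -> pd.Index:
        return self.baseline.index

    def targets(self, condition: str, min_lfc: float = 1.0) -> set[str]:
        """Genes with true enrichment above ``min_lfc`` in ``condition``."""
        col = self.lfc[condition]
        return set(col.index[col > min_lfc])

    @classmethod
    def planted(
        cls,
        n_genes: int = 2000,
        n_targets: int = 150,
        ip_conditions: tuple[str, ...] = ("cpeb1_ip",),
        lfc_ip: float = 3.0,
        lfc_ni: float = 1.0,
        dispersion: float = 0.05,
        baseline_log_mean: float = np.log(200.0),
        baseline_log_sd: float = 1.0,
        seed: int = DEFAULT_SEED,
    ) -> "RIPTruth":
        """Planted-target design: targets are 2**lfc_ip enriched in every
        IP condition over input and 2**lfc_ni in the NI background IP
        (so 8x over input and 4x over NI at the defaults)."""
        rng = np.random.default_rng(seed)
        genes = pd.Index([f"g{idx:05d}" for idx in range(n_genes)], name="gene")
        baseline = pd.Series(
            np.exp(rng.normal(baseline_log_mean, baseline_log_sd, n_genes)), index=genes
        )
        disp = pd.Series(np.full(n_genes, dispersion), index=genes)
        conds = ["ni_ip", *ip_conditions]
        lfc = pd.DataFrame(0.0, index=genes, columns=conds)
        target_idx = rng.choice(n_genes, size=n_targets, replace=False)
        lfc.iloc[target_idx, lfc.columns.get_indexer(["ni_ip"])[0]] = lfc_ni
        for c in ip_conditions:
            lfc.iloc[target_idx, lfc.columns.get_indexer([c])[0]] = lfc_ip
        return cls(baseline, disp, lfc)

    @classmethod
    def three_class(
        cls,
        n_genes: int = 2000,
        n_per_class: int = 50,
        lfc_shared: float = 3.0,
        lfc_pref_extra: float = 3.0,
        lfc_ni: float = 1.0,
        dispersion: float = 0.05,
        seed: int = DEFAULT_SEED,
    ) -> "RIPTruth":
        """CPEB1-preferential / CPEB2-4-preferential / shared target design.

        Preferential targets carry ``lfc_pref_extra`` additional log2 units
        in their own subfamily's IPs on top of the shared enrichment.
        """
        rng = np.random.default_rng(seed)
        base = cls.planted(
            n_genes=n_genes,
            n_targets=0,
            ip_conditions=RIP_IP_CONDITIONS,
            dispersion=dispersion,
            seed=seed,
        )
        lfc = base.lfc.copy()
        idx = rng.choice(n_genes, size=3 * n_per_class, replace=False)
        groups = {
            "cpeb1_pref": idx[:n_per_class],
            "cpeb24_pref": idx[n_per_class : 2 * n_per_class],
            "shared": idx[2 * n_per_class :],
        }
        for name, rows in groups.items():
            lfc.iloc[rows, lfc.columns.get_indexer(["ni_ip"])[0]] = lfc_ni
            for c in RIP_IP_CONDITIONS:
                lfc.iloc[rows, lfc.columns.get_indexer([c])[0]] = lfc_shared
            if name == "cpeb1_pref":
                lfc.iloc[rows, lfc.columns.get_indexer(["cpeb1_ip"])[0]] += lfc_pref_extra
            elif name == "cpeb24_pref":
                for c in ("cpeb2_ip", "cpeb3_ip", "cpeb4_ip"):
                    lfc.iloc[rows, lfc.columns.get_indexer([c])[0]] += lfc_pref_extra
        truth = cls(base.baseline, base.dispersion, lfc)
        object.__setattr__(truth, "class_labels", {
            name: set(base.baseline.index[rows]) for name, rows in groups.items()
        })
        return truth


def gen_ripseq_counts(
    truth: RIPTruth,
    n_reps: int = 6,
    lib_sizes: dict[str, float] | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Draw a negative-binomial count matrix from a :class:`RIPTruth`.

    Counts for gene g in a sample of condition c have mean
    ``baseline_g * lib_size * 2**lfc[g, c]`` and dispersion ``alpha_g``
    (variance mu + alpha*mu^2).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if (truth.dispersion <= 0).any():
        raise ValueError("dispersions must be > 0")
    rng = np.random.default_rng(seed)
    conditions = ["input", *truth.lfc.columns]
    sheet = SampleSheet.from_conditions({c: n_reps for c in conditions})
    alpha = truth.dispersion.to_numpy()
    size = 1.0 / alpha
    cols = {}
    for sid in sheet.sample_ids:
        cond = sid.rsplit("_r", 1)[0]
        lfc = np.zeros(len(truth.genes)) if cond == "input" else truth.lfc[cond].to_numpy()
        lib = (lib_sizes or {}).get(sid, 1.0)
        mu = truth.baseline.to_numpy() * lib * 2.0**lfc
        p = size / (size + mu)
        cols[sid] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(cols, index=truth.genes)
    return counts, sheet


# ---------------------------------------------------------------------------
# BioID intensity matrices


@dataclass(frozen=True)
class DropoutCurve:
    """Logistic MNAR dropout: P(missing | x) = expit((midpoint - x)/scale)."""

    midpoint: float = 6.0
    scale: float = 0.3

    def p_missing(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.scale == 0:
            return (x < self.midpoint).astype(float)
        return expit((self.midpoint - x) / self.scale)


@dataclass(frozen=True)
class BioIDTruth:
    """Per-protein true log10 intensities and hit labels."""

    table: pd.DataFrame  # protein, base_intensity, shift, is_hit, expected_route

    @property
    def hits(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_hit"], "protein"])

    @classmethod
    def default(
        cls,
        n_proteins: int = 1000,
        n_tested_hits: int = 18,
        n_rescued_hits: int = 12,
        null_mean: float = 7.5,
        null_sd: float = 0.8,
        tested_shift: float = 1.0,
        rescued_base: float = 5.4,
        rescued_shift: float = 2.0,
        seed: int = DEFAULT_SEED,
    ) -> "BioIDTruth":
        """30 planted proximity interactors among 1,000 proteins: 18 with a
        +1.0 log10 shift at detectable abundance (tested route) and 12 that
        drop out of the control but are abundant in the bait condition
        (rescued route)."""
        rng = np.random.default_rng(seed)
        n_hits = n_tested_hits + n_rescued_hits
        rows = []
        base = rng.normal(null_mean, null_sd, n_proteins)
        hit_idx = rng.choice(n_proteins, size=n_hits, replace=False)
        tested = set(hit_idx[:n_tested_hits])
        rescued = set(hit_idx[n_tested_hits:])
        for i in range(n_proteins):
            b, shift, route = base[i], 0.0, ""
            if i in tested:
                b = max(b, null_mean - 0.5)  # keep the tested route detectable
                shift = tested_shift
                route = "tested"
            elif i in rescued:
                b = rescued_base
                shift = rescued_shift
                route = "rescued"
            rows.append(
                {
                    "protein": f"p{i:04d}",
                    "base_intensity": b,
                    "shift": shift,
                    "is_hit": i in tested or i in rescued,
                    "expected_route": route,
                }
            )
        return cls(pd.DataFrame(rows))


def gen_bioid_matrix(
    truth: BioIDTruth,
    n_reps: int = 4,
    dropout: DropoutCurve | None = DropoutCurve(),
    noise_sd: float = 0.25,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Draw a protein x sample log10-intensity matrix with MNAR dropout.

    Values are Gaussian around the true intensity of each protein in each
    condition; every cell is then censored independently with probability
    ``dropout.p_missing(value)`` (missing-not-at-random: lower intensity,
    higher dropout). ``dropout=None`` disables censoring.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    sheet = SampleSheet.from_conditions(
        {"birA_control": n_reps, "cpeb_birA": n_reps}
    )
    t = truth.table
    cols = {}
    for sid in sheet.sample_ids:
        cond_shift = t["shift"].to_numpy() if sid.startswith("cpeb_birA") else 0.0
        vals = rng.normal(t["base_intensity"].to_numpy() + cond_shift, noise_sd)
        if dropout is not None:
            miss = rng.random(len(vals)) < dropout.p_missing(vals)
            vals = np.where(miss, np.nan, vals)
        cols[sid] = vals
    matrix = pd.DataFrame(cols, index=pd.Index(t["protein"], name="protein"))
    return matrix, sheet


# ---------------------------------------------------------------------------
# PSM tables

ENGINES = ("Andromeda", "Amanda", "Sequest")


def gen_psm_table(
    sites: list[tuple[str, int, str]],
    occupancy_pi: dict | float,
    occupancy_prog: dict | float,
    depth: int = 400,
    loc_beta: tuple[float, float] = (20.0, 1.0),
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Generate a PSM-level table with planted occupancies.

    Per site and condition, N_phos ~ Binomial(depth, occupancy) and
    N_nonphos = depth - N_phos; one row per PSM with a localization
    probability drawn from Beta(*loc_beta) for phospho PSMs. PSMs are
    distributed uniformly across three search engines.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")

    def occ_for(o, site):
        return o if np.isscalar(o) else o[site]

    rng = np.random.default_rng(seed)
    rows = []
    spectrum = 0
    for site in sites:
        protein, position, residue = site
        for condition, occ_map in (("PI", occupancy_pi), ("prog", occupancy_prog)):
            occ = float(occ_for(occ_map, site))
            if not 0 <= occ <= 1:
                raise ValueError("occupancies must be in [0,1]")
            n_phos = int(rng.binomial(depth, occ))
            for i in range(depth):
                is_phospho = i < n_phos
                rows.append(
                    {
                        "protein": protein,
                        "position": position,
                        "residue": residue,
                        "is_phospho": is_phospho,
                        "loc_prob": float(rng.beta(*loc_beta)) if is_phospho else np.nan,
                        "condition": condition,
                        "engine": ENGINES[int(rng.integers(0, len(ENGINES)))],
                        "spectrum_id": f"spec_{spectrum:07d}",
                    }
                )
                spectrum += 1
    return pd.DataFrame(
        rows,
        columns=[
            "protein",
            "position",
            "residue",
            "is_phospho",
            "loc_prob",
            "condition",
            "engine",
            "spectrum_id",
        ],
    )


# ---------------------------------------------------------------------------
# FRAP traces


def gen_frap_traces(
    k: float = 0.1,
    mobile: float = 0.8,
    n_traces: int = 1,
    n_pre: int = 50,
    n_post: int = 300,
    dt: float = 0.088,
    noise_sd: float = 0.0,
    bleach_depth: float = 0.3,
    acq_decay: float = 0.0,
    background: float = 100.0,
    cell_intensity: float = 2000.0,
    bleach_intensity: float = 1000.0,
    seed: int = DEFAULT_SEED,
) -> list[FRAPTrace]:
    """Simulate three-ROI FRAP traces with single-exponential recovery.

    Post-bleach, the (ideally normalized) bleach-ROI signal follows
    ``mobile * (1 - exp(-k t))``; ``bleach_depth`` is the fraction of the
    pre-bleach signal surviving the bleach, ``acq_decay`` an exponential
    acquisition-bleaching rate applied to bleach and whole-cell ROIs, and
    Gaussian noise of sd ``noise_sd`` (relative to each ROI's scale) is
    added to all three ROIs.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if not 0 <= mobile <= 1:
        raise ValueError("mobile fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    n_frames = n_pre + n_post
    time = np.arange(n_frames) * dt
    t_post = time[n_pre:] - time[n_pre]

    traces = []
    for _ in range(n_traces):
        decay = np.exp(-acq_decay * time)
        cell = cell_intensity * decay
        bleach = bleach_intensity * decay
        recovery = bleach_depth + (1.0 - bleach_depth) * mobile * (1.0 - np.exp(-k * t_post))
        bleach[n_pre:] *= recovery
        cell_n = cell + rng.normal(0.0, noise_sd * cell_intensity, n_frames)
        bleach_n = bleach + rng.normal(0.0, noise_sd * bleach_intensity, n_frames)
        bg_n = background + rng.normal(0.0, noise_sd * background, n_frames)
        traces.append(
            FRAPTrace(
                time=time,
                i_bleach=bleach_n + background,
                i_cell=cell_n + background,
                i_background=bg_n,
                n_pre=n_pre,
            )
        )
    return traces
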