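"""CPE / PAS motif scanning and 3' UTR cis-element architecture.

CPEB proteins bind cytoplasmic polyadenylation elements (CPEs) in 3' UTRs.
The canonical CPE is UUUUA(1-2)U (i.e. UUUUAU or UUUUAAU) and is bound by
all four CPEBs; the CPEB2-4 subfamily additionally binds a G-variant,
UUUUGU, often found in the extended form UUUUGUA. Regulation further
requires a polyadenylation signal hexamer (PAS; canonically AAUAAA or
AUUAAA, plus weaker non-canonical variants) close to the 3' end. A UTR is
predicted regulated when it carries at least one CPE of either flavour and
a PAS hexamer within a configurable window (default 60 nt) of the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import UTRRecord

CPE_CANONICAL = "CPE_CANONICAL"
CPE_G = "CPE_G"
PAS_CANONICAL = "PAS_CANONICAL"
PAS_NONCANONICAL = "PAS_NONCANONICAL"

#: Non-canonical PAS hexamers (beyond AAUAAA/AUUAAA) from the standard
#: human/vertebrate polyadenylation-signal catalogue; configurable.
DEFAULT_NONCANONICAL_PAS = (
    "UAUAAA",
    "AGUAAA",
    "AAGAAA",
    "AAUAUA",
    "AAUACA",
    "CAUAAA",
    "GAUAAA",
    "AAUGAA",
    "UUUAAA",
    "ACUAAA",
)


@dataclass(frozen=True)
class MotifConfig:
    """Motif definitions and the PAS-to-3'-end window."""

    cpe_canonical: tuple[str, ...] = ("UUUUAU", "UUUUAAU")
    cpe_g: str = "UUUUGU"
    cpe_g_extended: str = "UUUUGUA"
    pas_canonical: tuple[str, ...] = ("AAUAAA", "AUUAAA")
    pas_noncanonical: tuple[str, ...] = DEFAULT_NONCANONICAL_PAS
    max_pas_to_end: int = 60
    collapse_nested: bool = True

    def __post_init__(self) -> None:
        if self.max_pas_to_end < 6:
            raise ValueError("max_pas_to_end must be >= 6 (a PAS is a hexamer)")
        for pat in (
            *self.cpe_canonical,
            self.cpe_g,
            self.cpe_g_extended,
            *self.pas_canonical,
            *self.pas_noncanonical,
        ):
            if set(pat) - set("ACGU"):
                raise ValueError(f"pattern {pat!r} not over the RNA alphabet")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start``/``end`` are 1-based inclusive."""

    record_id: str
    motif_class: str
    start: int
    end: int
    matched_seq: str
    dist_to_3end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_CLASS_ORDER = {CPE_CANONICAL: 0, CPE_G: 1, PAS_CANONICAL: 2, PAS_NONCANONICAL: 3}


def _find_all(seq: str, pattern: str) -> list[int]:
    """All 0-based start positions of ``pattern`` in ``seq`` (overlaps allowed)."""
    hits = []
    start = seq.find(pattern)
    while start != -1:
        hits.append(start)
        start = seq.find(pattern, start + 1)
    return hits


def scan_motifs(record: UTRRecord, config: MotifConfig = MotifConfig()) -> list[MotifHit]:
    """Report every CPE and PAS occurrence in a canonical-form UTR.

    Overlapping hits across classes are all reported. Within the canonical
    CPE class, co-start matches collapse to the longest (UUUUAAU preferred
    over UUUUAU at the same start); the G-variant is extended to UUUUGUA
    when the next base is A.
    """
    seq = record.sequence
    n = len(seq)
    hits: list[MotifHit] = []

    def add(cls: str, start0: int, matched: str) -> None:
        end = start0 + len(matched)  # 1-based inclusive end == 0-based exclusive
        hits.append(
            MotifHit(record.id, cls, start0 + 1, end, matched, n - end)
        )

    # canonical CPE: longest match at each start
    canon = sorted(config.cpe_canonical, key=len, reverse=True)
    starts_seen: set[int] = set()
    for pat in canon if config.collapse_nested else config.cpe_canonical:
        for s in _find_all(seq, pat):
            if config.collapse_nested and s in starts_seen:
                continue
            starts_seen.add(s)
            add(CPE_CANONICAL, s, pat)

    # G-variant, extended when followed by A
    for s in _find_all(seq, config.cpe_g):
        ext_len = len(config.cpe_g_extended)
        if seq[s : s + ext_len] == config.cpe_g_extended:
            add(CPE_G, s, config.cpe_g_extended)
        else:
            add(CPE_G, s, config.cpe_g)

    for pat in config.pas_canonical:
        for s in _find_all(seq, pat):
            add(PAS_CANONICAL, s, pat)
    for pat in config.pas_noncanonical:
        for s in _find_all(seq, pat):
            add(PAS_NONCANONICAL, s, pat)

    hits.sort(key=lambda h: (h.start, _CLASS_ORDER[h.motif_class], h.end))
    return hits


@dataclass(frozen=True)
class UTRArchitecture:
    """Derived cis-element architecture of one UTR."""

    record_id: str
    n_cpe_canonical: int
    n_cpe_g: int
    n_pas: int
    nearest_cpe_to_pas_distance: int | None
    pas_within_window: bool
    predicted_regulated: bool
    features: dict = field(default_factory=dict)


def classify_architecture(
    hits: list[MotifHit], length: int, config: MotifConfig = MotifConfig()
) -> UTRArchitecture:
    """Classify a UTR as predicted CPEB-regulated from its motif hits.

    Predicted regulated requires >=1 CPE (canonical or G-variant) and a PAS
    hexamer whose end lies within ``config.max_pas_to_end`` nt of the 3'
    end. CPE-PAS distances run from the end of the CPE to the start of the
    PAS (negative when the CPE lies downstream of the PAS).
    """
    for h in hits:
        if h.end > length or h.start < 1:
            raise ValueError(
                f"hit [{h.start},{h.end}] outside sequence of length {length}"
            )
    cpes = [h for h in hits if h.motif_class in (CPE_CANONICAL, CPE_G)]
    pases = [h for h in hits if h.motif_class in (PAS_CANONICAL, PAS_NONCANONICAL)]
    record_id = hits[0].record_id if hits else ""

    pas_in_window = [p for p in pases if p.dist_to_3end <= config.max_pas_to_end]
    pas_within_window = len(pas_in_window) > 0

    nearest: int | None = None
    if cpes and pases:
        # distance end-of-CPE to start-of-PAS, smallest magnitude
        dists = [p.start - c.end for c in cpes for p in pases]
        nearest = min(dists, key=abs)

    n_cpe_canonical = sum(h.motif_class == CPE_CANONICAL for h in cpes)
    n_cpe_g = sum(h.motif_class == CPE_G for h in cpes)
    predicted = (n_cpe_canonical + n_cpe_g >= 1) and pas_within_window

    features = {
        "n_cpe_canonical": n_cpe_canonical,
        "n_cpe_g": n_cpe_g,
        "n_pas_canonical": sum(h.motif_class == PAS_CANONICAL for h in pases),
        "n_pas_noncanonical": sum(h.motif_class == PAS_NONCANONICAL for h in pases),
        "n_pas_in_window": len(pas_in_window),
        "min_pas_dist_to_3end": min((p.dist_to_3end for p in pases), default=None),
        "nearest_cpe_to_pas_distance": nearest,
        "utr_length": length,
    }
    return UTRArchitecture(
        record_id=record_id,
        n_cpe_canonical=n_cpe_canonical,
        n_cpe_g=n_cpe_g,
        n_pas=len(pases),
        nearest_cpe_to_pas_distance=nearest,
        pas_within_window=pas_within_window,
        predicted_regulated=predicted,
        features=features,
    )


def pas_distance_qc(
    records: list[UTRRecord],
    hits_by_record: dict[str, list[MotifHit]],
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record PAS-to-3'-end distance table plus group medians.

    ``groups`` optionally maps record id -> group label (e.g. target /
    non-target); the summary reports median PAS distance and median UTR
    length per group. Records with no PAS are flagged (``has_pas`` False)
    and excluded from the distance median.
    """
    if not records:
        raise ValueError("pas_distance_qc requires a non-empty record set")
    rows = []
    for rec in records:
        hits = hits_by_record.get(rec.id, [])
        pases = [
            h for h in hits if h.motif_class in (PAS_CANONICAL, PAS_NONCANONICAL)
        ]
        dist = min((p.dist_to_3end for p in pases), default=np.nan)
        rows.append(
            {
                "record_id": rec.id,
                "utr_length": rec.length,
                "has_pas": bool(pases),
                "pas_dist_to_3end": dist,
                "group": (groups or {}).get(rec.id, "all"),
            }
        )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("group")
        .agg(
            n=("record_id", "size"),
            median_utr_length=("utr_length", "median"),
            median_pas_dist=("pas_dist_to_3end", "median"),
            frac_with_pas=("has_pas", "mean"),
        )
        .reset_index()
    )
    return table, summary


def compare_oligos(a: str, b: str) -> list[int]:
    """1-based positions where two equal-length sequences differ, ascending."""
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": h.record_id,
                "motif_class": h.motif_class,
                "start": h.start,
                "end": h.end,
                "matched_seq": h.matched_seq,
                "dist_to_3end": h.dist_to_3end,
            }
            for h in hits
        ],
        columns=["record_id", "motif_class", "start", "end", "matched_seq", "dist_to_3end"],
    )
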