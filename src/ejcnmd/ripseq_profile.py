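"""RIP-Seq footprint positional analysis.

Filtering, barcode-based PCR-duplicate removal, per-feature counting and
RPKM, junction-anchored meta-exon coverage/end profiles, detection of the
EJC-protected interval, and replicate correlation.

The meta-exon profile pools internal exons of multi-exon APPRIS-principal
transcripts and records, over a 75-nt window anchored at the exon 5' end
and another anchored at the exon 3' end, the per-offset read depth and the
number of read 5'/3' ends (in transcription orientation).  EJC footprints
deplete read ends over the protected RNA segment, so the deposition site
appears as a contiguous run of near-zero end counts just upstream of exon
3' ends; :func:`detect_deposition_site` extracts that run and reports its
midpoint (canonically -24).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation3ui import TranscriptModel, select_isoforms

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FootprintAlignment:
    """One aligned footprint read (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    random_barcode: Optional[str] = None
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.read_id}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def end5(self) -> int:
        """Genomic 0-based position of the read 5' end (transcription sense)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def end3(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def read_sam(path: str | Path, barcode_tag: str = "RX") -> list[FootprintAlignment]:
    """Load alignments from SAM/BAM.

    The random barcode comes from the RX-style tag, falling back to the
    read-name suffix after the last underscore.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            if a.has_tag(barcode_tag):
                bc = a.get_tag(barcode_tag)
            elif "_" in a.query_name:
                bc = a.query_name.rsplit("_", 1)[1]
            else:
                bc = None
            out.append(
                FootprintAlignment(
                    a.reference_name,
                    a.reference_start,
                    a.reference_end,
                    "-" if a.is_reverse else "+",
                    a.mapping_quality,
                    bc,
                    a.query_name,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Filtering and deduplication
# ---------------------------------------------------------------------------


def filter_alignments(
    alignments: Iterable[FootprintAlignment],
    min_mapq: int = 60,
    min_len: int = 20,
) -> list[FootprintAlignment]:
    """Keep alignments with mapq >= min_mapq and length >= min_len."""
    return [a for a in alignments if a.mapq >= min_mapq and a.length >= min_len]


def deduplicate_footprints(
    alignments: Sequence[FootprintAlignment],
) -> list[FootprintAlignment]:
    """Collapse PCR duplicates: same coordinates and same random barcode.

    Among alignments sharing (chrom, start, end, strand) and barcode the
    first in input order is kept; output order is stable.
    """
    seen: set[tuple] = set()
    out = []
    for a in alignments:
        if a.random_barcode is None:
            raise ValueError(f"read {a.read_id!r} has no random barcode")
        key = (a.chrom, a.start, a.end, a.strand, a.random_barcode)
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# Feature counting and RPKM
# ---------------------------------------------------------------------------


def count_features(
    alignments: Iterable[FootprintAlignment],
    transcripts: Sequence[TranscriptModel],
    level: str = "gene",
) -> pd.Series:
    """Count reads per gene (or per exon/intron region set).

    A read increments a feature only when it overlaps features of exactly
    one gene; reads touching two genes are discarded as ambiguous.
    """
    if level not in ("gene", "region"):
        raise ValueError(f"unknown level {level!r}")
    # exon interval index per chromosome
    ivals: dict[str, list[tuple[int, int, str]]] = {}
    for t in transcripts:
        for e in t.exons:
            ivals.setdefault(e.chrom, []).append((e.start, e.end, t.gene_id))
    index = {chrom: sorted(v) for chrom, v in ivals.items()}
    starts = {c: np.array([x[0] for x in v]) for c, v in index.items()}
    max_exon = {c: max(e - s for s, e, _ in v) for c, v in index.items()}

    counts: dict[str, int] = {t.gene_id: 0 for t in transcripts}
    for a in alignments:
        v = index.get(a.chrom)
        if v is None:
            continue
        st = starts[a.chrom]
        i0 = int(np.searchsorted(st, a.start - max_exon[a.chrom]))
        i1 = int(np.searchsorted(st, a.end))
        hits = {
            gid for s, e, gid in v[i0:i1] if s < a.end and a.start < e
        }
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
    return pd.Series(counts, name="count").sort_index()


def region_rpkm(
    counts: Mapping[str, float] | pd.Series,
    lengths: Mapping[str, float] | pd.Series,
    library_size: float,
) -> pd.Series:
    """RPKM = count / (length_kb * library_size_millions)."""
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all region lengths must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return counts / (lengths / 1e3) / (library_size / 1e6)


def compare_rpkm_groups(
    rpkm: pd.Series, group_a: Sequence[str], group_b: Sequence[str]
) -> dict:
    """Rank-sum comparison of two region groups (e.g. exonic vs intronic)."""
    a = rpkm.reindex(group_a).dropna().to_numpy()
    b = rpkm.reindex(group_b).dropna().to_numpy()
    stat, p = stats.ranksums(a, b)
    return {
        "median_a": float(np.median(a)) if a.size else math.nan,
        "median_b": float(np.median(b)) if b.size else math.nan,
        "statistic": float(stat),
        "p_value": float(p),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


# ---------------------------------------------------------------------------
# Meta-exon profile
# ---------------------------------------------------------------------------


@dataclass
class MetaExonProfile:
    """Pooled junction-anchored coverage and read-end tracks.

    ``coverage_*`` are unit-sum densities; ``end5_counts``/``end3_counts``
    are raw read-end counts (their sums equal the number of read ends
    falling inside the windows).  Offsets on the 5' anchor run 0..window-1
    downstream of exon starts; on the 3' anchor they run -window..-1
    upstream of exon ends (offset -1 = last exonic base).
    """

    window: int
    coverage_5anchor: np.ndarray
    coverage_3anchor: np.ndarray
    end5_counts: dict[str, np.ndarray]
    end3_counts: dict[str, np.ndarray]
    n_exons_used: int

    def offsets_3anchor(self) -> np.ndarray:
        return np.arange(-self.window, 0)

    def offsets_5anchor(self) -> np.ndarray:
        return np.arange(self.window)

    def end_density(self, which: str, anchor: str = "3anchor") -> np.ndarray:
        counts = (self.end5_counts if which == "end5" else self.end3_counts)[anchor]
        total = counts.sum()
        return counts / total if total > 0 else counts.astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor": ["5anchor"] * self.window + ["3anchor"] * self.window,
                "offset": np.r_[self.offsets_5anchor(), self.offsets_3anchor()],
                "coverage": np.r_[self.coverage_5anchor, self.coverage_3anchor],
                "end5": np.r_[self.end5_counts["5anchor"], self.end5_counts["3anchor"]],
                "end3": np.r_[self.end3_counts["5anchor"], self.end3_counts["3anchor"]],
            }
        )


def meta_exon_profile(
    alignments: Sequence[FootprintAlignment],
    transcripts: Sequence[TranscriptModel],
    window: int = 75,
    min_exon_len: int = 150,
    min_exon_reads: int = 10,
) -> MetaExonProfile:
    """Pool coverage and read-end counts over eligible internal exons.

    Eligible exons are the internal (neither first nor last) exons of
    multi-exon APPRIS-principal transcripts, at least ``min_exon_len`` nt
    long (so the two anchors never overlap) and overlapped by at least
    ``min_exon_reads`` reads.  Offsets are strand-aware.
    """
    principal = select_isoforms(transcripts, "appris_principal")
    exons = []
    for t in principal:
        if t.n_exons >= 3:
            exons.extend(t.exons[1:-1])
    exons = [e for e in exons if len(e) >= min_exon_len]
    if not exons:
        raise ValueError("no eligible internal exons for the meta-exon profile")

    by_chrom: dict[str, list[FootprintAlignment]] = {}
    for a in alignments:
        by_chrom.setdefault(a.chrom, []).append(a)
    starts = {}
    for c, rs in by_chrom.items():
        rs.sort(key=lambda a: a.start)
        starts[c] = np.array([a.start for a in rs])
    max_len = max((a.length for a in alignments), default=0)

    cov5 = np.zeros(window)
    cov3 = np.zeros(window)
    e5 = {"5anchor": np.zeros(window, dtype=int), "3anchor": np.zeros(window, dtype=int)}
    e3 = {"5anchor": np.zeros(window, dtype=int), "3anchor": np.zeros(window, dtype=int)}
    n_used = 0

    for exon in exons:
        rs = by_chrom.get(exon.chrom)
        if not rs:
            continue
        st = starts[exon.chrom]
        i0 = int(np.searchsorted(st, exon.start - max_len))
        i1 = int(np.searchsorted(st, exon.end))
        overlapping = [
            a for a in rs[i0:i1] if a.end > exon.start and a.start < exon.end
        ]
        if len(overlapping) < min_exon_reads:
            continue
        n_used += 1
        for a in overlapping:
            _accumulate(exon, a, window, cov5, cov3, e5, e3)

    if n_used == 0:
        raise ValueError("no exon passed the read-count eligibility filter")
    for cov in (cov5, cov3):
        total = cov.sum()
        if total > 0:
            cov /= total
    return MetaExonProfile(window, cov5, cov3, e5, e3, n_used)


def _accumulate(exon, a, window, cov5, cov3, e5, e3):
    """Add one read's coverage and ends to both anchor windows."""
    # transcription-sense offset of a genomic position from each anchor
    if exon.strand == "+":
        off5 = lambda pos: pos - exon.start  # 0 at first exonic base
        off3 = lambda pos: pos - exon.end  # -1 at last exonic base
        span = (a.start, a.end - 1)
    else:
        off5 = lambda pos: exon.end - 1 - pos
        off3 = lambda pos: exon.start - 1 - pos
        span = (a.end - 1, a.start)  # transcription order

    # coverage over the clipped window intervals
    lo5 = max(0, min(off5(span[0]), off5(span[1])))
    hi5 = min(window - 1, max(off5(span[0]), off5(span[1])))
    if lo5 <= hi5:
        cov5[lo5 : hi5 + 1] += 1
    lo3 = max(-window, min(off3(span[0]), off3(span[1])))
    hi3 = min(-1, max(off3(span[0]), off3(span[1])))
    if lo3 <= hi3:
        cov3[window + lo3 : window + hi3 + 1] += 1

    for which, store in ((a.end5, e5), (a.end3, e3)):
        o5, o3 = off5(which), off3(which)
        if 0 <= o5 < window:
            store["5anchor"][o5] += 1
        if -window <= o3 <= -1:
            store["3anchor"][window + o3] += 1


# ---------------------------------------------------------------------------
# Deposition-site detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepositionCall:
    """Detected EJC-protected interval on the 3'-anchor end profile."""

    mode_offset: int
    protected_interval: tuple[int, int]
    width: int


def detect_deposition_site(
    profile: MetaExonProfile,
    search_window: tuple[int, int] = (-40, -10),
    depletion_fraction: float = 0.2,
    min_run: int = 3,
) -> Optional[DepositionCall]:
    """Locate the end-count-depleted interval upstream of exon 3' ends.

    Within the search window, the protected interval is the maximal
    contiguous run of offsets where both the 5'-end and 3'-end densities
    fall below ``depletion_fraction`` times their respective in-window
    maxima.  The mode is the run's integer midpoint with half-offsets
    rounded toward the junction.  Returns None (with a warning) when no run
    of length >= ``min_run`` exists.
    """
    if not 0 < depletion_fraction < 1:
        raise ValueError("depletion_fraction must be in (0, 1)")
    lo, hi = search_window
    if lo < -profile.window or hi >= 0:
        raise ValueError("search window must lie inside the 3'-anchor window")
    offsets = profile.offsets_3anchor()
    mask = (offsets >= lo) & (offsets <= hi)
    d5 = profile.end_density("end5")[mask]
    d3 = profile.end_density("end3")[mask]
    win_offsets = offsets[mask]
    if d5.max() == 0 or d3.max() == 0:
        logger.warning("no read ends in the search window")
        return None
    depleted = (d5 < depletion_fraction * d5.max()) & (
        d3 < depletion_fraction * d3.max()
    )

    best = None  # (length, start_idx)
    i = 0
    while i < len(depleted):
        if depleted[i]:
            j = i
            while j + 1 < len(depleted) and depleted[j + 1]:
                j += 1
            if best is None or (j - i + 1) > best[0]:
                best = (j - i + 1, i)
            i = j + 1
        else:
            i += 1
    if best is None or best[0] < min_run:
        logger.warning("no depleted run of length >= %d in the search window", min_run)
        return None
    length, start = best
    a = int(win_offsets[start])
    b = int(win_offsets[start + length - 1])
    mode = math.ceil((a + b) / 2)  # half-offsets round toward the junction
    return DepositionCall(mode, (a, b), length)


# ---------------------------------------------------------------------------
# Replicate correlation
# ---------------------------------------------------------------------------


def replicate_correlation(
    counts_a: pd.Series | Sequence[float],
    counts_b: pd.Series | Sequence[float],
    pseudocount: float = 0.0001,
) -> tuple[float, float]:
    """Pearson r and p on log2(count + pseudocount) vectors."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("replicate vectors must share a universe of >= 3 genes")
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(la, lb)
    return float(r), float(p)
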