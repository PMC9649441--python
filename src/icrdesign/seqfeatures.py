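"""CpG/GC sequence statistics, fixed-window genome scans, and profile-based
"sequence twin" search.

N handling: Ns are excluded from both numerator and denominator of every GC
fraction; windows with more than ``max_n_fraction`` Ns are skipped in scans.
CpG density per 100 bp uses the total window length.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np

from .core import CpGGrid, GenomicSequence, as_text, cpg_positions

log = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (1.0, 1.0, 1.0)


class UndefinedGCError(ValueError):
    """GC fraction is undefined (no non-N bases)."""


@dataclass(frozen=True)
class SequenceProfile:
    """Compositional profile of one sequence or genome window."""

    length: int
    gc_fraction: float
    cpg_count: int
    cpg_per_100bp: float
    local_gc: tuple[float, ...]
    local_window: int
    local_step: int
    last_tile_partial: bool
    cpg_spacings: tuple[int, ...]
    source: Optional[Tuple[str, int, int]] = None  # (contig, start, end)

    def __post_init__(self):
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction out of [0,1]: {self.gc_fraction}")


def _gc_fraction(text: str) -> float:
    n_n = text.count("N")
    denom = len(text) - n_n
    if denom == 0:
        raise UndefinedGCError("GC fraction undefined: sequence is all N")
    return (text.count("G") + text.count("C")) / denom


def profile_sequence(
    seq,
    local_window: int = 100,
    local_step: int = 100,
    source: Optional[Tuple[str, int, int]] = None,
) -> SequenceProfile:
    """Compute length, GC fraction, CpG count/density, per-tile GC, and the
    CpG spacing list for one sequence.

    Tiles are half-open ``[s, s+local_window)`` at ``local_step``; a final
    partial tile is included and flagged via ``last_tile_partial``.
    """
    if local_window < 1 or local_step < 1:
        raise ValueError("local_window and local_step must be >= 1")
    text = as_text(seq)
    length = len(text)
    gc = _gc_fraction(text)  # raises UndefinedGCError on all-N input
    grid = CpGGrid.from_sequence(text)
    local_gc = []
    partial = False
    for s in range(0, length, local_step):
        tile = text[s : s + local_window]
        if s + local_window > length:
            partial = True
        try:
            local_gc.append(_gc_fraction(tile))
        except UndefinedGCError:
            local_gc.append(float("nan"))
    if source is None and isinstance(seq, GenomicSequence) and seq.source is not None:
        contig, start = seq.source
        source = (contig, start, start + length)
    return SequenceProfile(
        length=length,
        gc_fraction=gc,
        cpg_count=len(grid),
        cpg_per_100bp=len(grid) * 100.0 / length,
        local_gc=tuple(local_gc),
        local_window=local_window,
        local_step=local_step,
        last_tile_partial=partial,
        cpg_spacings=tuple(grid.spacings()),
        source=source,
    )


@dataclass
class ScanStats:
    windows_emitted: int = 0
    windows_skipped_n: int = 0
    contigs_shorter_than_window: int = 0


def genome_window_scan(
    genome: Iterable[GenomicSequence],
    window: int = 1000,
    step: Optional[int] = None,
    max_n_fraction: float = 0.1,
    local_window: int = 100,
    local_step: int = 100,
    stats_out: Optional[ScanStats] = None,
) -> Iterator[SequenceProfile]:
    """Emit one profile per fully-contained window per contig, in input
    order then left to right. Windows with more than ``max_n_fraction`` Ns
    are skipped and counted in ``stats_out``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step is None:
        step = window
    if step < 1:
        raise ValueError("step must be >= 1")
    stats_ = stats_out if stats_out is not None else ScanStats()
    for contig in genome:
        text = contig.seq
        if len(text) < window:
            stats_.contigs_shorter_than_window += 1
            continue
        for start in range(0, len(text) - window + 1, step):
            sub = text[start : start + window]
            if sub.count("N") > max_n_fraction * window:
                stats_.windows_skipped_n += 1
                continue
            stats_.windows_emitted += 1
            yield profile_sequence(
                sub,
                local_window=local_window,
                local_step=local_step,
                source=(contig.id, start, start + window),
            )


@dataclass(frozen=True)
class TwinCandidate:
    """One genome window ranked by profile distance to the query."""

    contig: str
    start: int
    end: int
    profile: SequenceProfile
    distance: float


def spacing_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """Kolmogorov-Smirnov statistic between two CpG-spacing empirical
    distributions. Both empty -> 0; exactly one empty -> 1 (maximal)."""
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return 1.0
    return _ks_statistic(np.sort(np.asarray(a)), np.sort(np.asarray(b)))


def _ks_statistic(a_sorted: np.ndarray, b_sorted: np.ndarray) -> float:
    """Two-sample KS statistic on pre-sorted arrays (exact sup-distance of
    the empirical CDFs, equal to scipy.stats.ks_2samp(...).statistic)."""
    grid = np.concatenate([a_sorted, b_sorted])
    cdf_a = np.searchsorted(a_sorted, grid, side="right") / a_sorted.size
    cdf_b = np.searchsorted(b_sorted, grid, side="right") / b_sorted.size
    return float(np.abs(cdf_a - cdf_b).max())


def profile_distance(
    query: SequenceProfile,
    other: SequenceProfile,
    weights: Tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Weighted pseudo-metric on profiles: |dGC| + relative |dCpG count| +
    spacing KS distance. Symmetric, non-negative, zero on identical profiles."""
    w_gc, w_cpg, w_sp = weights
    ref_cpg = max(max(query.cpg_count, other.cpg_count), 1)
    d = w_gc * abs(query.gc_fraction - other.gc_fraction)
    d += w_cpg * abs(query.cpg_count - other.cpg_count) / ref_cpg
    d += w_sp * spacing_distance(query.cpg_spacings, other.cpg_spacings)
    return d


def _contig_partial_distances(
    text: str,
    qlen: int,
    qgc: float,
    qcpg: int,
    weights: Tuple[float, float, float],
    max_n_fraction: float,
    step: int,
):
    """Vectorized lower-bound distance (GC + CpG-count terms only) for every
    window offset of one contig. Returns (offsets, partial, gc, cpg)."""
    n = len(text)
    if n < qlen:
        return (np.empty(0, int),) * 4
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_n = arr == ord("N")
    is_cg = np.zeros(n, dtype=bool)
    is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    gc_cum = np.concatenate(([0], np.cumsum(is_gc)))
    n_cum = np.concatenate(([0], np.cumsum(is_n)))
    cg_cum = np.concatenate(([0], np.cumsum(is_cg)))

    offsets = np.arange(0, n - qlen + 1, step)
    gc_counts = gc_cum[offsets + qlen] - gc_cum[offsets]
    n_counts = n_cum[offsets + qlen] - n_cum[offsets]
    # CG start fully inside the window: start in [o, o + qlen - 1)
    cpg_counts = cg_cum[offsets + qlen - 1] - cg_cum[offsets]

    ok = n_counts <= max_n_fraction * qlen
    denom = qlen - n_counts
    ok &= denom > 0
    gc = np.where(denom > 0, gc_counts / np.maximum(denom, 1), np.nan)
    w_gc, w_cpg, _ = weights
    ref_cpg = np.maximum(np.maximum(cpg_counts, qcpg), 1)
    partial = w_gc * np.abs(gc - qgc) + w_cpg * np.abs(cpg_counts - qcpg) / ref_cpg
    return offsets[ok], partial[ok], gc[ok], cpg_counts[ok]


def find_twins(
    query: SequenceProfile,
    genome: Iterable[GenomicSequence],
    top_k: int = 5,
    weights: Tuple[float, float, float] = DEFAULT_WEIGHTS,
    step: int = 1,
    max_n_fraction: float = 0.1,
    max_full_evaluations: int = 500000,
) -> list[TwinCandidate]:
    """Rank genome windows of the query's length by profile distance.

    The GC and CpG-count terms are computed for every offset with prefix
    sums; they lower-bound the full distance, so the expensive spacing term
    is only evaluated in ascending lower-bound order until the bound proves
    no unevaluated window can enter the top ``top_k``. Overlapping windows
    are merged to the best-scoring offset. Output is sorted by (distance,
    contig, start); ordering is deterministic.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    contigs = list(genome)
    if not contigs:
        warnings.warn("find_twins: empty genome, returning no candidates")
        return []
    qlen = query.length
    q_spac = np.sort(np.asarray(query.cpg_spacings, dtype=float))
    w_sp = weights[2]

    entries = []  # (partial_distance, contig_index, offset)
    texts = {}
    cgpos = {}
    for ci, contig in enumerate(sorted(contigs, key=lambda c: c.id)):
        texts[ci] = (contig.id, contig.seq)
        cgpos[ci] = np.asarray(cpg_positions(contig.seq), dtype=np.int64)
        offs, partial, _, _ = _contig_partial_distances(
            contig.seq, qlen, query.gc_fraction, query.cpg_count, weights,
            max_n_fraction, step,
        )
        for o, p in zip(offs.tolist(), partial.tolist()):
            entries.append((p, ci, o))
    if not entries:
        warnings.warn("find_twins: no scannable windows (contigs too short?)")
        return []

    def window_spacings(ci: int, off: int) -> np.ndarray:
        pos = cgpos[ci]
        i0 = np.searchsorted(pos, off, side="left")
        i1 = np.searchsorted(pos, off + qlen - 1, side="left")
        return np.diff(pos[i0:i1]).astype(float)

    def full_distance(partial: float, ci: int, off: int) -> float:
        spac = window_spacings(ci, off)
        if q_spac.size == 0 and spac.size == 0:
            ks = 0.0
        elif q_spac.size == 0 or spac.size == 0:
            ks = 1.0
        else:
            ks = _ks_statistic(q_spac, np.sort(spac))
        return partial + w_sp * ks

    heapq.heapify(entries)
    accepted: list[tuple[float, str, int, int]] = []  # (dist, contig, start, ci)
    evaluated = 0
    while entries:
        partial, ci, off = heapq.heappop(entries)
        if len(accepted) >= top_k:
            kth = sorted(a[0] for a in accepted)[top_k - 1]
            if partial > kth:
                break
        if evaluated >= max_full_evaluations:
            log.warning("find_twins: evaluation cap reached (%d)", evaluated)
            break
        name, text = texts[ci]
        dist = full_distance(partial, ci, off)
        evaluated += 1
        cand = (dist, name, off, ci)
        # merge overlapping windows to the best-scoring offset
        keep = True
        for i, acc in enumerate(accepted):
            if acc[1] == name and acc[2] < off + qlen and off < acc[2] + qlen:
                if (dist, name, off) < (acc[0], acc[1], acc[2]):
                    accepted[i] = cand
                keep = False
                break
        if keep:
            accepted.append(cand)
    accepted.sort(key=lambda c: (c[0], c[1], c[2]))
    out = []
    for dist, name, off, ci in accepted[:top_k]:
        sub = texts[ci][1][off : off + qlen]
        prof = profile_sequence(sub, query.local_window, query.local_step,
                                source=(name, off, off + qlen))
        out.append(TwinCandidate(name, off, off + qlen, prof, dist))
    return out


def is_cpg_island_gg(profile: SequenceProfile) -> bool:
    """Gardiner-Garden CpG-island heuristic (optional extra, not part of the
    core similarity search): length >= 200, GC > 0.5, observed/expected
    CpG > 0.6 under the profile's own GC content."""
    if profile.length < 200 or profile.gc_fraction <= 0.5:
        return False
    exp = (profile.gc_fraction / 2) ** 2 * profile.length
    return exp > 0 and profile.cpg_count / exp > 0.6
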