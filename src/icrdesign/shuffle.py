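"""Constrained inter-CpG sequence shuffling.

The shuffler permutes only the bases between CpG dinucleotides, so the
number and position of every CpG is preserved exactly. Permutation happens
within fixed tiles (default 100 bp), which preserves each tile's base
composition — and therefore its GC content — exactly. On top of the tile
permutation, a repair pass removes CG dinucleotides and forbidden motifs
created at random, and a hill-climb of constrained pair swaps drives the
mismatch to the requested target (or maximizes it).

All randomness flows from the mandatory seed; identical seed + constraints
+ input give byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .core import GenomicSequence, as_text, cpg_positions, reverse_complement
from .motifscan import ZFP57_HEXAMER, MotifHit

MAXIMIZE = "maximize"

#: default forbidden motif: the ZFP57 hexanucleotide, checked on both strands
DEFAULT_FORBIDDEN = (ZFP57_HEXAMER,)


@dataclass(frozen=True)
class ShuffleConstraints:
    """Knobs of the constrained shuffle. ``target_mismatch`` is a fraction
    in (0, 1] or the string ``MAXIMIZE``."""

    target_mismatch: Union[float, str] = MAXIMIZE
    local_gc_window: int = 100
    local_gc_tolerance: float = 0.0
    forbid_new_cpg: bool = True
    forbid_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN
    max_iterations: int = 100000
    seed: int = 0

    def __post_init__(self):
        if self.target_mismatch != MAXIMIZE:
            t = float(self.target_mismatch)
            if not 0.0 < t <= 1.0:
                raise ValueError("target_mismatch must be in (0, 1] or MAXIMIZE")
        if not 0.0 <= self.local_gc_tolerance < 0.5:
            raise ValueError("local_gc_tolerance must be in [0, 0.5)")
        if self.local_gc_window < 1:
            raise ValueError("local_gc_window must be >= 1")


@dataclass(frozen=True)
class ConstraintAudit:
    """Independent post-hoc verification of every shuffle constraint."""

    grid_identical: bool
    base_multiset_identical: bool
    max_tile_gc_deviation: float
    novel_cpgs: int
    forbidden_motif_hits: int

    @property
    def all_passed(self) -> bool:
        return (
            self.grid_identical
            and self.base_multiset_identical
            and self.novel_cpgs == 0
            and self.forbidden_motif_hits == 0
        )


@dataclass(frozen=True)
class ShuffleResult:
    original: GenomicSequence
    shuffled: GenomicSequence
    mismatch_inter_cpg: float
    mismatch_total: float
    iterations_used: int
    status: str  # "reached" | "not_reached" | "maximized" | "degenerate"
    audit: ConstraintAudit
    seed: int
    trajectory: tuple[float, ...] = ()  # accepted hill-climb mismatch values


def mismatch(a, b, mask: str = "ALL") -> float:
    """Fraction of masked positions at which two equal-length strings
    differ. ``INTER_CPG`` masks out the CpG dinucleotide positions of ``a``.
    Empty mask returns 0 with a warning."""
    ta, tb = as_text(a), as_text(b)
    if len(ta) != len(tb):
        raise ValueError(f"length mismatch: {len(ta)} vs {len(tb)}")
    if mask == "ALL":
        idx = range(len(ta))
        total = len(ta)
    elif mask == "INTER_CPG":
        fixed = set()
        for p in cpg_positions(ta):
            fixed.add(p)
            fixed.add(p + 1)
        idx = [i for i in range(len(ta)) if i not in fixed]
        total = len(idx)
    else:
        raise ValueError(f"unknown mask {mask!r}")
    if total == 0:
        warnings.warn("mismatch: empty mask, returning 0")
        return 0.0
    return sum(1 for i in idx if ta[i] != tb[i]) / total


def _forbidden_patterns(motifs: Iterable[str]) -> tuple[str, ...]:
    pats = set()
    for m in motifs:
        pats.add(m)
        pats.add(reverse_complement(m))
    return tuple(sorted(pats))


def _count_occurrences(text: str, patterns: Sequence[str]) -> int:
    total = 0
    for p in patterns:
        start = text.find(p)
        while start != -1:
            total += 1
            start = text.find(p, start + 1)
    return total


class _State:
    """Mutable shuffle state with local constraint checks."""

    def __init__(self, original: str, grid: list[int], constraints: ShuffleConstraints):
        self.orig = original
        self.seq = list(original)
        self.grid = set(grid)
        self.fixed = set()
        for p in grid:
            self.fixed.add(p)
            self.fixed.add(p + 1)
        self.inter = [i for i in range(len(original)) if i not in self.fixed]
        self.cons = constraints
        self.patterns = _forbidden_patterns(constraints.forbid_motifs)
        self.maxpat = max((len(p) for p in self.patterns), default=0)

    def tiles(self) -> dict[int, list[int]]:
        w = self.cons.local_gc_window
        out: dict[int, list[int]] = {}
        for i in self.inter:
            out.setdefault(i // w, []).append(i)
        return out

    def local_violations(self, positions: Iterable[int]) -> int:
        """Count novel CGs and forbidden motifs in windows around the given
        positions (enough context to see any pattern they take part in)."""
        n = 0
        text = self.seq
        L = len(text)
        spans = set()
        pad = max(self.maxpat, 2)
        for i in positions:
            lo, hi = max(0, i - pad + 1), min(L, i + pad)
            spans.add((lo, hi))
        for lo, hi in spans:
            window = "".join(text[lo:hi])
            if self.cons.forbid_new_cpg:
                s = window.find("CG")
                while s != -1:
                    if (lo + s) not in self.grid:
                        n += 1
                    s = window.find("CG", s + 1)
            for p in self.patterns:
                s = window.find(p)
                while s != -1:
                    n += 1
                    s = window.find(p, s + 1)
        return n

    def global_violations(self) -> list[int]:
        """Positions of all novel CGs and forbidden-motif starts."""
        text = "".join(self.seq)
        bad = []
        if self.cons.forbid_new_cpg:
            s = text.find("CG")
            while s != -1:
                if s not in self.grid:
                    bad.append(s)
                s = text.find("CG", s + 1)
        for p in self.patterns:
            s = text.find(p)
            while s != -1:
                bad.append(s)
                s = text.find(p, s + 1)
        return sorted(set(bad))

    def swap_ok(self, i: int, j: int) -> bool:
        """Try swapping seq[i] and seq[j]; keep only if no local constraint
        violation appears. Returns True if the swap was kept."""
        before = self.local_violations((i, j))
        self.seq[i], self.seq[j] = self.seq[j], self.seq[i]
        after = self.local_violations((i, j))
        if after > before:
            self.seq[i], self.seq[j] = self.seq[j], self.seq[i]
            return False
        return True


def _greedy_anti_match(bases: list[str], originals: list[str], rng) -> list[str]:
    """Assign the multiset ``bases`` to positions with original bases
    ``originals`` while making as few positions keep their original base as
    possible: repeatedly place the most abundant remaining base on positions
    whose original differs."""
    from collections import Counter

    counts = Counter(bases)
    n = len(originals)
    order = list(range(n))
    rng.shuffle(order)
    result: list[Optional[str]] = [None] * n
    unplaced = []
    for i in order:
        # most abundant base that differs from the original here
        candidates = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        placed = False
        for b, c in candidates:
            if c > 0 and b != originals[i]:
                result[i] = b
                counts[b] -= 1
                placed = True
                break
        if not placed:
            unplaced.append(i)
    for i in unplaced:  # forced matches: only the original base remains
        for b, c in counts.items():
            if c > 0:
                result[i] = b
                counts[b] -= 1
                break
    return result  # type: ignore[return-value]


def shuffle_inter_cpg(
    seq: GenomicSequence, constraints: ShuffleConstraints
) -> ShuffleResult:
    """Permute the inter-CpG bases of ``seq`` under the constraints.

    CpG dinucleotide positions are never touched; bases move only within
    their local-GC tile, so per-tile composition (and GC) is conserved
    exactly. Infeasible targets yield status ``"not_reached"`` with the best
    result found — never a silent partial result.
    """
    text = as_text(seq)
    if "N" in text:
        raise ValueError("shuffle_inter_cpg: sequence contains N (shuffling Ns is undefined)")
    grid = cpg_positions(text)
    state = _State(text, grid, constraints)
    rng = np.random.default_rng(constraints.seed)

    if not state.inter:
        audit = audit_shuffle(text, text, constraints)
        return ShuffleResult(
            _as_genomic(seq), _as_genomic(seq, suffix="_shuffled"),
            0.0, 0.0, 0, "degenerate", audit, constraints.seed,
        )

    # 1. per-tile anti-matching permutation (exact per-tile composition)
    tiles = state.tiles()
    for tile_idx in sorted(tiles):
        positions = tiles[tile_idx]
        bases = [text[i] for i in positions]
        originals = [text[i] for i in positions]
        assigned = _greedy_anti_match(bases, originals, rng)
        for i, b in zip(positions, assigned):
            state.seq[i] = b

    # 2. repair pass: dissolve novel CGs / forbidden motifs by same-tile swaps
    iterations = 0
    for _ in range(20 * len(state.inter) + 1000):
        bad = state.global_violations()
        if not bad:
            break
        pos = bad[int(rng.integers(len(bad)))]
        span = range(pos, min(pos + max(state.maxpat, 2), len(text)))
        movable = [i for i in span if i in set(state.inter)]
        if not movable:  # cannot happen: forbidden patterns always contain inter bases
            break
        i = movable[int(rng.integers(len(movable)))]
        tile = tiles[i // constraints.local_gc_window]
        j = tile[int(rng.integers(len(tile)))]
        if i == j or state.seq[i] == state.seq[j]:
            continue
        before = len(state.global_violations())
        state.seq[i], state.seq[j] = state.seq[j], state.seq[i]
        if len(state.global_violations()) > before:
            state.seq[i], state.seq[j] = state.seq[j], state.seq[i]
        iterations += 1

    # 3. hill-climb: constrained pair swaps that increase inter-CpG mismatch
    inter = state.inter
    n_inter = len(inter)
    mismatches = sum(1 for i in inter if state.seq[i] != text[i])
    target = constraints.target_mismatch
    want = None if target == MAXIMIZE else float(target)
    trajectory = [mismatches / n_inter]
    tile_keys = sorted(tiles)
    used = 0
    stall = 0
    max_stall = max(10000, 5 * n_inter)
    while used < constraints.max_iterations:
        if want is not None and mismatches / n_inter >= want:
            break
        if stall >= max_stall:
            break
        used += 1
        tk = tile_keys[int(rng.integers(len(tile_keys)))]
        tile = tiles[tk]
        if len(tile) < 2:
            stall += 1
            continue
        i = tile[int(rng.integers(len(tile)))]
        j = tile[int(rng.integers(len(tile)))]
        if i == j or state.seq[i] == state.seq[j]:
            stall += 1
            continue
        old = (state.seq[i] == text[i]) + (state.seq[j] == text[j])
        new = (state.seq[j] == text[i]) + (state.seq[i] == text[j])
        if new >= old:  # not an improvement
            stall += 1
            continue
        if state.swap_ok(i, j):
            mismatches += old - new
            trajectory.append(mismatches / n_inter)
            stall = 0
        else:
            stall += 1

    shuffled_text = "".join(state.seq)
    m_inter = mismatch(text, shuffled_text, "INTER_CPG")
    m_total = mismatch(text, shuffled_text, "ALL")
    if want is None:
        status = "maximized"
    else:
        status = "reached" if m_inter >= want else "not_reached"
    audit = audit_shuffle(text, shuffled_text, constraints)
    return ShuffleResult(
        _as_genomic(seq),
        GenomicSequence(_as_genomic(seq).id + "_shuffled", shuffled_text),
        m_inter,
        m_total,
        used,
        status,
        audit,
        constraints.seed,
        tuple(trajectory),
    )


def _as_genomic(seq, suffix: str = "") -> GenomicSequence:
    if isinstance(seq, GenomicSequence):
        if suffix:
            return GenomicSequence(seq.id + suffix, seq.seq, seq.source)
        return seq
    return GenomicSequence("seq" + suffix, seq)


def audit_shuffle(
    original, shuffled, constraints: ShuffleConstraints
) -> ConstraintAudit:
    """Verify every shuffle constraint from scratch on a pair of sequences."""
    a, b = as_text(original), as_text(shuffled)
    grid_a, grid_b = cpg_positions(a), cpg_positions(b)
    w = constraints.local_gc_window
    max_dev = 0.0
    for s in range(0, len(a), w):
        ta, tb = a[s : s + w], b[s : s + w]
        if ta:
            gca = (ta.count("G") + ta.count("C")) / len(ta)
            gcb = (tb.count("G") + tb.count("C")) / len(tb)
            max_dev = max(max_dev, abs(gca - gcb))
    novel = len(set(grid_b) - set(grid_a)) if constraints.forbid_new_cpg else 0
    forb = _count_occurrences(b, _forbidden_patterns(constraints.forbid_motifs))
    return ConstraintAudit(
        grid_identical=grid_a == grid_b,
        base_multiset_identical=sorted(a) == sorted(b),
        max_tile_gc_deviation=max_dev,
        novel_cpgs=novel,
        forbidden_motif_hits=forb,
    )


@dataclass(frozen=True)
class ReconstitutionResult:
    sequence: GenomicSequence
    repaired_positions: tuple[int, ...]


def reconstitute_motifs(
    shuffled: GenomicSequence,
    original: GenomicSequence,
    hits: Sequence[MotifHit],
    return_report: bool = False,
):
    """Byte-copy the motif spans of ``original`` back into ``shuffled``.

    Hits must be located on the original sequence, in-bounds and
    non-overlapping. If the splice creates a CG dinucleotide across a span
    boundary that is not in the original grid, the base outside the span is
    repaired (C -> T on the left flank, G -> A on the right flank) and the
    repaired positions are reported.
    """
    st, ot = as_text(shuffled), as_text(original)
    if len(st) != len(ot):
        raise ValueError("shuffled and original must have the same length")
    spans = sorted((h.start, h.end) for h in hits)
    offenders = []
    prev_end = -1
    for s, e in spans:
        if s < 0 or e > len(ot) or s >= e:
            offenders.append((s, e, "out of bounds"))
        elif s < prev_end:
            offenders.append((s, e, "overlaps previous hit"))
        prev_end = max(prev_end, e)
    if offenders:
        raise ValueError(f"invalid motif hits: {offenders}")

    out = list(st)
    for s, e in spans:
        out[s:e] = ot[s:e]

    orig_grid = set(cpg_positions(ot))
    repaired = []
    for s, e in spans:
        # left junction: pair (s-1, s)
        if s >= 1 and out[s - 1] == "C" and out[s] == "G" and (s - 1) not in orig_grid:
            out[s - 1] = "T"
            repaired.append(s - 1)
        # right junction: pair (e-1, e)
        if e < len(out) and out[e - 1] == "C" and out[e] == "G" and (e - 1) not in orig_grid:
            out[e] = "A"
            repaired.append(e)
    result = GenomicSequence(
        (shuffled.id if isinstance(shuffled, GenomicSequence) else "seq")
        + "_reconstituted",
        "".join(out),
    )
    if return_report:
        return ReconstitutionResult(result, tuple(repaired))
    return result
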