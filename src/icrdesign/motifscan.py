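"""Motif scanning (exact IUPAC or PWM log-odds), disruption reports, and the
walking-replacement contribution scan with pluggable scorers.

Hit coordinates are always reported on the + strand (BED convention); the
strand is recorded separately. Overlapping hits are all reported.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .core import GenomicSequence, as_text, reverse_complement, validate_dna

ZFP57_HEXAMER = "TGCCGC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> str:
    parts = []
    for ch in pattern:
        try:
            opts = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif pattern") from None
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


@dataclass(frozen=True)
class MotifDef:
    """A motif as an IUPAC pattern or a position weight matrix.

    ``pwm`` rows are A, C, G, T over the motif length, columns summing to 1.
    """

    id: str = "ZFP57"
    pattern: Optional[str] = ZFP57_HEXAMER
    pwm: Optional[np.ndarray] = None
    scan_both_strands: bool = True

    def __post_init__(self):
        if self.pwm is not None:
            pwm = np.asarray(self.pwm, dtype=float)
            object.__setattr__(self, "pwm", pwm)
            if pwm.ndim != 2 or pwm.shape[0] != 4:
                raise ValueError("PWM must have shape (4, motif_length), rows A,C,G,T")
            if pwm.shape[1] < 2:
                raise ValueError("motif length must be >= 2")
            if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError("PWM columns must sum to 1 +/- 1e-9")
        elif self.pattern is not None:
            if len(self.pattern) < 2:
                raise ValueError("motif pattern length must be >= 2")
            _iupac_regex(self.pattern)  # validates the alphabet
        else:
            raise ValueError("MotifDef needs either a pattern or a PWM")

    @property
    def length(self) -> int:
        return self.pwm.shape[1] if self.pwm is not None else len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int
    end: int  # half-open
    strand: str  # "+" or "-"
    matched_text: str  # as read on the + strand
    contains_cpg: bool
    score: Optional[float] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end - self.start != len(self.matched_text):
            raise ValueError("hit span does not match matched_text length")


def _exact_hits(text: str, pattern: str, motif_id: str, strand: str) -> list[MotifHit]:
    rx = re.compile(f"(?=({_iupac_regex(pattern)}))")
    hits = []
    for m in rx.finditer(text):
        s, matched = m.start(), m.group(1)
        hits.append(
            MotifHit(motif_id, s, s + len(matched), strand, matched, "CG" in matched)
        )
    return hits


def _pwm_logodds_matrix(pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    eps = 1e-9
    return np.log2((pwm + eps) / (background[:, None] + eps))


def sequence_background(text: str, pseudocount: float = 0.5) -> np.ndarray:
    """Mononucleotide background from the sequence itself, with a
    pseudocount per base (A, C, G, T order)."""
    counts = np.array([text.count(b) for b in "ACGT"], dtype=float) + pseudocount
    return counts / counts.sum()


def _pwm_hits(
    text: str, motif: MotifDef, threshold: float, strand: str, motif_id: str
) -> list[MotifHit]:
    L = motif.length
    if len(text) < L:
        return []
    lom = _pwm_logodds_matrix(motif.pwm, sequence_background(text))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for s in range(len(text) - L + 1):
        window = text[s : s + L]
        if "N" in window:
            continue
        score = sum(lom[idx[b], j] for j, b in enumerate(window))
        if score >= threshold:
            hits.append(
                MotifHit(motif_id, s, s + L, strand, window, "CG" in window,
                         score=float(score))
            )
    return hits


def find_motifs(
    seq,
    motif: MotifDef = MotifDef(),
    pwm_threshold: Optional[float] = None,
) -> list[MotifHit]:
    """All motif occurrences on the + strand and, if enabled, the - strand
    (reported in + strand coordinates). Exact mode expands IUPAC codes; PWM
    mode keeps windows with log-odds >= ``pwm_threshold`` against the
    sequence's own base frequencies. Sorted by start, then + before -.
    """
    text = as_text(seq)
    if not text:
        raise ValueError("find_motifs: empty sequence")
    validate_dna(text)
    if motif.pwm is not None:
        thr = 0.0 if pwm_threshold is None else pwm_threshold
        hits = _pwm_hits(text, motif, thr, "+", motif.id)
        if motif.scan_both_strands:
            rc_motif = MotifDef(motif.id, pattern=None, pwm=motif.pwm[::-1, ::-1],
                                scan_both_strands=False)
            hits += [
                MotifHit(h.motif_id, h.start, h.end, "-", h.matched_text,
                         h.contains_cpg, h.score)
                for h in _pwm_hits(text, rc_motif, thr, "+", motif.id)
            ]
    else:
        hits = _exact_hits(text, motif.pattern, motif.id, "+")
        if motif.scan_both_strands:
            rc = iupac_reverse_complement(motif.pattern)
            hits += [
                MotifHit(h.motif_id, h.start, h.end, "-", h.matched_text,
                         h.contains_cpg)
                for h in _exact_hits(text, rc, motif.id, "+")
            ]
    hits.sort(key=lambda h: (h.start, h.strand))  # "+" < "-" in ASCII
    return hits


@dataclass(frozen=True)
class DisruptionReport:
    hits_original: tuple[MotifHit, ...]
    hits_variant: tuple[MotifHit, ...]
    fully_disrupted: bool


def disruption_report(
    original, variant, motif: MotifDef = MotifDef(),
    pwm_threshold: Optional[float] = None,
) -> DisruptionReport:
    """Compare motif content before/after sequence modification.

    ``fully_disrupted`` is true iff the variant has zero hits; vacuously
    true (with a warning) when the original had none either.
    """
    if len(as_text(original)) != len(as_text(variant)):
        raise ValueError("original and variant must have the same length")
    ho = find_motifs(original, motif, pwm_threshold)
    hv = find_motifs(variant, motif, pwm_threshold)
    if not ho:
        warnings.warn("disruption_report: original sequence has no motif hits; "
                      "'fully_disrupted' is vacuous")
    return DisruptionReport(tuple(ho), tuple(hv), len(hv) == 0)


Scorer = Callable[[str], float]


def motif_count_scorer(seq, motif: MotifDef = MotifDef()) -> float:
    """Both-strand exact-hit count of the motif. Empty sequence scores 0."""
    text = as_text(seq)
    if not text:
        warnings.warn("motif_count_scorer: empty sequence, score 0")
        return 0.0
    return float(len(find_motifs(text, motif)))


def pwm_logodds_scorer(motif: MotifDef, threshold: float = 0.0) -> Scorer:
    """Scorer factory: sum of per-window PWM log-odds at or above
    ``threshold``, both strands."""
    if motif.pwm is None:
        raise ValueError("pwm_logodds_scorer requires a PWM motif")

    def score(seq) -> float:
        text = as_text(seq)
        if not text:
            warnings.warn("pwm_logodds_scorer: empty sequence, score 0")
            return 0.0
        return float(sum(h.score for h in find_motifs(text, motif, threshold)))

    return score


@dataclass(frozen=True)
class ContributionProfile:
    """Per-offset scores of donor-window swap variants of a base sequence."""

    window: int
    step: int
    baseline_score: float
    offsets: tuple[int, ...]
    variant_scores: tuple[float, ...]

    @property
    def delta(self) -> tuple[float, ...]:
        return tuple(v - self.baseline_score for v in self.variant_scores)


def walking_swap_scan(
    base,
    donor,
    window: int = 10,
    step: int = 1,
    scorer: Scorer = motif_count_scorer,
) -> ContributionProfile:
    """For each offset, replace ``base[offset:offset+window)`` with the
    donor's same-coordinate window, score the variant, and record the score.
    At step 1 the profile has ``L - window + 1`` entries.
    """
    base_t, donor_t = as_text(base), as_text(donor)
    if len(base_t) != len(donor_t):
        raise ValueError(
            f"base ({len(base_t)} bp) and donor ({len(donor_t)} bp) lengths differ"
        )
    if not 1 <= window <= len(base_t):
        raise ValueError("window must satisfy 1 <= window <= sequence length")
    if step < 1:
        raise ValueError("step must be >= 1")
    baseline = scorer(base_t)
    offsets, scores = [], []
    for off in range(0, len(base_t) - window + 1, step):
        variant = base_t[:off] + donor_t[off : off + window] + base_t[off + window :]
        try:
            scores.append(float(scorer(variant)))
        except Exception as exc:
            raise RuntimeError(f"scorer failed at offset {off}: {exc}") from exc
        offsets.append(off)
    return ContributionProfile(window, step, float(baseline), tuple(offsets),
                               tuple(scores))
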