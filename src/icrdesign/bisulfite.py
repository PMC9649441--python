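"""Single-molecule bisulfite analysis at amplicon scale.

In-silico conversion, global alignment of converted reads against a
reference in bisulfite-collapsed space, per-CpG/per-molecule methylation
calls, read QC, and coverage-filtered summaries.

Strand forms, named after the bisulfite library convention:
OT (original top), OB (original bottom), CTOT/CTOB (their complements).
A read is reduced to + orientation and one of two collapse rules:

    OT   : read as-is,            reference C matches C or T
    CTOT : reverse-complement,    reference C matches C or T
    OB   : reverse-complement,    reference G matches G or A
    CTOB : read as-is,            reference G matches G or A

Directional mode tries OT and OB; non-directional tries all four and keeps
the best score, ties broken by the fixed priority OT > OB > CTOT > CTOB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align.substitution_matrices import Array as SubstArray

from .core import CpGGrid, GenomicSequence, as_text, cpg_positions, reverse_complement

METH = 1
UNMETH = 0
MISSING = -1

STRAND_PRIORITY = ("OT", "OB", "CTOT", "CTOB")

#: (orientation flip, collapse rule) per strand form
_FORM = {
    "OT": (False, "CT"),
    "CTOT": (True, "CT"),
    "OB": (True, "GA"),
    "CTOB": (False, "GA"),
}


@dataclass(frozen=True)
class BisulfiteRead:
    id: str
    seq: str
    library_strand: str = "UNKNOWN"

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"read {self.id!r} is empty")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id!r}: invalid characters {sorted(bad)}")
        if self.library_strand not in ("OT", "OB", "CTOT", "CTOB", "UNKNOWN"):
            raise ValueError(f"invalid library_strand {self.library_strand!r}")


@dataclass(frozen=True)
class QCThresholds:
    min_conversion: float = 0.95
    min_identity: float = 0.90


@dataclass(frozen=True)
class ReadQC:
    read_id: str
    conversion_rate: float
    identity: float
    passed: bool
    strand_form: str
    score: float
    reason: str = ""


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    strand_form: str
    score: float
    calls: np.ndarray  # per-CpG-site {METH, UNMETH, MISSING}
    qc: ReadQC


@dataclass
class MethylationCallMatrix:
    """Molecules x CpG-sites ternary call matrix with per-read QC."""

    reference_id: str
    cpg_sites: Tuple[int, ...]
    calls: np.ndarray  # shape (n_passing_reads, n_sites), int8
    read_ids: Tuple[str, ...]
    qc: Tuple[ReadQC, ...]  # all reads, passing and failing
    status: str = "ok"

    @property
    def n_molecules(self) -> int:
        return self.calls.shape[0]


@dataclass(frozen=True)
class MethylationSummary:
    reference_id: str
    sites: Tuple[int, ...]  # retained CpG site offsets
    fractions: Tuple[float, ...]  # per retained site, METH/(METH+UNMETH)
    coverages: Tuple[int, ...]
    excluded_sites: Tuple[int, ...]  # below min_coverage
    min_coverage: int
    aggregate: Optional[float]  # unweighted mean over retained sites


def convert_in_silico(
    reference: GenomicSequence,
    molecule_states: Sequence[int],
    conversion_rate: float = 1.0,
    strand: str = "OT",
    error_rate: float = 0.0,
    seed: int = 0,
    read_id: str = "read",
) -> BisulfiteRead:
    """Simulate bisulfite conversion + sequencing of one molecule.

    ``molecule_states`` gives METH/UNMETH per CpG of the reference, in grid
    order. Every unmethylated cytosine on the chosen strand converts to T
    with probability ``conversion_rate``; methylated CpG cytosines are
    retained. Sequencing errors are independent substitutions applied after
    conversion.
    """
    if not 0.0 <= conversion_rate <= 1.0:
        raise ValueError("conversion_rate must be in [0, 1]")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if strand not in ("OT", "OB"):
        raise ValueError("strand must be OT or OB")
    ref = as_text(reference)
    grid = cpg_positions(ref)
    if len(molecule_states) != len(grid):
        raise ValueError(
            f"molecule_states covers {len(molecule_states)} CpGs, "
            f"reference has {len(grid)}"
        )
    rng = np.random.default_rng(seed)
    if strand == "OT":
        text = ref
        # CpG C sits at the grid position itself
        cpg_c = {p: s for p, s in zip(grid, molecule_states)}
    else:
        text = reverse_complement(ref)
        L = len(ref)
        # on the bottom strand the CpG C is the complement of the + strand G
        # at grid position p + 1, which lands at rc index L - 2 - p
        cpg_c = {L - 2 - p: s for p, s in zip(grid, molecule_states)}
    out = []
    for i, base in enumerate(text):
        if base == "C":
            state = cpg_c.get(i)
            if state == METH:
                out.append("C")
            elif rng.random() < conversion_rate:
                out.append("T")
            else:
                out.append("C")
        else:
            out.append(base)
    if error_rate > 0:
        alphabet = "ACGT"
        for i in range(len(out)):
            if out[i] != "N" and rng.random() < error_rate:
                others = alphabet.replace(out[i], "")
                out[i] = others[int(rng.integers(3))]
    return BisulfiteRead(read_id, "".join(out), library_strand=strand)


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


_ALPHABET = "ACGTNYR"


def _substitution_matrix(sc: AlignScoring) -> SubstArray:
    m = SubstArray(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = sc.mismatch
    for b in "ACGT":
        m[b, b] = sc.match
    for b in "CT":
        m["Y", b] = m[b, "Y"] = sc.match
    for b in "GA":
        m["R", b] = m[b, "R"] = sc.match
    for b in _ALPHABET:  # N is neutral
        m["N", b] = m[b, "N"] = 0.0
    return m


_ALIGNER_CACHE: Dict[AlignScoring, Align.PairwiseAligner] = {}


def _make_aligner(sc: AlignScoring) -> Align.PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(sc)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = _substitution_matrix(sc)
        aligner.open_gap_score = sc.gap
        aligner.extend_gap_score = sc.gap
        _ALIGNER_CACHE[sc] = aligner
    return aligner


def _collapse_reference(ref: str, rule: str) -> str:
    return ref.replace("C", "Y") if rule == "CT" else ref.replace("G", "R")


def _column_map(alignment) -> Dict[int, str]:
    """Map reference position -> aligned read base (gaps absent)."""
    colmap: Dict[int, str] = {}
    target_blocks, query_blocks = alignment.aligned
    query = alignment.sequences[1]
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        for k in range(te - ts):
            colmap[ts + k] = query[qs + k]
    return colmap


def _evaluate_form(
    read_seq: str,
    ref: str,
    grid: Sequence[int],
    form: str,
    aligner: Align.PairwiseAligner,
):
    flip, rule = _FORM[form]
    query = reverse_complement(read_seq) if flip else read_seq
    target = _collapse_reference(ref, rule)
    aln = aligner.align(target, query)[0]
    colmap = _column_map(aln)

    grid_set = set(grid)
    calls = np.full(len(grid), MISSING, dtype=np.int8)
    if rule == "CT":
        meth_base, unmeth_base = "C", "T"
        call_cols = list(grid)
        non_cpg = [i for i, b in enumerate(ref) if b == "C" and i not in grid_set]
    else:
        meth_base, unmeth_base = "G", "A"
        call_cols = [p + 1 for p in grid]
        g_of_grid = {p + 1 for p in grid}
        non_cpg = [i for i, b in enumerate(ref) if b == "G" and i not in g_of_grid]

    for site_idx, col in enumerate(call_cols):
        b = colmap.get(col)
        if b == meth_base:
            calls[site_idx] = METH
        elif b == unmeth_base:
            calls[site_idx] = UNMETH

    converted = unconverted = 0
    for col in non_cpg:
        b = colmap.get(col)
        if b == unmeth_base:
            converted += 1
        elif b == meth_base:
            unconverted += 1
    total = converted + unconverted
    conversion = converted / total if total else 1.0

    matches = columns = 0
    for col, b in colmap.items():
        t = target[col]
        if t == "N" or b == "N":
            continue
        columns += 1
        if t == b or (t == "Y" and b in "CT") or (t == "R" and b in "GA"):
            matches += 1
    identity = matches / columns if columns else 0.0
    return float(aln.score), calls, conversion, identity


def align_bisulfite(
    read: BisulfiteRead,
    reference: GenomicSequence,
    mode: str = "non_directional",
    scoring: AlignScoring = AlignScoring(),
    qc_thresholds: QCThresholds = QCThresholds(),
) -> AlignedRead:
    """Globally align one read against the reference in bisulfite-collapsed
    space and derive per-CpG calls plus QC.

    Per-site call is METH iff the read shows the retained base at the
    informative CpG column, UNMETH iff the converted base, MISSING otherwise
    (gap, N, or any other base — never imputed).
    """
    if mode not in ("directional", "non_directional"):
        raise ValueError("mode must be 'directional' or 'non_directional'")
    ref = as_text(reference)
    if len(ref) < len(read.seq) / 2:
        raise ValueError("reference shorter than half the read: not an amplicon setting")
    grid = cpg_positions(ref)
    aligner = _make_aligner(scoring)
    forms = STRAND_PRIORITY if mode == "non_directional" else ("OT", "OB")
    best = None
    for form in forms:  # priority order: first strict improvement wins ties
        score, calls, conv, ident = _evaluate_form(read.seq, ref, grid, form, aligner)
        if best is None or score > best[0]:
            best = (score, form, calls, conv, ident)
    score, form, calls, conv, ident = best
    passed = conv >= qc_thresholds.min_conversion and ident >= qc_thresholds.min_identity
    reason = ""
    if not passed:
        reasons = []
        if conv < qc_thresholds.min_conversion:
            reasons.append(f"conversion {conv:.3f} < {qc_thresholds.min_conversion}")
        if ident < qc_thresholds.min_identity:
            reasons.append(f"identity {ident:.3f} < {qc_thresholds.min_identity}")
        reason = "; ".join(reasons)
    qc = ReadQC(read.id, conv, ident, passed, form, score, reason)
    return AlignedRead(read.id, form, score, calls, qc)


def call_matrix(
    reads: Sequence[BisulfiteRead],
    reference: GenomicSequence,
    mode: str = "non_directional",
    scoring: AlignScoring = AlignScoring(),
    qc_thresholds: QCThresholds = QCThresholds(),
) -> MethylationCallMatrix:
    """Align and call every read; one matrix row per QC-passing read."""
    if not reads:
        raise ValueError("call_matrix: no reads supplied")
    grid = tuple(cpg_positions(as_text(reference)))
    rows, ids, qcs = [], [], []
    for read in reads:
        aligned = align_bisulfite(read, reference, mode, scoring, qc_thresholds)
        qcs.append(aligned.qc)
        if aligned.qc.passed:
            rows.append(aligned.calls)
            ids.append(read.id)
    ref_id = reference.id if isinstance(reference, GenomicSequence) else "reference"
    if rows:
        calls = np.vstack(rows).astype(np.int8)
        status = "ok"
    else:
        calls = np.empty((0, len(grid)), dtype=np.int8)
        status = "no_passing_reads"
        warnings.warn("call_matrix: zero reads passed QC")
    return MethylationCallMatrix(ref_id, grid, calls, tuple(ids), tuple(qcs), status)


def summarize_methylation(
    matrix: MethylationCallMatrix, min_coverage: int = 1
) -> MethylationSummary:
    """Per-site methylation fractions over non-MISSING calls; sites covered
    fewer than ``min_coverage`` times are excluded and enumerated. The
    aggregate is the unweighted mean over retained sites."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    calls = matrix.calls
    meth = (calls == METH).sum(axis=0)
    unmeth = (calls == UNMETH).sum(axis=0)
    coverage = meth + unmeth
    retained, fractions, covs, excluded = [], [], [], []
    for i, site in enumerate(matrix.cpg_sites):
        if coverage[i] >= min_coverage:
            retained.append(site)
            fractions.append(meth[i] / coverage[i])
            covs.append(int(coverage[i]))
        else:
            excluded.append(site)
    aggregate = float(np.mean(fractions)) if fractions else None
    if aggregate is None:
        warnings.warn("summarize_methylation: all sites excluded, aggregate undefined")
    return MethylationSummary(
        matrix.reference_id,
        tuple(retained),
        tuple(fractions),
        tuple(covs),
        tuple(excluded),
        min_coverage,
        aggregate,
    )
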