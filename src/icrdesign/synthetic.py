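"""Synthetic input generators: CpG-island-like sequences with exact CpG
counts, toy genomes with planted twins, and bisulfite read sets under
bimodal / disordered / per-site epiallele scenarios.

Every generator is a pure function of (spec, seed) and emits its ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .bisulfite import METH, UNMETH, BisulfiteRead, convert_in_silico
from .core import GenomicSequence, as_text, cpg_positions
from .shuffle import MAXIMIZE, ShuffleConstraints, shuffle_inter_cpg

UNIFORM = "uniform"
CLUSTERED = "clustered"

KEEP_GRID_RESHUFFLE = "keep_grid_reshuffle"
VERBATIM = "verbatim"

BIMODAL = "bimodal"
DISORDERED = "disordered"
PER_SITE = "per_site"


class InfeasibleSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for a CpG-island-like sequence: exact CpG count, target GC."""

    length: int
    gc_fraction: float
    n_cpg: int
    spacing_model: str = UNIFORM
    seed: int = 0
    # clustered model: mixture of short and long inter-CpG gaps
    cluster_short_gap: float = 8.0
    cluster_long_gap: float = 58.0
    cluster_short_weight: float = 0.7

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.n_cpg < 0 or 2 * self.n_cpg > self.length:
            raise ValueError("need 2 * n_cpg <= length")
        if self.spacing_model not in (UNIFORM, CLUSTERED):
            raise ValueError(f"unknown spacing_model {self.spacing_model!r}")


def _place_cpgs_uniform(spec: SequenceSpec, rng) -> list[int]:
    # bijection between start positions with pairwise gaps >= 2 and a plain
    # sorted sample: p_k = r_k + 2k with r_k drawn without replacement
    n, L = spec.n_cpg, spec.length
    if n == 0:
        return []
    domain = L - 2 * n + 1 + (n - 1)  # r_k in [0, L - 2 - 2(n-1)] + slots
    r = np.sort(rng.choice(L - 2 * n + n, size=n, replace=False))
    return [int(r[k]) + k for k in range(n)]


def _place_cpgs_clustered(spec: SequenceSpec, rng) -> list[int]:
    n, L = spec.n_cpg, spec.length
    if n == 0:
        return []
    means = np.where(
        rng.random(n) < spec.cluster_short_weight,
        spec.cluster_short_gap,
        spec.cluster_long_gap,
    )
    gaps = rng.poisson(means).astype(float)  # gap before each CpG
    budget = L - 2 * n  # inter-CpG bases available
    total = gaps.sum()
    if total > budget:
        gaps = np.floor(gaps * (budget / total))
    positions = []
    cur = 0
    for g in gaps:
        cur += int(g)
        positions.append(cur)
        cur += 2
    assert positions[-1] + 2 <= L
    return positions


def generate_sequence(spec: SequenceSpec) -> GenomicSequence:
    """Generate a sequence with exactly ``spec.n_cpg`` CG dinucleotides and
    GC within +/- 0.02 of target.

    CpGs are placed first per the spacing model, inter-CpG bases are drawn
    to hit the GC target, and a repair pass removes accidental CGs by
    composition-preserving swaps. Rejects specs whose CpG count alone
    forces GC above target + 0.02.
    """
    L, n = spec.length, spec.n_cpg
    floor_gc = 2 * n / L
    if floor_gc > spec.gc_fraction + 0.02:
        raise InfeasibleSpecError(
            f"{n} CpGs in {L} bp force GC >= {floor_gc:.3f}, above target "
            f"{spec.gc_fraction} + 0.02"
        )
    rng = np.random.default_rng(spec.seed)
    place = _place_cpgs_uniform if spec.spacing_model == UNIFORM else _place_cpgs_clustered
    grid = place(spec, rng)

    seq = [""] * L
    grid_set = set()
    for p in grid:
        seq[p], seq[p + 1] = "C", "G"
        grid_set.add(p)
        grid_set.add(p + 1)
    inter = [i for i in range(L) if i not in grid_set]

    g_needed = int(np.clip(round(spec.gc_fraction * L) - 2 * n, 0, len(inter)))
    gc_positions_sel = rng.choice(len(inter), size=g_needed, replace=False)
    mask = np.zeros(len(inter), dtype=bool)
    mask[gc_positions_sel] = True
    for k, i in enumerate(inter):
        if mask[k]:
            seq[i] = "C" if rng.random() < 0.5 else "G"
        else:
            seq[i] = "A" if rng.random() < 0.5 else "T"

    _repair_accidental_cpgs(seq, grid_set, inter, rng)

    text = "".join(seq)
    realized = tuple(cpg_positions(text))
    if len(realized) != n:
        raise RuntimeError(
            f"internal error: realized {len(realized)} CpGs, wanted {n}"
        )
    gc = (text.count("G") + text.count("C")) / L
    if abs(gc - spec.gc_fraction) > 0.02:
        raise InfeasibleSpecError(
            f"realized GC {gc:.3f} outside target {spec.gc_fraction} +/- 0.02"
        )
    return GenomicSequence(f"synthetic_L{L}_gc{spec.gc_fraction}_n{n}_s{spec.seed}", text)


def _repair_accidental_cpgs(seq: list[str], grid_set: set, inter: list[int], rng,
                            max_rounds: int = 200) -> None:
    """Swap away CG dinucleotides outside the intended grid. Swaps exchange
    two inter-CpG bases, so composition (and GC) is untouched."""

    def bad_positions() -> list[int]:
        text = "".join(seq)
        out = []
        s = text.find("CG")
        while s != -1:
            if s not in grid_set:
                out.append(s)
            s = text.find("CG", s + 1)
        return out

    def creates_cg(i: int) -> bool:
        L = len(seq)
        if i + 1 < L and seq[i] == "C" and seq[i + 1] == "G" and i not in grid_set:
            return True
        if i >= 1 and seq[i - 1] == "C" and seq[i] == "G" and (i - 1) not in grid_set:
            return True
        return False

    for _ in range(max_rounds):
        bad = bad_positions()
        if not bad:
            return
        for pos in bad:
            # pos is the C of an accidental CG; both bases are inter-CpG
            i = pos if pos not in grid_set else pos + 1
            for _attempt in range(50):
                j = inter[int(rng.integers(len(inter)))]
                if seq[j] == seq[i]:
                    continue
                seq[i], seq[j] = seq[j], seq[i]
                if creates_cg(i) or creates_cg(j):
                    seq[i], seq[j] = seq[j], seq[i]
                    continue
                break
    if bad_positions():
        raise RuntimeError("could not repair accidental CpGs")


@dataclass(frozen=True)
class GenomeSpec:
    """Toy genome recipe: iid background with CpG depletion."""

    contigs: Tuple[Tuple[str, int], ...] = (("chr1", 200_000),)
    gc_fraction: float = 0.41
    cpg_depletion: float = 0.8  # fraction of background CGs broken up
    seed: int = 0


def generate_genome(spec: GenomeSpec) -> list[GenomicSequence]:
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    g = spec.gc_fraction / 2
    probs = np.array([0.5 - g, g, g, 0.5 - g])
    out = []
    for name, length in spec.contigs:
        arr = rng.choice(bases, size=length, p=probs)
        if spec.cpg_depletion > 0:
            text = "".join(arr)
            s = text.find("CG")
            while s != -1:
                if rng.random() < spec.cpg_depletion:
                    arr[s + 1] = "A" if rng.random() < 0.5 else "T"
                s = text.find("CG", s + 1)
            # breaking a CG can only remove CGs, never create one
        out.append(GenomicSequence(name, "".join(arr)))
    return out


def plant_twin(
    genome_spec: GenomeSpec,
    query: GenomicSequence,
    disguise: str = KEEP_GRID_RESHUFFLE,
    seed: int = 0,
    shuffle_iterations: int = 2000,
) -> Tuple[list[GenomicSequence], Tuple[str, int, int]]:
    """Generate a toy genome and embed a (possibly disguised) copy of the
    query at a random position. Returns the genome and the planted
    (contig, start, end) for recovery checks."""
    if disguise not in (KEEP_GRID_RESHUFFLE, VERBATIM):
        raise ValueError(f"unknown disguise mode {disguise!r}")
    rng = np.random.default_rng(seed)
    genome = generate_genome(GenomeSpec(
        genome_spec.contigs, genome_spec.gc_fraction, genome_spec.cpg_depletion,
        seed=seed,
    ))
    qlen = len(query)
    eligible = [i for i, c in enumerate(genome) if len(c) >= qlen]
    if not eligible:
        raise InfeasibleSpecError("no contig is long enough to hold the query")
    ci = eligible[int(rng.integers(len(eligible)))]
    contig = genome[ci]
    start = int(rng.integers(0, len(contig) - qlen + 1))

    if disguise == VERBATIM:
        insert = query.seq
    else:
        result = shuffle_inter_cpg(
            query,
            ShuffleConstraints(target_mismatch=MAXIMIZE,
                               max_iterations=shuffle_iterations,
                               seed=seed),
        )
        insert = result.shuffled.seq
    new_text = contig.seq[:start] + insert + contig.seq[start + qlen :]
    genome[ci] = GenomicSequence(contig.id, new_text)
    return genome, (contig.id, start, start + qlen)


@dataclass(frozen=True)
class EpialleleScenario:
    """Per-molecule methylation scenario for read simulation."""

    mode: str  # BIMODAL | DISORDERED | PER_SITE
    n_molecules: int
    f_methylated: Optional[float] = None  # BIMODAL: fraction fully methylated
    p: Optional[float] = None  # DISORDERED: per-CpG probability
    p_sites: Optional[Tuple[float, ...]] = None  # PER_SITE vector
    conversion_rate: float = 1.0
    error_rate: float = 0.0
    strands: Tuple[str, ...] = ("OT", "OB")
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.mode == BIMODAL:
            if self.f_methylated is None or not 0 <= self.f_methylated <= 1:
                raise ValueError("BIMODAL requires f_methylated in [0, 1]")
        elif self.mode == DISORDERED:
            if self.p is None or not 0 <= self.p <= 1:
                raise ValueError("DISORDERED requires p in [0, 1]")
        elif self.mode == PER_SITE:
            if self.p_sites is None or any(not 0 <= x <= 1 for x in self.p_sites):
                raise ValueError("PER_SITE requires a probability vector")
        else:
            raise ValueError(f"unknown scenario mode {self.mode!r}")
        for r in (self.conversion_rate, self.error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if not self.strands or set(self.strands) - {"OT", "OB"}:
            raise ValueError("strands must be a non-empty subset of {OT, OB}")


def generate_reads(
    reference: GenomicSequence, scenario: EpialleleScenario
) -> Tuple[list[BisulfiteRead], np.ndarray]:
    """Simulate full-length amplicon reads plus the true molecule-state
    matrix (n_molecules x n_CpGs, METH/UNMETH)."""
    grid = cpg_positions(reference)
    n_sites = len(grid)
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_molecules
    if scenario.mode == BIMODAL:
        fully = rng.random(n) < scenario.f_methylated
        states = np.where(fully[:, None], METH, UNMETH) * np.ones((1, n_sites), int)
    elif scenario.mode == DISORDERED:
        states = np.where(rng.random((n, n_sites)) < scenario.p, METH, UNMETH)
    else:
        p = np.asarray(scenario.p_sites, dtype=float)
        if len(p) != n_sites:
            raise ValueError(
                f"p_sites has {len(p)} entries, reference has {n_sites} CpGs"
            )
        states = np.where(rng.random((n, n_sites)) < p[None, :], METH, UNMETH)
    states = states.astype(np.int8)

    reads = []
    for m in range(n):
        strand = scenario.strands[int(rng.integers(len(scenario.strands)))]
        reads.append(
            convert_in_silico(
                reference,
                states[m].tolist(),
                conversion_rate=scenario.conversion_rate,
                strand=strand,
                error_rate=scenario.error_rate,
                seed=int(rng.integers(2**31)),
                read_id=f"mol{m:05d}_{strand}",
            )
        )
    return reads, states
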