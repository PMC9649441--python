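"""Readers and writers for FASTA/FASTQ/BED/TSV plus JSON run manifests.

All coordinates crossing file boundaries are 0-based, half-open.
"""

from __future__ import annotations

import csv
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bisulfite import BisulfiteRead
from .core import GenomicSequence, SequenceAlphabetError
from .motifscan import MotifHit
from .seqfeatures import SequenceProfile, TwinCandidate


def read_fasta(path) -> list[GenomicSequence]:
    """Read a (possibly wrapped, mixed-case) FASTA file. Lower-case input
    is uppercased with a warning; invalid characters are rejected naming
    the record."""
    path = Path(path)
    out = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        raise IOError(f"failed to parse FASTA {path}: {exc}") from exc
    for rec in records:
        raw = str(rec.seq)
        if raw != raw.upper():
            warnings.warn(f"FASTA record {rec.id!r}: lower-case bases uppercased")
        try:
            out.append(GenomicSequence.from_raw(rec.id, raw))
        except (SequenceAlphabetError, ValueError) as exc:
            raise IOError(f"FASTA {path}, record {rec.id!r}: {exc}") from exc
    if not out:
        warnings.warn(f"FASTA {path}: no records")
    return out


def write_fasta(seqs: Iterable[GenomicSequence], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_reads(path) -> list[BisulfiteRead]:
    """Read bisulfite reads from FASTQ or FASTA (by extension; qualities
    are parsed but ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:
        raise IOError(f"failed to parse {fmt.upper()} {path}: {exc}") from exc
    return [BisulfiteRead(rec.id, str(rec.seq).upper()) for rec in records]


def write_fastq(reads: Iterable[BisulfiteRead], path, quality: int = 40) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{chr(33 + quality) * len(r.seq)}\n")


def write_bed(records, path, name_prefix: str = "") -> None:
    """Write MotifHits or TwinCandidates as BED6 (0-based half-open).

    Twin candidates: name = rank (1-based), score = scaled distance.
    """
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            if isinstance(rec, MotifHit):
                fh.write(
                    f"query\t{rec.start}\t{rec.end}\t{name_prefix}{rec.motif_id}\t"
                    f"0\t{rec.strand}\n"
                )
            elif isinstance(rec, TwinCandidate):
                score = min(1000, int(round(rec.distance * 1000)))
                fh.write(
                    f"{rec.contig}\t{rec.start}\t{rec.end}\t{name_prefix}{i + 1}\t"
                    f"{score}\t+\n"
                )
            else:
                raise TypeError(f"cannot write {type(rec).__name__} as BED")


PROFILE_COLUMNS = ("contig", "start", "end", "length", "gc_fraction",
                   "cpg_count", "cpg_per_100bp")


def write_profiles_tsv(profiles: Iterable[SequenceProfile], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PROFILE_COLUMNS)
        for p in profiles:
            contig, start, end = p.source if p.source else (".", 0, p.length)
            w.writerow([contig, start, end, p.length, f"{p.gc_fraction:.6f}",
                        p.cpg_count, f"{p.cpg_per_100bp:.4f}"])


def write_tsv(rows: Iterable[Sequence], header: Sequence[str], path) -> None:
    """Generic TSV writer: one header line, then rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row)


def write_call_matrix_tsv(matrix, path) -> None:
    """Lollipop matrix: rows = molecules, columns = CpG reference offsets,
    values 1 (methylated) / 0 (unmethylated) / . (missing)."""
    symbol = {1: "1", 0: "0", -1: "."}
    header = ["molecule"] + [str(p) for p in matrix.cpg_sites]
    rows = (
        [rid] + [symbol[int(v)] for v in matrix.calls[i]]
        for i, rid in enumerate(matrix.read_ids)
    )
    write_tsv(rows, header, path)


def write_summary_tsv(summary, path) -> None:
    rows = [
        [site, f"{frac:.6f}", cov]
        for site, frac, cov in zip(summary.sites, summary.fractions, summary.coverages)
    ]
    write_tsv(rows, ["cpg_offset", "methylation_fraction", "coverage"], path)


def write_manifest(config: dict, path, seeds: Optional[dict] = None,
                   include_timestamp: bool = True) -> None:
    """JSON run manifest: effective config, seeds, package version."""
    from . import __version__

    manifest = {
        "package": "icrdesign",
        "version": __version__,
        "config": config,
        "seeds": seeds or {},
    }
    if include_timestamp:
        manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
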