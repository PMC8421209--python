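"""Sequence and call-set I/O, coordinate conventions, and low-complexity filtering.

All coordinates are 0-based, half-open internally; 1-based positions appear
only in report writers (TSV/VCF).
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    pass


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceGenome:
    """Uppercase DNA contigs keyed by name, in file order."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def slice(self, iv: GenomicInterval) -> str:
        seq = self.contigs[iv.contig][iv.start : iv.end]
        return revcomp(seq) if iv.strand == "-" else seq


@dataclass(slots=True)
class ReadRecord:
    """One sequencing read; ``mate`` is 'single', 'first' or 'second'."""

    id: str
    seq: str
    qual: str | None = None
    mate: str = "single"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FastqParseError(
                f"read {self.id!r}: qual length {len(self.qual)} != "
                f"seq length {len(self.seq)}"
            )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def load_reference(path: str | Path) -> ReferenceGenome:
    """Load a (possibly line-wrapped) FASTA file; sequences are uppercased.

    Raises :class:`FastaParseError` on an empty file, duplicate contig names
    or non-FASTA content.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as handle:
        first = handle.read(1)
        if not first:
            raise FastaParseError(f"{path}: empty FASTA file")
        if first != ">":
            raise FastaParseError(f"{path}: does not start with '>' (line 1)")
        handle.seek(0)
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0]
            if name in contigs:
                raise FastaParseError(f"{path}: duplicate contig name {name!r}")
            contigs[name] = seq.upper()
    if not contigs:
        raise FastaParseError(f"{path}: no records found")
    return ReferenceGenome(contigs)


def write_reference(ref: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in ref.contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def _fastq_records(path: str | Path, mate: str) -> Iterator[ReadRecord]:
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield ReadRecord(title.split()[0], seq.upper(), qual, mate)
        except ValueError as exc:  # truncated/malformed record
            raise FastqParseError(f"{path}: {exc}") from exc


def stream_reads(
    path1: str | Path, path2: str | Path | None = None
) -> Iterator[ReadRecord]:
    """Yield reads from one FASTQ file, or from a pair in interleaved order.

    Paired files must have matched ordering; a length mismatch between the
    two files raises :class:`FastqParseError`.
    """
    if path2 is None:
        yield from _fastq_records(path1, "single")
        return
    it1 = _fastq_records(path1, "first")
    it2 = _fastq_records(path2, "second")
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise FastqParseError(f"{path2}: fewer records than {path1}")
        yield r1
        yield r2
    if next(it2, None) is not None:
        raise FastqParseError(f"{path1}: fewer records than {path2}")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as FASTQ (gzip if the path ends in .gz); returns count."""
    n = 0
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            out.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# DUST low-complexity score
# ---------------------------------------------------------------------------

DEFAULT_DUST_THRESHOLD = 7.0


def dust_score(seq: str, window: int = 64) -> float:
    """Low-complexity score in [0, 100] (DUST-style triplet statistic).

    The sequence is tiled into windows of ``window`` bases (the last window
    may be shorter).  In a window of length w with overlapping-triplet counts
    c_t, the window score is

        100 * sum_t c_t (c_t - 1) / 2  /  ((w - 2)(w - 3) / 2)

    and the read score is the maximum over windows.  A homopolymer window
    scores 100; a window whose triplets are all distinct scores 0.
    """
    n = len(seq)
    if n < 3:
        raise ValueError("dust_score requires a sequence of length >= 3")
    best = 0.0
    for start in range(0, n, window):
        w = min(window, n - start)
        if w < 4:  # denominator vanishes; fewer than 2 triplets
            continue
        counts: dict[str, int] = {}
        chunk = seq[start : start + w]
        for i in range(w - 2):
            t = chunk[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        num = sum(c * (c - 1) for c in counts.values()) / 2.0
        den = (w - 2) * (w - 3) / 2.0
        best = max(best, 100.0 * num / den)
    return best


def passes_dust(seq: str, threshold: float = DEFAULT_DUST_THRESHOLD,
                window: int = 64) -> bool:
    """True when the read should be kept (score <= threshold, no N bases)."""
    if "N" in seq:
        return False
    return dust_score(seq, window) <= threshold


# ---------------------------------------------------------------------------
# Call-set TSV / VCF
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "contig",
    "left_bp_1based",
    "right_bp_1based",
    "ins_seq",
    "template_start_1based",
    "template_end_1based",
    "template_strand",
    "template_identity",
    "event_class",
    "microhomology",
    "microhomeology",
    "support",
    "subclonal",
]


def write_calls_tsv(calls: Sequence, path: str | Path) -> None:
    """Write calls (``MMBTICall`` objects) to TSV with 1-based coordinates."""
    rows = []
    for c in calls:
        tm = c.templates[0] if c.templates else None
        mh = c.junctions[0].mh if c.junctions else ""
        mheo = c.junctions[0].mheo if c.junctions else ""
        rows.append(
            {
                "contig": c.contig,
                "left_bp_1based": c.left_bp + 1,
                "right_bp_1based": c.right_bp + 1,
                "ins_seq": c.ins_seq,
                "template_start_1based": tm.interval.start + 1 if tm else "",
                "template_end_1based": tm.interval.end if tm else "",
                "template_strand": tm.interval.strand if tm else "",
                "template_identity": round(tm.identity, 4) if tm else "",
                "event_class": c.event_class,
                "microhomology": mh,
                "microhomeology": mheo,
                "support": c.support,
                "subclonal": c.subclonal,
            }
        )
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    missing = set(CALL_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing call columns {sorted(missing)}")
    return df


def write_calls_vcf(calls: Sequence, ref: ReferenceGenome, path: str | Path) -> None:
    """Write calls as minimal VCF 4.2 INS records (INFO: template, MH)."""
    with _open_text(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, length in ref.lengths.items():
            out.write(f"##contig=<ID={name},length={length}>\n")
        out.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        out.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Right breakpoint">\n')
        out.write('##INFO=<ID=TMPL,Number=1,Type=String,Description="Template interval contig:start-end:strand (1-based)">\n')
        out.write('##INFO=<ID=MH,Number=1,Type=Integer,Description="Junction microhomology (bp)">\n')
        out.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Event class">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls, 1):
            pos = c.left_bp  # base before the junction, 0-based
            ref_base = ref[c.contig][pos - 1] if pos > 0 else ref[c.contig][0]
            alt = ref_base + c.ins_seq
            info = [f"SVTYPE=INS", f"END={c.right_bp + 1}", f"CLASS={c.event_class}"]
            if c.templates:
                tm = c.templates[0]
                info.append(
                    f"TMPL={tm.interval.contig}:{tm.interval.start + 1}-"
                    f"{tm.interval.end}:{tm.interval.strand}"
                )
            if c.junctions:
                info.append(f"MH={c.junctions[0].mh}")
            out.write(
                f"{c.contig}\t{pos}\t{'call_%d' % i}\t{ref_base}\t{alt}\t.\tPASS\t"
                + ";".join(info)
                + "\n"
            )
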