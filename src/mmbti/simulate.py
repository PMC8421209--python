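"""Benchmark genome construction and Illumina-like paired-end read simulation.

The generator reproduces the structure of the sensitivity benchmark: a
reference into which inverted-template insertions are planted at regular
intervals (each insertion is the reverse complement of a template located
80 bp upstream of the insertion point), in two modes:

* ``append``  — the insertion is added without removing reference bases;
* ``replace`` — the insertion substitutes the same number of reference bases
  at the insertion site.

Reads are 125 bp paired-end with a Gaussian insert-size distribution
(500 ± 20 bp by default) at 30× depth, with i.i.d. substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval, ReadRecord, ReferenceGenome, revcomp

DEFAULT_TEMPLATE_OFFSET = 80
DEFAULT_SIZE_RANGE = (20, 50)


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """One planted insertion, recorded in original-reference coordinates."""

    contig: str
    pos: int                    # 0-based insertion breakpoint
    ins_len: int
    mode: str                   # "append" | "replace"
    template: GenomicInterval   # source interval; strand "-" = copied inverted
    ins_seq: str

    def __post_init__(self) -> None:
        if self.mode not in ("append", "replace"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if len(self.ins_seq) != self.ins_len:
            raise ValueError("ins_seq length disagrees with ins_len")


@dataclass(slots=True)
class SimConfig:
    """Read-simulation parameters (Illumina-like paired-end)."""

    read_len: int = 125
    insert_mean: int = 500
    insert_sd: float = 20.0
    depth: float = 30.0
    base_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 36:
            raise ValueError("read_len must be >= 36")
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert_mean must exceed 2 * read_len")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0.0 <= self.base_error_rate < 1.0):
            raise ValueError("base_error_rate must be in [0, 1)")


def make_random_reference(
    length: int, gc: float = 0.41, seed: int = 0, contig: str = "sim1"
) -> ReferenceGenome:
    """Random reference with the requested GC content; deterministic per seed."""
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if length < 10_000:
        raise ValueError("reference length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    gchalf = gc / 2.0
    codes = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8),
        size=length,
        p=[at, gchalf, gchalf, at],
    )
    return ReferenceGenome({contig: codes.tobytes().decode("ascii")})


def _junction_ambiguous(ref_seq: str, pos: int, ins: str, mode: str) -> bool:
    """True when the planted breakpoint admits an equivalent shifted placement.

    A pure insertion at ``pos`` can be rotated left when its last base equals
    the reference base just upstream, or right when its first base equals the
    base the right flank resumes at.  Sites are slid until neither holds, so
    every truth record has a unique, exactly recoverable placement.
    """
    right_resume = pos if mode == "append" else pos + len(ins)
    if ins[0] == ref_seq[pos]:
        return True
    if ins[-1] == ref_seq[right_resume - 1]:
        return True
    return False


def _n_run_near(ref_seq: str, lo: int, hi: int) -> bool:
    return "N" in ref_seq[max(0, lo) : hi]


def plant_insertions(
    ref: ReferenceGenome,
    n: int,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    mode: str = "append",
    template_offset: int = DEFAULT_TEMPLATE_OFFSET,
    seed: int = 0,
    min_spacing: int = 1000,
    margin: int = 500,
) -> tuple[ReferenceGenome, list[TruthRecord]]:
    """Plant ``n`` inverted-template insertions at regular intervals.

    Each insertion is the reverse complement of the ``ins_len`` bases starting
    ``template_offset`` bp upstream of the insertion point.  ``append`` keeps
    all reference bases; ``replace`` substitutes ``ins_len`` reference bases.
    Sites near N runs are skipped, and each site is slid forward (a few bases)
    until the planted junctions admit no alternative breakpoint placement, so
    the truth manifest is exact.  Deterministic for a fixed seed.
    """
    if mode not in ("append", "replace"):
        raise ValueError(f"invalid mode {mode!r}")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid size range {size_range}")
    if n < 0:
        raise ValueError("n must be non-negative")

    (contig, seq), *rest = ref.contigs.items()
    if rest:
        raise ValueError("plant_insertions expects a single-contig reference")
    usable = len(seq) - 2 * margin
    max_feasible = max(0, usable // min_spacing)
    if n > max_feasible:
        raise ValueError(
            f"cannot place {n} insertions with spacing >= {min_spacing} bp "
            f"and {margin} bp margins in a {len(seq)} bp reference "
            f"(max feasible: {max_feasible})"
        )

    rng = np.random.default_rng(seed)
    truths: list[TruthRecord] = []
    if n:
        step = usable // n
        positions = [margin + step // 2 + i * step for i in range(n)]
        sizes = rng.integers(lo, hi + 1, size=n)
        for base_pos, ins_len in zip(positions, sizes.tolist()):
            placed = False
            for shift in range(50):
                pos = base_pos + shift
                t0 = pos - template_offset
                if t0 < 0 or pos + ins_len > len(seq):
                    break
                if _n_run_near(seq, t0, pos + ins_len):
                    continue
                template_seq = seq[t0 : t0 + ins_len]
                ins = revcomp(template_seq)
                if _junction_ambiguous(seq, pos, ins, mode):
                    continue
                truths.append(
                    TruthRecord(
                        contig=contig,
                        pos=pos,
                        ins_len=ins_len,
                        mode=mode,
                        template=GenomicInterval(contig, t0, t0 + ins_len, "-"),
                        ins_seq=ins,
                    )
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place an unambiguous insertion near {base_pos}"
                )

    # assemble the mutated sequence in one pass, in coordinate order
    pieces: list[str] = []
    cursor = 0
    for t in truths:
        pieces.append(seq[cursor : t.pos])
        pieces.append(t.ins_seq)
        cursor = t.pos + (t.ins_len if mode == "replace" else 0)
    pieces.append(seq[cursor:])
    mutated = ReferenceGenome({contig: "".join(pieces)})
    return mutated, truths


def simulate_reads(
    genome: ReferenceGenome, cfg: SimConfig
) -> Iterator[ReadRecord]:
    """Yield paired reads (first, second, first, second, ...) from a genome.

    Fragment count is ``depth * genome_len / (2 * read_len)`` (rounded);
    fragment starts are uniform, insert lengths Gaussian truncated at
    2 * read_len; read 2 is the reverse complement of the fragment's 3' end.
    Substitution errors are i.i.d. at ``base_error_rate``.
    """
    (contig, seq), *rest = genome.contigs.items()
    if rest:
        raise ValueError("simulate_reads expects a single-contig genome")
    glen = len(seq)
    if glen <= cfg.insert_mean:
        raise ValueError("genome shorter than the mean insert size")

    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_len
    n_frag = int(round(cfg.depth * glen / (2.0 * rl)))

    frag_lens = np.rint(
        rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_frag)
    ).astype(np.int64)
    np.clip(frag_lens, 2 * rl, glen, out=frag_lens)
    starts = rng.integers(0, glen - frag_lens + 1)
    n_err = rng.binomial(rl, cfg.base_error_rate, size=2 * n_frag)

    alts = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG"}
    for i in range(n_frag):
        s = int(starts[i])
        fl = int(frag_lens[i])
        r1 = seq[s : s + rl]
        r2 = revcomp(seq[s + fl - rl : s + fl])
        for j, (r, mate) in enumerate(((r1, "first"), (r2, "second"))):
            k = int(n_err[2 * i + j])
            if k:
                chars = list(r)
                for p in rng.integers(0, rl, size=k).tolist():
                    chars[p] = alts[chars[p]][int(rng.integers(0, 3))]
                r = "".join(chars)
            yield ReadRecord(f"frag{i}/{j + 1}", r, None, mate)


# ---------------------------------------------------------------------------
# Truth manifest TSV
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "contig", "pos_1based", "mode", "ins_len",
    "template_start_1based", "template_end_1based", "template_strand", "ins_seq",
]


def write_truth_tsv(truths: Sequence[TruthRecord], path: str | Path) -> None:
    rows = [
        {
            "contig": t.contig,
            "pos_1based": t.pos + 1,
            "mode": t.mode,
            "ins_len": t.ins_len,
            "template_start_1based": t.template.start + 1,
            "template_end_1based": t.template.end,
            "template_strand": t.template.strand,
            "ins_seq": t.ins_seq,
        }
        for t in truths
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return [
        TruthRecord(
            contig=row.contig,
            pos=int(row.pos_1based) - 1,
            ins_len=int(row.ins_len),
            mode=row.mode,
            template=GenomicInterval(
                row.contig,
                int(row.template_start_1based) - 1,
                int(row.template_end_1based),
                row.template_strand,
            ),
            ins_seq=row.ins_seq,
        )
        for row in df.itertuples()
    ]
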