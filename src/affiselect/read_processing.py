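"""Amplicon read funnel: paired reads -> merged DNA -> insert -> protein pool.

Each selection round yields paired-end amplicon reads over a constant-flanked
insert.  The funnel merges each pair on its overlap, locates the constant
flanks, translates the in-frame insert, and deduplicates to a pool of unique
proteins.  Read counts are kept only as metadata: all downstream clustering
is count-free.  Every read is accounted for exactly once, either in the
surviving pool or in a named rejection counter.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ReadPair",
    "RoundPool",
    "Rejection",
    "merge_pairs",
    "extract_insert",
    "translate_insert",
    "build_pool",
    "process_reads",
    "read_fastq_pairs",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed read record (unequal sequence/quality, bad alphabet)."""


@dataclass(frozen=True)
class Rejection:
    """A counted, non-exceptional funnel outcome."""

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass
class ReadPair:
    id: str
    read1: str
    qual1: Sequence[int]
    read2: str
    qual2: Sequence[int]

    def __post_init__(self) -> None:
        for seq, qual in ((self.read1, self.qual1), (self.read2, self.qual2)):
            if len(seq) != len(qual):
                raise FormatError(f"{self.id}: sequence/quality length mismatch")
            if set(seq) - set("ACGTN"):
                raise FormatError(f"{self.id}: non-ACGTN base in read")


@dataclass
class RoundPool:
    """Unique proteins from one selection round.

    ``counts`` records read multiplicities as metadata only; ``provenance``
    counts reads discarded at each funnel stage.
    """

    label: str
    sequences: list[str]
    counts: dict[str, int] | None = None
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("duplicate sequences in pool")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("pool sequences differ in length")
        if self.counts is not None and any(c <= 0 for c in self.counts.values()):
            raise ValueError("counts must be positive")

    def __len__(self) -> int:
        return len(self.sequences)


def merge_pairs(
    pair: ReadPair, min_overlap: int = 12, max_mismatch_frac: float = 0.1
) -> str | Rejection:
    """Overlap-merge a read pair into one amplicon sequence.

    Read 2 is reverse-complemented, then the longest suffix of read 1
    matching a prefix of the flipped read 2 with mismatch fraction at most
    ``max_mismatch_frac`` (greedy maximal overlap) defines the join.  At
    overlap mismatches the higher-quality base wins; ties go to read 1.
    """
    if min_overlap < 8:
        raise ValueError("min_overlap must be >= 8")
    r1, q1 = pair.read1, list(pair.qual1)
    r2 = reverse_complement(pair.read2)
    q2 = list(pair.qual2)[::-1]
    max_ov = min(len(r1), len(r2))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail, head = r1[len(r1) - ov :], r2[:ov]
        mism = sum(1 for a, b in zip(tail, head) if a != b or a == "N")
        if mism / ov <= max_mismatch_frac:
            joined = []
            for k in range(ov):
                i1 = len(r1) - ov + k
                a, b = r1[i1], r2[k]
                if a == b:
                    joined.append(a)
                else:
                    qa = -1 if a == "N" else q1[i1]
                    qb = -1 if b == "N" else q2[k]
                    joined.append(a if qa >= qb else b)
            return r1[: len(r1) - ov] + "".join(joined) + r2[ov:]
    return Rejection("merge_failed")


def _best_flank_match(seq: str, flank: str, start: int = 0) -> tuple[int, int]:
    """(position, mismatches) of the best substitution-only flank placement."""
    best_pos, best_mm = -1, len(flank) + 1
    for i in range(start, len(seq) - len(flank) + 1):
        mm = sum(1 for a, b in zip(seq[i : i + len(flank)], flank) if a != b)
        if mm < best_mm:
            best_pos, best_mm = i, mm
            if mm == 0:
                break
    return best_pos, best_mm


def extract_insert(
    merged: str, design, max_flank_mismatch: int = 2
) -> str | Rejection:
    """Cut the DNA strictly between the design's constant flanks.

    Substitution-only flank matching (indels in a constant primer region
    would break the frame regardless).  If the forward orientation fails,
    the reverse complement is tried.
    """
    for seq in (merged, reverse_complement(merged)):
        p5, mm5 = _best_flank_match(seq, design.flank5_dna)
        if p5 < 0 or mm5 > max_flank_mismatch:
            continue
        insert_start = p5 + len(design.flank5_dna)
        p3, mm3 = _best_flank_match(seq, design.flank3_dna, start=insert_start)
        if p3 < 0 or mm3 > max_flank_mismatch:
            continue
        insert = seq[insert_start:p3]
        if len(insert) % 3 != 0:
            return Rejection("frameshift")
        return insert
    return Rejection("flank_not_found")


def translate_insert(insert: str) -> str | Rejection:
    """Standard-genetic-code translation of an in-frame insert."""
    if len(insert) % 3 != 0:
        raise ValueError("insert length not divisible by 3")
    if "N" in insert:
        return Rejection("ambiguous_codon")
    protein = str(Seq(insert).translate())
    if "*" in protein:
        return Rejection("internal_stop")
    return protein


def build_pool(
    proteins: Iterable[str],
    label: str,
    design,
    provenance: dict[str, int] | None = None,
) -> RoundPool:
    """Deduplicate translated proteins into a RoundPool.

    Entries whose length differs from the design length are counted under
    ``bad_length`` and dropped.  Counts keep multiplicities as metadata.
    """
    counts: Counter[str] = Counter()
    prov = dict(provenance or {})
    bad = 0
    for p in proteins:
        if len(p) != design.protein_length:
            bad += 1
        else:
            counts[p] += 1
    if bad:
        prov["bad_length"] = prov.get("bad_length", 0) + bad
    if not counts:
        raise ValueError("empty pool")
    # deterministic order: descending count then lexicographic
    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    return RoundPool(label=label, sequences=ordered, counts=dict(counts), provenance=prov)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Iterate ReadPairs from two parallel FASTQ files (gzip-transparent)."""
    with _open_text(path1) as fh1, _open_text(path2) as fh2:
        for rec1, rec2 in zip(
            SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq"), strict=True
        ):
            yield ReadPair(
                id=rec1.id,
                read1=str(rec1.seq).upper(),
                qual1=rec1.letter_annotations["phred_quality"],
                read2=str(rec2.seq).upper(),
                qual2=rec2.letter_annotations["phred_quality"],
            )


def process_reads(
    pairs: Iterable[ReadPair],
    design,
    label: str,
    min_overlap: int = 12,
    max_mismatch_frac: float = 0.1,
    max_flank_mismatch: int = 2,
    drop_cysteine: bool = False,
) -> RoundPool:
    """Run the full funnel over an iterable of read pairs.

    Provenance counters partition the input: ``reads_in`` equals the pool's
    total read count plus the sum of all rejection counters.
    """
    prov: Counter[str] = Counter()
    proteins: list[str] = []
    for pair in pairs:
        prov["reads_in"] += 1
        merged = merge_pairs(pair, min_overlap, max_mismatch_frac)
        if isinstance(merged, Rejection):
            prov[merged.reason] += 1
            continue
        insert = extract_insert(merged, design, max_flank_mismatch)
        if isinstance(insert, Rejection):
            prov[insert.reason] += 1
            continue
        protein = translate_insert(insert)
        if isinstance(protein, Rejection):
            prov[protein.reason] += 1
            continue
        if drop_cysteine and "C" in protein:
            prov["cysteine"] += 1
            continue
        proteins.append(protein)
    pool = build_pool(proteins, label, design, provenance=dict(prov))
    return pool


def write_pool_fasta(pool: RoundPool, path: str | Path) -> None:
    """Unique proteins as FASTA; header = label | ordinal | read count."""
    with open(path, "w") as fh:
        for i, seq in enumerate(pool.sequences, start=1):
            count = (pool.counts or {}).get(seq, 1)
            fh.write(f">{pool.label}_{i:06d} count={count}\n{seq}\n")


def read_pool_fasta(path: str | Path, label: str, design) -> RoundPool:
    """Load a pre-merged / pre-translated pool from FASTA."""
    proteins: list[str] = []
    counts: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        n = 1
        for tok in rec.description.split():
            if tok.startswith("count="):
                n = int(tok[6:])
        proteins.extend([seq] * 1)
        counts[seq] += n
    pool = build_pool(proteins, label, design)
    pool.counts = dict(counts)
    return pool


def write_provenance_tsv(pools: Sequence[RoundPool], path: str | Path) -> None:
    keys = sorted({k for p in pools for k in p.provenance})
    with open(path, "w") as fh:
        fh.write("pool\tunique_sequences\t" + "\t".join(keys) + "\n")
        for p in pools:
            vals = "\t".join(str(p.provenance.get(k, 0)) for k in keys)
            fh.write(f"{p.label}\t{len(p)}\t{vals}\n")
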