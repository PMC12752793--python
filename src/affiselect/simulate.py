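"""Synthetic display-selection campaigns with planted binder families.

Simulates, round by round, the population genetics of an in-vitro selection:
a randomized scaffold library seeded with planted binder families (each a
parent protein plus a mutational halo of near-neighbours), per-round
affinity capture against a background rate, an elution mode that either
keeps every binder (EDTA) or gates on epitope class (competition with a
known binder), RT/PCR substitution mutation, log-normally biased
amplification, and finally paired-end sequencing with substitution errors.

The generator emits paired FASTQ plus a truth ledger naming each read's
source protein and family, so that the read-processing funnel and the
clustering stage can be scored against planted ground truth.

In the deterministic (infinite-population) limit a single binder family at
frequency f with capture probability w against background b enriches to

    f' = f*w / (f*w + (1 - f)*b)

per round; the stochastic simulation matches this in expectation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import LibraryDesign
from .grantham import AMINO_ACIDS, sequence_distance
from .read_processing import reverse_complement

__all__ = [
    "BinderFamily",
    "CampaignConfig",
    "WeightedPool",
    "simulate_library",
    "simulate_round",
    "emit_fastq",
    "run_campaign",
    "generate_separated_parents",
    "ExtinctionError",
]

# one fixed codon per residue (E. coli-common choices); used for scaffold
# and for encoding planted protein variants back to DNA
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAC",
}

# NNS codons (N = ACGT, S = CG) minus the amber stop TAG
_NNS_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "CG"
]
from Bio.Seq import Seq as _Seq

_NNS_SENSE = [c for c in _NNS_CODONS if str(_Seq(c).translate()) != "*"]


class ExtinctionError(RuntimeError):
    """No molecule survived a round; retry with another seed or milder settings."""


@dataclass(frozen=True)
class BinderFamily:
    """A planted binder: parent protein, capture fitness, epitope class, halo.

    ``halo_rate`` is the per-randomized-position substitution probability
    used when spiking family variants into the naive library;
    ``initial_freq`` the family's share of the naive library;
    ``halo_candidates``, if set, restricts halo substitutions to residues
    within that Grantham distance of the parent residue (bounding the
    family radius).
    """

    parent: str
    fitness: float
    epitope_class: str = "A1-competable"
    halo_rate: float = 0.02
    initial_freq: float = 0.001
    halo_candidates: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fitness <= 1:
            raise ValueError("fitness must be in (0, 1]")
        if not 0 <= self.initial_freq <= 1:
            raise ValueError("initial_freq must be in [0, 1]")


@dataclass(frozen=True)
class CampaignConfig:
    design: LibraryDesign
    families: tuple[BinderFamily, ...] = ()
    n_rounds: int = 4
    elution_schedule: tuple[str, ...] | None = None  # per-round EDTA|competition
    background_capture: float = 0.005
    mutation_rate: float = 1e-4  # per base per round (RT/PCR)
    pcr_bias_sd: float = 0.5  # sigma of log-normal amplification factors
    reads_per_round: int = 20000
    seq_error_rate: float = 1e-3  # per base sequencing substitution
    pool_size: int = 100000  # molecules carried between rounds
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.reads_per_round < 1:
            raise ValueError("n_rounds and reads_per_round must be >= 1")
        for p in (self.background_capture, self.mutation_rate, self.seq_error_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.elution_schedule is not None:
            if len(self.elution_schedule) != self.n_rounds:
                raise ValueError("elution_schedule length != n_rounds")
            if set(self.elution_schedule) - {"EDTA", "competition"}:
                raise ValueError("elution modes are EDTA or competition")
        for fam in self.families:
            if len(fam.parent) != self.design.protein_length:
                raise ValueError("family parent length != design length")

    def elution(self, round_index: int) -> str:
        if self.elution_schedule is None:
            return "EDTA"
        return self.elution_schedule[round_index]


@dataclass
class WeightedPool:
    """Unique DNA inserts with integer molecule counts and family labels."""

    dna: list[str]
    counts: np.ndarray  # integer molecule counts
    family: list[int]  # family index or -1 for background

    def total(self) -> int:
        return int(self.counts.sum())

    def compact(self) -> "WeightedPool":
        keep = self.counts > 0
        return WeightedPool(
            dna=[d for d, k in zip(self.dna, keep) if k],
            counts=self.counts[keep].copy(),
            family=[f for f, k in zip(self.family, keep) if k],
        )


def _encode_protein(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein)


def _random_insert(design: LibraryDesign, rng: np.random.Generator) -> str:
    codons = [_CODON[aa] for aa in design.scaffold]
    for p in design.randomized_positions:
        codons[p] = _NNS_SENSE[rng.integers(len(_NNS_SENSE))]
    return "".join(codons)


def _halo_variant(
    fam: BinderFamily, design: LibraryDesign, rng: np.random.Generator
) -> str:
    residues = list(fam.parent)
    for p in design.randomized_positions:
        if rng.random() < fam.halo_rate:
            if fam.halo_candidates is not None:
                options = [
                    aa
                    for aa in AMINO_ACIDS
                    if aa != residues[p]
                    and sequence_distance(aa, residues[p]) <= fam.halo_candidates
                ]
            else:
                options = [aa for aa in AMINO_ACIDS if aa != residues[p]]
            if options:
                residues[p] = options[rng.integers(len(options))]
    return _encode_protein("".join(residues))


def simulate_library(
    config: CampaignConfig, n: int, rng: np.random.Generator | None = None
) -> WeightedPool:
    """Draw the naive (round-0) library of ``n`` molecules.

    Randomized positions receive NNS codons (stop-free sense subset);
    scaffold positions the fixed scaffold codons.  Each planted family
    contributes ``round(n * initial_freq)`` molecules, drawn as the parent
    with per-position halo substitutions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if config.design.scaffold is None:
        raise ValueError("design.scaffold is required for simulation")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    molecules: dict[tuple[str, int], int] = {}
    n_family = [int(round(n * f.initial_freq)) for f in config.families]
    n_bg = n - sum(n_family)
    for fi, (fam, nf) in enumerate(zip(config.families, n_family)):
        for _ in range(nf):
            key = (_halo_variant(fam, config.design, rng), fi)
            molecules[key] = molecules.get(key, 0) + 1
    for _ in range(n_bg):
        key = (_random_insert(config.design, rng), -1)
        molecules[key] = molecules.get(key, 0) + 1
    keys = sorted(molecules)
    return WeightedPool(
        dna=[k[0] for k in keys],
        counts=np.array([molecules[k] for k in keys], dtype=np.int64),
        family=[k[1] for k in keys],
    )


def _capture_probability(
    family_index: int, config: CampaignConfig, elution: str
) -> float:
    if family_index < 0:
        return config.background_capture
    fam = config.families[family_index]
    if elution == "competition" and fam.epitope_class != "A1-competable":
        return config.background_capture
    return fam.fitness


def simulate_round(
    pool: WeightedPool,
    config: CampaignConfig,
    round_index: int,
    rng: np.random.Generator | None = None,
) -> WeightedPool:
    """One capture -> elution -> mutation -> amplification cycle.

    Capture is binomial per unique sequence at the molecule's capture
    probability (family fitness, or background for non-binders and for
    non-competable binders under competition elution).  Survivors mutate at
    ``mutation_rate`` per base; amplification multiplies each unique
    sequence's count by an i.i.d. log-normal factor (``pcr_bias_sd``) and
    the pool is resampled back to ``pool_size`` molecules.
    """
    if pool.total() == 0:
        raise ExtinctionError("empty input pool")
    rng = rng if rng is not None else np.random.default_rng(config.seed + round_index + 1)
    elution = config.elution(round_index)

    probs = np.array(
        [_capture_probability(f, config, elution) for f in pool.family]
    )
    survivors = rng.binomial(pool.counts, probs)
    if survivors.sum() == 0:
        raise ExtinctionError(f"no survivors in round {round_index}")
    pool = WeightedPool(dna=list(pool.dna), counts=survivors, family=list(pool.family)).compact()

    # RT/PCR substitution mutation: expected count*L*mu events; each event
    # moves one molecule copy to a single-substitution neighbour
    if config.mutation_rate > 0:
        L = len(pool.dna[0])
        new: dict[tuple[str, int], int] = {}
        for dna, cnt, fam in zip(pool.dna, pool.counts, pool.family):
            n_events = rng.binomial(int(cnt) * L, config.mutation_rate)
            n_events = min(n_events, int(cnt))
            if n_events:
                pool_counts_remaining = int(cnt) - n_events
                for _ in range(n_events):
                    site = rng.integers(L)
                    base = dna[site]
                    alt = "ACGT".replace(base, "")[rng.integers(3)]
                    mut = dna[:site] + alt + dna[site + 1 :]
                    key = (mut, fam)
                    new[key] = new.get(key, 0) + 1
                cnt = pool_counts_remaining
            key = (dna, fam)
            new[key] = new.get(key, 0) + int(cnt)
        keys = sorted(new)
        pool = WeightedPool(
            dna=[k[0] for k in keys],
            counts=np.array([new[k] for k in keys], dtype=np.int64),
            family=[k[1] for k in keys],
        ).compact()

    # biased amplification then multinomial resampling to pool_size
    factors = (
        rng.lognormal(0.0, config.pcr_bias_sd, size=len(pool.dna))
        if config.pcr_bias_sd > 0
        else np.ones(len(pool.dna))
    )
    weights = pool.counts * factors
    resampled = rng.multinomial(config.pool_size, weights / weights.sum())
    return WeightedPool(
        dna=list(pool.dna), counts=resampled.astype(np.int64), family=list(pool.family)
    ).compact()


def _apply_seq_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = list(read)
    n_err = rng.binomial(len(arr), rate)
    for _ in range(n_err):
        site = rng.integers(len(arr))
        arr[site] = "ACGT".replace(arr[site], "")[rng.integers(3)]
    return "".join(arr)


def emit_fastq(
    pool: WeightedPool,
    config: CampaignConfig,
    round_label: str,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[Path, Path, Path]:
    """Sample reads from a pool and write paired FASTQ plus a truth ledger.

    Reads are drawn multinomially in proportion to molecule counts; each
    amplicon is flank5 + insert + flank3; read 1 covers the 5' end, read 2
    the reverse complement of the 3' end, both truncated to the read length;
    substitution errors at ``seq_error_rate``; constant Q40 qualities.
    Returns (fastq_r1, fastq_r2, ledger) paths.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p1 = out_dir / f"{round_label}_R1.fastq.gz"
    p2 = out_dir / f"{round_label}_R2.fastq.gz"
    pl = out_dir / f"{round_label}_truth.tsv"

    weights = pool.counts / pool.counts.sum()
    draws = rng.multinomial(config.reads_per_round, weights)
    design = config.design
    from Bio.Seq import Seq

    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2, open(pl, "w") as fl:
        fl.write("read_id\tinsert_dna\tprotein\tfamily\n")
        read_no = 0
        for dna, n_reads, fam in zip(pool.dna, draws, pool.family):
            if n_reads == 0:
                continue
            amplicon = design.flank5_dna + dna + design.flank3_dna
            rlen = min(config.read_length, len(amplicon))
            protein = str(Seq(dna).translate())
            fam_label = f"family_{fam}" if fam >= 0 else "background"
            for _ in range(n_reads):
                read_no += 1
                rid = f"{round_label}:{read_no:07d}"
                r1 = _apply_seq_errors(amplicon[:rlen], config.seq_error_rate, rng)
                r2 = _apply_seq_errors(
                    reverse_complement(amplicon)[:rlen], config.seq_error_rate, rng
                )
                q = "I" * rlen
                f1.write(f"@{rid}/1\n{r1}\n+\n{q}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{q}\n")
                fl.write(f"{rid}\t{dna}\t{protein}\t{fam_label}\n")
    return p1, p2, pl


def run_campaign(
    config: CampaignConfig, out_dir: str | Path
) -> pd.DataFrame:
    """Simulate the full campaign; write per-round FASTQ/ledgers and a summary.

    Returns the per-round summary table (round, elution mode, unique
    sequences, binder fraction, top-read share).
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    pool = simulate_library(config, config.pool_size, rng)
    rows = []
    for r in range(config.n_rounds):
        pool = simulate_round(pool, config, r, rng)
        label = f"R{r + 1}"
        emit_fastq(pool, config, label, out_dir, rng)
        counts = pool.counts
        binder = counts[[f >= 0 for f in pool.family]].sum() / counts.sum()
        rows.append(
            {
                "round": label,
                "elution": config.elution(r),
                "unique_sequences": len(pool.dna),
                "binder_fraction": float(binder),
                "top_read_share": float(counts.max() / counts.sum()),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "campaign_summary.tsv", sep="\t", index=False)
    return summary


def expected_enrichment(f: float, w: float, b: float) -> float:
    """Deterministic-limit binder frequency after one round."""
    return f * w / (f * w + (1 - f) * b)


def generate_separated_parents(
    design: LibraryDesign,
    n_families: int,
    min_distance: float,
    rng: np.random.Generator,
    max_tries: int = 10000,
) -> list[str]:
    """Rejection-sample parent proteins with pairwise Grantham distance
    >= ``min_distance`` (differences only at randomized positions)."""
    if design.scaffold is None:
        raise ValueError("design.scaffold required")
    parents: list[str] = []
    for _ in range(max_tries):
        residues = list(design.scaffold)
        for p in design.randomized_positions:
            residues[p] = AMINO_ACIDS[rng.integers(20)]
        cand = "".join(residues)
        if all(sequence_distance(cand, p) >= min_distance for p in parents):
            parents.append(cand)
            if len(parents) == n_families:
                return parents
    raise RuntimeError(
        f"could not place {n_families} parents at min distance {min_distance}"
    )
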