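"""End-to-end campaign pipeline and report assembly.

Binds the computational stages together in the order of a selection
campaign: per-round reads -> unique-protein pools -> count-free clustering
-> consensus dendrogram -> representative picking, plus a quantitation
report table over kinetic and dose-response fits.  Every output file opens
with a header comment recording tool version, seed, and a hash of the
configuration, and reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterSet,
    build_dendrogram,
    cluster_pool,
    heatmap_matrix,
    linkage_to_newick,
    logo_matrix,
    select_representatives,
)
from .design import LibraryDesign
from .read_processing import (
    RoundPool,
    process_reads,
    read_fastq_pairs,
    read_pool_fasta,
    write_pool_fasta,
    write_provenance_tsv,
)

log = logging.getLogger("affiselect")

__all__ = ["PipelineConfig", "run_pipeline", "quantitation_report", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    design: LibraryDesign
    rounds: dict[str, tuple[str, ...]]  # label -> (r1.fastq, r2.fastq) or (pool.fasta,)
    out_dir: str = "results"
    linkage: str = "average"
    cutoff: float | None = 100.0
    n_clusters: int | None = None
    positions: str = "all"
    consensus_mode: str = "grantham"
    n_representatives: int = 25
    drop_cysteine: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        design = LibraryDesign.from_yaml(raw["design"]) if isinstance(
            raw["design"], str
        ) else LibraryDesign(**raw["design"])
        rounds = {k: tuple(v) for k, v in raw["rounds"].items()}
        kwargs = {k: raw[k] for k in (
            "out_dir", "linkage", "cutoff", "n_clusters", "positions",
            "consensus_mode", "n_representatives", "drop_cysteine", "seed",
        ) if k in raw}
        return cls(design=design, rounds=rounds, **kwargs)

    def digest(self) -> str:
        # analytic parameters only: the output location does not change results
        payload = {
            k: v for k, v in self.__dict__.items() if k not in ("design", "out_dir")
        }
        payload["design"] = self.design.name
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (
        f"# affiselect {__version__} seed={config.seed} config={config.digest()}\n"
    )


def _load_round(label: str, files: Sequence[str], config: PipelineConfig) -> RoundPool:
    paths = [Path(f) for f in files]
    for p in paths:
        if not p.exists():
            raise PipelineError("read_processing", f"missing input file {p} for round {label}")
    if len(paths) == 1:  # pre-merged / pre-translated FASTA pool
        return read_pool_fasta(paths[0], label, config.design)
    if len(paths) != 2:
        raise PipelineError("read_processing", f"round {label}: expected 1 or 2 files")
    return process_reads(
        read_fastq_pairs(paths[0], paths[1]),
        config.design,
        label,
        drop_cysteine=config.drop_cysteine,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run reads -> pools -> clustering -> representatives; write the bundle.

    Clustering runs on the union of unique sequences over all rounds (the
    campaign-wide sequence space); per-round pools, the cluster table,
    consensus FASTA, newick dendrogram, logo and heatmap matrices, the
    representative list and a JSON summary are written under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config)

    pools: list[RoundPool] = []
    for label in sorted(config.rounds):
        log.info("processing round %s", label)
        pool = _load_round(label, config.rounds[label], config)
        pools.append(pool)
        write_pool_fasta(pool, out / f"pool_{label}.fasta")
    write_provenance_tsv(pools, out / "provenance.tsv")

    union = sorted({s for p in pools for s in p.sequences})
    round_of = {}
    for p in pools:
        for s in p.sequences:
            round_of.setdefault(s, p.label)

    log.info("clustering %d unique sequences", len(union))
    try:
        clusters = cluster_pool(
            union,
            linkage=config.linkage,
            cutoff=config.cutoff,
            n_clusters=config.n_clusters,
            positions=config.positions,
            consensus_mode=config.consensus_mode,
        )
    except ValueError as exc:
        raise PipelineError("clustering", str(exc)) from exc

    with open(out / "clusters.tsv", "w") as fh:
        fh.write(header)
        fh.write("sequence\tround\tcluster\tdistance_to_consensus\n")
        from .grantham import sequence_distance

        for cid, cluster in enumerate(clusters.clusters):
            for seq in sorted(cluster.members):
                d = sequence_distance(seq, cluster.consensus)
                fh.write(f"{seq}\t{round_of[seq]}\t{cid}\t{d:g}\n")

    with open(out / "consensus.fasta", "w") as fh:
        for cid, cluster in enumerate(clusters.clusters):
            fh.write(
                f">cluster_{cid:03d} size={cluster.size} diversity={cluster.diversity:.2f}\n"
                f"{cluster.consensus}\n"
            )

    if len(clusters) >= 2:
        Z = build_dendrogram(clusters.consensuses)
        labels = [f"cluster_{i:03d}" for i in range(len(clusters))]
        (out / "dendrogram.nwk").write_text(linkage_to_newick(Z, labels) + "\n")

    logo = logo_matrix(union)
    with open(out / "logo_matrix.tsv", "w") as fh:
        fh.write(header)
        logo.to_csv(fh, sep="\t", index_label="position")

    hm = heatmap_matrix(clusters)
    with open(out / "heatmap_matrix.tsv", "w") as fh:
        fh.write(header)
        hm.to_csv(fh, sep="\t")

    n_rep = min(config.n_representatives, len(clusters))
    reps = select_representatives(clusters, n_rep)
    with open(out / "representatives.fasta", "w") as fh:
        for i, seq in enumerate(reps, 1):
            fh.write(f">representative_{i:03d}\n{seq}\n")

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": config.digest(),
        "rounds": {p.label: {"unique_sequences": len(p), **p.provenance} for p in pools},
        "union_unique_sequences": len(union),
        "n_clusters": len(clusters),
        "n_representatives": n_rep,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def quantitation_report(
    fits: dict[str, object], pairs: Sequence[tuple[str, str]] = ()
) -> pd.DataFrame:
    """Tabulate kinetic / dose-response fits with fold-change comparisons.

    ``fits`` maps a label to a KineticFit or OneSiteFit; ``pairs`` declares
    (numerator, denominator) labels whose KD or half-dose ratio is added as
    a fold-change row.
    """
    from .doseresponse import OneSiteFit, fold_change
    from .kinetics import KineticFit

    if not fits:
        raise ValueError("no fits to report")
    rows = []
    for label, fit in fits.items():
        if isinstance(fit, KineticFit):
            rows.append(
                {"label": label, "kind": fit.model, "top": fit.rmax,
                 "half_dose_or_KD_M": fit.KD, "rss": fit.rss}
            )
        elif isinstance(fit, OneSiteFit):
            rows.append(
                {"label": label, "kind": "one_site", "top": fit.top,
                 "half_dose_or_KD_M": fit.half_dose, "rss": fit.rss}
            )
        else:
            raise TypeError(f"unsupported fit type for {label}: {type(fit)!r}")
    table = pd.DataFrame(rows).set_index("label")
    for num, den in pairs:
        table.loc[f"{num}/{den}", "kind"] = "fold_change"
        table.loc[f"{num}/{den}", "half_dose_or_KD_M"] = fold_change(
            table.loc[num, "half_dose_or_KD_M"], table.loc[den, "half_dose_or_KD_M"]
        )
    return table
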