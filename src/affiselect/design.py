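"""Library designs: the coordinate frame shared by all sequences in a campaign.

A display library is a fixed-length scaffold protein with a declared set of
randomized surface positions, flanked in the amplicon by constant DNA from
the library-specific PCR primers.  Every downstream step (insert extraction,
translation, clustering, simulation) works in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["LibraryDesign", "DEFAULT_DESIGN"]

_DNA = set("ACGT")


@dataclass(frozen=True)
class LibraryDesign:
    """Scaffold template plus randomized positions and constant flanks.

    Parameters
    ----------
    name : short library label (e.g. ``"L5"``, ``"L6"``).
    protein_length : length of the displayed protein, in residues.
    randomized_positions : 0-based residue indices that were randomized.
    flank5_dna, flank3_dna : constant DNA immediately before / after the
        insert in the sequenced amplicon (gene-specific primer tails).
    scaffold : optional full-length scaffold protein; randomized positions
        in it are placeholders only.  Required by the simulator.
    """

    name: str
    protein_length: int
    randomized_positions: tuple[int, ...]
    flank5_dna: str
    flank3_dna: str
    scaffold: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.protein_length <= 0:
            raise ValueError("protein_length must be positive")
        pos = tuple(sorted(set(int(p) for p in self.randomized_positions)))
        object.__setattr__(self, "randomized_positions", pos)
        if pos and (pos[0] < 0 or pos[-1] >= self.protein_length):
            raise ValueError("randomized_positions outside [0, protein_length)")
        for label, flank in (("flank5_dna", self.flank5_dna), ("flank3_dna", self.flank3_dna)):
            if not flank or set(flank) - _DNA:
                raise ValueError(f"{label} must be non-empty uppercase DNA over ACGT")
        if self.scaffold is not None and len(self.scaffold) != self.protein_length:
            raise ValueError("scaffold length != protein_length")

    @property
    def insert_length(self) -> int:
        """Expected insert length in nucleotides (3 x protein_length)."""
        return 3 * self.protein_length

    @classmethod
    def from_yaml(cls, path: str) -> "LibraryDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            name=raw["name"],
            protein_length=int(raw["protein_length"]),
            randomized_positions=tuple(raw["randomized_positions"]),
            flank5_dna=raw["flank5_dna"].upper(),
            flank3_dna=raw["flank3_dna"].upper(),
            scaffold=raw.get("scaffold"),
        )

    def to_yaml(self, path: str) -> None:
        data = {
            "name": self.name,
            "protein_length": self.protein_length,
            "randomized_positions": list(self.randomized_positions),
            "flank5_dna": self.flank5_dna,
            "flank3_dna": self.flank3_dna,
        }
        if self.scaffold is not None:
            data["scaffold"] = self.scaffold
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# A synthetic Sul7d-like design used as the default simulation frame: a
# 60-residue scaffold with ten randomized binding-surface positions
# (residues 9, 10, 27, 29, 31, 33, 35, 37, 44, 46 in 1-based numbering).
# The scaffold protein is an invented stand-in, not a natural sequence;
# the flanks are gene-specific amplicon-PCR primer tails.
DEFAULT_DESIGN = LibraryDesign(
    name="L6-sim",
    protein_length=60,
    randomized_positions=(8, 9, 26, 28, 30, 32, 34, 36, 43, 45),
    flank5_dna="ATCCGCGACCAAAGTAAAATTC",
    flank3_dna="CTGCTGGAGAAACTGAAGCT",
    scaffold=(
        "MVKVKFKYKGXXKEVDTSKIKKVWRVGKMXSXTXDXVXLXAEGNGFXIXLADDVDKAFGK"
    ).replace("X", "A"),
)
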