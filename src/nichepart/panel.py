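"""Marker panels for strain-resolved amplicon typing.

A panel describes one short amplified marker (in the motivating system, a
199-bp fragment of a housekeeping gene shared by four *Lactobacillus*
species of the honey-bee gut) together with the positions at which the
strains carry discriminatory SNPs.  A merged amplicon read is assigned to a
strain by reading off the bases at those positions and matching them
against each strain's expected SNP profile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised when a marker panel violates its invariants."""


@dataclass(frozen=True)
class MarkerPanel:
    """Per-strain marker references and discriminatory SNP profiles.

    Parameters
    ----------
    strain_names
        Strain identifiers, one per reference sequence.
    reference_sequences
        One uppercase A/C/G/T string per strain; all the same length.
    snp_positions
        0-based offsets (within the merged amplicon) of the discriminatory
        positions, strictly increasing.
    snp_profiles
        For each strain, the expected base at each ``snp_position``.
        Profiles must be pairwise distinct.
    """

    strain_names: tuple[str, ...]
    reference_sequences: tuple[str, ...]
    snp_positions: tuple[int, ...]
    snp_profiles: tuple[tuple[str, ...], ...]
    _lookup: dict[tuple[str, ...], str] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.validate()
        object.__setattr__(
            self,
            "_lookup",
            {prof: name for name, prof in zip(self.strain_names, self.snp_profiles)},
        )

    @property
    def marker_length(self) -> int:
        return len(self.reference_sequences[0])

    @property
    def n_strains(self) -> int:
        return len(self.strain_names)

    def validate(self) -> None:
        if not self.strain_names:
            raise PanelError("panel has no strains")
        if len(set(self.strain_names)) != len(self.strain_names):
            raise PanelError("duplicate strain names")
        if len(self.reference_sequences) != len(self.strain_names):
            raise PanelError("one reference sequence required per strain")
        length = len(self.reference_sequences[0])
        for name, seq in zip(self.strain_names, self.reference_sequences):
            if len(seq) != length:
                raise PanelError(f"reference for {name} has length {len(seq)} != {length}")
            if not set(seq) <= _VALID_BASES:
                raise PanelError(f"reference for {name} contains non-ACGT characters")
        if list(self.snp_positions) != sorted(set(self.snp_positions)):
            raise PanelError("snp_positions must be strictly increasing and unique")
        if self.snp_positions and not (0 <= self.snp_positions[0] and self.snp_positions[-1] < length):
            raise PanelError("snp_positions must lie within the marker")
        if not self.snp_positions:
            raise PanelError("panel needs at least one SNP position")
        if len(self.snp_profiles) != len(self.strain_names):
            raise PanelError("one SNP profile required per strain")
        for name, prof, seq in zip(self.strain_names, self.snp_profiles, self.reference_sequences):
            if len(prof) != len(self.snp_positions):
                raise PanelError(f"profile for {name} has wrong length")
            for pos, base in zip(self.snp_positions, prof):
                if seq[pos] != base:
                    raise PanelError(
                        f"profile for {name} disagrees with its reference at position {pos}"
                    )
        if len(set(self.snp_profiles)) != len(self.snp_profiles):
            raise PanelError("SNP profiles are not pairwise distinct")

    @classmethod
    def from_references(
        cls,
        strain_names: list[str] | tuple[str, ...],
        reference_sequences: list[str] | tuple[str, ...],
        snp_positions: list[int] | tuple[int, ...],
    ) -> "MarkerPanel":
        """Build a panel, deriving SNP profiles from the references."""
        if reference_sequences and snp_positions:
            shortest = min(len(s) for s in reference_sequences)
            if any(p < 0 or p >= shortest for p in snp_positions):
                raise PanelError("snp_positions must lie within every reference")
        profiles = tuple(
            tuple(seq[pos] for pos in snp_positions) for seq in reference_sequences
        )
        return cls(
            tuple(strain_names),
            tuple(s.upper() for s in reference_sequences),
            tuple(int(p) for p in snp_positions),
            profiles,
        )

    def profile_of(self, consensus: str) -> tuple[str, ...]:
        """Bases of ``consensus`` at the panel's SNP positions."""
        return tuple(consensus[p] for p in self.snp_positions)

    def match(self, profile: tuple[str, ...]) -> str | None:
        """Exact-profile strain lookup; ``None`` when no strain matches."""
        return self._lookup.get(profile)

    # -- plain-text round trip --------------------------------------------

    def to_files(self, fasta_path: str | Path, tsv_path: str | Path) -> None:
        """Write references as FASTA and SNP profiles as a 3-column TSV."""
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in zip(self.strain_names, self.reference_sequences)
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        with open(tsv_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["position", "strain", "expected_base"])
            for pos, column in zip(
                self.snp_positions, zip(*self.snp_profiles)
            ):
                for strain, base in zip(self.strain_names, column):
                    writer.writerow([pos, strain, base])

    @classmethod
    def from_files(cls, fasta_path: str | Path, tsv_path: str | Path) -> "MarkerPanel":
        """Load a panel from a FASTA of markers and a (position, strain, base) TSV."""
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if not records:
            raise PanelError(f"no sequences in {fasta_path}")
        names = [r.id for r in records]
        seqs = [str(r.seq).upper() for r in records]
        positions: list[int] = []
        with open(tsv_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                pos = int(row["position"])
                if pos not in positions:
                    positions.append(pos)
                strain = row["strain"]
                if strain not in names:
                    raise PanelError(f"TSV names unknown strain {strain!r}")
                idx = names.index(strain)
                if seqs[idx][pos] != row["expected_base"].upper():
                    raise PanelError(
                        f"TSV base for {strain} at {pos} disagrees with FASTA reference"
                    )
        return cls.from_references(names, seqs, sorted(positions))
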