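"""Target RNA definitions and run configuration.

A targeted probing run interrogates a small panel of known RNAs.  Each
target is a sequence plus two coordinate annotations: the probed region
(positions 1..n, numbered 5'->3' from the transcription start) and the
site where the reverse-transcription (RT) primer anneals.  RT initiates
at the primer and extends 3'->5' across the probed region, so every
position the cDNA can report on lies strictly 5' of the primer site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

_RNA_BASES = set("ACGU")
_DNA_TO_RNA = str.maketrans("Tt", "Uu")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_COMPLEMENT_DNA = str.maketrans("ACGTacgt", "TGCAtgca")


def as_rna(sequence: str) -> str:
    """Uppercase RNA alphabet (T -> U)."""
    return sequence.upper().translate(_DNA_TO_RNA)


def as_dna(sequence: str) -> str:
    """Uppercase DNA alphabet (U -> T), as it appears in sequencing reads."""
    return sequence.upper().translate(_RNA_TO_DNA)


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT_DNA)[::-1]


@dataclass(frozen=True)
class TargetRNA:
    """A probed RNA target.

    Parameters
    ----------
    name : str
        Unique identifier within a run.
    sequence : str
        Full-length RNA sequence, 5'->3', position 1 = transcription start.
        DNA input (T) is converted to RNA (U).
    probed_end : int
        n, the last probed position; the probed region is [1, n].
    rt_primer_start, rt_primer_end : int
        1-based inclusive interval on the target where the RT primer anneals.
        Must lie strictly 3' of the probed region.
    """

    name: str
    sequence: str
    probed_end: int
    rt_primer_start: int
    rt_primer_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", as_rna(self.sequence))
        bad = set(self.sequence) - _RNA_BASES
        if bad:
            raise ValueError(f"target {self.name!r}: non-ACGU characters {sorted(bad)}")
        if not 1 <= self.probed_end < self.rt_primer_start:
            raise ValueError(
                f"target {self.name!r}: probed region [1, {self.probed_end}] must lie "
                f"strictly 5' of the RT primer site (starts {self.rt_primer_start})"
            )
        if not self.rt_primer_start <= self.rt_primer_end <= len(self.sequence):
            raise ValueError(f"target {self.name!r}: RT primer interval out of range")

    @property
    def n(self) -> int:
        """Number of probed nucleotides."""
        return self.probed_end

    @property
    def probed_sequence(self) -> str:
        return self.sequence[: self.probed_end]

    @property
    def rt_primer_site_sequence(self) -> str:
        """Sense-strand sequence under the RT primer (the primer itself is its
        reverse complement)."""
        return self.sequence[self.rt_primer_start - 1 : self.rt_primer_end]

    @property
    def rt_primer_sequence(self) -> str:
        """The RT primer oligo (DNA, 5'->3')."""
        return reverse_complement(as_dna(self.rt_primer_site_sequence))

    def subsequence(self, start: int, end: int) -> str:
        """1-based inclusive subsequence."""
        if not 1 <= start <= end <= len(self.sequence):
            raise ValueError(f"interval [{start}, {end}] out of range or reversed")
        return self.sequence[start - 1 : end]


@dataclass
class RunConfig:
    """Run-level configuration: targets, channel handles, adapter.

    The handle barcodes distinguishing the (+) and (-) channels are not
    universal constants; they are required configuration with the
    conventional defaults plus="RRRY" / minus="YYYR" (IUPAC codes).
    """

    targets: list[TargetRNA] = field(default_factory=list)
    plus_handle: str = "RRRY"
    minus_handle: str = "YYYR"
    adapter: str = "AGATCGGAAGAGC"
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        names = [t.name for t in self.targets]
        if len(names) != len(set(names)):
            raise ValueError("target names must be unique within a run")
        if len(self.plus_handle) != len(self.minus_handle):
            raise ValueError("handle patterns must have equal length")

    def target(self, name: str) -> TargetRNA:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(name)


def read_targets_fasta(path: str | Path, primer_sites: dict[str, tuple[int, int]],
                       probed_ends: dict[str, int] | None = None) -> list[TargetRNA]:
    """Load targets from FASTA plus per-target RT-primer coordinates.

    ``probed_ends`` defaults each target's probed region to end one
    nucleotide before its RT primer.
    """
    targets = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in primer_sites:
            raise KeyError(f"no RT primer coordinates for target {rec.id!r}")
        start, end = primer_sites[rec.id]
        probed_end = (probed_ends or {}).get(rec.id, start - 1)
        targets.append(TargetRNA(rec.id, str(rec.seq), probed_end, start, end))
    return targets


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    Expected layout::

        adapter: AGATCGGAAGAGC
        plus_handle: RRRY
        minus_handle: YYYR
        max_mismatches: 1
        targets:
          - name: crR12
            sequence: GGG...   # or fasta: targets.fa (relative to the config)
            probed_end: 60
            rt_primer_start: 61
            rt_primer_end: 80
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    targets = []
    for entry in raw.get("targets", []):
        if "fasta" in entry:
            seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(path.parent / entry["fasta"]), "fasta")}
            sequence = seqs[entry["name"]]
        else:
            sequence = entry["sequence"]
        targets.append(
            TargetRNA(
                name=entry["name"],
                sequence=sequence,
                probed_end=int(entry["probed_end"]),
                rt_primer_start=int(entry["rt_primer_start"]),
                rt_primer_end=int(entry["rt_primer_end"]),
            )
        )
    return RunConfig(
        targets=targets,
        plus_handle=raw.get("plus_handle", "RRRY"),
        minus_handle=raw.get("minus_handle", "YYYR"),
        adapter=raw.get("adapter", "AGATCGGAAGAGC"),
        max_mismatches=int(raw.get("max_mismatches", 1)),
    )
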