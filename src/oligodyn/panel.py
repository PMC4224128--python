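"""Reference sequence panels with taxonomy.

A :class:`ReferencePanel` plays the role a curated 16S reference collection
(e.g. an oral-microbiome full-length rRNA database) plays in a real
analysis: every entry carries a nucleotide sequence plus family / genus /
species labels and a taxon identifier.  Panels round-trip through FASTA
with pipe-delimited taxonomy in the description line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PanelEntry:
    """One reference sequence with its taxonomy."""

    name: str
    sequence: str
    family: str
    genus: str
    species: str
    taxon_id: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("panel entry name must be non-empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"entry {self.name!r}: sequence contains non-ACGT symbols {sorted(bad)}"
            )
        for field in ("family", "genus", "species", "taxon_id"):
            if not getattr(self, field):
                raise ValueError(f"entry {self.name!r}: taxonomy field {field!r} is empty")


class ReferencePanel:
    """An ordered collection of uniquely named reference sequences."""

    def __init__(self, entries: Iterable[PanelEntry]):
        self.entries: list[PanelEntry] = list(entries)
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate entry names in panel: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __getitem__(self, name: str) -> PanelEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.family, None)
        return list(seen)

    def to_fasta(self, path: str | Path) -> None:
        """Write the panel as FASTA with ``name|family|genus|species|taxon_id`` headers."""
        records = [
            SeqRecord(
                Seq(e.sequence),
                id=f"{e.name}|{e.family}|{e.genus}|{e.species}|{e.taxon_id}",
                description="",
            )
            for e in self.entries
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferencePanel":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 5:
                raise ValueError(
                    f"reference header {rec.id!r} must have 5 pipe-delimited fields "
                    "(name|family|genus|species|taxon_id)"
                )
            entries.append(PanelEntry(parts[0], str(rec.seq).upper(), *parts[1:]))
        return cls(entries)
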