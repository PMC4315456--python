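"""Reference 16S sequences, Greengenes-style taxonomy, and per-rank grouping.

A reference collection pairs a FASTA file of (near) full-length 16S rRNA
sequences with a two-column TSV mapping sequence id to a seven-rank lineage
string.  Lineages are accepted either rank-tagged (``k__Bacteria; p__...``)
or as bare semicolon-separated names, and are normalised internally to the
rank-tagged form.  Training groups sequences by the taxon name they carry at
one rank (phylum ... genus); each such group is the one-vs-rest unit used
downstream for training and for confusion counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)
#: Ranks at which classifiers are trained (the tool classifies phylum->genus).
CLASSIFY_RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus")

RANK_TAGS: dict[str, str] = {
    "kingdom": "k", "phylum": "p", "class": "c", "order": "o",
    "family": "f", "genus": "g", "species": "s",
}
_TAG_TO_RANK = {v: k for k, v in RANK_TAGS.items()}

_SEQ_TRANSLATE = str.maketrans({"U": "T", "u": "T"})


class FastaParseError(ValueError):
    """Raised when a reference FASTA cannot be parsed; names the bad line."""


@dataclass(frozen=True)
class Lineage:
    """Ordered seven-rank taxonomic lineage; unassigned ranks are empty strings.

    The prefix property holds by construction: a named rank never appears
    below an unnamed one (`parse` truncates violations with a warning).
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"lineage needs {len(RANKS)} ranks, got {len(self.names)}")

    @classmethod
    def parse(cls, text: str, context: str = "") -> "Lineage":
        """Parse a lineage string in rank-tagged or bare dialect.

        Rank-tagged tokens (``p__Firmicutes``) are placed by their tag; bare
        tokens are placed positionally starting at kingdom.  A named rank
        under an unnamed one is truncated (with the ranks below it) and a
        warning is emitted, because per-rank grouping requires consistent
        lineage prefixes.
        """
        names = [""] * len(RANKS)
        tokens = [t.strip() for t in text.strip().split(";")]
        tokens = [t for t in tokens if t != ""] if any("__" in t for t in tokens) else tokens
        for pos, token in enumerate(tokens):
            if len(token) >= 3 and token[1:3] == "__" and token[0].lower() in _TAG_TO_RANK:
                rank_i = RANKS.index(_TAG_TO_RANK[token[0].lower()])
                names[rank_i] = token[3:].strip()
            elif pos < len(RANKS):
                names[pos] = token.strip()
        # enforce the prefix property: truncate below the first gap
        gap = None
        for i, name in enumerate(names):
            if name == "":
                gap = i
                break
        if gap is not None and any(n != "" for n in names[gap + 1:]):
            warnings.warn(
                f"lineage {context or text!r} names a rank below an unnamed "
                f"{RANKS[gap]}; truncating below the gap",
                stacklevel=2,
            )
            names = names[: gap] + [""] * (len(RANKS) - gap)
        return cls(tuple(names))

    def at(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.names[RANKS.index(rank)]

    def to_greengenes(self) -> str:
        return ";".join(f"{RANK_TAGS[r]}__{n}" for r, n in zip(RANKS, self.names))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_greengenes()


@dataclass
class ReferenceRecord:
    """One 16S sequence with its taxonomic lineage."""

    id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass
class RankGroup:
    """All sequences carrying one taxon name at one rank."""

    rank: str
    label: str
    members: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to T; other symbols pass through unchanged."""
    return seq.upper().translate(_SEQ_TRANSLATE)


def _check_fasta_header(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} does not start a FASTA record "
                    f"(expected '>'): {line.strip()[:40]!r}"
                )
            return


def read_taxonomy(taxonomy_path: str | Path) -> dict[str, str]:
    """Read a two-column (id TAB lineage) taxonomy map; empty file -> empty map."""
    mapping: dict[str, str] = {}
    with open(taxonomy_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise ValueError(
                    f"{taxonomy_path}: line {lineno} is not two tab-separated columns"
                )
            mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def read_reference(
    fasta_path: str | Path, taxonomy_path: str | Path
) -> list[ReferenceRecord]:
    """Load reference sequences that have a taxonomy entry.

    FASTA entries without a taxonomy line are counted and reported via a
    warning rather than silently dropped.  Duplicate FASTA ids are an error.
    """
    fasta_path = Path(fasta_path)
    _check_fasta_header(fasta_path)
    taxonomy = read_taxonomy(taxonomy_path)

    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    unmapped = 0
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{fasta_path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        if entry.id not in taxonomy:
            unmapped += 1
            continue
        lineage = Lineage.parse(taxonomy[entry.id], context=entry.id)
        records.append(
            ReferenceRecord(entry.id, normalize_sequence(str(entry.seq)), lineage)
        )
    if unmapped:
        warnings.warn(
            f"{unmapped} FASTA sequence(s) had no taxonomy entry and were skipped",
            stacklevel=2,
        )
    return records


def write_reference(
    records: Iterable[ReferenceRecord],
    fasta_path: str | Path,
    taxonomy_path: str | Path,
) -> None:
    """Write records back to FASTA + taxonomy TSV (rank-tagged lineage strings)."""
    records = list(records)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    with open(taxonomy_path, "w") as fh:
        for r in records:
            fh.write(f"{r.id}\t{r.lineage.to_greengenes()}\n")


def group_by_rank(
    records: Iterable[ReferenceRecord], rank: str
) -> tuple[list[RankGroup], int]:
    """Group records by their taxon name at `rank`.

    Returns the groups (one per distinct non-empty taxon, in order of first
    appearance) and the count of records excluded for being unlabelled at
    that rank.  Group sizes plus the exclusion count always sum to the input
    size.
    """
    if rank not in CLASSIFY_RANKS:
        raise ValueError(
            f"unknown or unsupported rank {rank!r}; expected one of {CLASSIFY_RANKS}"
        )
    groups: dict[str, RankGroup] = {}
    excluded = 0
    for record in records:
        label = record.lineage.at(rank)
        if label == "":
            excluded += 1
            continue
        groups.setdefault(label, RankGroup(rank, label)).members.append(record.id)
    return list(groups.values()), excluded


def build_parent_maps(
    lineages: Mapping[str, Lineage] | Iterable[Lineage],
) -> dict[str, dict[str, list[str]]]:
    """For each classified rank below phylum, map taxon -> sorted parent taxa.

    Used by the optional hierarchically-consistent classification mode.
    """
    if isinstance(lineages, Mapping):
        lineages = lineages.values()
    maps: dict[str, dict[str, set[str]]] = {r: {} for r in CLASSIFY_RANKS[1:]}
    for lin in lineages:
        for upper, lower in zip(CLASSIFY_RANKS[:-1], CLASSIFY_RANKS[1:]):
            parent, child = lin.at(upper), lin.at(lower)
            if parent and child:
                maps[lower].setdefault(child, set()).add(parent)
    return {r: {c: sorted(p) for c, p in m.items()} for r, m in maps.items()}
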