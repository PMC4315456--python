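"""Hypervariable-region excision by fuzzy primer matching.

A hypervariable region (HVR) of the 16S rRNA gene is delimited by two
conserved primer-binding sites.  Given a forward primer and a reverse primer
(the reverse written 5'->3' on the reverse strand, as primers are published),
the region is the span *between* the two sites on the forward strand; primer
sites themselves are removed from the excised sequence.

Matching is ungapped: a primer is slid along the sequence and scored by
IUPAC-aware Hamming distance, where an ambiguity code matches any of its
expansion bases (R matches A or G, N matches anything).  The leftmost window
with the fewest mismatches wins, which keeps extraction deterministic.  No
indels are tolerated; degenerate primer bases already absorb the documented
site variability, so the default mismatch budget is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Union

import numpy as np

from .reference_db import ReferenceRecord

# IUPAC nucleotide codes as 4-bit masks (A=1, C=2, G=4, T=8); two codes
# "match" iff their masks intersect.
IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN" + "acgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBN" + "tgcaayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to its IUPAC bitmasks; unknown symbols get 0 (match nothing)."""
    return np.array([IUPAC_BITS.get(c, 0) for c in seq.upper()], dtype=np.uint8)


def _validate_primer(primer: str, min_len: int = 1) -> None:
    bad = {c for c in primer.upper() if c not in IUPAC_BITS}
    if bad:
        raise ValueError(f"primer {primer!r} contains non-IUPAC symbols {sorted(bad)}")
    if len(primer) < min_len:
        raise ValueError(f"primer {primer!r} shorter than {min_len} nt")


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair delimiting one named region.

    `reverse` is written 5'->3' on the reverse strand; its reverse complement
    is what appears on the forward strand downstream of the forward site.
    """

    region: str
    forward: str
    reverse: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        _validate_primer(self.forward, min_len=10)
        _validate_primer(self.reverse, min_len=10)
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


class PrimerMatch(NamedTuple):
    position: int  # 0-based start of the matched window
    mismatches: int


@dataclass(frozen=True)
class ExtractionResult:
    """A successfully excised region: coordinates are 0-based half-open on the
    source sequence as given.  For reverse-strand hits (strand ``-``) the
    reported `sequence` is the region read off the reverse complement, i.e.
    ``revcomp(source[start:end])``, so downstream featurization always sees
    primer-defined orientation."""

    source_id: str
    region: str
    start: int
    end: int
    sequence: str
    fwd_mismatches: int
    rev_mismatches: int
    strand: str = "+"


@dataclass(frozen=True)
class ExtractionFailure:
    """No-match outcome with a machine-readable reason code."""

    source_id: str
    region: str
    reason: str  # forward_not_found | reverse_not_found | empty_region


def match_primer(
    sequence: str, primer: str, max_mismatches: int = 0
) -> Optional[PrimerMatch]:
    """Best ungapped primer placement, or None.

    Scans every window of the sequence and returns the leftmost window with
    the fewest IUPAC-aware mismatches, provided that count is within
    `max_mismatches`.  An empty sequence or a primer longer than the sequence
    simply yields no match.
    """
    _validate_primer(primer)
    m, n = len(primer), len(sequence)
    if n == 0 or m > n:
        return None
    seq_bits = _encode(sequence)
    primer_bits = _encode(primer)
    windows = np.lib.stride_tricks.sliding_window_view(seq_bits, m)
    mismatches = ((windows & primer_bits) == 0).sum(axis=1)
    best = int(mismatches.argmin())  # argmin is leftmost among ties
    if mismatches[best] > max_mismatches:
        return None
    return PrimerMatch(best, int(mismatches[best]))


def _extract_one_strand(
    seq: str, pair: PrimerPair
) -> Union[tuple[int, int, int, int], str]:
    """Locate fwd site then the reverse site downstream; return coords or a reason."""
    fwd = match_primer(seq, pair.forward, pair.max_mismatches)
    if fwd is None:
        return "forward_not_found"
    region_start = fwd.position + len(pair.forward)
    downstream = seq[region_start:]
    rev_site = reverse_complement(pair.reverse)
    rev = match_primer(downstream, rev_site, pair.max_mismatches)
    if rev is None:
        return "reverse_not_found"
    region_end = region_start + rev.position
    if region_end <= region_start:
        return "empty_region"
    return region_start, region_end, fwd.mismatches, rev.mismatches


def extract_region(
    record: ReferenceRecord | tuple[str, str], pair: PrimerPair
) -> Union[ExtractionResult, ExtractionFailure]:
    """Excise the region between the primer sites of `pair`.

    The forward strand is tried first; if either site is missing the reverse
    complement of the source is searched, because reference databases mix
    orientations.  Coordinates always refer to the source as given.
    """
    if isinstance(record, ReferenceRecord):
        source_id, seq = record.id, record.sequence
    else:
        source_id, seq = record
    seq = seq.upper()

    hit = _extract_one_strand(seq, pair)
    if not isinstance(hit, str):
        start, end, fmm, rmm = hit
        return ExtractionResult(
            source_id, pair.region, start, end, seq[start:end], fmm, rmm, "+"
        )
    forward_reason = hit

    rc = reverse_complement(seq)
    hit = _extract_one_strand(rc, pair)
    if not isinstance(hit, str):
        start, end, fmm, rmm = hit
        n = len(seq)
        return ExtractionResult(
            source_id, pair.region, n - end, n - start, rc[start:end], fmm, rmm, "-"
        )
    return ExtractionFailure(source_id, pair.region, forward_reason)


@dataclass(frozen=True)
class CoverageReport:
    """Fraction of a reference collection a primer pair can extract from.

    Pairs covering at most half the collection are flagged `rejected`,
    mirroring the selection rule that drops regions (such as V1/V9) whose
    primers recover 50% or fewer of the database sequences.
    """

    region: str
    fraction: float
    n_extracted: int
    n_total: int

    @property
    def rejected(self) -> bool:
        return self.fraction <= 0.5


def coverage(
    records: Iterable[ReferenceRecord | tuple[str, str]], pair: PrimerPair
) -> CoverageReport:
    records = list(records)
    if not records:
        raise ValueError("coverage requires a nonempty record collection")
    n_ok = sum(
        isinstance(extract_region(r, pair), ExtractionResult) for r in records
    )
    return CoverageReport(pair.region, n_ok / len(records), n_ok, len(records))


def extract_all(
    records: Iterable[ReferenceRecord], pair: PrimerPair
) -> tuple[list[ExtractionResult], list[ExtractionFailure]]:
    """Run `extract_region` over a collection, splitting hits from failures."""
    hits: list[ExtractionResult] = []
    misses: list[ExtractionFailure] = []
    for record in records:
        out = extract_region(record, pair)
        (hits if isinstance(out, ExtractionResult) else misses).append(out)
    return hits, misses


# Literature primer pairs for the individual regions V2-V8 (E. coli
# numbering of the classic amplicon primers) and the combined regions formed
# by one region's forward and a downstream region's reverse primer.  These
# defaults are data, not algorithm: override them with a TSV via
# `load_primer_table` to reproduce any particular protocol.
_SINGLE_PRIMERS: dict[str, tuple[str, str]] = {
    "V2": ("AGAGTTTGATCMTGGCTCAG", "TGCTGCCTCCCGTAGGAGT"),     # 27F / 338R
    "V3": ("CCTACGGGAGGCAGCAG", "ATTACCGCGGCTGCTGG"),          # 341F / 518R
    "V4": ("GTGCCAGCMGCCGCGGTAA", "GGACTACHVGGGTWTCTAAT"),     # 515F / 806R
    "V5": ("GGATTAGATACCCBRGTAGTC", "CCGTCAATTCMTTTRAGTTT"),   # 785F / 907R
    "V6": ("CAACGCGAAGAACCTTACC", "CRRCACGAGCTGACGAC"),        # 967F / 1061R
    "V7": ("CAACGAGCGCAACCC", "ACGTCATCCCCACCTTCC"),           # 1100F / 1193R
    "V8": ("GGGCTACACACGYGCWAC", "GACGGGCGGTGTGTRCA"),         # 1237F / 1391R
}
_COMBINED = ("V23", "V34", "V35", "V45", "V56", "V67", "V78")


def _default_pairs() -> dict[str, PrimerPair]:
    pairs = {
        name: PrimerPair(name, fwd, rev) for name, (fwd, rev) in _SINGLE_PRIMERS.items()
    }
    for combo in _COMBINED:
        first, last = "V" + combo[1], "V" + combo[2]
        pairs[combo] = PrimerPair(
            combo, _SINGLE_PRIMERS[first][0], _SINGLE_PRIMERS[last][1]
        )
    return pairs


DEFAULT_PRIMERS: dict[str, PrimerPair] = _default_pairs()


def load_primer_table(path: str | Path) -> dict[str, PrimerPair]:
    """Read a primer table TSV: region, forward, reverse[, max_mismatches]."""
    pairs: dict[str, PrimerPair] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() == "region":
                continue  # header
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno} needs >= 3 columns")
            mm = int(parts[3]) if len(parts) > 3 and parts[3].strip() else 0
            pairs[parts[0].strip()] = PrimerPair(
                parts[0].strip(), parts[1].strip().upper(), parts[2].strip().upper(), mm
            )
    return pairs


def write_primer_table(pairs: Iterable[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tforward\treverse\tmax_mismatches\n")
        for p in pairs:
            fh.write(f"{p.region}\t{p.forward}\t{p.reverse}\t{p.max_mismatches}\n")


def write_extraction_outputs(
    hits: Iterable[ExtractionResult],
    fasta_path: str | Path,
    coords_path: str | Path,
) -> None:
    """Write excised regions as FASTA plus a 0-based half-open coordinates TSV."""
    hits = list(hits)
    with open(fasta_path, "w") as fh:
        for h in hits:
            fh.write(f">{h.source_id}\n{h.sequence}\n")
    with open(coords_path, "w") as fh:
        fh.write("id\tregion\tstart\tend\tstrand\tfwd_mismatches\trev_mismatches\n")
        for h in hits:
            fh.write(
                f"{h.source_id}\t{h.region}\t{h.start}\t{h.end}\t{h.strand}"
                f"\t{h.fwd_mismatches}\t{h.rev_mismatches}\n"
            )
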