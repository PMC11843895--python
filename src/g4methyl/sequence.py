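"""Amplicon sequence handling, CpG-site indexing, and G4Hunter PQS scoring.

Coordinates are 0-based half-open throughout; reporting-style CpG site
numbers (rank + ``numbering_offset``) are attached to the index but never
used in arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "AmpliconSequence",
    "CpGIndex",
    "PQSTrack",
    "GenomicInterval",
    "load_fasta",
    "study_sequence",
    "reverse_complement",
    "find_cpg_sites",
    "g4hunter_scores",
    "call_pqs",
    "pqs_cpg_overlap",
    "write_bed",
    "write_bedgraph",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

#: window length and score cutoff of the published G4Hunter defaults
DEFAULT_WINDOW = 25
DEFAULT_THRESHOLD = 1.2


def _check_alphabet(seq: str, context: str = "sequence") -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"{context} contains non-ACGT character(s): {sorted(bad)!r} "
            "(ambiguity codes and RNA are rejected)"
        )


@dataclass(frozen=True)
class AmpliconSequence:
    """A named DNA sequence; the stored strand is the coding (C-rich) strand."""

    id: str
    seq: str
    numbering_offset: int = 3

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"amplicon {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())
        _check_alphabet(self.seq, f"amplicon {self.id!r}")
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CpGIndex:
    """0-based positions of the C of each CG dinucleotide on the stored strand."""

    positions: tuple[int, ...]
    site_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.site_numbers):
            raise ValueError("positions and site_numbers must be parallel")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, position: int) -> bool:
        return position in self._position_set

    @property
    def _position_set(self) -> frozenset[int]:
        return frozenset(self.positions)

    def site_number(self, position: int) -> int:
        return self.site_numbers[self.positions.index(position)]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on an amplicon."""

    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PQSTrack:
    """Per-base G4Hunter scores, sliding-window means, and called intervals."""

    base_scores: tuple[int, ...]
    window_scores: tuple[float, ...]
    window: int
    intervals: tuple[GenomicInterval, ...] = field(default_factory=tuple)
    threshold: float = DEFAULT_THRESHOLD


def _parse_fasta(path: Path) -> Iterator[tuple[str, str]]:
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif name is None:
                raise ValueError(f"{path}: sequence data before first header")
            else:
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def load_fasta(
    path: str | Path,
    record: str | None = None,
    numbering_offset: int = 3,
) -> AmpliconSequence:
    """Load one record from a FASTA file (the first, unless ``record`` names one).

    Sequences are uppercased; any character outside {A, C, G, T} is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = dict(_parse_fasta(path))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if record is None:
        rec_id = next(iter(records))
    elif record in records:
        rec_id = record
    else:
        raise KeyError(f"{path}: no record named {record!r}; has {list(records)}")
    return AmpliconSequence(rec_id, records[rec_id], numbering_offset)


def study_sequence(name: str, numbering_offset: int = 3) -> AmpliconSequence:
    """Load one of the bundled study oligo/amplicon sequences by name."""
    ref = resources.files("g4methyl.data") / "study_oligos.fasta"
    with resources.as_file(ref) as path:
        return load_fasta(path, record=name, numbering_offset=numbering_offset)


def reverse_complement(seq: str) -> str:
    _check_alphabet(seq.upper())
    return seq.upper().translate(_COMPLEMENT)[::-1]


def find_cpg_sites(amplicon: AmpliconSequence) -> CpGIndex:
    """Index every CG dinucleotide (position of the C) on the stored strand."""
    seq = amplicon.seq
    positions = tuple(
        i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
    )
    numbers = tuple(amplicon.numbering_offset + rank for rank in range(len(positions)))
    return CpGIndex(positions, numbers)


def _base_scores(seq: str) -> list[int]:
    # run-length scoring: base in a G-run of length k scores +min(k, 4),
    # in a C-run -min(k, 4); A/T score 0
    scores: list[int] = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        if seq[i] == "G":
            scores.extend([min(run, 4)] * run)
        elif seq[i] == "C":
            scores.extend([-min(run, 4)] * run)
        else:
            scores.extend([0] * run)
        i = j
    return scores


def g4hunter_scores(
    amplicon: AmpliconSequence, window: int = DEFAULT_WINDOW
) -> PQSTrack:
    """Per-base G4Hunter run scores and sliding-window means."""
    seq = amplicon.seq
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(seq):
        raise ValueError(
            f"window {window} exceeds sequence length {len(seq)} for {amplicon.id!r}"
        )
    base = _base_scores(seq)
    # cumulative-sum sliding means
    csum = [0]
    for s in base:
        csum.append(csum[-1] + s)
    win = tuple(
        (csum[i + window] - csum[i]) / window for i in range(len(seq) - window + 1)
    )
    return PQSTrack(tuple(base), win, window)


def call_pqs(
    track: PQSTrack,
    threshold: float = DEFAULT_THRESHOLD,
    min_width: int = 1,
) -> list[GenomicInterval]:
    """Call PQS intervals as merged unions of windows with |mean| >= threshold.

    Qualifying windows of the same sign that overlap or abut in base
    coordinates are merged; '+' marks G-rich stretches on the stored strand,
    '-' C-rich ones.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    w = track.window
    out: list[GenomicInterval] = []
    cur_start = cur_end = None
    cur_strand = None
    for i, score in enumerate(track.window_scores):
        if abs(score) < threshold:
            continue
        strand = "+" if score > 0 else "-"
        if cur_start is not None and strand == cur_strand and i <= cur_end:
            cur_end = i + w
        else:
            if cur_start is not None and cur_end - cur_start >= min_width:
                out.append(GenomicInterval(cur_start, cur_end, cur_strand))
            cur_start, cur_end, cur_strand = i, i + w, strand
    if cur_start is not None and cur_end - cur_start >= min_width:
        out.append(GenomicInterval(cur_start, cur_end, cur_strand))
    return out


def pqs_cpg_overlap(
    intervals: list[GenomicInterval],
    cpg_index: CpGIndex,
    seq_length: int | None = None,
) -> dict[int, str]:
    """Label each CpG site 'PQS' or 'non-PQS' by interval containment.

    A site counts as PQS if either its C position or the paired G position
    (position + 1) lies inside any interval.
    """
    if seq_length is not None:
        for iv in intervals:
            if iv.end > seq_length:
                raise ValueError(f"interval [{iv.start}, {iv.end}) exceeds sequence")
    labels = {}
    for pos in cpg_index.positions:
        hit = any(pos in iv or (pos + 1) in iv for iv in intervals)
        labels[pos] = "PQS" if hit else "non-PQS"
    return labels


def write_bed(
    intervals: list[GenomicInterval],
    track: PQSTrack,
    amplicon: AmpliconSequence,
    path: str | Path,
) -> None:
    """Write called PQS intervals as 6-column BED (score = mean window score x100)."""
    w = track.window
    with open(path, "w") as fh:
        for iv in intervals:
            win_idx = range(iv.start, min(iv.end - w + 1, len(track.window_scores)))
            vals = [track.window_scores[i] for i in win_idx] or [0.0]
            score = round(100 * sum(vals) / len(vals))
            fh.write(
                f"{amplicon.id}\t{iv.start}\t{iv.end}\tPQS\t{score}\t{iv.strand}\n"
            )


def write_bedgraph(
    track: PQSTrack, amplicon: AmpliconSequence, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, score in enumerate(track.window_scores):
            fh.write(f"{amplicon.id}\t{i}\t{i + 1}\t{score:.6g}\n")
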