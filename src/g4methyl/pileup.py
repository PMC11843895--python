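"""Per-read cytosine modification-probability calls and strand-resolved pileup.

Two distinct code paths operate on the same calls:

* methylation patterns use confidence-thresholded calls (argmax state kept
  only when its probability reaches the threshold, default 0.65);
* the modification-calling accuracy statistic uses *all* calls, with no
  filtering, and rescales the mean canonical probability linearly so that
  1 maps to 100% and the uninformative 1/3 maps to 0%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .sequence import AmpliconSequence, CpGIndex

logger = logging.getLogger(__name__)

__all__ = [
    "ModProbTriple",
    "ReadModCalls",
    "SiteCall",
    "MethylationPileup",
    "DEFAULT_CALL_THRESHOLD",
    "read_call_table",
    "write_call_table",
    "read_modbam",
    "classify_call",
    "pileup",
    "site_accuracy",
    "accuracy_track",
    "global_modification_levels",
    "write_bedmethyl",
    "read_bedmethyl",
]

DEFAULT_CALL_THRESHOLD = 0.65
_SUM_TOL = 1e-6
_STATES = ("canonical", "5mC", "5hmC")


@dataclass(frozen=True)
class ModProbTriple:
    """Probabilities of canonical C, 5mC and 5hmC at one read x site."""

    p_c: float
    p_m: float
    p_h: float

    def __post_init__(self) -> None:
        for name, p in (("p_c", self.p_c), ("p_m", self.p_m), ("p_h", self.p_h)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        total = self.p_c + self.p_m + self.p_h
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {total}, not 1 (tol {_SUM_TOL})")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_c, self.p_m, self.p_h)


@dataclass(frozen=True)
class ReadModCalls:
    """One read's strand and its per-site probability triples.

    ``strand`` is '+' for the coding (C-rich) strand, '-' for the template
    (G-rich) strand; call positions are always the 0-based coding-strand C
    position of the site, regardless of strand.
    """

    read_id: str
    strand: str
    calls: dict[int, ModProbTriple]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand symbol {self.strand!r}")


@dataclass(frozen=True)
class SiteCall:
    state: str  # canonical | 5mC | 5hmC | filtered
    max_prob: float


@dataclass
class PileupRow:
    coverage_total: int = 0
    n_canonical: int = 0
    n_5mC: int = 0
    n_5hmC: int = 0
    n_filtered: int = 0
    sum_p_c: float = 0.0  # over ALL calls (accuracy path, unfiltered)

    @property
    def n_retained(self) -> int:
        return self.n_canonical + self.n_5mC + self.n_5hmC

    @property
    def frac_5mC(self) -> float | None:
        return self.n_5mC / self.n_retained if self.n_retained else None

    @property
    def frac_5hmC(self) -> float | None:
        return self.n_5hmC / self.n_retained if self.n_retained else None

    @property
    def mean_p_c(self) -> float | None:
        return self.sum_p_c / self.coverage_total if self.coverage_total else None

    @property
    def accuracy_pct(self) -> float | None:
        m = self.mean_p_c
        return None if m is None else _accuracy_pct(m)


@dataclass
class MethylationPileup:
    """Per-(site position, strand) counts, fractions and accuracy."""

    rows: dict[tuple[int, str], PileupRow]
    threshold: float
    cpg_index: CpGIndex | None = None
    amplicon_id: str = ""

    def row(self, position: int, strand: str) -> PileupRow:
        return self.rows[(position, strand)]

    def keys(self):
        return sorted(self.rows)


def _accuracy_pct(mean_p_c: float) -> float:
    # linear map pinned at 1 -> 100% and 1/3 -> 0%; negatives not clamped
    return 100.0 * (mean_p_c - 1.0 / 3.0) / (2.0 / 3.0)


def classify_call(
    triple: ModProbTriple, threshold: float = DEFAULT_CALL_THRESHOLD
) -> SiteCall:
    """Argmax state, filtered when the winning probability is below threshold.

    Ties break canonical > 5mC > 5hmC for determinism.
    """
    if threshold <= 1.0 / 3.0 or threshold > 1.0:
        raise ValueError(
            f"threshold {threshold} outside (1/3, 1]: every triple would pass"
        )
    probs = triple.as_tuple()
    best = max(range(3), key=lambda i: (probs[i], -i))
    if probs[best] < threshold:
        return SiteCall("filtered", probs[best])
    return SiteCall(_STATES[best], probs[best])


def read_call_table(path: str | Path) -> list[ReadModCalls]:
    """Parse the native call TSV (read_id, strand, site_pos, p_c, p_m, p_h)."""
    path = Path(path)
    grouped: dict[tuple[str, str], dict[int, ModProbTriple]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                expected = ["read_id", "strand", "site_pos", "p_c", "p_m", "p_h"]
                if header != expected:
                    raise ValueError(f"{path}:{lineno}: bad header {header}")
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            read_id, strand, pos_s, pc_s, pm_s, ph_s = fields
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                pos = int(pos_s)
                triple = ModProbTriple(float(pc_s), float(pm_s), float(ph_s))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            key = (read_id, strand)
            if key not in grouped:
                grouped[key] = {}
                order.append(key)
            grouped[key][pos] = triple
    return [ReadModCalls(rid, strand, grouped[(rid, strand)]) for rid, strand in order]


def write_call_table(reads: list[ReadModCalls], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstrand\tsite_pos\tp_c\tp_m\tp_h\n")
        for read in reads:
            for pos in sorted(read.calls):
                t = read.calls[pos]
                # 9 significant digits so re-read triples still sum to 1
                fh.write(
                    f"{read.read_id}\t{read.strand}\t{pos}"
                    f"\t{t.p_c:.9g}\t{t.p_m:.9g}\t{t.p_h:.9g}\n"
                )


def _decode_ml(byte: int) -> float:
    return (byte + 0.5) / 256.0


def _encode_ml(prob: float) -> int:
    return min(255, max(0, int(prob * 256.0)))


def read_modbam(path: str | Path, amplicon: AmpliconSequence) -> list[ReadModCalls]:
    """Extract per-site (p_c, p_m, p_h) triples from MM/ML-tagged alignments.

    ML bytes decode as (b + 0.5)/256; p_c = 1 - p_m - p_h. Reverse-strand
    alignments report the modified base at the reference G of the CpG; those
    calls are stored against the coding-strand C position (ref position - 1)
    with strand '-'.
    """
    import pysam

    from .sequence import find_cpg_sites

    index = find_cpg_sites(amplicon)
    cpg_positions = set(index.positions)
    reads: list[ReadModCalls] = []
    n_unaligned = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                n_unaligned += 1
                continue
            mods = aln.modified_bases
            if mods is None or not any(k[0] == "C" and k[2] in ("m", "h") for k in mods):
                raise ValueError(
                    f"read {aln.query_name!r} lacks C+m/C+h MM/ML modification tags"
                )
            per_qpos: dict[int, dict[str, float]] = {}
            for (base, _flag, code), entries in mods.items():
                if base != "C" or code not in ("m", "h"):
                    continue
                for qpos, byte in entries:
                    per_qpos.setdefault(qpos, {})[code] = _decode_ml(byte)
            q2r = {
                q: r for q, r in aln.get_aligned_pairs(matches_only=True)
            }
            strand = "-" if aln.is_reverse else "+"
            calls: dict[int, ModProbTriple] = {}
            for qpos, probs in per_qpos.items():
                rpos = q2r.get(qpos)
                if rpos is None:
                    continue
                site = rpos - 1 if strand == "-" else rpos
                if site not in cpg_positions:
                    continue
                p_m = probs.get("m", 0.0)
                p_h = probs.get("h", 0.0)
                if p_m + p_h > 1.0 + _SUM_TOL:
                    raise ValueError(
                        f"read {aln.query_name!r} site {site}: "
                        f"p_m + p_h = {p_m + p_h:.4f} > 1 after ML decoding"
                    )
                calls[site] = ModProbTriple(max(0.0, 1.0 - p_m - p_h), p_m, p_h)
            if calls:
                reads.append(ReadModCalls(aln.query_name, strand, calls))
    if n_unaligned:
        logger.info("skipped %d unaligned read(s)", n_unaligned)
    return reads


def pileup(
    reads: list[ReadModCalls],
    cpg_index: CpGIndex,
    threshold: float = DEFAULT_CALL_THRESHOLD,
    amplicon_id: str = "",
) -> MethylationPileup:
    """Aggregate read calls into per-(site, strand) counts and fractions."""
    valid = set(cpg_index.positions)
    rows: dict[tuple[int, str], PileupRow] = {}
    for read in reads:
        for pos, triple in read.calls.items():
            if pos not in valid:
                raise KeyError(
                    f"read {read.read_id!r} calls position {pos}, "
                    "which is not a CpG site of the amplicon"
                )
            row = rows.setdefault((pos, read.strand), PileupRow())
            row.coverage_total += 1
            row.sum_p_c += triple.p_c
            call = classify_call(triple, threshold)
            if call.state == "canonical":
                row.n_canonical += 1
            elif call.state == "5mC":
                row.n_5mC += 1
            elif call.state == "5hmC":
                row.n_5hmC += 1
            else:
                row.n_filtered += 1
    return MethylationPileup(rows, threshold, cpg_index, amplicon_id)


def site_accuracy(reads: list[ReadModCalls], site: int, strand: str) -> float:
    """Accuracy statistic at one (site, strand): 100 * (mean p_c - 1/3)/(2/3).

    Uses all calls with no confidence filtering.
    """
    probs = [
        read.calls[site].p_c
        for read in reads
        if read.strand == strand and site in read.calls
    ]
    if not probs:
        raise ValueError(f"no coverage at site {site} strand {strand}")
    return _accuracy_pct(sum(probs) / len(probs))


def accuracy_track(pile: MethylationPileup) -> dict[tuple[int, str], float]:
    """Per-(site, strand) accuracy percentages from unfiltered mean p_c."""
    return {
        key: row.accuracy_pct for key, row in pile.rows.items() if row.coverage_total
    }


def global_modification_levels(pile: MethylationPileup) -> tuple[float, float]:
    """Pooled (5mC, 5hmC) levels over all sites and strands, retained calls only."""
    retained = sum(r.n_retained for r in pile.rows.values())
    if retained == 0:
        raise ValueError("pileup has no retained calls")
    n_m = sum(r.n_5mC for r in pile.rows.values())
    n_h = sum(r.n_5hmC for r in pile.rows.values())
    return n_m / retained, n_h / retained


_BEDMETHYL_COLUMNS = [
    "chrom",
    "start",
    "end",
    "site_number",
    "strand",
    "coverage_total",
    "n_retained",
    "n_5mC",
    "n_5hmC",
    "n_filtered",
    "pct_5mC",
    "accuracy_pct",
]


def write_bedmethyl(pile: MethylationPileup, path: str | Path) -> None:
    """bedMethyl-like TSV, one row per (site, strand), ordered by position then strand."""
    index = pile.cpg_index
    with open(path, "w") as fh:
        fh.write("\t".join(_BEDMETHYL_COLUMNS) + "\n")
        for pos, strand in sorted(pile.rows):
            row = pile.rows[(pos, strand)]
            number = index.site_number(pos) if index is not None else -1
            pct = "" if row.frac_5mC is None else f"{100 * row.frac_5mC:.6g}"
            acc = "" if row.accuracy_pct is None else f"{row.accuracy_pct:.6g}"
            fh.write(
                f"{pile.amplicon_id}\t{pos}\t{pos + 1}\t{number}\t{strand}"
                f"\t{row.coverage_total}\t{row.n_retained}\t{row.n_5mC}"
                f"\t{row.n_5hmC}\t{row.n_filtered}\t{pct}\t{acc}\n"
            )


def read_bedmethyl(path: str | Path) -> dict[tuple[int, str], dict]:
    """Re-read a bedMethyl-like TSV into per-(position, strand) count dicts."""
    out: dict[tuple[int, str], dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _BEDMETHYL_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            key = (int(f[1]), f[4])
            out[key] = {
                "chrom": f[0],
                "site_number": int(f[3]),
                "coverage_total": int(f[5]),
                "n_retained": int(f[6]),
                "n_5mC": int(f[7]),
                "n_5hmC": int(f[8]),
                "n_filtered": int(f[9]),
                "pct_5mC": float(f[10]) if f[10] else math.nan,
                "accuracy_pct": float(f[11]) if f[11] else math.nan,
            }
    return out
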