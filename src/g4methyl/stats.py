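"""Region x strand methylation summaries and the unequal-variance strand contrast.

The unit of replication is the CpG site: per-site percent-5mC values within a
(region, strand) cell form the samples entering the Welch t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

from scipy import stats as _sps

from .pileup import MethylationPileup

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSummary",
    "WelchResult",
    "DifferentialReport",
    "region_strand_summary",
    "welch_t_test",
    "differential_report",
    "sites_in_number_range",
    "write_report",
]

#: default primary PQS region in reporting-style CpG site numbers, inclusive
DEFAULT_PQS_SITE_RANGE = (47, 72)


@dataclass(frozen=True)
class RegionSummary:
    region: str  # 'PQS' | 'non-PQS'
    strand: str
    n_sites: int
    mean_pct_5mC: float
    sem_pct_5mC: float


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_two_tailed: float


@dataclass(frozen=True)
class DifferentialReport:
    summaries: tuple[RegionSummary, ...]  # 2 regions x 2 strands
    contrasts: dict[str, WelchResult]  # region label -> strand contrast
    region_definition: str

    def summary(self, region: str, strand: str) -> RegionSummary:
        for s in self.summaries:
            if s.region == region and s.strand == strand:
                return s
        raise KeyError((region, strand))


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Two-sided t-test with unequal variances (Welch-Satterthwaite df)."""
    a = [float(x) for x in sample_a]
    b = [float(x) for x in sample_b]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 observations per sample, got {n1} and {n2}")
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("both samples have zero variance")
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return WelchResult(t, df, min(p, 1.0))


def _per_site_pct(pile: MethylationPileup) -> dict[tuple[int, str], float]:
    out = {}
    for key, row in pile.rows.items():
        if row.frac_5mC is not None:
            out[key] = 100.0 * row.frac_5mC
    return out


def sites_in_number_range(
    pile: MethylationPileup, lo: int, hi: int
) -> dict[int, str]:
    """Label each indexed site PQS/non-PQS by an inclusive site-number range."""
    index = pile.cpg_index
    if index is None:
        raise ValueError("pileup carries no CpG index")
    return {
        pos: "PQS" if lo <= num <= hi else "non-PQS"
        for pos, num in zip(index.positions, index.site_numbers)
    }


def region_strand_summary(
    pile: MethylationPileup, site_labels: dict[int, str]
) -> list[RegionSummary]:
    """Mean and SEM of per-site pct 5mC for each (region, strand) cell.

    Sites missing either strand (no retained calls) are dropped and counted
    in the log.
    """
    pct = _per_site_pct(pile)
    usable = []
    dropped = 0
    for pos in site_labels:
        if (pos, "+") in pct and (pos, "-") in pct:
            usable.append(pos)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d site(s) lacking both-strand coverage", dropped)
    summaries = []
    for region in ("PQS", "non-PQS"):
        for strand in ("+", "-"):
            vals = [pct[(p, strand)] for p in usable if site_labels[p] == region]
            if not vals:
                raise ValueError(f"region {region!r} strand {strand!r} has zero sites")
            n = len(vals)
            mean = sum(vals) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1)) if n > 1 else 0.0
            summaries.append(RegionSummary(region, strand, n, mean, sd / math.sqrt(n)))
    return summaries


def differential_report(
    pile: MethylationPileup,
    pqs_sites: dict[int, str] | None = None,
    region_override: tuple[int, int] | None = None,
) -> DifferentialReport:
    """Four region x strand summaries plus the two within-region strand contrasts.

    ``pqs_sites`` maps site positions to labels (e.g. from PQS overlap);
    ``region_override`` is an inclusive site-number range that wins when given.
    """
    if region_override is not None:
        labels = sites_in_number_range(pile, *region_override)
        definition = f"site numbers {region_override[0]}-{region_override[1]}"
    elif pqs_sites is not None:
        labels = pqs_sites
        definition = "PQS interval overlap"
    else:
        labels = sites_in_number_range(pile, *DEFAULT_PQS_SITE_RANGE)
        definition = (
            f"site numbers {DEFAULT_PQS_SITE_RANGE[0]}-{DEFAULT_PQS_SITE_RANGE[1]}"
        )
    summaries = region_strand_summary(pile, labels)
    pct = _per_site_pct(pile)
    usable = [p for p in labels if (p, "+") in pct and (p, "-") in pct]
    contrasts = {}
    for region in ("PQS", "non-PQS"):
        sites = [p for p in usable if labels[p] == region]
        g_strand = [pct[(p, "-")] for p in sites]
        c_strand = [pct[(p, "+")] for p in sites]
        contrasts[region] = welch_t_test(g_strand, c_strand)
    return DifferentialReport(tuple(summaries), contrasts, definition)


def _fmt_p(p: float) -> str:
    return "< 0.0001" if p < 1e-4 else f"{p:.4g}"


def write_report(report: DifferentialReport, path: str | Path) -> None:
    """Emit the report as a TSV with a provenance header line."""
    with open(path, "w") as fh:
        fh.write(f"# region definition: {report.region_definition}\n")
        fh.write("region\tstrand\tn_sites\tmean_pct_5mC\tsem_pct_5mC\n")
        for s in report.summaries:
            fh.write(
                f"{s.region}\t{s.strand}\t{s.n_sites}"
                f"\t{s.mean_pct_5mC:.6g}\t{s.sem_pct_5mC:.6g}\n"
            )
        fh.write("\n# strand contrasts (G-rich '-' vs C-rich '+')\n")
        fh.write("region\tt\tdf\tp_two_tailed\n")
        for region, res in report.contrasts.items():
            fh.write(
                f"{region}\t{res.t_statistic:.6g}\t{res.df:.6g}"
                f"\t{res.p_two_tailed:.6g}\n"
            )


def report_text(report: DifferentialReport) -> str:
    """Human-readable block mirroring 'mean% +/- SEM% vs ..., p value'."""
    lines = [f"Region definition: {report.region_definition}"]
    for region in ("PQS", "non-PQS"):
        g = report.summary(region, "-")
        c = report.summary(region, "+")
        p = report.contrasts[region].p_two_tailed
        lines.append(
            f"{region}: G-rich {g.mean_pct_5mC:.0f}% ± {g.sem_pct_5mC:.0f}% vs. "
            f"C-rich {c.mean_pct_5mC:.0f}% ± {c.sem_pct_5mC:.0f}%, "
            f"p value {_fmt_p(p)}"
        )
    return "\n".join(lines)
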