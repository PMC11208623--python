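"""Agreement between mtDNAcn methods and cohort summaries.

Method comparison uses the Pearson product-moment correlation on the raw
mtDNAcn scale (a log-scale option exists for heavy-tailed cohorts but is
off by default).  Cohort summaries report arithmetic mean and sample SD
(n-1 denominator).
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PairedEstimates:
    """One sample's mtDNAcn under two or more methods."""

    sample_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise ValueError(f"sample {self.sample_id}: mtDNAcn values must be positive")


@dataclass(frozen=True)
class ConcordanceReport:
    method_pair: tuple[str, str]
    n: int
    pearson_r: float
    scatter_rows: tuple[tuple[str, float, float], ...]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation; raises (never NaN) on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def group_summary(values: Sequence[float], group: str = "") -> tuple[int, float, float | None]:
    """(n, mean, sample SD); SD is None (not assessable) when n < 2."""
    n = len(values)
    if n == 0:
        raise ValueError(f"group {group!r}: no values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n >= 2 else None
    return n, mean, sd


def method_concordance(
    paired: Sequence[PairedEstimates],
    pair: tuple[str, str] | None = None,
    log_scale: bool = False,
) -> list[ConcordanceReport]:
    """Pairwise Pearson concordance between methods.

    With ``pair`` given, reports that one pair; otherwise all k(k-1)/2
    pairs over the methods present.  A pair needs >= 3 samples carrying
    both methods.
    """
    methods = sorted({m for p in paired for m in p.values})
    pairs = [tuple(sorted(pair))] if pair else list(itertools.combinations(methods, 2))
    reports = []
    for a, b in pairs:
        rows = [(p.sample_id, p.values[a], p.values[b])
                for p in paired if a in p.values and b in p.values]
        if len(rows) < 3:
            raise ValueError(f"insufficient overlap between methods {a!r} and {b!r} "
                             f"({len(rows)} shared samples; need >= 3)")
        xs = [r[1] for r in rows]
        ys = [r[2] for r in rows]
        if log_scale:
            xs = [math.log(v) for v in xs]
            ys = [math.log(v) for v in ys]
        reports.append(ConcordanceReport(
            method_pair=(a, b), n=len(rows),
            pearson_r=pearson_r(xs, ys),
            scatter_rows=tuple(sorted(rows)),
        ))
    return reports


def join_results(tables: Mapping[str, Mapping[str, float]]) -> list[PairedEstimates]:
    """Join per-method {sample_id: mtdnacn} maps into PairedEstimates rows."""
    all_samples = sorted({s for t in tables.values() for s in t})
    out = []
    for sample_id in all_samples:
        values = {m: t[sample_id] for m, t in tables.items() if sample_id in t}
        if len(values) >= 2:
            out.append(PairedEstimates(sample_id, values))
    return out


def write_concordance_tsv(reports: Sequence[ConcordanceReport], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["method_a", "method_b", "n", "pearson_r"])
    for r in sorted(reports, key=lambda r: r.method_pair):
        writer.writerow([r.method_pair[0], r.method_pair[1], r.n, f"{r.pearson_r:.6g}"])


def scatter_plot(report: ConcordanceReport, path: str) -> None:
    """Optional scatter of one method pair (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [r[1] for r in report.scatter_rows]
    ys = [r[2] for r in report.scatter_rows]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(xs, ys, s=12)
    ax.set_xlabel(report.method_pair[0])
    ax.set_ylabel(report.method_pair[1])
    ax.set_title(f"Pearson r = {report.pearson_r:.3f} (n = {report.n})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
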