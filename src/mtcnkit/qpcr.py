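"""Relative mtDNA copy number from qPCR threshold-cycle (Ct) tables.

The assay amplifies two mitochondrial targets (ND1, ND6) and two nuclear
single-copy targets (BECN1, NEB) in triplicate.  With perfect per-cycle
doubling, the Ct difference between a nuclear and a mitochondrial gene
measures the log2 abundance ratio of mitochondrial to nuclear template:

    dCt1 = Ct(BECN1) - Ct(ND1),   N1 = 2**dCt1
    dCt2 = Ct(NEB)   - Ct(ND6),   N2 = 2**dCt2
    mtDNAcn = (N1 + N2) / 2                       (paired method)

The commercial-kit style alternative normalizes both mitochondrial genes
against the geometric mean of the two nuclear reference signals, which in
Ct space is the arithmetic mean of the two nuclear Cts:

    refCt = (Ct(BECN1) + Ct(NEB)) / 2
    mtDNAcn = (2**(refCt - Ct(ND1)) + 2**(refCt - Ct(ND6))) / 2

Both estimators operate on replicate-averaged Cts and carry QC flags for
replicate scatter, undetermined wells, and no-template-control failures.
"""

from __future__ import annotations

import csv
import logging
import math
import statistics
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

MITO_GENES = ("ND1", "ND6")
NUCLEAR_GENES = ("BECN1", "NEB")
KNOWN_GENES = MITO_GENES + NUCLEAR_GENES

#: Sentinel for a well whose fluorescence never crossed threshold in 40 cycles.
UNDETERMINED = None

MAX_CYCLES = 40.0

# QC flag names
TOO_FEW_REPLICATES = "TOO_FEW_REPLICATES"
HIGH_CT_SD = "HIGH_CT_SD"
HAS_UNDETERMINED = "HAS_UNDETERMINED"
TIED = "TIED"

DEFAULT_HIGH_SD_CYCLES = 0.5
DEFAULT_NTC_MAX_CT = 35.0
DEFAULT_REFERENCE_DRIFT_FRACTION = 0.20


@dataclass(frozen=True)
class PrimerSpec:
    """One oligo of the four-gene panel; Tm is carried as metadata only."""

    name: str
    target_gene: str
    orientation: str
    sequence: str
    reported_tm: float

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError(f"primer {self.name}: sequence must be non-empty A/C/G/T")
        if self.target_gene not in KNOWN_GENES:
            raise ValueError(f"primer {self.name}: unknown target gene {self.target_gene}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: orientation must be forward|reverse")


def load_primer_panel() -> list[PrimerSpec]:
    """Load the packaged eight-primer panel (forward+reverse for each gene)."""
    text = resources.files("mtcnkit.data").joinpath("primers.tsv").read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    panel = [
        PrimerSpec(
            name=r["name"],
            target_gene=r["target_gene"],
            orientation=r["orientation"],
            sequence=r["sequence"],
            reported_tm=float(r["reported_tm"]),
        )
        for r in rows
    ]
    assert len(panel) == 8
    return panel


@dataclass(frozen=True)
class CtMeasurement:
    """A single well's threshold-cycle observation."""

    sample_id: str
    gene: str
    replicate_index: int
    ct: float | None  # None == undetermined
    plate_id: str = "plate1"
    run_date: str = ""
    is_ntc: bool = False
    input_mass_ng: float = 2.0

    def __post_init__(self) -> None:
        if self.ct is not None and not (0.0 <= self.ct <= MAX_CYCLES):
            raise ValueError(
                f"{self.sample_id}/{self.gene} rep {self.replicate_index}: "
                f"ct {self.ct} outside [0, {MAX_CYCLES}]"
            )
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be a positive integer")


@dataclass(frozen=True)
class ReplicateSummary:
    sample_id: str
    gene: str
    n_used: int
    mean_ct: float
    sd_ct: float
    cv_pct: float
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class GenePairing:
    """Ordered (mitochondrial, nuclear) gene pairs used for dCt1/dCt2."""

    pairs: tuple[tuple[str, str], ...] = (("ND1", "BECN1"), ("ND6", "NEB"))

    def __post_init__(self) -> None:
        genes = [g for pair in self.pairs for g in pair]
        if len(genes) != len(set(genes)):
            raise ValueError("each gene may appear at most once in the pairing")
        for mito, nuc in self.pairs:
            if mito not in MITO_GENES or nuc not in NUCLEAR_GENES:
                raise ValueError(f"invalid pair ({mito}, {nuc})")


@dataclass(frozen=True)
class MtcnResult:
    sample_id: str
    delta_ct_1: float
    delta_ct_2: float
    n_1: float
    n_2: float
    mtdnacn: float
    method: str  # "paired" | "geomean"
    qc_flags: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# parsing

_GENE_ALIASES = {
    "ND1": "ND1", "MT-ND1": "ND1", "MTND1": "ND1",
    "ND6": "ND6", "MT-ND6": "ND6", "MTND6": "ND6",
    "BECN1": "BECN1", "NEB": "NEB", "NEB1": "NEB",
}

REQUIRED_COLUMNS = ("sample_id", "gene", "replicate", "ct", "is_ntc")


def normalize_gene(raw: str) -> str | None:
    """Map a gene label to its canonical name, or None if unrecognized."""
    return _GENE_ALIASES.get(raw.strip().upper())


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in ("true", "1", "yes", "t")


def parse_ct_table(
    stream: IO[str] | Iterable[str],
    schema: Mapping[str, str] | None = None,
) -> list[CtMeasurement]:
    """Parse a Ct plate CSV into measurements.

    Expected header columns: ``sample_id,gene,replicate,ct,plate_id,run_date,
    is_ntc`` (``plate_id``/``run_date`` optional).  ``schema`` maps the
    canonical column names to the file's actual column names.  The ct column
    accepts a number or the literal ``Undetermined`` (case-insensitive;
    empty also maps to the undetermined sentinel).  Rows with unknown gene
    names are rejected with a logged warning.
    """
    schema = dict(schema or {})
    reader = csv.DictReader(stream)
    header = reader.fieldnames or []
    colmap = {canon: schema.get(canon, canon) for canon in
              REQUIRED_COLUMNS + ("plate_id", "run_date", "input_mass_ng")}
    for canon in REQUIRED_COLUMNS:
        if colmap[canon] not in header:
            raise ValueError(f"missing required column: {colmap[canon]}")

    out: list[CtMeasurement] = []
    for row in reader:
        raw_gene = row[colmap["gene"]]
        gene = normalize_gene(raw_gene)
        if gene is None:
            log.warning("rejected row with unknown gene name %r (sample %s)",
                        raw_gene, row[colmap["sample_id"]])
            continue
        raw_ct = (row[colmap["ct"]] or "").strip()
        ct = UNDETERMINED if raw_ct == "" or raw_ct.lower() == "undetermined" else float(raw_ct)
        out.append(CtMeasurement(
            sample_id=row[colmap["sample_id"]],
            gene=gene,
            replicate_index=int(row[colmap["replicate"]]),
            ct=ct,
            plate_id=row.get(colmap["plate_id"], "plate1") or "plate1",
            run_date=row.get(colmap["run_date"], "") or "",
            is_ntc=_parse_bool(row[colmap["is_ntc"]]),
            input_mass_ng=float(row.get(colmap["input_mass_ng"]) or 2.0),
        ))
    return out


# ---------------------------------------------------------------------------
# replicate aggregation and QC

def summarize_replicates(
    measurements: Sequence[CtMeasurement],
    high_sd_cycles: float = DEFAULT_HIGH_SD_CYCLES,
) -> list[ReplicateSummary]:
    """Aggregate replicate wells per (sample, gene) with QC flags.

    Undetermined wells are excluded from the mean/sd (imputing them at the
    cycle cap would bias dCt) but raise HAS_UNDETERMINED.  A group whose
    wells are all undetermined produces no summary.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    groups: dict[tuple[str, str], list[CtMeasurement]] = {}
    for m in measurements:
        if m.is_ntc:
            raise ValueError("NTC wells must go through check_ntc, not replicate summaries")
        groups.setdefault((m.sample_id, m.gene), []).append(m)

    out = []
    for (sample_id, gene), wells in groups.items():
        cts = [w.ct for w in wells if w.ct is not None]
        flags = set()
        if len(cts) < len(wells):
            flags.add(HAS_UNDETERMINED)
        if not cts:
            log.warning("all replicates undetermined for %s/%s; no summary", sample_id, gene)
            continue
        mean_ct = statistics.fmean(cts)
        sd_ct = statistics.stdev(cts) if len(cts) >= 2 else 0.0
        if len(cts) < 2:
            flags.add(TOO_FEW_REPLICATES)
        if sd_ct > high_sd_cycles:
            flags.add(HIGH_CT_SD)
        out.append(ReplicateSummary(
            sample_id=sample_id, gene=gene, n_used=len(cts),
            mean_ct=mean_ct, sd_ct=sd_ct,
            cv_pct=100.0 * sd_ct / mean_ct if mean_ct > 0 else 0.0,
            flags=frozenset(flags),
        ))
    return out


@dataclass(frozen=True)
class NtcVerdict:
    gene: str
    status: str  # PASS | FAIL | WARN
    offending_wells: tuple[CtMeasurement, ...] = ()


def check_ntc(
    ntc_measurements: Sequence[CtMeasurement],
    max_allowed_ct: float = DEFAULT_NTC_MAX_CT,
) -> dict[str, NtcVerdict]:
    """Per-gene verdict on no-template-control wells.

    A gene passes when every NTC well is undetermined or amplifies later
    than ``max_allowed_ct``; amplification at or below it indicates
    contamination.  Genes with no NTC wells get WARN, never a silent pass.
    """
    for m in ntc_measurements:
        if not m.is_ntc:
            raise ValueError(f"non-NTC well passed to check_ntc: {m.sample_id}/{m.gene}")
    verdicts = {}
    by_gene: dict[str, list[CtMeasurement]] = {g: [] for g in KNOWN_GENES}
    for m in ntc_measurements:
        by_gene.setdefault(m.gene, []).append(m)
    for gene, wells in by_gene.items():
        if not wells:
            verdicts[gene] = NtcVerdict(gene, "WARN")
            continue
        bad = tuple(w for w in wells if w.ct is not None and w.ct <= max_allowed_ct)
        verdicts[gene] = NtcVerdict(gene, "FAIL" if bad else "PASS", bad)
    return verdicts


# ---------------------------------------------------------------------------
# estimators

def _summary_lookup(summaries: Iterable[ReplicateSummary], sample_id: str) -> dict[str, ReplicateSummary]:
    return {s.gene: s for s in summaries if s.sample_id == sample_id}


def delta_ct(
    pairing: GenePairing,
    summaries: Sequence[ReplicateSummary],
    sample_id: str,
) -> tuple[float, float]:
    """dCt per pair: nuclear mean Ct minus mitochondrial mean Ct."""
    by_gene = _summary_lookup(summaries, sample_id)
    out = []
    for mito, nuc in pairing.pairs:
        for gene in (mito, nuc):
            if gene not in by_gene:
                raise ValueError(f"sample {sample_id}: missing replicate summary for gene {gene}")
        out.append(by_gene[nuc].mean_ct - by_gene[mito].mean_ct)
    d1, d2 = out
    return d1, d2


def relative_copy_number(delta_ct: float) -> float:
    """N = 2**dCt, assuming perfect per-cycle doubling."""
    if not math.isfinite(delta_ct):
        raise ValueError(f"delta_ct must be finite, got {delta_ct}")
    return 2.0 ** delta_ct


def mtdnacn_paired(n_1: float, n_2: float) -> float:
    """Final relative copy number: arithmetic mean of the two pair estimates."""
    if n_1 <= 0 or n_2 <= 0:
        raise ValueError("relative copy numbers must be positive")
    return (n_1 + n_2) / 2.0


def mtdnacn_paired_result(
    summaries: Sequence[ReplicateSummary],
    sample_id: str,
    pairing: GenePairing = GenePairing(),
) -> MtcnResult:
    """Paired-gene estimator for one sample, with propagated QC flags."""
    d1, d2 = delta_ct(pairing, summaries, sample_id)
    n1, n2 = relative_copy_number(d1), relative_copy_number(d2)
    flags = frozenset().union(*(s.flags for s in summaries if s.sample_id == sample_id))
    return MtcnResult(sample_id, d1, d2, n1, n2, mtdnacn_paired(n1, n2), "paired", flags)


def mtdnacn_geomean(
    summaries: Sequence[ReplicateSummary],
    sample_id: str,
) -> MtcnResult:
    """Commercial-kit style estimator.

    Both mitochondrial genes are normalized against the geometric mean of
    the two nuclear reference signals; in Ct space that geometric mean is
    the arithmetic mean of the nuclear Cts.  Equals the paired estimator
    exactly whenever the two nuclear mean Cts coincide.
    """
    by_gene = _summary_lookup(summaries, sample_id)
    for gene in KNOWN_GENES:
        if gene not in by_gene:
            raise ValueError(f"sample {sample_id}: missing replicate summary for gene {gene}")
    ref_ct = (by_gene["BECN1"].mean_ct + by_gene["NEB"].mean_ct) / 2.0
    d1 = ref_ct - by_gene["ND1"].mean_ct
    d2 = ref_ct - by_gene["ND6"].mean_ct
    n1, n2 = relative_copy_number(d1), relative_copy_number(d2)
    flags = frozenset().union(*(s.flags for s in summaries if s.sample_id == sample_id))
    return MtcnResult(sample_id, d1, d2, n1, n2, (n1 + n2) / 2.0, "geomean", flags)


def analyze_plate(
    measurements: Sequence[CtMeasurement],
    method: str = "paired",
    pairing: GenePairing = GenePairing(),
    high_sd_cycles: float = DEFAULT_HIGH_SD_CYCLES,
    ntc_max_ct: float = DEFAULT_NTC_MAX_CT,
) -> tuple[list[MtcnResult], dict]:
    """Full plate workflow: NTC QC, replicate aggregation, per-sample estimates.

    Returns results sorted by sample id plus a QC dict with the per-gene NTC
    verdicts and any samples dropped for missing gene data.
    """
    if method not in ("paired", "geomean"):
        raise ValueError(f"unknown method {method!r}")
    ntc = [m for m in measurements if m.is_ntc]
    samples = [m for m in measurements if not m.is_ntc]
    verdicts = check_ntc(ntc, max_allowed_ct=ntc_max_ct)
    summaries = summarize_replicates(samples, high_sd_cycles=high_sd_cycles)
    results = []
    for sample_id in sorted({m.sample_id for m in samples}):
        if method == "paired":
            results.append(mtdnacn_paired_result(summaries, sample_id, pairing))
        else:
            results.append(mtdnacn_geomean(summaries, sample_id))
    qc = {
        "ntc": {g: v.status for g, v in verdicts.items()},
        "ntc_offending_wells": {
            g: [f"{w.sample_id}/rep{w.replicate_index}/ct={w.ct}" for w in v.offending_wells]
            for g, v in verdicts.items() if v.offending_wells
        },
    }
    return results, qc


# ---------------------------------------------------------------------------
# reference-sample and replicate-variability reporting

def _cv_pct(values: Sequence[float]) -> float:
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) >= 2 else 0.0
    return 100.0 * sd / mean if mean else 0.0


def reference_sample_qc(
    reference_results: Mapping[str, float],
    drift_fraction: float = DEFAULT_REFERENCE_DRIFT_FRACTION,
) -> dict:
    """Across-plate drift report for the inter-run reference DNA (NA12878).

    ``reference_results`` maps plate id to the reference sample's mtDNAcn on
    that plate.  A plate is flagged when its reference value deviates from
    the across-plate mean by more than ``drift_fraction``.  Reference values
    are reported only; sample estimates are never renormalized against them.
    """
    if not reference_results:
        return {"status": "WARN", "message": "no reference results", "plates": {},
                "mean": None, "sd": None, "cv_pct": None, "flagged_plates": []}
    values = list(reference_results.values())
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) >= 2 else 0.0
    flagged = [plate for plate, v in reference_results.items()
               if abs(v - mean) / mean > drift_fraction]
    return {
        "status": "OK",
        "plates": dict(reference_results),
        "mean": mean,
        "sd": sd,
        "cv_pct": 100.0 * sd / mean if mean else 0.0,
        "flagged_plates": sorted(flagged),
    }


def replicate_variability(
    tagged_results: Sequence[tuple[str, str, str, float]],
) -> dict[str, dict[str, float | str]]:
    """Inter-/intra-day coefficient of variation per sample.

    ``tagged_results`` rows are ``(sample_id, day, plate_run, mtdnacn)``.
    Inter-day CV pools one value per day (the mean across same-day runs);
    intra-day CV pools repeated runs within a day.  An axis with fewer than
    two observations is reported as "NA".
    """
    by_sample: dict[str, list[tuple[str, str, float]]] = {}
    for sample_id, day, run, value in tagged_results:
        by_sample.setdefault(sample_id, []).append((day, run, value))

    table: dict[str, dict[str, float | str]] = {}
    for sample_id, rows in by_sample.items():
        by_day: dict[str, list[float]] = {}
        for day, _run, value in rows:
            by_day.setdefault(day, []).append(value)
        day_means = [statistics.fmean(v) for v in by_day.values()]
        inter: float | str = _cv_pct(day_means) if len(day_means) >= 2 else "NA"
        intra_cvs = [_cv_pct(v) for v in by_day.values() if len(v) >= 2]
        intra: float | str = statistics.fmean(intra_cvs) if intra_cvs else "NA"
        table[sample_id] = {"inter_day_cv_pct": inter, "intra_day_cv_pct": intra}
    return table


# ---------------------------------------------------------------------------
# output

RESULT_COLUMNS = ("sample_id", "method", "delta_ct_1", "delta_ct_2",
                  "n_1", "n_2", "mtdnacn", "qc_flags")


def write_results_tsv(results: Sequence[MtcnResult], stream: IO[str]) -> None:
    """Write per-sample results sorted by sample id, 6 significant digits."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(RESULT_COLUMNS)
    for r in sorted(results, key=lambda r: r.sample_id):
        writer.writerow([
            r.sample_id, r.method,
            f"{r.delta_ct_1:.6g}", f"{r.delta_ct_2:.6g}",
            f"{r.n_1:.6g}", f"{r.n_2:.6g}", f"{r.mtdnacn:.6g}",
            ";".join(sorted(r.qc_flags)),
        ])
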