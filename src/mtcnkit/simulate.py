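"""Synthetic cohorts, qPCR plates, and low-pass WGS alignments.

Everything the estimators consume can be generated here from a per-sample
ground-truth copy number, so the full pipeline (plates -> dCt estimators,
alignments -> coverage estimator, concordance) runs end-to-end offline.

Cohort truth: per-sample true mtDNAcn is drawn from a lognormal whose
moments match the requested (mean, sd) — defaults are the study groups this
simulator emulates: infants 229.2 +/- 66.4 and mothers 136.7 +/- 41.8
(relative copies, mean +/- SD).  Lognormal keeps values strictly positive
without truncation.

qPCR plates: the nuclear targets sit at a baseline Ct (default 25 cycles
for 2 ng input); a sample with true ratio R shifts its mitochondrial
targets earlier by log_eff(R) cycles.  Gaussian noise of sd ``ct_sd``
(default 0.15 cycles) is added independently per well; triplicates plus
per-gene no-template controls are emitted.  With zero noise and efficiency
2 the paired estimator returns R exactly.

lpWGS: reads are error-free 100M-CIGAR alignments on a toy diploid genome
(two 200 kb autosomes + a 16,569 bp mitochondrial contig).  Read counts per
contig are Poisson with mean length*depth/read_length, where mitochondrial
depth is (R/2) times the autosomal target depth — the coverage-ratio
estimator's expected value is then exactly R.  The model deliberately omits
sequencing error, GC bias, duplicates and NUMT cross-mapping (a
mito-identical autosomal segment can be planted to study the latter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .lpwgs import (
    ContigClassification,
    ContigDepth,
    CoverageSummary,
    classify_contigs,
)
from .qpcr import CtMeasurement

# Study-group defaults the simulator emulates (relative copies)
INFANT_MEAN, INFANT_SD = 229.2, 66.4
MOTHER_MEAN, MOTHER_SD = 136.7, 41.8

PLATE_COLUMNS = ("sample_id", "gene", "replicate", "ct", "plate_id", "run_date", "is_ntc")

_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class QpcrNoiseModel:
    """Technical noise for synthetic Ct plates."""

    ct_sd: float = 0.15
    nuclear_baseline_ct: float = 25.0
    efficiency: float = 2.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be >= 0")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must lie in (1, 2]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class ToyGenomeSpec:
    """Small genome used for alignment simulation at full mito scale."""

    autosomes: tuple[tuple[str, int], ...] = (("chr1", 200_000), ("chr2", 200_000))
    mito: tuple[str, int] = ("chrM", 16_569)
    read_length: int = 100
    target_autosomal_depth: float = 1.0

    def __post_init__(self) -> None:
        for _, length in self.contigs:
            if length < self.read_length:
                raise ValueError("every contig must be at least one read long")
        if self.target_autosomal_depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def contigs(self) -> tuple[tuple[str, int], ...]:
        return self.autosomes + (self.mito,)

    def classification(self) -> list[ContigClassification]:
        return classify_contigs(self.contigs)

    def header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in self.contigs],
        })


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_cohort(
    n_infants: int,
    n_mothers: int,
    infant_mean: float = INFANT_MEAN,
    infant_sd: float = INFANT_SD,
    mother_mean: float = MOTHER_MEAN,
    mother_sd: float = MOTHER_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth table: sample_id, group (infant|mother), true_mtdnacn.

    Moment-matched lognormal per group; bit-reproducible under a fixed seed.
    """
    if n_infants < 0 or n_mothers < 0:
        raise ValueError("cohort sizes must be >= 0")
    for mean, sd in ((infant_mean, infant_sd), (mother_mean, mother_sd)):
        if mean <= 0 or sd <= 0:
            raise ValueError("group mean and sd must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, mean, sd in (("infant", n_infants, infant_mean, infant_sd),
                               ("mother", n_mothers, mother_mean, mother_sd)):
        mu, sigma = _lognormal_params(mean, sd)
        values = rng.lognormal(mu, sigma, size=n)
        rows += [(f"{group}{i + 1:03d}", group, float(v)) for i, v in enumerate(values)]
    df = pd.DataFrame(rows, columns=["sample_id", "group", "true_mtdnacn"])
    df.attrs["provenance"] = {
        "seed": seed,
        "infant": {"n": n_infants, "mean": infant_mean, "sd": infant_sd},
        "mother": {"n": n_mothers, "mean": mother_mean, "sd": mother_sd},
    }
    return df


def simulate_ct_plate(
    truth: pd.DataFrame,
    noise: QpcrNoiseModel = QpcrNoiseModel(),
    seed: int = 0,
    plate_id: str = "plate1",
    run_date: str = "2000-01-01",
    input_mass_ng: float = 2.0,
) -> pd.DataFrame:
    """Synthetic Ct plate in the parser's input schema.

    Per sample and replicate: nuclear Cts = baseline + noise; mitochondrial
    Cts = baseline - log_eff(true_mtdnacn) + noise.  Doubling the template
    mass shifts every gene's Ct earlier by one cycle (at efficiency 2), so
    the ratio estimators are mass-invariant.  One undetermined NTC well per
    gene is appended.
    """
    rng = np.random.default_rng(seed)
    log_eff = np.log(noise.efficiency)
    mass_shift = -np.log(input_mass_ng / 2.0) / log_eff
    rows = []
    for sample_id, r in zip(truth["sample_id"], truth["true_mtdnacn"]):
        mito_shift = -np.log(r) / log_eff
        for gene, shift in (("ND1", mito_shift), ("ND6", mito_shift),
                            ("BECN1", 0.0), ("NEB", 0.0)):
            base = noise.nuclear_baseline_ct + shift + mass_shift
            if base < 0:
                raise ValueError(
                    f"sample {sample_id}/{gene}: noiseless Ct {base:.2f} < 0; "
                    "increase nuclear_baseline_ct")
            for rep in range(1, noise.replicates + 1):
                ct = base + rng.normal(0.0, noise.ct_sd) if noise.ct_sd > 0 else base
                rows.append((sample_id, gene, rep, float(ct), plate_id, run_date, False))
    for gene in ("ND1", "ND6", "BECN1", "NEB"):
        rows.append(("NTC", gene, 1, None, plate_id, run_date, True))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def plate_to_measurements(plate: pd.DataFrame) -> list[CtMeasurement]:
    """Convert a simulated plate frame to measurements without a CSV round-trip."""
    return [
        CtMeasurement(
            sample_id=row.sample_id, gene=row.gene, replicate_index=int(row.replicate),
            ct=None if row.ct is None or (isinstance(row.ct, float) and np.isnan(row.ct))
            else float(row.ct),
            plate_id=row.plate_id, run_date=str(row.run_date), is_ntc=bool(row.is_ntc),
        )
        for row in plate.itertuples(index=False)
    ]


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    out = plate.copy()
    out["ct"] = out["ct"].map(lambda v: "Undetermined" if v is None or
                              (isinstance(v, float) and np.isnan(v)) else f"{v:.6g}")
    out["is_ntc"] = out["is_ntc"].map(lambda b: "true" if b else "false")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# lpWGS

def _contig_depths(true_mtdnacn: float, genome: ToyGenomeSpec) -> dict[str, float]:
    mito_name, _ = genome.mito
    depths = {name: genome.target_autosomal_depth for name, _ in genome.autosomes}
    depths[mito_name] = genome.target_autosomal_depth * true_mtdnacn / 2.0
    return depths


def simulate_lpwgs_alignments(
    true_mtdnacn: float,
    genome: ToyGenomeSpec = ToyGenomeSpec(),
    seed: int = 0,
    sample_id: str = "sample",
    out_sam: str | Path | None = None,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Sample error-free alignments whose expected coverage ratio encodes R.

    Reads are primary, MAPQ 60, fully matched (CIGAR ``<read_length>M``),
    with uniform start positions that keep each read inside its contig.
    When ``out_sam`` is given the records are also written as plain SAM.
    """
    if true_mtdnacn < 0:
        raise ValueError("true_mtdnacn must be >= 0")
    rng = np.random.default_rng(seed)
    header = genome.header()
    rl = genome.read_length
    reads: list[pysam.AlignedSegment] = []
    for ref_id, (name, length) in enumerate(genome.contigs):
        depth = _contig_depths(true_mtdnacn, genome)[name]
        n = int(rng.poisson(length * depth / rl))
        starts = rng.integers(0, length - rl + 1, size=n)
        for i, start in enumerate(starts):
            a = pysam.AlignedSegment(header)
            a.query_name = f"{sample_id}.{name}.{i}"
            a.flag = 0
            a.reference_id = ref_id
            a.reference_start = int(start)
            a.mapping_quality = 60
            a.cigartuples = [(0, rl)]
            reads.append(a)
    if out_sam is not None:
        with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
            for a in reads:
                fh.write(a)
    return header, reads


def expected_depth_profile(
    true_mtdnacn: float,
    genome: ToyGenomeSpec = ToyGenomeSpec(),
) -> CoverageSummary:
    """Noiseless analytic coverage summary (no read sampling).

    Feeding this to the coverage-ratio estimator returns ``true_mtdnacn``
    exactly; it is the zero-noise limit used for identity checks.
    """
    depths = _contig_depths(true_mtdnacn, genome)
    per_contig = {name: ContigDepth(length, depths[name] * length)
                  for name, length in genome.contigs}
    mito_name, mito_len = genome.mito
    return CoverageSummary(
        per_contig=per_contig,
        autosomal_mean_depth=genome.target_autosomal_depth,
        mito_mean_depth=depths[mito_name],
        reads_kept=0,
        reads_filtered={},
        mito_read_count=int(round(depths[mito_name] * mito_len / genome.read_length)),
    )


def write_toy_genome_fasta(
    genome: ToyGenomeSpec,
    path: str | Path,
    seed: int = 0,
) -> None:
    """Random A/C/G/T sequence for each contig of the toy genome."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for name, length in genome.contigs:
            seq = "".join(_DNA[rng.integers(0, 4, size=length)])
            fh.write(f">{name}\n")
            for i in range(0, length, 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# synthetic haplogroup panel

DEFAULT_PANEL_HAPLOGROUPS = ("A2", "B2", "C1", "D1", "H1", "J1", "L0", "M7", "U5", "X2")


def random_mito_sequence(length: int = 16_569, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_DNA[rng.integers(0, 4, size=length)])


def mutate_sequence(sequence: str, n_substitutions: int, seed: int = 0) -> str:
    """Plant ``n_substitutions`` random substitutions at distinct positions."""
    rng = np.random.default_rng(seed)
    seq = list(sequence)
    for pos in rng.choice(len(seq), size=n_substitutions, replace=False):
        current = seq[pos]
        seq[pos] = rng.choice([b for b in "ACGT" if b != current])
    return "".join(seq)


def simulate_haplogroup_panel(
    haplogroups: Sequence[str] = DEFAULT_PANEL_HAPLOGROUPS,
    length: int = 16_569,
    n_variants: int = 60,
    seed: int = 0,
) -> dict[str, str]:
    """Synthetic labeled mitochondrial consensus sequences.

    All sequences derive from one random ancestor; each haplogroup carries
    its own set of ``n_variants`` planted substitutions, mimicking the
    variant sets that define real haplogroup branches.  Synthetic stand-in
    only — no phylogenetic structure beyond the shared ancestor.
    """
    ancestor = random_mito_sequence(length, seed)
    rng = np.random.default_rng(seed)
    return {hap: mutate_sequence(ancestor, n_variants, seed=int(rng.integers(2**31)))
            for hap in haplogroups}
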