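"""Glue running simulated cohorts through every estimator.

Shared by the command-line interface, the test suite, and the reproduction
script, so the same code path produces every published-style number.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import lpwgs, qpcr, simulate


def qpcr_estimates(plate: pd.DataFrame, method: str = "paired") -> dict[str, float]:
    """Per-sample mtDNAcn from a simulated (or parsed) plate frame."""
    measurements = simulate.plate_to_measurements(plate)
    results, _qc = qpcr.analyze_plate(measurements, method=method)
    return {r.sample_id: r.mtdnacn for r in results}


def lpwgs_estimates(
    truth: pd.DataFrame,
    genome: simulate.ToyGenomeSpec = simulate.ToyGenomeSpec(),
    seed: int = 0,
    policy: lpwgs.ReadFilterPolicy = lpwgs.ReadFilterPolicy(),
) -> dict[str, float]:
    """Sampled-read coverage-ratio estimates for every truth row.

    Each sample gets an independent child seed spawned from ``seed`` so the
    whole cohort is reproducible from one integer.
    """
    classification = genome.classification()
    rng = np.random.default_rng(seed)
    out = {}
    for row in truth.itertuples(index=False):
        child = int(rng.integers(2**31))
        _header, reads = simulate.simulate_lpwgs_alignments(
            row.true_mtdnacn, genome, seed=child, sample_id=row.sample_id)
        summary = lpwgs.mean_depth(reads, classification, policy)
        out[row.sample_id] = lpwgs.mtdnacn_from_coverage(summary, row.sample_id).mtdnacn
    return out


def lpwgs_estimates_analytic(
    truth: pd.DataFrame,
    genome: simulate.ToyGenomeSpec = simulate.ToyGenomeSpec(),
) -> dict[str, float]:
    """Noiseless coverage-ratio estimates from analytic depth profiles."""
    out = {}
    for row in truth.itertuples(index=False):
        summary = simulate.expected_depth_profile(row.true_mtdnacn, genome)
        out[row.sample_id] = lpwgs.mtdnacn_from_coverage(summary, row.sample_id).mtdnacn
    return out
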