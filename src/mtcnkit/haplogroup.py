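"""Simplified k-mer mitochondrial haplogroup caller.

Haplogroups are branches of the mitochondrial phylogeny defined by variant
sets; because mtDNA is non-recombining, the k-mers of a haplogroup's
consensus sequence act as a fingerprint.  This module builds a library of
k-mer sets from labeled mitochondrial sequences and scores a query by the
fraction of each haplogroup's k-mers it contains:

    score(h) = |kmers(query) ∩ kmers(h)| / |kmers(h)|

The asymmetric score tolerates extra query content (e.g. read sets larger
than a consensus).  The mitochondrial genome is circular, so k-mers wrap
around the origin by default.  This is an intentionally simplified stand-in
for full k-mer haplogroup classifiers built on PhyloTree-derived libraries
(e.g. Phy-mer): it ships no real phylogenetic panel, no weighting, and no
heteroplasmy awareness.  Build a real panel from labeled consensus FASTA if
you need one.

Haplogroups are mapped to coarse geographic regions (macrohaplogroups A-D
are prevalent in Indigenous American lineages, L in Africa, ...) via a
longest-prefix lookup in an editable TSV.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence
import logging

from Bio import SeqIO

log = logging.getLogger(__name__)

DNA = set("ACGT")
UNCLASSIFIED = "unclassified"
TIED = "TIED"
DEFAULT_K = 12
#: Minimum top score to accept a call.  Two unrelated 16.5 kb sequences
#: share ~L^2/4^k k-mers by chance (score ~0.001 at k=12); real matches
#: score near 1, so any floor well between the two works.
DEFAULT_MIN_SCORE = 0.05


def sequence_kmers(sequence: str, k: int, circular: bool = True) -> set[str]:
    """Distinct k-mers of a sequence; a circular sequence wraps k-1 bases.

    Characters outside A/C/G/T (ambiguity codes) break the sliding window:
    any k-mer containing one is dropped with a warning.
    """
    seq = sequence.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} shorter than k={k}")
    extended = seq + seq[: k - 1] if circular else seq
    kmers = set()
    dropped = 0
    for i in range(len(extended) - k + 1):
        kmer = extended[i : i + k]
        if set(kmer) <= DNA:
            kmers.add(kmer)
        else:
            dropped += 1
    if dropped:
        log.warning("dropped %d k-mers containing ambiguity codes", dropped)
    if not kmers:
        raise ValueError("sequence yielded no valid k-mers")
    return kmers


@dataclass(frozen=True)
class KmerPanel:
    """Haplogroup -> k-mer set library plus a prefix -> region map."""

    k: int
    entries: Mapping[str, frozenset[str]]
    region_map: Mapping[str, str]

    def __post_init__(self) -> None:
        for hap, kmers in self.entries.items():
            if not kmers:
                raise ValueError(f"haplogroup {hap}: empty k-mer set")
            bad = next((m for m in kmers if len(m) != self.k or set(m) - DNA), None)
            if bad is not None:
                raise ValueError(f"haplogroup {hap}: invalid k-mer {bad!r}")

    def region_for(self, haplogroup: str) -> str:
        """Longest-prefix region lookup; 'other' when nothing matches."""
        for plen in range(len(haplogroup), 0, -1):
            region = self.region_map.get(haplogroup[:plen])
            if region is not None:
                return region
        return "other"


@dataclass(frozen=True)
class HaplogroupCall:
    sample_id: str
    ranked: tuple[tuple[str, float], ...]  # (haplogroup, score), non-increasing
    best: str
    region: str
    qc_flags: frozenset[str] = frozenset()


def load_region_map(stream: IO[str] | None = None) -> dict[str, str]:
    """Load the prefix->region TSV (packaged default when no stream given)."""
    if stream is None:
        text = resources.files("mtcnkit.data").joinpath("region_map.tsv").read_text()
        rows = csv.DictReader(text.splitlines(), delimiter="\t")
    else:
        rows = csv.DictReader(stream, delimiter="\t")
    return {r["prefix"]: r["region"] for r in rows}


def build_kmer_panel(
    labeled_sequences: Mapping[str, str],
    k: int = DEFAULT_K,
    circular: bool = True,
    region_map: Mapping[str, str] | None = None,
) -> KmerPanel:
    """Build a panel from {haplogroup: mito sequence}."""
    entries = {hap: frozenset(sequence_kmers(seq, k, circular=circular))
               for hap, seq in labeled_sequences.items()}
    if not entries:
        raise ValueError("no labeled sequences supplied")
    return KmerPanel(k=k, entries=entries,
                     region_map=dict(region_map) if region_map is not None else load_region_map())


def panel_from_fasta(
    fasta: str | Path | IO[str],
    labels: Mapping[str, str] | None = None,
    k: int = DEFAULT_K,
    circular: bool = True,
    region_map: Mapping[str, str] | None = None,
) -> KmerPanel:
    """Build a panel from a FASTA of mitochondrial consensus sequences.

    ``labels`` maps record id to haplogroup name; by default the record id
    itself is the haplogroup.
    """
    seqs = {}
    for record in SeqIO.parse(fasta, "fasta"):
        hap = (labels or {}).get(record.id, record.id)
        seqs[hap] = str(record.seq)
    return build_kmer_panel(seqs, k=k, circular=circular, region_map=region_map)


def call_haplogroup(
    query: str | Iterable[str],
    panel: KmerPanel,
    sample_id: str = "sample",
    circular: bool = True,
    min_score: float = DEFAULT_MIN_SCORE,
) -> HaplogroupCall:
    """Score every panel haplogroup against a query sequence or read set.

    ``query`` is a single consensus sequence or an iterable of reads (reads
    are treated as linear fragments).  Ties on the top score are broken
    lexicographically and flagged TIED.  A query whose best score falls
    below ``min_score`` (chance-collision level) is "unclassified".
    """
    if isinstance(query, str):
        qkmers = sequence_kmers(query, panel.k, circular=circular)
    else:
        qkmers = set()
        for read in query:
            if len(read) >= panel.k:
                qkmers |= sequence_kmers(read, panel.k, circular=False)
        if not qkmers:
            raise ValueError("query reads yielded no k-mers")

    scored = sorted(
        ((hap, len(qkmers & kmers) / len(kmers)) for hap, kmers in panel.entries.items()),
        key=lambda t: (-t[1], t[0]),
    )
    flags = set()
    if scored[0][1] < min_score:
        return HaplogroupCall(sample_id, tuple(scored), UNCLASSIFIED, "other")
    if len(scored) > 1 and scored[1][1] == scored[0][1]:
        flags.add(TIED)
    best = scored[0][0]
    return HaplogroupCall(sample_id, tuple(scored), best,
                          panel.region_for(best), frozenset(flags))


def region_tally(calls: Sequence[HaplogroupCall]) -> dict[str, int]:
    """Counts per region, ordered by descending count then region name."""
    counts = Counter(c.region for c in calls)
    return dict(sorted(counts.items(), key=lambda t: (-t[1], t[0])))


def write_panel_tsv(panel: KmerPanel, stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["haplogroup", "kmer"])
    for hap in sorted(panel.entries):
        for kmer in sorted(panel.entries[hap]):
            writer.writerow([hap, kmer])


def read_panel_tsv(stream: IO[str], region_map: Mapping[str, str] | None = None) -> KmerPanel:
    rows = list(csv.DictReader(stream, delimiter="\t"))
    if not rows:
        raise ValueError("empty panel table")
    entries: dict[str, set[str]] = {}
    for r in rows:
        entries.setdefault(r["haplogroup"], set()).add(r["kmer"])
    k = len(next(iter(next(iter(entries.values())))))
    return KmerPanel(k=k, entries={h: frozenset(s) for h, s in entries.items()},
                     region_map=dict(region_map) if region_map is not None else load_region_map())


def write_calls_tsv(calls: Sequence[HaplogroupCall], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["sample_id", "best", "score", "region", "qc_flags"])
    for c in sorted(calls, key=lambda c: c.sample_id):
        score = c.ranked[0][1] if c.ranked else 0.0
        writer.writerow([c.sample_id, c.best, f"{score:.6g}", c.region,
                         ";".join(sorted(c.qc_flags))])
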