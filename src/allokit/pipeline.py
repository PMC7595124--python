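"""End-to-end convenience wrappers over the module-level operations."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hmm, kmers
from .kmers import (
    DiagnosticKmerSet,
    HomeologMap,
    KmerCountMatrix,
    SubgenomePartition,
    scaled_min_total,
)


@dataclass
class SubgenomePhasing:
    matrix: KmerCountMatrix
    kmer_set: DiagnosticKmerSet
    partition: SubgenomePartition
    tracks: pd.DataFrame


def phase_subgenomes(
    genome: dict[str, np.ndarray],
    homeolog_map: HomeologMap,
    k: int = 13,
    min_total: float | None = None,
    min_fold: float = 2.0,
    window_size: int = 10_000,
    max_conflicts: int = 0,
) -> SubgenomePhasing:
    """Count k-mers, select diagnostic ones, partition, filter, and track.

    ``min_total=None`` scales the genome-wide occurrence threshold to the
    genome size (100 per 2 Gb, floor 10).
    """
    matrix = kmers.count_kmers(genome, k=k)
    if min_total is None:
        min_total = scaled_min_total(sum(matrix.chromosome_lengths.values()))
    kset = kmers.select_diagnostic_kmers(
        matrix, homeolog_map, min_total=min_total, min_fold=min_fold
    )
    partition = kmers.cluster_chromosomes(matrix, kset, homeolog_map)
    kset = kmers.consistency_filter(kset, partition, homeolog_map,
                                    max_conflicts=max_conflicts)
    tracks = kmers.density_tracks(genome, kset, window_size)
    return SubgenomePhasing(matrix=matrix, kmer_set=kset, partition=partition,
                            tracks=tracks)


@dataclass
class ExchangeAnalysis:
    params: hmm.HMMParams
    segments: dict[str, pd.DataFrame]
    calls: pd.DataFrame


def find_exchanges(
    phasing: SubgenomePhasing,
    homeolog_map: HomeologMap,
    switch_prob: float = 1e-3,
    min_windows: int = 3,
    em: bool = False,
) -> ExchangeAnalysis:
    """Estimate HMM emissions, segment every chromosome, call exchanges."""
    params = hmm.estimate_emissions(
        phasing.tracks, phasing.partition, em=em, switch_prob=switch_prob
    )
    segments = hmm.segment_genome(phasing.tracks, params, min_windows=min_windows)
    calls = hmm.call_exchanges(segments, phasing.partition, homeolog_map,
                               tracks=phasing.tracks)
    return ExchangeAnalysis(params=params, segments=segments, calls=calls)
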