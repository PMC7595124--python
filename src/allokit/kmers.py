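"""Subgenome identification from differential k-mers.

A paleo-allopolyploid carries relict repeats that amplified in only one of
its two progenitors. Short k-mers (k = 13 at chromosome scale) descending
from such repeats are therefore enriched on one member of every homeologous
chromosome pair; a k-mer is *diagnostic* when (1) it occurs at least
``min_total`` times genome-wide and (2) it is at least ``min_fold`` enriched
in one member of every pair, with the favored side consistent across pairs.
Hierarchical clustering of chromosomes on diagnostic-k-mer profiles then
bipartitions the genome into the A and B subgenomes without requiring any
extant progenitor sequence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from . import seqs
from .errors import DegenerateDataError, InputError

Genome = dict[str, np.ndarray]


@dataclass
class HomeologMap:
    """Pairing of homeologous chromosomes, with optional exclusions.

    Chromosomes that cannot be paired one-to-one (e.g. a fusion product
    homeologous to two partners) go in ``excluded`` and take no part in
    diagnostic-k-mer selection.
    """

    pairs: list[tuple[str, str]]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for c1, c2 in self.pairs:
            for c in (c1, c2):
                if c in seen:
                    raise InputError(f"chromosome {c!r} appears in more than one pair")
                seen.add(c)
        for c in self.excluded:
            if c in seen:
                raise InputError(f"excluded chromosome {c!r} also appears in a pair")

    @property
    def chromosomes(self) -> list[str]:
        return [c for pair in self.pairs for c in pair]

    @classmethod
    def from_tsv(cls, path) -> "HomeologMap":
        pairs, excluded = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#excluded"):
                    excluded.extend(line.split()[1:])
                elif line.startswith("#"):
                    continue
                else:
                    f = line.split("\t")
                    if len(f) < 2:
                        raise InputError(f"homeolog map line needs two columns: {line!r}")
                    pairs.append((f[0], f[1]))
        return cls(pairs=pairs, excluded=excluded)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c1, c2 in self.pairs:
                fh.write(f"{c1}\t{c2}\n")
            if self.excluded:
                fh.write("#excluded " + " ".join(self.excluded) + "\n")


@dataclass
class KmerCountMatrix:
    """Canonical k-mer occurrence counts per chromosome.

    ``counts`` is indexed by packed canonical k-mer codes (uint64); use
    :meth:`kmer` to recover the sequence of a row.
    """

    k: int
    counts: pd.DataFrame  # index: canonical codes, columns: chromosomes
    chromosome_lengths: dict[str, int]

    def kmer(self, code: int) -> str:
        return seqs.code_to_kmer(int(code), self.k)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DiagnosticKmerSet:
    """K-mers passing the occurrence and per-pair fold thresholds.

    ``table`` is indexed by k-mer sequence with columns ``label`` (A/B, or a
    provisional orientation before :func:`consistency_filter` has run),
    ``consistency``, plus ``favored_<pair>`` / ``fold_<pair>`` per pair.
    """

    k: int
    table: pd.DataFrame
    min_total: float
    min_fold: float

    def __len__(self) -> int:
        return len(self.table)

    def labels(self) -> pd.Series:
        return self.table["label"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="kmer")


@dataclass
class SubgenomePartition:
    """Bipartition of chromosomes into subgenomes A and B."""

    assignment: dict[str, str]
    linkage: np.ndarray | None
    score: float
    consistent: bool  # every homeolog pair split one A / one B

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, sub in self.assignment.items():
                fh.write(f"{chrom}\t{sub}\n")

    @classmethod
    def from_tsv(cls, path) -> "SubgenomePartition":
        assignment = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    chrom, sub = line.split()[:2]
                    assignment[chrom] = sub
        return cls(assignment=assignment, linkage=None, score=float("nan"), consistent=True)


# ---------------------------------------------------------------------------


def count_kmers(genome: Genome | str, k: int = 13) -> KmerCountMatrix:
    """Count canonical k-mers per chromosome (exact, N-windows skipped)."""
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        genome = seqs.read_fasta(genome)
    if not genome:
        raise InputError("empty genome")
    per_chrom = {}
    lengths = {}
    for name, codes in genome.items():
        lengths[name] = len(codes)
        _, canon = seqs.rolling_canonical_codes(codes, k)
        if canon.size:
            uniq, cnt = np.unique(canon, return_counts=True)
        else:
            uniq, cnt = np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
        per_chrom[name] = pd.Series(cnt, index=uniq)
    counts = pd.DataFrame(per_chrom).fillna(0).astype(np.int64)
    counts = counts.sort_index()
    return KmerCountMatrix(k=k, counts=counts, chromosome_lengths=lengths)


def scaled_min_total(genome_size_bp: float, reference_min: float = 100.0,
                     reference_genome: float = 2e9, floor: float = 10.0) -> float:
    """Scale the genome-wide occurrence threshold to the genome size.

    The 100-occurrence default is calibrated to a ~2 Gb assembly; smaller
    (synthetic) genomes scale proportionally, floored at ``floor``.
    """
    return max(floor, reference_min * genome_size_bp / reference_genome)


def select_diagnostic_kmers(
    matrix: KmerCountMatrix,
    homeolog_map: HomeologMap,
    min_total: float = 100.0,
    min_fold: float = 2.0,
    length_normalize: bool = True,
) -> DiagnosticKmerSet:
    """Retain k-mers diagnostic of subgenome ancestry.

    A k-mer is kept when its genome-wide total is >= ``min_total`` and, for
    every homeolog pair, its density (counts per bp when
    ``length_normalize``, raw counts otherwise; pseudocount 1 either way) is
    >= ``min_fold``-fold higher on one member. Ties at exactly ``min_fold``
    are kept. Labels are provisional until :func:`consistency_filter` maps
    them onto a :class:`SubgenomePartition`.
    """
    if not homeolog_map.pairs:
        raise InputError("homeolog map has no pairs")
    for c in homeolog_map.chromosomes:
        if c not in matrix.counts.columns:
            raise InputError(f"chromosome {c!r} missing from count matrix")
    counts = matrix.counts
    total = counts.sum(axis=1)
    candidates = counts.loc[total >= min_total]
    if candidates.empty:
        return DiagnosticKmerSet(matrix.k, _empty_table(homeolog_map), min_total, min_fold)

    keep = np.ones(len(candidates), dtype=bool)
    favored = {}
    folds = {}
    for c1, c2 in homeolog_map.pairs:
        d1 = (candidates[c1].to_numpy() + 1.0)
        d2 = (candidates[c2].to_numpy() + 1.0)
        if length_normalize:
            d1 = d1 / matrix.chromosome_lengths[c1]
            d2 = d2 / matrix.chromosome_lengths[c2]
        fold = d1 / d2
        pair_ok = (fold >= min_fold) | (fold <= 1.0 / min_fold)
        keep &= pair_ok
        favored[(c1, c2)] = np.where(fold >= 1.0, c1, c2)
        folds[(c1, c2)] = np.where(fold >= 1.0, fold, 1.0 / fold)

    idx = candidates.index[keep]
    data = {}
    first_pair = homeolog_map.pairs[0]
    anchor = min(first_pair)
    prov = np.where(
        np.isin(favored[first_pair][keep], [anchor]), "A", "B"
    )
    data["label"] = prov
    data["consistency"] = np.full(keep.sum(), np.nan)
    data["total"] = total.loc[idx].to_numpy()
    for pair in homeolog_map.pairs:
        tag = f"{pair[0]}|{pair[1]}"
        data[f"favored_{tag}"] = favored[pair][keep]
        data[f"fold_{tag}"] = folds[pair][keep]
    table = pd.DataFrame(data, index=[matrix.kmer(c) for c in idx])
    table.index.name = "kmer"
    return DiagnosticKmerSet(matrix.k, table, min_total, min_fold)


def _empty_table(homeolog_map: HomeologMap) -> pd.DataFrame:
    cols = ["label", "consistency", "total"]
    for c1, c2 in homeolog_map.pairs:
        cols += [f"favored_{c1}|{c2}", f"fold_{c1}|{c2}"]
    return pd.DataFrame(columns=cols)


def cluster_chromosomes(
    matrix: KmerCountMatrix,
    kmer_set: DiagnosticKmerSet,
    homeolog_map: HomeologMap | None = None,
) -> SubgenomePartition:
    """Bipartition chromosomes by clustering diagnostic-k-mer profiles.

    Chromosomes are clustered on length-normalized diagnostic-k-mer counts
    (correlation distance, average linkage) and cut into two clusters. The
    cluster containing the lexicographically smallest chromosome name is
    labelled "A" — an arbitrary but deterministic orientation that callers
    can re-anchor on real data. When a homeolog map is given, the partition
    is checked for pair integrity (one A and one B member per pair) and
    flagged if violated.
    """
    if len(kmer_set) < 2:
        raise InputError("need at least 2 diagnostic k-mers to cluster")
    codes = [seqs.kmer_to_code(km) for km in kmer_set.table.index]
    chroms = matrix.chromosomes
    profile = matrix.counts.loc[codes, chroms].to_numpy(dtype=float).T
    lengths = np.array([matrix.chromosome_lengths[c] for c in chroms], dtype=float)
    profile = profile / lengths[:, None] * 1e6  # counts per Mb

    if len(chroms) < 2:
        raise InputError("need at least 2 chromosomes")
    dist = pdist(profile, metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)
    linkage = sch.linkage(dist, method="average")
    labels = sch.fcluster(linkage, t=2, criterion="maxclust")

    anchor = min(chroms)
    a_cluster = labels[chroms.index(anchor)]
    assignment = {c: ("A" if lab == a_cluster else "B") for c, lab in zip(chroms, labels)}

    score = _silhouette(squareform(dist), labels)
    consistent = True
    if homeolog_map is not None:
        for c1, c2 in homeolog_map.pairs:
            if assignment.get(c1) == assignment.get(c2):
                consistent = False
    return SubgenomePartition(assignment=assignment, linkage=linkage, score=score,
                              consistent=consistent)


def _silhouette(dmat: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    if n < 3 or len(set(labels)) < 2:
        return float("nan")
    s = []
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        if not same.any():
            s.append(0.0)
            continue
        a = dmat[i, same].mean()
        b = dmat[i, ~same & (np.arange(n) != i)].mean()
        s.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(s))


def consistency_filter(
    kmer_set: DiagnosticKmerSet,
    partition: SubgenomePartition,
    homeolog_map: HomeologMap,
    max_conflicts: int = 0,
) -> DiagnosticKmerSet:
    """Drop k-mers whose per-pair enrichment conflicts with the partition.

    For each k-mer the favored member of every pair is mapped to its
    subgenome; k-mers disagreeing with their majority subgenome on more than
    ``max_conflicts`` pairs are removed, and labels/consistency scores are
    recomputed from the partition.
    """
    table = kmer_set.table
    if table.empty:
        raise DegenerateDataError("diagnostic set is empty; relax thresholds")
    votes = np.zeros((len(table), 2), dtype=int)  # columns: A, B
    for c1, c2 in homeolog_map.pairs:
        fav = table[f"favored_{c1}|{c2}"].to_numpy()
        sub = np.array([partition.assignment[c] for c in fav])
        votes[:, 0] += sub == "A"
        votes[:, 1] += sub == "B"
    majority = np.where(votes[:, 0] >= votes[:, 1], "A", "B")
    conflicts = votes.min(axis=1)
    n_pairs = votes.sum(axis=1)
    keep = conflicts <= max_conflicts
    if not keep.any():
        raise DegenerateDataError(
            "all diagnostic k-mers conflict with the partition; "
            "raise max_conflicts or lower min_fold/min_total"
        )
    out = table.loc[keep].copy()
    out["label"] = majority[keep]
    out["consistency"] = 1.0 - conflicts[keep] / n_pairs[keep]
    return DiagnosticKmerSet(kmer_set.k, out, kmer_set.min_total, kmer_set.min_fold)


def density_track(
    chromosome_name: str,
    codes: np.ndarray,
    kmer_set: DiagnosticKmerSet,
    window_size: int,
) -> pd.DataFrame:
    """Per-window counts of A- and B-labelled diagnostic k-mer occurrences.

    Windows are non-overlapping, the last truncated; an occurrence is binned
    by its start coordinate. Output columns: chromosome, start, end, n_A,
    n_B (BED4-compatible with ``n_A|n_B`` as the name field).
    """
    if window_size < kmer_set.k:
        raise InputError("window_size must be >= k")
    L = len(codes)
    positions, canon = seqs.rolling_canonical_codes(codes, kmer_set.k)
    label_of = {seqs.kmer_to_code(km): lab for km, lab in kmer_set.table["label"].items()}
    n_windows = max(1, -(-L // window_size))
    nA = np.zeros(n_windows, dtype=np.int64)
    nB = np.zeros(n_windows, dtype=np.int64)
    if canon.size and label_of:
        keys = np.fromiter(label_of.keys(), dtype=np.uint64)
        is_a = np.fromiter((label_of[int(c)] == "A" for c in keys), dtype=bool)
        order = np.argsort(keys)
        keys, is_a = keys[order], is_a[order]
        loc = np.searchsorted(keys, canon)
        loc_clip = np.clip(loc, 0, len(keys) - 1)
        hit = keys[loc_clip] == canon
        wins = positions[hit] // window_size
        hit_a = is_a[loc_clip[hit]]
        np.add.at(nA, wins[hit_a], 1)
        np.add.at(nB, wins[~hit_a], 1)
    starts = np.arange(n_windows) * window_size
    ends = np.minimum(starts + window_size, L)
    return pd.DataFrame(
        {
            "chromosome": chromosome_name,
            "start": starts,
            "end": ends,
            "n_A": nA,
            "n_B": nB,
        }
    )


def density_tracks(genome: Genome, kmer_set: DiagnosticKmerSet, window_size: int) -> pd.DataFrame:
    """Concatenated :func:`density_track` over all chromosomes."""
    return pd.concat(
        [density_track(name, codes, kmer_set, window_size) for name, codes in genome.items()],
        ignore_index=True,
    )


def write_track_bed(track: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.start}\t{row.end}\t{row.n_A}|{row.n_B}\n")


def read_track_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name = line.split("\t")
            na, nb = name.strip().split("|")
            rows.append((chrom, int(start), int(end), int(na), int(nb)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "n_A", "n_B"])
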