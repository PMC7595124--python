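"""Ready-made synthetic study designs.

Each preset wires the low-level generators in :mod:`allokit.synthetic` into
a complete dataset at desk scale, with the planted ground truth attached.
The defaults mirror the biological scenario the toolkit targets: two
progenitors separated ~7.2 My accumulating lineage-specific LTR bursts,
hybridization with a reciprocal distal exchange, a weak (median 1.04) B-ward
expression bias, and triploid interspecific hybrids with a genome-wide 2:1
ancestry dosage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .kmers import HomeologMap
from .synthetic import ExchangeSpec, ProgenitorSpec, SyntheticTruth, TEBurstSpec

DEFAULT_RATE = 2.1e-8  # substitutions/site/year
DEFAULT_DIVERGENCE_MY = 7.2


@dataclass
class AllotetraploidDataset:
    genome: dict[str, np.ndarray]
    truth: SyntheticTruth
    homeolog_map: HomeologMap
    rate: float
    ltr_length: int
    families: dict[str, TEBurstSpec] = field(default_factory=dict)


def _random_consensus(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _element_kmers(consensus: str, ltr_length: int, k: int = 13) -> set[str]:
    from . import seqs

    full = consensus + consensus[:ltr_length]
    out = set()
    for i in range(len(full) - k + 1):
        km = full[i:i + k]
        rc = seqs.decode(seqs.revcomp(seqs.encode(km)))
        out.add(min(km, rc))
    return out


def _disjoint_consensus(rng, length: int, ltr_length: int,
                        taken: set[str]) -> tuple[str, set[str]]:
    """Draw a consensus whose element shares no canonical 13-mer with
    previously drawn families.

    Two independently drawn ~1 kb consensi share an exact 13-mer with
    probability ~1.5%; such chance homology would make a "subgenome
    specific" family partially shared and corrupt the planted truth, so
    offending draws are rejected.
    """
    while True:
        s = _random_consensus(rng, length)
        kms = _element_kmers(s, ltr_length)
        if kms.isdisjoint(taken):
            return s, kms


def allotetraploid(
    seed: int = 0,
    n_pairs: int = 4,
    chromosome_length: int = 500_000,
    rate: float = DEFAULT_RATE,
    divergence_my: float = DEFAULT_DIVERGENCE_MY,
    family_copies: int = 200,
    shared_copies: int = 200,
    element_internal: int = 700,
    ltr_length: int = 300,
    specific_age_my: float = 4.0,
    shared_age_my: float = 2.5,
    exchanges: list[ExchangeSpec] | None = None,
) -> AllotetraploidDataset:
    """Synthetic allotetraploid with planted subgenome-specific TE bursts.

    Builds a common ancestor (``n_pairs`` chromosomes), diverges the A and B
    progenitors for ``divergence_my`` each, plants one A-specific and one
    B-specific LTR family (``family_copies`` copies, age ``specific_age_my``)
    plus a shared family split over both lineages (post-hybridization-like:
    present genome-wide), then hybridizes with the requested exchanges
    (default: one reciprocal distal exchange at 20% of length on pair 0).
    """
    if exchanges is None:
        exchanges = [ExchangeSpec(pair_index=0, breakpoint_fraction=0.2)]
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=12)
    spec = ProgenitorSpec(
        n_chromosomes=n_pairs,
        chromosome_length=chromosome_length,
        divergence_time=divergence_my,
        substitution_rate=rate,
        seed=int(sub[0]),
    )
    ancestor = synthetic.simulate_ancestor(spec)
    years = divergence_my * 1e6
    genome_a = synthetic.diverge(ancestor, rate, years, int(sub[1]))
    genome_b = synthetic.diverge(ancestor, rate, years, int(sub[2]))

    taken: set[str] = set()
    cons_a, kms = _disjoint_consensus(rng, ltr_length + element_internal,
                                      ltr_length, taken)
    taken |= kms
    cons_b, kms = _disjoint_consensus(rng, ltr_length + element_internal,
                                      ltr_length, taken)
    taken |= kms
    shared_consensus, _ = _disjoint_consensus(
        rng, ltr_length + element_internal, ltr_length, taken)
    fam_a = TEBurstSpec(
        family_id="famA", consensus=cons_a,
        n_copies=family_copies, burst_age=specific_age_my, target="A",
        ltr_length=ltr_length, seed=int(sub[3]),
    )
    fam_b = TEBurstSpec(
        family_id="famB", consensus=cons_b,
        n_copies=family_copies, burst_age=specific_age_my, target="B",
        ltr_length=ltr_length, seed=int(sub[4]),
    )
    shared_a = TEBurstSpec(
        family_id="famShared", consensus=shared_consensus,
        n_copies=shared_copies // 2, burst_age=shared_age_my, target="both",
        ltr_length=ltr_length, seed=int(sub[5]),
    )
    shared_b = TEBurstSpec(
        family_id="famShared", consensus=shared_consensus,
        n_copies=shared_copies - shared_copies // 2, burst_age=shared_age_my,
        target="both", ltr_length=ltr_length, seed=int(sub[6]),
    )
    genome_a, reg_a = synthetic.plant_te_burst(genome_a, fam_a, rate)
    genome_b, reg_b = synthetic.plant_te_burst(genome_b, fam_b, rate)
    genome_a, reg_a = synthetic.plant_te_burst(genome_a, shared_a, rate, registry=reg_a)
    genome_b, reg_b = synthetic.plant_te_burst(genome_b, shared_b, rate, registry=reg_b)

    genome, truth = synthetic.hybridize(
        genome_a, genome_b, exchanges, registry=reg_a, registry_B=reg_b
    )
    truth.seeds = {"master": seed}
    pairs = [
        (f"chr{2 * i + 1:02d}", f"chr{2 * i + 2:02d}") for i in range(n_pairs)
    ]
    return AllotetraploidDataset(
        genome=genome,
        truth=truth,
        homeolog_map=HomeologMap(pairs=pairs),
        rate=rate,
        ltr_length=ltr_length,
        families={"famA": fam_a, "famB": fam_b, "famShared": shared_a},
    )


def ltr_pairs_from_registry(
    genome: dict[str, np.ndarray], registry: list[dict], ltr_length: int,
    family: str | None = None,
) -> list[tuple[str, str, str]]:
    """Extract the two terminal repeats of every planted LTR element copy."""
    from . import seqs

    out = []
    for i, e in enumerate(registry):
        if family is not None and e["family"] != family:
            continue
        codes = genome[e["chromosome"]][e["start"] : e["end"]]
        if len(codes) < 2 * ltr_length:
            continue  # copy truncated by an exchange breakpoint
        out.append(
            (
                f"{e['family']}_{i}",
                seqs.decode(codes[:ltr_length]),
                seqs.decode(codes[-ltr_length:]),
            )
        )
    return out


def expression(
    seed: int = 0,
    n_pairs: int = 5000,
    median_bias: float = 1.04,
    dispersion: float = 0.01,
    n_samples: int = 4,
    silent_fraction: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """Homeolog count matrix with a planted median B/A bias (default 1.04)."""
    return synthetic.simulate_homeolog_counts(
        n_pairs=n_pairs, median_bias=median_bias, dispersion=dispersion,
        n_samples=n_samples, silent_fraction=silent_fraction, seed=seed,
    )


@dataclass
class AdmixtureDataset:
    observation: pd.DataFrame
    truth: dict
    marker_positions: dict[str, np.ndarray]
    chromosome_lengths: dict[str, int]
    window_size: int
    ploidy: int


def admixture(
    seed: int = 0,
    ploidy: int = 3,
    n_chromosomes: int = 4,
    chromosome_length: int = 5_000_000,
    markers_per_chromosome: int = 5000,
    deviant_fraction: float = 0.05,
    depth_mean: float = 10.0,
    error_rate: float = 0.01,
    markers_per_window: int = 50,
) -> AdmixtureDataset:
    """Admixed accession with a dominant dosage and planted deviant blocks.

    The dominant dosage is (ploidy-1, 1) sp1:sp2 — e.g. 2:1 for a triploid
    interspecific hybrid; each chromosome carries one deviant block of the
    complementary dosage covering ``deviant_fraction`` of its length at a
    random (non-window-aligned) position.
    """
    rng = np.random.default_rng(seed)
    dominant = (ploidy - 1, 1)
    deviant = (1, ploidy - 1)
    marker_positions = {}
    blocks = []
    spacing = chromosome_length // markers_per_chromosome
    for i in range(n_chromosomes):
        chrom = f"chr{i + 1:02d}"
        pos = np.sort(
            rng.choice(chromosome_length, size=markers_per_chromosome, replace=False)
        )
        marker_positions[chrom] = pos
        blen = int(deviant_fraction * chromosome_length)
        bstart = int(rng.integers(spacing, chromosome_length - blen - spacing))
        blocks += [
            (chrom, 0, bstart, dominant),
            (chrom, bstart, bstart + blen, deviant),
            (chrom, bstart + blen, chromosome_length, dominant),
        ]
    obs, truth = synthetic.simulate_admixed_accession(
        ploidy=ploidy,
        marker_positions=marker_positions,
        ancestry_blocks=blocks,
        depth_mean=depth_mean,
        error_rate=error_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    window_size = spacing * markers_per_window
    return AdmixtureDataset(
        observation=obs,
        truth=truth,
        marker_positions=marker_positions,
        chromosome_lengths={c: chromosome_length for c in marker_positions},
        window_size=window_size,
        ploidy=ploidy,
    )
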