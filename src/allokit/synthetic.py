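"""Synthetic allotetraploid data with planted ground truth.

Every downstream stage of the toolkit (subgenome phasing, exchange calling,
dating, expression bias, ancestry painting) is exercised on data produced
here, where the answer is known by construction. The generator emulates:

* two progenitor genomes diverged from a common ancestor under a
  Jukes-Cantor substitution process, each carrying lineage-specific
  transposable-element bursts;
* their merger into a tetraploid, optionally with reciprocal distal
  exchanges between homeologous chromosomes;
* a shared (post-hybridization) element burst spread over both subgenomes;
* homeolog expression count matrices with a planted median B/A bias;
* LTR element pairs mutated for a known age at a known rate;
* admixed accessions of ploidy 2/3/4 with planted ancestry blocks observed
  through Poisson read depth and binomial allele sampling.

All coordinates are 0-based, half-open. Every dataset is accompanied by a
:class:`SyntheticTruth` recording the planted structure, and identical specs
with identical seeds reproduce byte-identical output.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import seqs
from .errors import InputError, SaturationError

Genome = dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# specs and truth containers


@dataclass
class ProgenitorSpec:
    """Parameters of the shared ancestor and its two descendant lineages.

    ``divergence_time`` is the time (My) since the A and B progenitors split
    from their common ancestor; each lineage accumulates substitutions for
    that long at ``substitution_rate`` (substitutions/site/year).
    """

    n_chromosomes: int = 4
    chromosome_length: int = 500_000
    gc_content: float = 0.46
    divergence_time: float = 7.2
    substitution_rate: float = 2.1e-8
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise InputError("n_chromosomes must be >= 1")
        if self.chromosome_length <= 0:
            raise InputError("chromosome_length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise InputError("gc_content must be in [0, 1]")
        if self.divergence_time <= 0:
            raise InputError("divergence_time must be positive")


@dataclass
class TEBurstSpec:
    """A transposable-element amplification burst.

    ``target`` selects where copies land: ``"A"``/``"B"`` for a
    progenitor-specific burst (must predate hybridization to be diagnostic)
    or ``"both"`` for post-hybridization activity spread over the whole
    tetraploid. For LTR retrotransposon families, ``ltr_length`` marks the
    leading ``ltr_length`` bp of the consensus as the long terminal repeat;
    each inserted copy then carries two independently mutated LTRs whose
    mutual divergence clocks the copy's age (expected p-distance corresponds
    to ``2 * rate * burst_age``).
    """

    family_id: str
    consensus: str
    n_copies: int
    burst_age: float  # My
    target: str = "both"
    ltr_length: int = 0
    seed: int = 0

    def __post_init__(self):
        if not self.consensus:
            raise InputError("consensus must be non-empty")
        if self.target not in ("A", "B", "both"):
            raise InputError("target must be 'A', 'B' or 'both'")
        if self.n_copies < 0:
            raise InputError("n_copies must be >= 0")
        if not 0 <= self.ltr_length <= len(self.consensus):
            raise InputError("ltr_length must fit inside the consensus")


@dataclass
class ExchangeSpec:
    """A homeologous exchange of distal chromosome segments.

    ``breakpoint_fraction`` is measured from the distal (high-coordinate)
    end and must be strictly inside (0, 0.5) so the exchange stays distal.
    Reciprocal exchanges swap equal-length segments, conserving dosage;
    non-reciprocal ones copy one partner's segment over the other's.
    """

    pair_index: int
    breakpoint_fraction: float
    reciprocal: bool = True

    def __post_init__(self):
        if not 0.0 < self.breakpoint_fraction < 0.5:
            raise InputError("breakpoint_fraction must be in (0, 0.5)")


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every synthetic dataset."""

    subgenome_of_chromosome: dict[str, str] = field(default_factory=dict)
    # (chromosome, start, end, donor_subgenome)
    exchange_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    # dicts: family, chromosome, start, end, age
    te_copy_registry: list[dict] = field(default_factory=list)
    planted_bias: float | None = None
    # accession -> list of (chromosome, start, end, (dosage_sp1, dosage_sp2))
    ancestry_blocks: dict[str, list] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonable)

    def exchange_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, donor in self.exchange_intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{donor}\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(type(x))


# ---------------------------------------------------------------------------
# genome-level operations


def simulate_ancestor(spec: ProgenitorSpec) -> Genome:
    """Draw i.i.d. chromosomes at the requested GC content."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1:02d}": rng.choice(4, size=spec.chromosome_length, p=p).astype(np.uint8)
        for i in range(spec.n_chromosomes)
    }


def diverge(genome: Genome, rate: float, time_years: float, seed: int) -> Genome:
    """Mutate a genome under Jukes-Cantor for ``time_years`` at ``rate``.

    Each site independently changes with probability
    ``(3/4) * (1 - exp(-(4/3) * rate * time))`` to one of the other three
    bases uniformly — the exact JC transition kernel, so observed p-distance
    has that closed-form expectation.
    """
    rt = rate * time_years
    if rt < 0:
        raise InputError("rate * time must be non-negative")
    if rt >= 0.7:
        raise SaturationError(f"rate*time = {rt:.3g} saturates the JC model (limit 0.7)")
    p_diff = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * rt))
    rng = np.random.default_rng(seed)
    out: Genome = {}
    for name, codes in genome.items():
        new = codes.copy()
        hit = np.nonzero((rng.random(len(codes)) < p_diff) & (codes < 4))[0]
        if hit.size:
            new[hit] = (new[hit] + rng.integers(1, 4, size=hit.size)) % 4
        out[name] = new
    return out


def _mutate(codes: np.ndarray, p_diff: float, rng) -> np.ndarray:
    new = codes.copy()
    hit = np.nonzero((rng.random(len(codes)) < p_diff) & (codes < 4))[0]
    if hit.size:
        new[hit] = (new[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return new


def _jc_pdiff(rate: float, age_my: float) -> float:
    rt = rate * age_my * 1e6
    if rt >= 0.7:
        raise SaturationError(f"rate*age = {rt:.3g} saturates the JC model")
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * rt))


def plant_te_burst(
    genome: Genome,
    spec: TEBurstSpec,
    rate: float,
    registry: list[dict] | None = None,
    chromosomes: list[str] | None = None,
    allow_nesting: bool = False,
) -> tuple[Genome, list[dict]]:
    """Insert mutated copies of a TE family at random positions.

    Each copy is independently mutated for ``burst_age`` My at ``rate``
    before insertion; LTR families additionally get a second, independently
    mutated terminal repeat appended, so the two LTRs of one copy diverge
    with expectation ``2 * rate * age``. Insertion points falling inside a
    previously planted copy are re-drawn unless ``allow_nesting``.

    Returns the modified genome and the (extended) registry; registry
    entries are dicts with keys family/chromosome/start/end/age and final
    (post-insertion) coordinates. Pre-existing registry coordinates are
    shifted to stay correct.
    """
    registry = list(registry) if registry else []
    if chromosomes is None:
        chromosomes = list(genome.keys())
    for c in chromosomes:
        if c not in genome:
            raise InputError(f"target chromosome {c!r} not in genome")
    out = {k: v for k, v in genome.items()}
    if spec.n_copies == 0:
        return out, registry
    rng = np.random.default_rng(spec.seed)
    consensus = seqs.encode(spec.consensus)
    p_diff = _jc_pdiff(rate, spec.burst_age)
    # choose a chromosome for each copy, then process per chromosome
    chrom_choice = rng.choice(len(chromosomes), size=spec.n_copies)
    for ci, chrom in enumerate(chromosomes):
        n_here = int(np.sum(chrom_choice == ci))
        if n_here == 0:
            continue
        existing = [(e["start"], e["end"]) for e in registry if e["chromosome"] == chrom]
        L = len(out[chrom])
        positions: list[int] = []
        for _ in range(n_here):
            for _attempt in range(1000):
                pos = int(rng.integers(0, L + 1))
                if pos in positions:
                    continue
                if not allow_nesting and any(s < pos < e for s, e in existing):
                    continue
                break
            else:  # pragma: no cover - pathological density
                raise InputError(f"could not place TE copy on {chrom}: too crowded")
            positions.append(pos)
        order = np.argsort(positions, kind="stable")
        elements = []
        for _ in range(n_here):
            elem = _mutate(consensus, p_diff, rng)
            if spec.ltr_length > 0:
                ltr2 = _mutate(consensus[: spec.ltr_length], p_diff, rng)
                elem = np.concatenate([elem, ltr2])
            elements.append(elem)
        sorted_pos = [positions[i] for i in order]
        sorted_elems = [elements[i] for i in order]
        # splice all insertions in one pass
        pieces, prev, shift = [], 0, 0
        new_entries = []
        for pos, elem in zip(sorted_pos, sorted_elems):
            pieces.append(out[chrom][prev:pos])
            pieces.append(elem)
            start = pos + shift
            new_entries.append(
                {
                    "family": spec.family_id,
                    "chromosome": chrom,
                    "start": start,
                    "end": start + len(elem),
                    "age": spec.burst_age,
                }
            )
            shift += len(elem)
            prev = pos
        pieces.append(out[chrom][prev:])
        out[chrom] = np.concatenate(pieces)
        # shift pre-existing entries downstream of each insertion
        for e in registry:
            if e["chromosome"] != chrom:
                continue
            delta = sum(
                len(el) for p, el in zip(sorted_pos, sorted_elems) if p <= e["start"]
            )
            e["start"] += delta
            e["end"] += delta
        registry.extend(new_entries)
    return out, registry


def hybridize(
    genome_A: Genome,
    genome_B: Genome,
    exchanges: list[ExchangeSpec] | None = None,
    registry: list[dict] | None = None,
    registry_B: list[dict] | None = None,
) -> tuple[Genome, SyntheticTruth]:
    """Merge two progenitor genomes into a tetraploid and apply exchanges.

    Progenitor chromosomes are paired by index; pair *i* becomes
    (``chr{2i+1}``, ``chr{2i+2}``) with the odd member from A and the even
    member from B. Reciprocal exchanges swap equal-length distal segments
    (dosage-conserving); TE registry entries inside a swapped segment move
    with it. Registries may be passed either as a single combined list
    (chromosome names matching the progenitor genomes, assumed distinct
    between A and B inputs with identical naming — pass ``registry`` for A
    and ``registry_B`` for B).
    """
    if len(genome_A) != len(genome_B):
        raise InputError("progenitor genomes must have equal chromosome counts")
    exchanges = exchanges or []
    truth = SyntheticTruth()
    tetra: Genome = {}
    names_A = list(genome_A.keys())
    names_B = list(genome_B.keys())
    rename: dict[tuple[str, str], str] = {}
    for i, (na, nb) in enumerate(zip(names_A, names_B)):
        new_a, new_b = f"chr{2 * i + 1:02d}", f"chr{2 * i + 2:02d}"
        rename[("A", na)] = new_a
        rename[("B", nb)] = new_b
        tetra[new_a] = genome_A[na].copy()
        tetra[new_b] = genome_B[nb].copy()
        truth.subgenome_of_chromosome[new_a] = "A"
        truth.subgenome_of_chromosome[new_b] = "B"
    tetra = dict(sorted(tetra.items()))

    combined: list[dict] = []
    for sub, reg in (("A", registry), ("B", registry_B)):
        for e in reg or []:
            e2 = dict(e)
            e2["chromosome"] = rename[(sub, e["chromosome"])]
            combined.append(e2)

    for ex in exchanges:
        if not 0 <= ex.pair_index < len(names_A):
            raise InputError(f"pair_index {ex.pair_index} out of range")
        ca = f"chr{2 * ex.pair_index + 1:02d}"
        cb = f"chr{2 * ex.pair_index + 2:02d}"
        La, Lb = len(tetra[ca]), len(tetra[cb])
        seg = int(round(ex.breakpoint_fraction * min(La, Lb)))
        if seg == 0:
            continue
        tail_a, tail_b = tetra[ca][La - seg :].copy(), tetra[cb][Lb - seg :].copy()
        if ex.reciprocal:
            tetra[ca] = np.concatenate([tetra[ca][: La - seg], tail_b])
            tetra[cb] = np.concatenate([tetra[cb][: Lb - seg], tail_a])
            truth.exchange_intervals.append((ca, La - seg, La, "B"))
            truth.exchange_intervals.append((cb, Lb - seg, Lb, "A"))
        else:
            tetra[ca] = np.concatenate([tetra[ca][: La - seg], tail_b])
            truth.exchange_intervals.append((ca, La - seg, len(tetra[ca]), "B"))
        # registry entries travel with the swapped segments (by midpoint)
        cut_a, cut_b = La - seg, Lb - seg

        def _in_tail(e, chrom, cut):
            return e["chromosome"] == chrom and (e["start"] + e["end"]) / 2 >= cut

        tail_entries_a = [e for e in combined if _in_tail(e, ca, cut_a)]
        tail_entries_b = [e for e in combined if _in_tail(e, cb, cut_b)]
        if ex.reciprocal:
            for e in tail_entries_a:
                e["chromosome"] = cb
                e["start"] += cut_b - cut_a
                e["end"] += cut_b - cut_a
            for e in tail_entries_b:
                e["chromosome"] = ca
                e["start"] += cut_a - cut_b
                e["end"] += cut_a - cut_b
        else:
            for e in tail_entries_a:
                combined.remove(e)
            for e in tail_entries_b:
                dup = dict(e)
                dup["chromosome"] = ca
                dup["start"] += cut_a - cut_b
                dup["end"] += cut_a - cut_b
                combined.append(dup)
    truth.te_copy_registry = combined
    return tetra, truth


# ---------------------------------------------------------------------------
# expression counts


def simulate_homeolog_counts(
    n_pairs: int = 5000,
    median_bias: float = 1.04,
    dispersion: float = 0.01,
    n_samples: int = 4,
    library_sizes: list[float] | float = 5e6,
    silent_fraction: float = 0.3,
    ratio_sd: float = 0.1,
    baseline_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an expression count matrix for homeolog pairs.

    Per-pair baseline expression is lognormal; the B member is scaled by a
    per-pair lognormal ratio whose median equals ``median_bias``. Counts are
    gamma-Poisson with squared coefficient of variation ``dispersion``
    (``0`` gives pure Poisson); a ``silent_fraction`` of gene-sample cells
    is zeroed to mimic tissue-restricted expression.

    Returns a (2*n_pairs genes) x (n_samples) integer DataFrame with rows
    ``pair{i}_A`` / ``pair{i}_B``, and a truth dict with the per-pair ratios.
    """
    if median_bias <= 0:
        raise InputError("median_bias must be positive")
    if not 0 <= silent_fraction < 1:
        raise InputError("silent_fraction must be in [0, 1)")
    if n_pairs < 1:
        raise InputError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    if np.isscalar(library_sizes):
        library_sizes = [float(library_sizes)] * n_samples
    if len(library_sizes) != n_samples:
        raise InputError("library_sizes length must equal n_samples")
    base = rng.lognormal(mean=np.log(100.0), sigma=baseline_sd, size=n_pairs)
    ratio = median_bias * rng.lognormal(mean=0.0, sigma=ratio_sd, size=n_pairs)
    expr = np.empty(2 * n_pairs)
    expr[0::2] = base
    expr[1::2] = base * ratio
    frac = expr / expr.sum()
    counts = np.empty((2 * n_pairs, n_samples), dtype=np.int64)
    for j, lib in enumerate(library_sizes):
        mean = frac * lib
        if dispersion > 0:
            shape = 1.0 / dispersion
            mean = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)
        counts[:, j] = rng.poisson(mean)
    if silent_fraction > 0:
        silent = rng.random(counts.shape) < silent_fraction
        counts[silent] = 0
    index = [f"pair{i}_{m}" for i in range(n_pairs) for m in ("A", "B")]
    df = pd.DataFrame(counts, index=index, columns=[f"sample{j}" for j in range(n_samples)])
    truth = {"planted_bias": median_bias, "pair_ratio": ratio, "baseline": base, "seed": seed}
    return df, truth


# ---------------------------------------------------------------------------
# dated LTR / codon pairs


def simulate_ltr_pairs(
    n_pairs: int, length: int, age_my: float, rate: float, seed: int = 0
) -> list[tuple[str, str, str]]:
    """Pairs of terminal repeats from elements inserted ``age_my`` ago.

    Each pair derives from one random ancestral LTR, with both copies
    independently mutated for ``age_my`` at ``rate`` — mutual divergence has
    expectation ``2 * rate * age``. Returns (id, seq1, seq2) tuples.
    """
    if length < 1 or n_pairs < 1:
        raise InputError("length and n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    p_diff = _jc_pdiff(rate, age_my)
    out = []
    for i in range(n_pairs):
        anc = rng.integers(0, 4, size=length).astype(np.uint8)
        a = _mutate(anc, p_diff, rng)
        b = _mutate(anc, p_diff, rng)
        out.append((f"ltr{i}", seqs.decode(a), seqs.decode(b)))
    return out


_STOPS = {"TAA", "TAG", "TGA"}


def simulate_codon_pairs(
    n_pairs: int,
    n_codons: int,
    divergence_my: float,
    rate: float,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Codon-aligned homeolog CDS pairs diverged ``divergence_my`` ago.

    Both copies evolve neutrally from a random stop-free ancestor for
    ``divergence_my`` each, so synonymous-site divergence has expectation
    ``2 * rate * divergence_my``; codon draws that would create an internal
    stop are re-drawn.
    """
    rng = np.random.default_rng(seed)
    p_diff = _jc_pdiff(rate, divergence_my)
    sense = [c for c in ("".join(b) for b in itertools.product("ACGT", repeat=3)) if c not in _STOPS]
    sense_codes = np.array([seqs.encode(c) for c in sense])
    out = []
    for i in range(n_pairs):
        anc = sense_codes[rng.integers(0, len(sense_codes), size=n_codons)].reshape(-1)
        copies = []
        for _ in range(2):
            cur = _mutate(anc, p_diff, rng)
            cod = cur.reshape(-1, 3)
            for _round in range(100):
                bad = np.nonzero(
                    [seqs.decode(c) in _STOPS for c in cod]
                )[0]
                if not bad.size:
                    break
                for bi in bad:
                    cod[bi] = _mutate(anc.reshape(-1, 3)[bi], p_diff, rng)
            copies.append(seqs.decode(cod.reshape(-1)))
        out.append((f"pair{i}", copies[0], copies[1]))
    return out


# ---------------------------------------------------------------------------
# admixed accessions


def simulate_admixed_accession(
    ploidy: int,
    marker_positions: dict[str, np.ndarray],
    ancestry_blocks: list[tuple[str, int, int, tuple[int, int]]],
    depth_mean: float = 10.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Observe an admixed accession at ancestry-informative markers.

    ``ancestry_blocks`` is a list of (chromosome, start, end,
    (dosage_sp1, dosage_sp2)) tuples tiling each chromosome; every dosage
    vector must sum to the ploidy. At each marker the total read depth is
    Poisson(``depth_mean``) and species-1 reads are binomial with success
    probability ``(d1/ploidy)(1-e) + (1-d1/ploidy)e``.

    Returns a table (chromosome, pos, depth_sp1, depth_sp2) and a truth dict.
    """
    if ploidy not in (2, 3, 4):
        raise InputError("ploidy must be 2, 3 or 4")
    for chrom, start, end, dosage in ancestry_blocks:
        if len(dosage) != 2 or sum(dosage) != ploidy or min(dosage) < 0:
            raise InputError(f"dosage {dosage} on {chrom}:{start}-{end} must sum to ploidy {ploidy}")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, pos_arr in marker_positions.items():
        pos_arr = np.asarray(pos_arr)
        blocks = [b for b in ancestry_blocks if b[0] == chrom]
        for pos in pos_arr:
            dosage = None
            for _, start, end, d in blocks:
                if start <= pos < end:
                    dosage = d
                    break
            if dosage is None:
                raise InputError(f"marker {chrom}:{pos} not covered by any ancestry block")
            p = (dosage[0] / ploidy) * (1 - error_rate) + (1 - dosage[0] / ploidy) * error_rate
            depth = rng.poisson(depth_mean)
            n1 = rng.binomial(depth, p) if depth > 0 else 0
            rows.append((chrom, int(pos), int(n1), int(depth - n1)))
    df = pd.DataFrame(rows, columns=["chromosome", "pos", "depth_sp1", "depth_sp2"])
    truth = {"ploidy": ploidy, "ancestry_blocks": ancestry_blocks, "seed": seed}
    return df, truth
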