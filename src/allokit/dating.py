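"""Molecular dating of allopolyploidy events.

Three clocks are implemented:

* **LTR insertion ages** — the two long terminal repeats of a
  retrotransposon copy are identical at insertion and diverge thereafter,
  so a copy's age is ``d / (2r)`` where ``d`` is the Jukes-Cantor corrected
  LTR-LTR distance and ``r`` the substitution rate per site per year.
* **Rate calibration** — families active on both subgenomes and in an
  outgroup lineage give per-family rates ``d / (2 * split_time)`` against a
  known outgroup split (default 10 My); the working rate is the median
  across families.
* **Homeolog Ks** — synonymous divergence between homeologous coding genes
  (Nei-Gojobori 1986 pathway counting, Jukes-Cantor corrected) dates the
  progenitor split as the mode of the Ks distribution over ``2 * r_syn``.

All distances use pairwise deletion: only columns where both sequences
carry an unambiguous base (and, for Ks, whole codons) are compared.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .errors import InputError, SaturationError

_GAPLIKE = set("-.Nn")


@dataclass
class AlignedPair:
    """Two aligned DNA sequences compared over complete-case columns."""

    id: str
    seq1: str
    seq2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.seq2):
            raise InputError(f"{self.id}: aligned sequences differ in length")
        if len(self.seq1) == 0:
            raise InputError(f"{self.id}: empty alignment")

    def site_counts(self) -> tuple[int, int]:
        """(n_comparable_sites, n_differences) over unambiguous columns."""
        n_sites = n_diff = 0
        for a, b in zip(self.seq1.upper(), self.seq2.upper()):
            if a not in "ACGT" or b not in "ACGT":
                continue
            n_sites += 1
            n_diff += a != b
        return n_sites, n_diff


def p_distance(pair: AlignedPair) -> float:
    """Proportion of differing sites over comparable columns."""
    n_sites, n_diff = pair.site_counts()
    if n_sites == 0:
        raise InputError(f"{pair.id}: no comparable sites")
    return n_diff / n_sites


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); requires p < 0.75."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"p-distance {p} outside [0, 0.75); JC saturated")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ltr_insertion_age(distance: float, rate: float) -> float:
    """Insertion age in My from an LTR-LTR distance (subs/site)."""
    if rate <= 0:
        raise InputError("rate must be positive")
    if distance < 0:
        raise InputError("distance must be non-negative")
    return distance / (2.0 * rate) / 1e6


@dataclass
class RateCalibration:
    """Substitution rate calibrated against an outgroup split time."""

    family_rates: dict[str, float]
    split_time_my: float
    rate: float  # substitutions/site/year


def calibrate_rate(
    family_distances: dict[str, float], split_time_my: float = 10.0
) -> RateCalibration:
    """Median per-family substitution rate from outgroup distances.

    ``family_distances`` maps family id to its median JC distance to the
    outgroup lineage; each family's rate is ``d / (2 * split_time)`` and the
    calibration rate is the median across families.
    """
    if not family_distances:
        raise InputError("need at least one family distance")
    if split_time_my <= 0:
        raise InputError("split_time must be positive")
    rates = {
        fam: d / (2.0 * split_time_my * 1e6) for fam, d in family_distances.items()
    }
    return RateCalibration(
        family_rates=rates,
        split_time_my=split_time_my,
        rate=float(np.median(list(rates.values()))),
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori Ks/Ka

_STANDARD_CODE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    _STANDARD_CODE[_b1 + _b2 + _b3] = _AA[_i]


def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one codon.

    Each position contributes one site, split by the fraction of its three
    possible changes that are synonymous; changes to stop codons count as
    nonsynonymous (the original NG86 convention).
    """
    aa = _STANDARD_CODE[codon]
    syn = 0.0
    for i in range(3):
        n_syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            n_syn += _STANDARD_CODE[alt] == aa
        syn += n_syn / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences between two codons.

    All mutational pathways (orderings of the differing positions) are
    weighted equally; pathways passing through a stop codon are excluded
    unless every pathway does.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _STANDARD_CODE[nxt] == "*":
                blocked = True
            if _STANDARD_CODE[nxt] == _STANDARD_CODE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        results.append((syn, non, blocked))
    open_paths = [r for r in results if not r[2]]
    use = open_paths if open_paths else results
    sd = float(np.mean([r[0] for r in use]))
    nd = float(np.mean([r[1] for r in use]))
    return sd, nd


@dataclass
class CodonAlignedPair:
    """Codon-aligned coding sequences (length divisible by 3, no internal stops)."""

    id: str
    seq1: str
    seq2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.seq2):
            raise InputError(f"{self.id}: aligned CDS differ in length")
        if len(self.seq1) == 0 or len(self.seq1) % 3:
            raise InputError(f"{self.id}: CDS length must be a positive multiple of 3")
        for seq in (self.seq1, self.seq2):
            for i in range(0, len(seq) - 3, 3):
                cod = seq[i : i + 3].upper()
                if cod in ("TAA", "TAG", "TGA"):
                    raise InputError(f"{self.id}: internal stop codon at position {i}")

    def codons(self):
        """Comparable codon pairs (both codons unambiguous ACGT triplets)."""
        for i in range(0, len(self.seq1), 3):
            a = self.seq1[i : i + 3].upper()
            b = self.seq2[i : i + 3].upper()
            if set(a) <= set("ACGT") and set(b) <= set("ACGT"):
                yield a, b


@dataclass
class KsKaResult:
    id: str
    ks: float  # NaN when saturated
    ka: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated: bool = False


def ks_nei_gojobori(pair: CodonAlignedPair) -> KsKaResult:
    """Ks and Ka by Nei-Gojobori pathway counting, Jukes-Cantor corrected.

    Site counts are averaged between the two sequences; proportions >= 0.75
    cannot be corrected and are flagged saturated with the value missing.
    """
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for a, b in pair.codons():
        sa, na = _codon_sites(a)
        sb, nb = _codon_sites(b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_diffs(a, b)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise InputError(f"{pair.id}: no comparable codons")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    ks = float("nan") if ps >= 0.75 else jukes_cantor(ps)
    ka = float("nan") if pn >= 0.75 else jukes_cantor(pn)
    return KsKaResult(
        id=pair.id, ks=ks, ka=ka, syn_sites=S, nonsyn_sites=N,
        syn_diffs=Sd, nonsyn_diffs=Nd, saturated=saturated,
    )


# ---------------------------------------------------------------------------
# event dating from a Ks (or distance) distribution


@dataclass
class EventTime:
    time_my: float
    mode: float  # primary mode of the distance distribution
    modes: list[tuple[float, float]] = field(default_factory=list)  # (value, density)
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def _kde_modes(values: np.ndarray) -> list[tuple[float, float]]:
    kde = gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(max(0.0, lo - pad), hi + pad, 2048)
    dens = kde(grid)
    peaks = [
        (grid[i], dens[i])
        for i in range(1, len(grid) - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    peaks.sort(key=lambda t: -t[1])
    return peaks


def event_time_from_ks(
    values,
    rate_per_year: float,
    min_values: int = 20,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> EventTime:
    """Date an event as the Ks-distribution mode over ``2 * rate``.

    The mode is the highest peak of a Gaussian KDE (Silverman bandwidth);
    all local maxima are reported so multimodal (e.g. two-event) inputs are
    visible. A percentile bootstrap (``n_bootstrap`` resamples, seeded)
    gives a CI on the inferred time in My.
    """
    values = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(values) < min_values:
        raise InputError(f"need >= {min_values} values for a stable mode, got {len(values)}")
    if rate_per_year <= 0:
        raise InputError("rate must be positive")
    to_my = 1.0 / (2.0 * rate_per_year * 1e6)
    if np.ptp(values) == 0:
        t = values[0] * to_my
        return EventTime(time_my=t, mode=values[0], modes=[(values[0], float("inf"))],
                         ci_low=t, ci_high=t)
    peaks = _kde_modes(values)
    mode = peaks[0][0]
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        sample = rng.choice(values, size=len(values), replace=True)
        if np.ptp(sample) == 0:
            boots.append(sample[0])
            continue
        boots.append(_kde_modes(sample)[0][0])
    boots = np.array(boots) * to_my
    return EventTime(
        time_my=mode * to_my,
        mode=float(mode),
        modes=[(float(v), float(d)) for v, d in peaks],
        ci_low=float(np.percentile(boots, 2.5)),
        ci_high=float(np.percentile(boots, 97.5)),
    )
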