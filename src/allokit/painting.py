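"""Chromosome painting of admixed accessions by ancestry dosage.

Two interfertile species (here "sp1" and "sp2") that hybridize at multiple
ploidies can be distinguished at *ancestry-informative markers*: sites
fixed for different alleles in unadmixed diploid exemplars of each species,
outside repeat-masked regions. For an accession of ploidy m, each genomic
window is scored for the dosage g in {0..m} of species-1 chromosome sets:
the log-likelihood of g sums binomial terms over the window's markers with
success probability (g/m)(1-e) + (1-g/m)e for sequencing error e. An HMM
over the m+1 dosage states smooths the per-window calls into segments, and
a genome summary reports length-weighted ancestry fractions, the modal
dosage, and windows deviating from it (candidate introgressions or gene
conversions).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .errors import DegenerateDataError, InputError


@dataclass
class AncestryMarkerSet:
    """Fixed-difference markers between two species."""

    markers: pd.DataFrame  # chromosome, pos, allele_sp1, allele_sp2
    exemplars_sp1: list[str]
    exemplars_sp2: list[str]

    def __len__(self):
        return len(self.markers)

    def to_tsv(self, path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)


def discover_markers(
    genotypes: pd.DataFrame,
    species_of_exemplar: dict[str, str],
    mask: pd.DataFrame | None = None,
) -> AncestryMarkerSet:
    """Fixed differences between two species from diploid exemplars.

    ``genotypes`` has columns ``chromosome``, ``pos`` and one column per
    exemplar with diploid genotypes as two-character strings ("AA", "AG",
    "./." or "" for missing). A site is retained when every non-missing
    exemplar of species 1 is homozygous for one allele, every non-missing
    exemplar of species 2 is homozygous for a different allele, and at
    least one exemplar per species is non-missing. Sites inside ``mask``
    intervals (BED-style columns chromosome/start/end) are removed.
    """
    sp1 = [e for e, s in species_of_exemplar.items() if s == "sp1"]
    sp2 = [e for e, s in species_of_exemplar.items() if s == "sp2"]
    if not sp1 or not sp2:
        raise InputError("need exemplars for both species")
    for e in sp1 + sp2:
        if e not in genotypes.columns:
            raise InputError(f"exemplar column {e!r} missing from genotype table")

    def _fixed_allele(row, exemplars):
        allele = None
        n_obs = 0
        for e in exemplars:
            g = str(row[e]).upper().replace("/", "").replace("|", "")
            if g in ("", "..", "NN", "NAN", "NONE"):
                continue
            if len(g) != 2 or g[0] != g[1] or g[0] not in "ACGT":
                return None, -1  # heterozygous or unparseable: not fixed
            if allele is None:
                allele = g[0]
            elif g[0] != allele:
                return None, -1
            n_obs += 1
        return allele, n_obs

    rows = []
    for _, row in genotypes.iterrows():
        a1, n1 = _fixed_allele(row, sp1)
        a2, n2 = _fixed_allele(row, sp2)
        if n1 < 1 or n2 < 1 or a1 is None or a2 is None or a1 == a2:
            continue
        rows.append((row["chromosome"], int(row["pos"]), a1, a2))
    markers = pd.DataFrame(rows, columns=["chromosome", "pos", "allele_sp1", "allele_sp2"])
    if mask is not None and not markers.empty and not mask.empty:
        keep = np.ones(len(markers), dtype=bool)
        for m in mask.itertuples(index=False):
            keep &= ~(
                (markers["chromosome"] == m.chromosome)
                & (markers["pos"] >= m.start)
                & (markers["pos"] < m.end)
            ).to_numpy()
        markers = markers[keep].reset_index(drop=True)
    markers = markers.sort_values(["chromosome", "pos"]).reset_index(drop=True)
    return AncestryMarkerSet(markers=markers, exemplars_sp1=sp1, exemplars_sp2=sp2)


# ---------------------------------------------------------------------------


def window_dosage(
    observation: pd.DataFrame,
    ploidy: int,
    window_size: int,
    error_rate: float = 0.01,
    chromosome_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window ancestry-dosage likelihoods from allele depths.

    ``observation`` has columns chromosome, pos, depth_sp1, depth_sp2. For
    each window and dosage g in {0..ploidy}, the log-likelihood sums
    binomial terms over markers; windows with zero total depth (or no
    markers) are reported with ``missing=True``. Returns a table with one
    row per window: coordinates, logL_0..logL_m, ml_dosage (species-1
    copies), posterior of the ML dosage (flat prior), missing flag.
    """
    if ploidy < 1:
        raise InputError("ploidy must be >= 1")
    if not 0 <= error_rate < 0.5:
        raise InputError("error_rate must be in [0, 0.5)")
    gs = np.arange(ploidy + 1)
    ps = (gs / ploidy) * (1 - error_rate) + (1 - gs / ploidy) * error_rate
    rows = []
    for chrom, obs in observation.groupby("chromosome", sort=True):
        obs = obs.sort_values("pos")
        L = chromosome_lengths.get(chrom) if chromosome_lengths else int(obs["pos"].max()) + 1
        n_windows = max(1, -(-L // window_size))
        win = obs["pos"].to_numpy() // window_size
        d1 = obs["depth_sp1"].to_numpy(float)
        d2 = obs["depth_sp2"].to_numpy(float)
        for w in range(n_windows):
            sel = win == w
            start, end = w * window_size, min((w + 1) * window_size, L)
            tot = d1[sel] + d2[sel]
            covered = sel.any() and tot.sum() > 0
            row = {"chromosome": chrom, "start": start, "end": end, "missing": not covered}
            if covered:
                # xlogy keeps 0*log(0) = 0 so error_rate=0 stays well defined
                ll = np.array([
                    np.sum(xlogy(d1[sel], p) + xlogy(d2[sel], 1 - p)) for p in ps
                ])
            else:
                ll = np.zeros(ploidy + 1)
            for g in gs:
                row[f"logL_{g}"] = ll[g]
            post = np.exp(ll - ll.max())
            post /= post.sum()
            row["ml_dosage"] = int(np.argmax(ll)) if covered else -1
            row["posterior"] = float(post.max()) if covered else float("nan")
            rows.append(row)
    if not rows:
        raise DegenerateDataError("no windows could be scored")
    df = pd.DataFrame(rows)
    if df["missing"].all():
        raise DegenerateDataError("all windows have zero depth")
    return df


def smooth_dosage(
    windows: pd.DataFrame, ploidy: int, tau: float = 1e-3
) -> pd.DataFrame:
    """Viterbi smoothing of window dosage likelihoods into segments.

    The HMM has states g in {0..ploidy}; per boundary the state persists
    with probability 1 - tau and switches to each alternative with
    tau / ploidy. Missing windows emit a flat likelihood and are bridged by
    the flanking state. Returns segments (chromosome, start, end,
    dosage_sp1, dosage_sp2, mean_posterior, n_windows); dosage vectors
    always sum to the ploidy.
    """
    if not 0 < tau <= 0.5:
        raise InputError("tau must be in (0, 0.5]")
    n_states = ploidy + 1
    logT = np.full((n_states, n_states), np.log(tau / ploidy))
    np.fill_diagonal(logT, np.log(1 - tau))
    ll_cols = [f"logL_{g}" for g in range(n_states)]
    segments = []
    for chrom, win in windows.groupby("chromosome", sort=True):
        win = win.sort_values("start").reset_index(drop=True)
        logB = win[ll_cols].to_numpy(float)
        T = len(win)
        delta = np.zeros((T, n_states))
        back = np.zeros((T, n_states), dtype=int)
        delta[0] = logB[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logT
            best = np.argmax(cand, axis=0)
            for s in range(n_states):  # tie toward staying in the same state
                if cand[s, s] >= cand[best[s], s]:
                    best[s] = s
            back[t] = best
            delta[t] = cand[best, np.arange(n_states)] + logB[t]
        path = np.zeros(T, dtype=int)
        path[-1] = int(np.argmax(delta[-1]))
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        post = np.exp(logB - logB.max(axis=1, keepdims=True))
        post /= post.sum(axis=1, keepdims=True)
        start = 0
        for t in range(1, T + 1):
            if t == T or path[t] != path[start]:
                g = int(path[start])
                segments.append(
                    {
                        "chromosome": chrom,
                        "start": int(win["start"].iloc[start]),
                        "end": int(win["end"].iloc[t - 1]),
                        "dosage_sp1": g,
                        "dosage_sp2": ploidy - g,
                        "mean_posterior": float(post[start:t, g].mean()),
                        "n_windows": t - start,
                    }
                )
                start = t
    return pd.DataFrame(segments)


def genome_summary(segments: pd.DataFrame, ploidy: int) -> dict:
    """Length-weighted ancestry fractions, modal dosage and deviant windows."""
    if segments.empty:
        raise InputError("no segments")
    lengths = (segments["end"] - segments["start"]).to_numpy(float)
    d1 = segments["dosage_sp1"].to_numpy(float)
    total = lengths.sum()
    frac1 = float((lengths * d1 / ploidy).sum() / total)
    by_dosage = segments.assign(length=lengths).groupby("dosage_sp1")["length"].sum()
    modal = int(by_dosage.idxmax())
    deviants = segments[segments["dosage_sp1"] != modal]
    return {
        "fraction_sp1": frac1,
        "fraction_sp2": 1.0 - frac1,
        "modal_dosage": (modal, ploidy - modal),
        "deviant_fraction": float(
            (deviants["end"] - deviants["start"]).sum() / total
        ),
        "deviant_segments": deviants[["chromosome", "start", "end", "dosage_sp1", "dosage_sp2"]]
        .to_dict("records"),
    }


def dosage_from_genotype_fraction(fraction: float, ploidy: int) -> tuple[int, int]:
    """Convert a fractional genotype call to an integer dosage vector.

    Called genotypes for polyploids are often coded on a 0..1 scale (e.g.
    0, 0.33, 0.67, 1 for a triploid); the nearest multiple of 1/ploidy
    gives the species-1 copy number.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InputError("genotype fraction must be in [0, 1]")
    g = int(round(fraction * ploidy))
    return g, ploidy - g


def write_dosage_bed(segments: pd.DataFrame, path) -> None:
    """Segments as BED with name=dosage vector and score=posterior*1000."""
    with open(path, "w") as fh:
        for row in segments.itertuples(index=False):
            score = int(round(row.mean_posterior * 1000))
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t"
                f"{row.dosage_sp1}:{row.dosage_sp2}\t{score}\t+\n"
            )
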