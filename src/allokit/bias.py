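"""Subgenome bias in gene retention and homeolog expression.

Retention bias: against an outgroup representing the preduplication gene
set, a gene is *retained* on a subgenome when at least one co-ortholog
survives there; the A-vs-B retained/lost 2x2 table is tested with a
two-sided Fisher exact test (full hypergeometric enumeration).

Expression bias: homeolog expression is compared as counts per million
(cpm) after summing replicate libraries within a sample group. The median
B/A ratio is taken over pairs where *both* members exceed ``min_cpm``
(a silent member would make the ratio degenerate); X-fold bias counts
(X = 2, 5, 10) use pairs where at least one member passes, with the silent
member floored at a 0.5-cpm pseudocount. Pairs inside homeologous-exchange
regions can be stratified and re-oriented by *source* subgenome to ask
whether bias travels with the DNA or with its new location.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError


def cpm(counts: pd.DataFrame, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Counts-per-million after combining replicates within groups.

    ``groups`` maps each column of ``counts`` to a group name; replicate
    columns are summed before scaling each group to one million. With
    ``groups=None`` every column is its own group.
    """
    if (counts.to_numpy() < 0).any():
        raise InputError("counts must be non-negative")
    if groups is None:
        groups = {c: c for c in counts.columns}
    missing = set(counts.columns) - set(groups)
    if missing:
        raise InputError(f"columns without a group: {sorted(missing)}")
    combined = counts.T.groupby(pd.Series(groups)).sum().T
    totals = combined.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise InputError(f"group(s) with zero total counts: {list(zero.index)}")
    return combined / totals * 1e6


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the same margins
    whose point probability does not exceed the observed one (within 1e-7
    relative tolerance). The all-zero table returns 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise InputError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    return float(min(1.0, p))


@dataclass
class RetentionSummary:
    retained_A: int
    lost_A: int
    retained_B: int
    lost_B: int
    p_two_sided: float

    @property
    def fraction_A(self) -> float:
        return self.retained_A / (self.retained_A + self.lost_A)

    @property
    def fraction_B(self) -> float:
        return self.retained_B / (self.retained_B + self.lost_B)


def retention_fractions(table: pd.DataFrame) -> RetentionSummary:
    """Per-subgenome retention fractions with a two-sided exact test.

    ``table`` has one row per preduplication (outgroup) gene with columns
    ``genes_A`` and ``genes_B`` holding the co-ortholog lists (lists, or
    comma-separated strings, empty meaning lost on that subgenome).
    """
    if table.empty:
        raise InputError("ortholog table is empty")

    def _nonempty(v) -> bool:
        if isinstance(v, str):
            return bool(v.strip())
        if v is None or (np.isscalar(v) and pd.isna(v)):
            return False
        return len(v) > 0

    ret_a = table["genes_A"].map(_nonempty)
    ret_b = table["genes_B"].map(_nonempty)
    ra, la = int(ret_a.sum()), int((~ret_a).sum())
    rb, lb = int(ret_b.sum()), int((~ret_b).sum())
    p = fisher_exact_2x2(ra, la, rb, lb)
    return RetentionSummary(retained_A=ra, lost_A=la, retained_B=rb, lost_B=lb,
                            p_two_sided=p)


# ---------------------------------------------------------------------------
# expression bias


def _group_stats(cpm_a: np.ndarray, cpm_b: np.ndarray, min_cpm: float,
                 folds: tuple) -> dict:
    both = (cpm_a > min_cpm) & (cpm_b > min_cpm)
    either = (cpm_a > min_cpm) | (cpm_b > min_cpm)
    stats: dict = {
        "n_pairs_ratio": int(both.sum()),
        "n_pairs_fold": int(either.sum()),
        "median_ba_ratio": float(np.median(cpm_b[both] / cpm_a[both])) if both.any() else float("nan"),
    }
    # pseudocount path: floor the silent member at 0.5 cpm
    a = np.maximum(cpm_a[either], 0.5)
    b = np.maximum(cpm_b[either], 0.5)
    ratio = b / a
    fold_counts = {}
    for X in folds:
        nb = int((ratio >= X).sum())
        na = int((ratio <= 1.0 / X).sum())
        fold_counts[X] = {"B_favored": nb, "A_favored": na}
    stats["fold_counts"] = fold_counts
    two = folds[0] if folds else 2
    nb2 = fold_counts.get(two, {}).get("B_favored", 0)
    na2 = fold_counts.get(two, {}).get("A_favored", 0)
    # excess of B-favored pairs at the smallest fold, as a share of all
    # qualifying pairs (stable), plus the A-relative version for comparison
    # with "X% more pairs" phrasing (noisy when fold counts are small)
    n_fold = stats["n_pairs_fold"]
    stats["excess_b_pct"] = 100.0 * (nb2 - na2) / n_fold if n_fold else float("nan")
    stats["excess_b_vs_a_pct"] = 100.0 * (nb2 - na2) / na2 if na2 else float("inf")
    return stats


def pair_bias_stats(
    cpm_A: pd.DataFrame,
    cpm_B: pd.DataFrame,
    min_cpm: float = 0.5,
    folds: tuple = (2, 5, 10),
) -> dict:
    """Median B/A expression ratio and X-fold bias counts.

    ``cpm_A`` and ``cpm_B`` are aligned pair-by-group cpm matrices for the
    A and B member of each homeolog pair. Statistics are returned per group
    and pooled over all (pair, group) observations; ``excess_b_pct`` is the
    percent excess of B-favored over A-favored pairs at the smallest fold.
    """
    if cpm_A.shape != cpm_B.shape or list(cpm_A.columns) != list(cpm_B.columns):
        raise InputError("cpm_A and cpm_B must be aligned (same pairs, same groups)")
    if cpm_A.empty:
        raise InputError("no homeolog pairs")
    report: dict = {"per_group": {}, "min_cpm": min_cpm, "folds": list(folds)}
    for g in cpm_A.columns:
        report["per_group"][g] = _group_stats(
            cpm_A[g].to_numpy(float), cpm_B[g].to_numpy(float), min_cpm, folds
        )
    pooled_a = cpm_A.to_numpy(float).ravel()
    pooled_b = cpm_B.to_numpy(float).ravel()
    report["pooled"] = _group_stats(pooled_a, pooled_b, min_cpm, folds)
    medians = [s["median_ba_ratio"] for s in report["per_group"].values()
               if np.isfinite(s["median_ba_ratio"])]
    report["median_of_group_medians"] = float(np.median(medians)) if medians else float("nan")
    if report["pooled"]["n_pairs_ratio"] == 0:
        raise InputError(f"no pair passes min_cpm={min_cpm} in any group")
    return report


def exchanged_region_bias(
    cpm_A: pd.DataFrame,
    cpm_B: pd.DataFrame,
    exchanged: pd.Series,
    min_cpm: float = 0.5,
    folds: tuple = (2, 5, 10),
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Expression bias stratified by homeologous-exchange status.

    ``cpm_A``/``cpm_B`` are oriented by *current location* (the member now
    sitting on the A subgenome is in ``cpm_A``). ``exchanged`` is a boolean
    Series per pair. For exchanged pairs the members have swapped locations,
    so source-subgenome orientation flips the ratio: the stratified report
    gives each stratum's median B/A ratio in source orientation, the
    location-orientation median for comparison, and a bootstrap CI (seeded)
    on the source-orientation difference of stratum medians.
    """
    exchanged = exchanged.astype(bool)
    anc_idx = cpm_A.index[~exchanged.to_numpy()]
    exc_idx = cpm_A.index[exchanged.to_numpy()]
    out: dict = {"ancestral": None, "exchanged": None, "missing_strata": []}

    def _median_ratio(ai, flip: bool):
        a = cpm_A.loc[ai].to_numpy(float).ravel()
        b = cpm_B.loc[ai].to_numpy(float).ravel()
        ok = (a > min_cpm) & (b > min_cpm)
        if not ok.any():
            return float("nan"), np.empty(0)
        r = b[ok] / a[ok]
        if flip:
            r = 1.0 / r
        return float(np.median(r)), r

    for name, idx, flip in (("ancestral", anc_idx, False), ("exchanged", exc_idx, True)):
        if len(idx) == 0:
            out["missing_strata"].append(name)
            continue
        med_source, ratios = _median_ratio(idx, flip)
        med_location = float(np.median(1.0 / ratios)) if flip and ratios.size else med_source
        if not flip:
            med_location = med_source
        out[name] = {
            "n_pairs": int(len(idx)),
            "median_ba_source_orientation": med_source,
            "median_ba_location_orientation": med_location,
            "_ratios_source": ratios,
        }
    if out["ancestral"] and out["exchanged"]:
        ra = out["ancestral"].pop("_ratios_source")
        rx = out["exchanged"].pop("_ratios_source")
        rng = np.random.default_rng(seed)
        diffs = [
            np.median(rng.choice(rx, size=len(rx), replace=True))
            - np.median(rng.choice(ra, size=len(ra), replace=True))
            for _ in range(n_bootstrap)
        ]
        out["difference_of_medians_source"] = float(np.median(rx) - np.median(ra))
        out["difference_ci"] = [float(np.percentile(diffs, 2.5)),
                                float(np.percentile(diffs, 97.5))]
    else:
        for name in ("ancestral", "exchanged"):
            if out[name]:
                out[name].pop("_ratios_source", None)
    return out
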