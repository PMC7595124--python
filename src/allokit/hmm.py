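"""Homeologous-exchange calling with a two-state HMM.

Each chromosome is summarized as windowed counts of A- and B-diagnostic
k-mer occurrences. The hidden state of a window is its ancestry (A or B);
the emission is binomial on the A-count given the window total, which makes
inference invariant to window-to-window repeat-density fluctuations. Empty
windows are uninformative (likelihood 1 in both states) rather than
dropped, so coordinates are preserved. Viterbi segmentation followed by a
minimum-run smoothing yields ancestry segments; a segment whose state
differs from its chromosome's bulk subgenome assignment is an exchange
call, flagged reciprocal when the homeolog partner carries a complementary
opposite-state segment with >= 50% reciprocal coordinate overlap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import DegenerateDataError, InputError
from .kmers import HomeologMap, SubgenomePartition


@dataclass
class HMMParams:
    """Emission and transition parameters of the two-state ancestry HMM.

    ``p_a`` (``p_b``) is the probability that a diagnostic k-mer occurrence
    is A-labelled in a window of true state A (B); ``switch_prob`` is the
    per-boundary probability of changing state.
    """

    p_a: float
    p_b: float
    switch_prob: float = 1e-3
    start_probs: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        if not 0.0 < self.p_b < self.p_a < 1.0:
            raise InputError("need 0 < p_b < p_a < 1")
        if not 0.0 < self.switch_prob < 0.5:
            raise InputError("switch_prob must be in (0, 0.5)")
        if abs(sum(self.start_probs) - 1.0) > 1e-9:
            raise InputError("start_probs must sum to 1")


STATES = ("A", "B")


def _log_emissions(n_a: np.ndarray, n_b: np.ndarray, params: HMMParams) -> np.ndarray:
    """Log binomial emission likelihoods, shape (n_windows, 2).

    Windows with zero total emit likelihood 1 in both states.
    """
    n = n_a + n_b
    out = np.zeros((len(n), 2))
    nz = n > 0
    choose = gammaln(n[nz] + 1) - gammaln(n_a[nz] + 1) - gammaln(n_b[nz] + 1)
    for s, p in enumerate((params.p_a, params.p_b)):
        out[nz, s] = choose + n_a[nz] * np.log(p) + n_b[nz] * np.log(1 - p)
    return out


def estimate_emissions(
    tracks: pd.DataFrame,
    partition: SubgenomePartition,
    trim_fraction: float = 0.25,
    em: bool = False,
    max_iter: int = 50,
    tol: float = 1e-6,
    switch_prob: float = 1e-3,
    noise_floor: float = 0.05,
) -> HMMParams:
    """Estimate emission probabilities from bulk-assigned chromosomes.

    ``p_a`` is the pooled fraction of A-labelled occurrences over windows of
    A-assigned chromosomes after trimming ``trim_fraction`` of windows from
    each chromosome end (distal regions may harbor exchanges and would
    contaminate the estimate); ``p_b`` likewise. With ``em=True`` the
    moment estimates seed an EM refinement over all windows (transitions
    held fixed), stopped at ``max_iter`` iterations or a log-likelihood
    improvement below ``tol``.

    Diagnostic occurrences are clustered inside repeat copies, so windows
    between copies see only stray opposite-label occurrences; with the raw
    pooled estimates (often > 0.999) one or two strays would outweigh the
    transition penalty. ``noise_floor`` therefore bounds the emissions into
    ``[noise_floor, 1 - noise_floor]``; set it to 0 to disable.
    """
    if tracks[["n_A", "n_B"]].to_numpy().sum() == 0:
        raise DegenerateDataError("all-zero density tracks; cannot estimate emissions")
    sums = {"A": np.zeros(2), "B": np.zeros(2)}
    for chrom, sub in partition.assignment.items():
        t = tracks[tracks["chromosome"] == chrom].sort_values("start")
        if t.empty:
            continue
        ntrim = int(len(t) * trim_fraction)
        core = t.iloc[ntrim : len(t) - ntrim] if len(t) > 2 * ntrim else t
        sums[sub] += [core["n_A"].sum(), core["n_B"].sum()]
    for sub in ("A", "B"):
        if sums[sub].sum() == 0:
            raise DegenerateDataError(f"no occurrences on subgenome-{sub} chromosomes")
    p_a = sums["A"][0] / sums["A"].sum()
    p_b = sums["B"][0] / sums["B"].sum()
    eps = max(noise_floor, 1e-6)
    p_a, p_b = min(max(p_a, eps), 1 - eps), min(max(p_b, eps), 1 - eps)
    if p_a <= p_b:
        raise DegenerateDataError("estimated p_a <= p_b; partition and tracks disagree")
    params = HMMParams(p_a=float(p_a), p_b=float(p_b), switch_prob=switch_prob)
    if em:
        params = _em_refine(tracks, params, max_iter=max_iter, tol=tol)
        params = replace(
            params,
            p_a=float(min(max(params.p_a, eps), 1 - eps)),
            p_b=float(min(max(params.p_b, eps), 1 - eps)),
        )
    return params


def _em_refine(tracks: pd.DataFrame, params: HMMParams, max_iter: int, tol: float) -> HMMParams:
    prev_ll = -np.inf
    for _ in range(max_iter):
        num = np.zeros(2)
        den = np.zeros(2)
        ll = 0.0
        for _, t in tracks.groupby("chromosome", sort=False):
            t = t.sort_values("start")
            n_a = t["n_A"].to_numpy()
            n_b = t["n_B"].to_numpy()
            post, chrom_ll = _forward_backward(n_a, n_b, params)
            ll += chrom_ll
            num += post.T @ n_a
            den += post.T @ (n_a + n_b)
        eps = 1e-6
        p = np.clip(num / np.maximum(den, 1e-300), eps, 1 - eps)
        if p[0] <= p[1]:  # label switching guard: keep state 0 the A-rich one
            p = p[::-1]
        params = replace(params, p_a=float(p[0]), p_b=float(p[1]))
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return params


def _log_transition(params: HMMParams) -> np.ndarray:
    s = params.switch_prob
    return np.log(np.array([[1 - s, s], [s, 1 - s]]))


def _forward_backward(n_a, n_b, params) -> tuple[np.ndarray, float]:
    logB = _log_emissions(n_a, n_b, params)
    logT = _log_transition(params)
    logpi = np.log(np.asarray(params.start_probs))
    T = len(n_a)
    alpha = np.zeros((T, 2))
    alpha[0] = logpi + logB[0]
    for t in range(1, T):
        alpha[t] = logB[t] + logsumexp(alpha[t - 1][:, None] + logT, axis=0)
    beta = np.zeros((T, 2))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(logT + (logB[t + 1] + beta[t + 1])[None, :], axis=1)
    loglik = float(logsumexp(alpha[-1]))
    post = np.exp(alpha + beta - loglik)
    post /= post.sum(axis=1, keepdims=True)
    return post, loglik


def decode(track: pd.DataFrame, params: HMMParams) -> tuple[np.ndarray, np.ndarray, float]:
    """Viterbi path and forward-backward posteriors for one chromosome.

    Returns ``(path, posteriors, loglik)`` where ``path`` is an array of
    "A"/"B" per window and ``posteriors`` has shape (n_windows, 2) with
    rows summing to 1. Viterbi ties are broken toward the previous state,
    favoring fewer segments.
    """
    t = track.sort_values("start")
    n_a = t["n_A"].to_numpy()
    n_b = t["n_B"].to_numpy()
    T = len(n_a)
    if T == 0:
        raise InputError("empty track")
    logB = _log_emissions(n_a, n_b, params)
    logT = _log_transition(params)
    logpi = np.log(np.asarray(params.start_probs))

    delta = np.zeros((T, 2))
    back = np.zeros((T, 2), dtype=np.int8)
    delta[0] = logpi + logB[0]
    for ti in range(1, T):
        for s in range(2):
            cand = delta[ti - 1] + logT[:, s]
            # tie toward staying in the same state
            best = s if cand[s] >= cand[1 - s] else 1 - s
            back[ti, s] = best
            delta[ti, s] = cand[best] + logB[ti, s]
    path_idx = np.zeros(T, dtype=np.int8)
    path_idx[-1] = 0 if delta[-1, 0] >= delta[-1, 1] else 1
    for ti in range(T - 2, -1, -1):
        path_idx[ti] = back[ti + 1, path_idx[ti + 1]]
    post, loglik = _forward_backward(n_a, n_b, params)
    path = np.array(STATES)[path_idx]
    return path, post, loglik


def segment(
    track: pd.DataFrame,
    path: np.ndarray,
    posteriors: np.ndarray,
    min_windows: int = 3,
) -> pd.DataFrame:
    """Collapse a window-state path into ancestry segments.

    Maximal constant-state runs are formed; runs shorter than
    ``min_windows`` are iteratively merged into the flanking state with the
    higher adjacent posterior (shortest run first), so single-window noise
    does not fragment the segmentation. Segments tile the chromosome.
    """
    t = track.sort_values("start").reset_index(drop=True)
    states = list(path)
    T = len(states)
    runs = _runs(states)
    while len(runs) > 1:
        lengths = [e - s for s, e, _ in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_windows:
            break
        s, e, _st = runs[shortest]
        left_state = runs[shortest - 1][2] if shortest > 0 else None
        right_state = runs[shortest + 1][2] if shortest < len(runs) - 1 else None
        if left_state is None:
            new_state = right_state
        elif right_state is None:
            new_state = left_state
        else:
            lp = posteriors[s - 1, STATES.index(left_state)]
            rp = posteriors[e, STATES.index(right_state)]
            new_state = left_state if lp >= rp else right_state
        for i in range(s, e):
            states[i] = new_state
        runs = _runs(states)
    rows = []
    for s, e, st in runs:
        rows.append(
            {
                "chromosome": t["chromosome"].iloc[0],
                "start": int(t["start"].iloc[s]),
                "end": int(t["end"].iloc[e - 1]),
                "state": st,
                "mean_posterior": float(posteriors[s:e, STATES.index(st)].mean()),
                "n_windows": e - s,
            }
        )
    return pd.DataFrame(rows)


def _runs(states: list) -> list[tuple[int, int, str]]:
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((start, i, states[start]))
            start = i
    return runs


def segment_genome(
    tracks: pd.DataFrame, params: HMMParams, min_windows: int = 3
) -> dict[str, pd.DataFrame]:
    """Decode and segment every chromosome in a combined track table."""
    out = {}
    for chrom, t in tracks.groupby("chromosome", sort=False):
        path, post, _ = decode(t, params)
        out[chrom] = segment(t, path, post, min_windows=min_windows)
    return out


def call_exchanges(
    segments_by_chrom: dict[str, pd.DataFrame],
    partition: SubgenomePartition,
    homeolog_map: HomeologMap,
    min_reciprocal_overlap: float = 0.5,
    tracks: pd.DataFrame | None = None,
    min_support: float = 25,
    refine_min_count: int = 5,
) -> pd.DataFrame:
    """Call homeologous exchanges from per-chromosome segmentations.

    A segment whose state differs from its chromosome's bulk subgenome is an
    exchange call. A call is flagged ``reciprocal`` when the homeolog
    partner has a complementary opposite-state call whose coordinates
    overlap reciprocally by at least ``min_reciprocal_overlap``; ``distal``
    marks calls touching a chromosome end.

    When ``tracks`` are supplied, calls are additionally polished against
    the raw windowed counts: a call must contain at least ``min_support``
    occurrences of its own state (diagnostic k-mers hit the wrong subgenome
    roughly once per chromosome per k-mer by chance, so a handful of stray
    occurrences in a copy-free stretch can fool the Viterbi path, while a
    genuine exchanged segment carries hundreds of occurrences per repeat
    copy), and each non-terminal call edge is refined to the midpoint
    between the flanking windows holding ``refine_min_count`` or more
    opposite- and own-state occurrences — the breakpoint is only localized
    to the gap between the last old-ancestry repeat and the first
    new-ancestry one.
    """
    partner = {}
    for c1, c2 in homeolog_map.pairs:
        partner[c1], partner[c2] = c2, c1
    calls = []
    for chrom, segs in segments_by_chrom.items():
        bulk = partition.assignment.get(chrom)
        if bulk is None:
            continue
        chrom_start = int(segs["start"].min())
        chrom_end = int(segs["end"].max())
        for row in segs.itertuples(index=False):
            if row.state == bulk:
                continue
            calls.append(
                {
                    "chromosome": chrom,
                    "start": row.start,
                    "end": row.end,
                    "state": row.state,
                    "mean_posterior": row.mean_posterior,
                    "n_windows": row.n_windows,
                    "distal": row.start == chrom_start or row.end == chrom_end,
                    "reciprocal": False,
                }
            )
    calls_df = pd.DataFrame(
        calls,
        columns=[
            "chromosome", "start", "end", "state", "mean_posterior",
            "n_windows", "distal", "reciprocal",
        ],
    )
    if tracks is not None and not calls_df.empty:
        calls_df = _polish_calls(calls_df, segments_by_chrom, tracks,
                                 min_support, refine_min_count)
    for i, row in calls_df.iterrows():
        p = partner.get(row["chromosome"])
        if p is None:
            continue
        if p not in segments_by_chrom:
            warnings.warn(f"no segmentation for partner {p} of {row['chromosome']}; "
                          "reciprocity cannot be assessed")
            continue
        mates = calls_df[
            (calls_df["chromosome"] == p)
            & (calls_df["state"] == partition.assignment[row["chromosome"]])
        ]
        for _, m in mates.iterrows():
            ov = min(row["end"], m["end"]) - max(row["start"], m["start"])
            if ov <= 0:
                continue
            f1 = ov / (row["end"] - row["start"])
            f2 = ov / (m["end"] - m["start"])
            if min(f1, f2) >= min_reciprocal_overlap:
                calls_df.at[i, "reciprocal"] = True
                break
    if tracks is not None:
        _joint_refine_reciprocal(calls_df, segments_by_chrom, partition, partner)
    return calls_df


def _joint_refine_reciprocal(
    calls_df: pd.DataFrame,
    segments_by_chrom: dict[str, pd.DataFrame],
    partition: SubgenomePartition,
    partner: dict[str, str],
) -> None:
    """Pool breakpoint evidence across the two partners of a reciprocal call.

    A balanced reciprocal exchange swaps equal-length distal segments, so
    both partners carry the same breakpoint offset from the chromosome end;
    averaging the two independently refined offsets roughly halves the
    localization error.
    """
    ends = {c: int(s["end"].max()) for c, s in segments_by_chrom.items()}
    done = set()
    for i, row in calls_df.iterrows():
        if i in done or not row["reciprocal"] or not row["distal"]:
            continue
        p = partner.get(row["chromosome"])
        mates = calls_df[
            (calls_df["chromosome"] == p)
            & calls_df["reciprocal"]
            & calls_df["distal"]
            & (calls_df["state"] == partition.assignment[row["chromosome"]])
        ]
        if len(mates) != 1:
            continue
        j = mates.index[0]
        mate = calls_df.loc[j]
        # both distal at the high-coordinate end
        if row["end"] != ends[row["chromosome"]] or mate["end"] != ends[p]:
            continue
        off = ((ends[row["chromosome"]] - row["start"]) + (ends[p] - mate["start"])) // 2
        calls_df.at[i, "start"] = ends[row["chromosome"]] - off
        calls_df.at[j, "start"] = ends[p] - off
        done.update((i, j))


def _polish_calls(
    calls_df: pd.DataFrame,
    segments_by_chrom: dict[str, pd.DataFrame],
    tracks: pd.DataFrame,
    min_support: float,
    refine_min_count: int,
) -> pd.DataFrame:
    keep_rows = []
    for _, row in calls_df.iterrows():
        chrom = row["chromosome"]
        t = tracks[tracks["chromosome"] == chrom].sort_values("start")
        segs = segments_by_chrom[chrom]
        chrom_start = int(segs["start"].min())
        chrom_end = int(segs["end"].max())
        own = t["n_A"] if row["state"] == "A" else t["n_B"]
        other = t["n_B"] if row["state"] == "A" else t["n_A"]
        inside = (t["start"] >= row["start"]) & (t["start"] < row["end"])
        if own[inside].sum() < min_support:
            continue
        start, end = int(row["start"]), int(row["end"])
        strong_own = t.loc[inside & (own >= refine_min_count)]
        # The Viterbi boundary sits at one edge of the uninformative gap
        # between the flanking repeat copies (ties favor the previous
        # state); the midpoint of that gap is the better point estimate and
        # may fall on either side of the Viterbi boundary.
        if start != chrom_start and not strong_own.empty:
            first_own = int(strong_own["start"].iloc[0])
            before = t.loc[(t["start"] < first_own) & (other >= refine_min_count)]
            last_other_end = int(before["end"].iloc[-1]) if not before.empty else start
            start = max(chrom_start, (last_other_end + first_own) // 2)
        if end != chrom_end and not strong_own.empty:
            last_own = int(strong_own["end"].iloc[-1])
            after = t.loc[(t["start"] >= last_own) & (other >= refine_min_count)]
            first_other = int(after["start"].iloc[0]) if not after.empty else end
            end = min(chrom_end, (last_own + first_other) // 2)
        new = dict(row)
        new["start"], new["end"] = start, end
        keep_rows.append(new)
    return pd.DataFrame(keep_rows, columns=calls_df.columns).reset_index(drop=True)


def write_segments_bed(segments_by_chrom: dict[str, pd.DataFrame], path) -> None:
    """Write ancestry segments as BED6 (name=state, score=posterior*1000)."""
    with open(path, "w") as fh:
        for chrom in sorted(segments_by_chrom):
            for row in segments_by_chrom[chrom].itertuples(index=False):
                score = int(round(row.mean_posterior * 1000))
                fh.write(f"{chrom}\t{row.start}\t{row.end}\t{row.state}\t{score}\t+\n")
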