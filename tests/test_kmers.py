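"""Diagnostic k-mer selection and subgenome clustering."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokit import seqs
from allokit.errors import DegenerateDataError, InputError
from allokit.kmers import (
    HomeologMap,
    KmerCountMatrix,
    cluster_chromosomes,
    consistency_filter,
    count_kmers,
    density_track,
    density_tracks,
    scaled_min_total,
    select_diagnostic_kmers,
)


def _matrix(data: dict[str, dict[str, int]], k=3, lengths=None) -> KmerCountMatrix:
    """Build a count matrix from {kmer: {chrom: count}}."""
    df = pd.DataFrame(data).T.fillna(0).astype(np.int64)
    df.index = [seqs.kmer_to_code(km) for km in data]
    lengths = lengths or {c: 1000 for c in df.columns}
    return KmerCountMatrix(k=k, counts=df, chromosome_lengths=lengths)


class TestCountKmers:
    def test_hand_counts_canonical(self):
        m = count_kmers({"c": seqs.encode("AAAA")}, k=3)
        # AAA occurs at two positions; canonical form of AAA is AAA
        assert m.counts.loc[seqs.kmer_to_code("AAA"), "c"] == 2
        assert m.counts["c"].sum() == 2

    def test_palindrome_counted_once_per_position(self):
        m = count_kmers({"c": seqs.encode("ACGT")}, k=4)
        assert m.counts.loc[seqs.kmer_to_code("ACGT"), "c"] == 1
        assert m.counts["c"].sum() == 1

    def test_total_positions(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 4, size=10_000).astype(np.uint8)
        for k in (5, 13):
            m = count_kmers({"c": codes}, k=k)
            assert m.counts["c"].sum() == 10_000 - k + 1

    def test_n_windows_skipped(self):
        m = count_kmers({"c": seqs.encode("AANAA")}, k=2)
        assert m.counts["c"].sum() == 2  # AA, AA; windows touching N dropped

    def test_empty_genome_rejected(self):
        with pytest.raises(InputError):
            count_kmers({}, k=3)

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=60), st.integers(2, 6))
    def test_strand_symmetry(self, s, k):
        """Counting a sequence and its reverse complement is identical."""
        fwd = count_kmers({"c": seqs.encode(s)}, k=k)
        rev = count_kmers({"c": seqs.revcomp(seqs.encode(s))}, k=k)
        assert fwd.counts["c"].to_dict() == rev.counts["c"].to_dict()


def _brute_force_select(genome, hmap, k, min_total, min_fold):
    """Independent oracle: enumerate every k-mer string and apply the rules."""
    from collections import Counter

    per_chrom = {}
    for name, codes in genome.items():
        s = seqs.decode(codes)
        c = Counter()
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if "N" in km:
                continue
            rc = seqs.decode(seqs.revcomp(seqs.encode(km)))
            c[min(km, rc)] += 1
        per_chrom[name] = c
    all_kmers = set().union(*per_chrom.values())
    selected = set()
    for km in all_kmers:
        total = sum(per_chrom[c][km] for c in genome)
        if total < min_total:
            continue
        ok = True
        for c1, c2 in hmap.pairs:
            d1 = (per_chrom[c1][km] + 1) / len(genome[c1])
            d2 = (per_chrom[c2][km] + 1) / len(genome[c2])
            fold = d1 / d2
            if not (fold >= min_fold or fold <= 1 / min_fold):
                ok = False
                break
        if ok:
            selected.add(km)
    return selected


class TestSelectDiagnosticKmers:
    def test_equal_counts_rejected(self):
        m = _matrix({"AAA": {"c1": 50, "c2": 50}, "CCC": {"c1": 80, "c2": 10}})
        out = select_diagnostic_kmers(m, HomeologMap([("c1", "c2")]), min_total=50)
        assert list(out.table.index) == ["CCC"]

    def test_fold_tie_retained(self):
        # density fold exactly 2 with pseudocount: (39+1)/(19+1) = 2
        m = _matrix({"AAA": {"c1": 39, "c2": 19}})
        out = select_diagnostic_kmers(m, HomeologMap([("c1", "c2")]), min_total=10)
        assert len(out) == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        data = {
            seqs.code_to_kmer(i, 3): {"c1": int(rng.integers(0, 60)),
                                      "c2": int(rng.integers(0, 60))}
            for i in range(32)
        }
        m = _matrix(data)
        hmap = HomeologMap([("c1", "c2")])
        base = len(select_diagnostic_kmers(m, hmap, min_total=20, min_fold=1.5))
        assert len(select_diagnostic_kmers(m, hmap, min_total=40, min_fold=1.5)) <= base
        assert len(select_diagnostic_kmers(m, hmap, min_total=20, min_fold=3.0)) <= base

    def test_zero_pairs_rejected(self):
        m = _matrix({"AAA": {"c1": 10}})
        with pytest.raises(InputError):
            select_diagnostic_kmers(m, HomeologMap([]))

    def test_matches_brute_force_on_small_genome(self):
        from allokit.synthetic import (ProgenitorSpec, TEBurstSpec, hybridize,
                                       plant_te_burst, simulate_ancestor)

        anc = simulate_ancestor(ProgenitorSpec(n_chromosomes=2,
                                               chromosome_length=20_000, seed=8))
        fam = TEBurstSpec("fam", "ACGGTTACCGGATTACA" * 3, n_copies=40,
                          burst_age=0.5, seed=9)
        a, _ = plant_te_burst(anc, fam, rate=2.1e-8)
        b = simulate_ancestor(ProgenitorSpec(n_chromosomes=2,
                                             chromosome_length=20_000, seed=10))
        genome, _ = hybridize(a, b)
        hmap = HomeologMap([("chr01", "chr02"), ("chr03", "chr04")])
        k, min_total, min_fold = 7, 10, 2.0
        m = count_kmers(genome, k=k)
        mine = set(select_diagnostic_kmers(m, hmap, min_total, min_fold).table.index)
        oracle = _brute_force_select(genome, hmap, k, min_total, min_fold)
        assert mine == oracle
        assert len(oracle) > 0


class TestClusterChromosomes:
    def test_anticorrelated_pairs_split_exactly(self):
        m = _matrix({
            "AAA": {"c1": 100, "c2": 0, "c3": 90, "c4": 0},
            "CCC": {"c1": 0, "c2": 100, "c3": 0, "c4": 110},
            "GGG": {"c1": 80, "c2": 0, "c3": 70, "c4": 0},
        })
        hmap = HomeologMap([("c1", "c2"), ("c3", "c4")])
        kset = select_diagnostic_kmers(m, hmap, min_total=50)
        part = cluster_chromosomes(m, kset, hmap)
        assert part.consistent
        assert part.assignment == {"c1": "A", "c2": "B", "c3": "A", "c4": "B"}

    def test_single_pair_trivial_bipartition(self):
        m = _matrix({"AAA": {"c1": 100, "c2": 1}, "CCC": {"c1": 2, "c2": 120}})
        hmap = HomeologMap([("c1", "c2")])
        kset = select_diagnostic_kmers(m, hmap, min_total=50)
        part = cluster_chromosomes(m, kset, hmap)
        assert sorted(part.assignment.values()) == ["A", "B"]
        assert part.assignment["c1"] == "A"  # lexicographic anchor

    def test_recovers_planted_subgenomes(self, tetra_ds, phasing):
        truth = tetra_ds.truth.subgenome_of_chromosome
        assert phasing.partition.assignment == truth
        assert phasing.partition.consistent


class TestConsistencyFilter:
    def _setup(self):
        m = _matrix({
            "AAA": {"c1": 100, "c2": 0, "c3": 90, "c4": 0},
            "CCC": {"c1": 0, "c2": 100, "c3": 0, "c4": 110},
            "GTG": {"c1": 80, "c2": 0, "c3": 0, "c4": 70},  # conflicted
        })
        hmap = HomeologMap([("c1", "c2"), ("c3", "c4")])
        kset = select_diagnostic_kmers(m, hmap, min_total=50)
        part = cluster_chromosomes(m, kset, hmap)
        return kset, part, hmap

    def test_conflicted_kmer_removed(self):
        kset, part, hmap = self._setup()
        out = consistency_filter(kset, part, hmap, max_conflicts=0)
        assert "GTG" not in out.table.index
        assert set(out.table.index) == {"AAA", "CCC"}

    def test_all_consistent_unchanged_with_labels(self):
        kset, part, hmap = self._setup()
        out = consistency_filter(kset, part, hmap, max_conflicts=1)
        assert set(out.table.index) == {"AAA", "CCC", "GTG"}
        assert out.table.loc["AAA", "label"] == "A"
        assert out.table.loc["CCC", "label"] == "B"
        assert (consistency_filter(out, part, hmap).table["consistency"] >= 0.5).all()

    def test_all_removed_raises(self):
        m = _matrix({"GTG": {"c1": 80, "c2": 0, "c3": 0, "c4": 70}})
        hmap = HomeologMap([("c1", "c2"), ("c3", "c4")])
        kset = select_diagnostic_kmers(m, hmap, min_total=50)
        part_assign = {"c1": "A", "c2": "B", "c3": "A", "c4": "B"}
        from allokit.kmers import SubgenomePartition
        part = SubgenomePartition(part_assign, None, 1.0, True)
        with pytest.raises(DegenerateDataError):
            consistency_filter(kset, part, hmap, max_conflicts=0)

    def test_shared_family_absent_from_final_set(self, tetra_ds, phasing):
        shared = tetra_ds.families["famShared"].consensus
        shared_kmers = {shared[i:i + 13] for i in range(len(shared) - 12)}
        canon = set()
        for km in shared_kmers:
            rc = seqs.decode(seqs.revcomp(seqs.encode(km)))
            canon.add(min(km, rc))
        assert canon.isdisjoint(set(phasing.kmer_set.table.index))


class TestDensityTrack:
    def test_no_occurrences_all_zero(self):
        m = _matrix({"AAA": {"c1": 5, "c2": 1}})
        kset = select_diagnostic_kmers(m, HomeologMap([("c1", "c2")]), min_total=5)
        codes = seqs.encode("CGCGCGCGCG" * 10)
        track = density_track("x", codes, kset, window_size=50)
        assert (track[["n_A", "n_B"]].to_numpy() == 0).all()

    def test_window_sums_match_matrix(self, tetra_ds, phasing):
        m, kset = phasing.matrix, phasing.kmer_set
        chrom = "chr01"
        track = density_track(chrom, tetra_ds.genome[chrom], kset, 10_000)
        codes = [seqs.kmer_to_code(km) for km in kset.table.index]
        labels = kset.table["label"].to_numpy()
        sub = m.counts.loc[codes, chrom].to_numpy()
        assert track["n_A"].sum() == sub[labels == "A"].sum()
        assert track["n_B"].sum() == sub[labels == "B"].sum()

    def test_a_chromosome_dominated_by_a_kmers(self, tetra_ds, phasing):
        from scipy.stats import binomtest

        track = phasing.tracks
        t = track[track.chromosome == "chr03"]  # A chromosome, no exchange
        informative = t[(t.n_A + t.n_B) > 0]
        wins_a = int((informative.n_A > informative.n_B).sum())
        res = binomtest(wins_a, len(informative), 0.5, alternative="greater")
        assert res.pvalue < 0.01

    def test_window_smaller_than_k_rejected(self, phasing):
        with pytest.raises(InputError):
            density_track("x", seqs.encode("ACGT" * 10), phasing.kmer_set, 5)


class TestScaledMinTotal:
    def test_scales_linearly_with_floor(self):
        assert scaled_min_total(2e9) == 100
        assert scaled_min_total(1e9) == 50
        assert scaled_min_total(4e6) == 10  # floor


class TestPlantedFamilyRecovery:
    def test_planted_family_kmers_recovered_and_labelled(self, tetra_ds, phasing):
        """Diagnostic k-mers passing thresholds from the A-specific family are
        in the final set with label A (checked against the truth registry)."""
        famA = tetra_ds.families["famA"].consensus
        full = famA + famA[: tetra_ds.ltr_length]
        canon = set()
        for i in range(len(full) - 12):
            km = full[i:i + 13]
            rc = seqs.decode(seqs.revcomp(seqs.encode(km)))
            canon.add(min(km, rc))
        table = phasing.kmer_set.table
        hits = [km for km in canon if km in table.index]
        # most consensus k-mers survive mutation and thresholds
        assert len(hits) > 0.5 * len(canon)
        labels = table.loc[hits, "label"]
        assert (labels == "A").all()
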