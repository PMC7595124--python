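"""Generator correctness: construction, determinism, statistical calibration."""
import numpy as np
import pytest

from allokit import seqs, synthetic
from allokit.errors import InputError, SaturationError
from allokit.synthetic import (
    ExchangeSpec,
    ProgenitorSpec,
    TEBurstSpec,
    diverge,
    hybridize,
    plant_te_burst,
    simulate_admixed_accession,
    simulate_ancestor,
    simulate_homeolog_counts,
)


class TestSimulateAncestor:
    def test_lengths_and_gc(self):
        spec = ProgenitorSpec(n_chromosomes=2, chromosome_length=100_000,
                              gc_content=0.5, seed=7)
        genome = simulate_ancestor(spec)
        assert len(genome) == 2
        for codes in genome.values():
            assert len(codes) == 100_000
            at = np.mean((codes == 0) | (codes == 3))
            # binomial s.d. of the A+T fraction
            sd = np.sqrt(0.5 * 0.5 / 100_000)
            assert abs(at - 0.5) < 3 * sd

    def test_deterministic(self):
        spec = ProgenitorSpec(n_chromosomes=2, chromosome_length=10_000, seed=7)
        g1 = simulate_ancestor(spec)
        g2 = simulate_ancestor(spec)
        for c in g1:
            assert np.array_equal(g1[c], g2[c])

    def test_gc_one_gives_only_gc(self):
        spec = ProgenitorSpec(n_chromosomes=1, chromosome_length=5_000,
                              gc_content=1.0, seed=0)
        (codes,) = simulate_ancestor(spec).values()
        assert set(np.unique(codes)) <= {1, 2}

    def test_invalid_length_rejected(self):
        with pytest.raises(InputError):
            ProgenitorSpec(chromosome_length=0)


class TestDiverge:
    def test_zero_time_identity(self):
        g = simulate_ancestor(ProgenitorSpec(n_chromosomes=1, chromosome_length=1_000, seed=1))
        out = diverge(g, rate=1e-8, time_years=0, seed=5)
        assert all(np.array_equal(out[c], g[c]) for c in g)

    def test_p_distance_matches_closed_form(self):
        g = simulate_ancestor(ProgenitorSpec(n_chromosomes=1, chromosome_length=1_000_000, seed=2))
        rate, years = 1e-8, 5e6
        out = diverge(g, rate, years, seed=11)
        p_obs = np.mean(out["chr01"] != g["chr01"])
        p_exp = 0.75 * (1 - np.exp(-4 / 3 * rate * years))  # 0.0484
        sd = np.sqrt(p_exp * (1 - p_exp) / 1_000_000)
        assert abs(p_exp - 0.0484) < 1e-4
        assert abs(p_obs - p_exp) < 3 * sd

    def test_independent_seeds_differ(self):
        g = simulate_ancestor(ProgenitorSpec(n_chromosomes=1, chromosome_length=50_000, seed=2))
        o1 = diverge(g, 1e-8, 5e6, seed=1)
        o2 = diverge(g, 1e-8, 5e6, seed=2)
        assert not np.array_equal(o1["chr01"], o2["chr01"])

    def test_saturation_rejected(self):
        g = simulate_ancestor(ProgenitorSpec(n_chromosomes=1, chromosome_length=1_000, seed=1))
        with pytest.raises(SaturationError):
            diverge(g, rate=1e-7, time_years=1e7, seed=0)


class TestPlantTeBurst:
    def _genome(self, n=2, L=50_000, seed=3):
        return simulate_ancestor(ProgenitorSpec(n_chromosomes=n, chromosome_length=L, seed=seed))

    def test_zero_copies_is_identity(self):
        g = self._genome()
        spec = TEBurstSpec("fam", "ACGT" * 50, n_copies=0, burst_age=1.0, seed=0)
        out, reg = plant_te_burst(g, spec, rate=2.1e-8)
        assert reg == []
        assert all(np.array_equal(out[c], g[c]) for c in g)

    def test_registry_records_every_copy_at_its_coordinates(self):
        g = self._genome()
        consensus = "".join("ACGT"[i % 4] for i in range(200))
        spec = TEBurstSpec("fam", consensus, n_copies=30, burst_age=0.0, seed=4)
        out, reg = plant_te_burst(g, spec, rate=2.1e-8, chromosomes=["chr01"])
        assert len(reg) == 30
        assert {e["chromosome"] for e in reg} == {"chr01"}
        for e in reg:
            # age 0: inserted copy is the unmutated consensus
            assert seqs.decode(out[e["chromosome"]][e["start"]:e["end"]]) == consensus

    def test_total_length_grows_by_copies(self):
        g = self._genome()
        spec = TEBurstSpec("fam", "A" * 100, n_copies=10, burst_age=0.0, seed=4)
        out, _ = plant_te_burst(g, spec, rate=2.1e-8)
        assert sum(map(len, out.values())) == sum(map(len, g.values())) + 10 * 100

    def test_no_nesting_by_default(self):
        g = self._genome(n=1, L=5_000)
        spec = TEBurstSpec("fam", "C" * 300, n_copies=10, burst_age=0.0, seed=9)
        _, reg = plant_te_burst(g, spec, rate=2.1e-8)
        iv = sorted((e["start"], e["end"]) for e in reg)
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            assert e1 <= s2

    def test_ltr_divergence_matches_expectation(self):
        g = self._genome(n=1, L=200_000)
        rate, age = 2.1e-8, 4.0
        spec = TEBurstSpec("fam", "ACGT" * 250, n_copies=100, burst_age=age,
                           ltr_length=400, seed=12)
        out, reg = plant_te_burst(g, spec, rate=rate)
        dists = []
        for e in reg:
            copy = out[e["chromosome"]][e["start"]:e["end"]]
            dists.append(np.mean(copy[:400] != copy[-400:]))
        rt = 2 * rate * age * 1e6
        p_exp = 0.75 * (1 - np.exp(-4 / 3 * rt))
        sd = np.sqrt(p_exp * (1 - p_exp) / (400 * 100))
        assert abs(np.mean(dists) - p_exp) < 3 * sd


class TestHybridize:
    def _progenitors(self, L=20_000):
        a = simulate_ancestor(ProgenitorSpec(n_chromosomes=2, chromosome_length=L, seed=1))
        b = simulate_ancestor(ProgenitorSpec(n_chromosomes=2, chromosome_length=L, seed=2))
        return a, b

    def test_no_exchange_truth_empty(self):
        a, b = self._progenitors()
        tetra, truth = hybridize(a, b)
        assert truth.exchange_intervals == []
        assert sorted(tetra) == ["chr01", "chr02", "chr03", "chr04"]
        assert truth.subgenome_of_chromosome == {
            "chr01": "A", "chr02": "B", "chr03": "A", "chr04": "B"}

    def test_reciprocal_exchange_swaps_tails(self):
        a, b = self._progenitors()
        tetra, truth = hybridize(a, b, [ExchangeSpec(0, 0.2)])
        seg = int(round(0.2 * 20_000))
        assert len(truth.exchange_intervals) == 2
        (c1, s1, e1, d1), (c2, s2, e2, d2) = truth.exchange_intervals
        assert (e1 - s1) == (e2 - s2) == seg
        assert {d1, d2} == {"A", "B"}
        a_names = list(a)
        assert np.array_equal(tetra["chr01"][-seg:], b[list(b)[0]][-seg:])
        assert np.array_equal(tetra["chr02"][-seg:], a[a_names[0]][-seg:])

    def test_reciprocal_conserves_total_length(self):
        a, b = self._progenitors()
        before = sum(map(len, a.values())) + sum(map(len, b.values()))
        tetra, _ = hybridize(a, b, [ExchangeSpec(0, 0.3), ExchangeSpec(1, 0.1)])
        assert sum(map(len, tetra.values())) == before

    def test_bad_breakpoint_rejected(self):
        with pytest.raises(InputError):
            ExchangeSpec(0, 0.7)


class TestHomeologCounts:
    def test_null_bias_recovered(self):
        counts, _ = simulate_homeolog_counts(
            n_pairs=4000, median_bias=1.0, dispersion=0.0,
            silent_fraction=0.0, seed=3)
        a = counts.iloc[0::2].to_numpy(float)
        b = counts.iloc[1::2].to_numpy(float)
        ok = (a > 5) & (b > 5)
        med = np.median(b[ok] / a[ok])
        assert abs(med - 1.0) < 0.02

    def test_column_sums_near_library_sizes(self):
        counts, _ = simulate_homeolog_counts(
            n_pairs=2000, dispersion=0.0, silent_fraction=0.0,
            library_sizes=1e6, n_samples=3, seed=4)
        assert np.allclose(counts.sum(axis=0), 1e6, rtol=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            simulate_homeolog_counts(median_bias=0)
        with pytest.raises(InputError):
            simulate_homeolog_counts(silent_fraction=1.0)


class TestAdmixedAccession:
    def test_diploid_f1_fraction_half(self):
        pos = {"chr01": np.arange(0, 100_000, 100)}
        blocks = [("chr01", 0, 100_000, (1, 1))]
        obs, _ = simulate_admixed_accession(2, pos, blocks, depth_mean=200,
                                            error_rate=0.0, seed=5)
        frac = obs["depth_sp1"].sum() / (obs["depth_sp1"] + obs["depth_sp2"]).sum()
        assert abs(frac - 0.5) < 0.01

    def test_triploid_two_to_one(self):
        pos = {"chr01": np.arange(0, 100_000, 100)}
        blocks = [("chr01", 0, 100_000, (2, 1))]
        obs, _ = simulate_admixed_accession(3, pos, blocks, depth_mean=20,
                                            error_rate=0.0, seed=6)
        frac = obs["depth_sp1"].sum() / (obs["depth_sp1"] + obs["depth_sp2"]).sum()
        assert abs(frac - 2 / 3) < 0.02

    def test_deterministic(self):
        pos = {"chr01": np.arange(0, 10_000, 10)}
        blocks = [("chr01", 0, 10_000, (2, 1))]
        o1, _ = simulate_admixed_accession(3, pos, blocks, depth_mean=10, seed=7)
        o2, _ = simulate_admixed_accession(3, pos, blocks, depth_mean=10, seed=7)
        assert o1.equals(o2)

    def test_bad_dosage_rejected(self):
        pos = {"chr01": np.array([10])}
        with pytest.raises(InputError):
            simulate_admixed_accession(2, pos, [("chr01", 0, 100, (2, 1))])


class TestPresetTruth:
    def test_specific_families_target_their_subgenome(self, tetra_ds):
        truth = tetra_ds.truth
        sub = truth.subgenome_of_chromosome
        # famA copies sit on A chromosomes except where an exchange moved them
        exchanged = {(c, s, e) for c, s, e, _ in truth.exchange_intervals}
        for e in truth.te_copy_registry:
            if e["family"] not in ("famA", "famB"):
                continue
            want = "A" if e["family"] == "famA" else "B"
            on_exchange = any(
                c == e["chromosome"] and s <= e["start"] < ee
                for c, s, ee in exchanged
            )
            if not on_exchange:
                assert sub[e["chromosome"]] == want

    def test_shared_family_on_both_subgenomes(self, tetra_ds):
        subs = {
            tetra_ds.truth.subgenome_of_chromosome[e["chromosome"]]
            for e in tetra_ds.truth.te_copy_registry
            if e["family"] == "famShared"
        }
        assert subs == {"A", "B"}

    def test_registry_coordinates_match_sequence(self, tetra_ds):
        # every registered copy is recoverable: correct length, and its two
        # LTRs are much more similar to each other than random sequence
        ltr = tetra_ds.ltr_length
        reg = tetra_ds.truth.te_copy_registry
        checked = 0
        for e in reg[::40]:
            copy = tetra_ds.genome[e["chromosome"]][e["start"]:e["end"]]
            if len(copy) < 2 * ltr:
                continue  # truncated by an exchange breakpoint
            p = np.mean(copy[:ltr] != copy[-ltr:])
            assert p < 0.5
            checked += 1
        assert checked >= 10
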