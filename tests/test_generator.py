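import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import ks_2samp

from spscreen import (
    GeneratorConfig,
    SPRecord,
    accept_batch,
    assemble_sps,
    build_frequency_dictionaries,
    design_candidates,
    extract_region,
    generate_accepted_batch,
    retro_translate,
    sample_region_batch,
    two_sample_ks,
)
from spscreen.generator import region_feature_table

from .oracles import ks_statistic_enumerate


def toy_record(n_body: str, h: str, c_body: str, site: str, ac: str, idx: int = 0) -> SPRecord:
    aa = "M" + n_body + h + c_body + site + ac
    return SPRecord(
        id=f"toy{idx}",
        aa_seq=aa,
        n_end=1 + len(n_body),
        h_end=1 + len(n_body) + len(h),
        c_end=len(aa) - len(ac),
    )


class TestDictionaries:
    def test_pooled_counts_normalize_correctly(self):
        recs = [
            toy_record("KK", "LLLLLLLLLL", "SSS", "AKA", "AEK", 0),
            toy_record("KR", "LLLLLLLLLL", "SSS", "AKA", "AEK", 1),
        ]
        freqs = build_frequency_dictionaries(recs)
        assert freqs.d_n == {"K": 0.75, "R": 0.25}
        assert freqs.d_m1 == {"A": 1.0}
        assert freqs.d_m3 == {"A": 1.0}
        assert freqs.d_m2 == {"K": 1.0}

    def test_every_dictionary_sums_to_one(self, reference_set):
        freqs = build_frequency_dictionaries(reference_set)
        for dictionary in freqs.as_tuple():
            assert sum(dictionary.values()) == pytest.approx(1.0, abs=1e-9)

    def test_initial_met_is_excluded_from_the_n_dictionary(self):
        recs = [toy_record("KK", "LLLLLLLLLL", "SSS", "AKA", "AEK")]
        assert "M" not in build_frequency_dictionaries(recs).d_n

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            build_frequency_dictionaries([])

    def test_empty_scope_across_reference_rejected(self):
        # N-regions of length 1 leave the N-body dictionary empty
        rec = SPRecord(id="x", aa_seq="MLLLLLLLLLLSSAKAAEK", n_end=1, h_end=11, c_end=16)
        with pytest.raises(ValueError, match="N body"):
            build_frequency_dictionaries([rec])


class TestSampling:
    def test_n_region_strings_start_with_met_within_length_range(self, reference_set, rng):
        freqs = build_frequency_dictionaries(reference_set)
        cfg = GeneratorConfig(batch_size=300)
        batch = sample_region_batch(freqs, "N", cfg, rng)
        assert len(batch) == 300
        assert all(s[0] == "M" and 2 <= len(s) <= 11 for s in batch)

    def test_h_region_lengths(self, reference_set, rng):
        freqs = build_frequency_dictionaries(reference_set)
        batch = sample_region_batch(freqs, "H", GeneratorConfig(batch_size=200), rng)
        assert all(9 <= len(s) <= 16 for s in batch)

    def test_c_region_is_body_plus_cleavage_site(self, reference_set, rng):
        freqs = build_frequency_dictionaries(reference_set)
        batch = sample_region_batch(freqs, "C", GeneratorConfig(batch_size=200), rng)
        assert all(7 <= len(s) <= 14 for s in batch)

    def test_same_seed_reproduces_the_batch(self, reference_set):
        freqs = build_frequency_dictionaries(reference_set)
        cfg = GeneratorConfig(batch_size=50)
        a = sample_region_batch(freqs, "Ac", cfg, np.random.default_rng(5))
        b = sample_region_batch(freqs, "Ac", cfg, np.random.default_rng(5))
        assert a == b

    def test_unknown_region_kind_rejected(self, reference_set, rng):
        freqs = build_frequency_dictionaries(reference_set)
        with pytest.raises(ValueError):
            sample_region_batch(freqs, "Z", GeneratorConfig(batch_size=5), rng)


class TestKolmogorovSmirnov:
    def test_identical_samples_have_zero_statistic(self):
        d, p = two_sample_ks([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_samples_have_statistic_one(self):
        d, _ = two_sample_ks([1.0, 2.0], [3.0, 4.0])
        assert d == 1.0

    def test_shifted_triples(self):
        d, _ = two_sample_ks([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_matches_exhaustive_ecdf_oracle_on_small_samples(self, rng):
        for _ in range(40):
            a = rng.integers(0, 6, size=rng.integers(1, 13)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(1, 13)).astype(float)
            d, _ = two_sample_ks(a, b)
            assert d == pytest.approx(ks_statistic_enumerate(a, b))

    def test_agrees_with_scipy_asymptotic(self, rng):
        a, b = rng.normal(size=300), rng.normal(0.2, 1, size=250)
        d, p = two_sample_ks(a, b)
        ref = ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-2, abs=1e-4)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ks([], [1.0])


class TestAcceptance:
    def test_batch_resampled_from_reference_is_accepted(self, reference_set, rng):
        cfg = GeneratorConfig(batch_size=2000)
        for kind in ("N", "H", "C", "Ac"):
            strings = [extract_region(r, kind) for r in reference_set]
            batch = list(rng.choice(strings, size=cfg.batch_size))
            accepted, _ = accept_batch(batch, reference_set, kind, cfg)
            assert accepted, kind

    def test_degenerate_polyleucine_batch_is_rejected(self, reference_set):
        cfg = GeneratorConfig(batch_size=500)
        cfg.ks_min_pass["N"] = 27  # maximum: all compared features must match
        batch = ["M" + "L" * 8] * 500
        accepted, p_values = accept_batch(batch, reference_set, "N", cfg)
        assert not accepted
        assert p_values["Charge"] < 0.1

    def test_zero_threshold_always_accepts(self, reference_set, rng):
        cfg = GeneratorConfig(batch_size=100)
        cfg.ks_min_pass["N"] = 0
        accepted, _ = accept_batch(["M" + "L" * 5] * 100, reference_set, "N", cfg)
        assert accepted

    def test_threshold_above_feature_count_rejected(self, reference_set):
        cfg = GeneratorConfig(batch_size=10)
        cfg.ks_min_pass["Ac"] = 99
        with pytest.raises(ValueError, match="exceeds"):
            accept_batch(["AAA"] * 10, reference_set, "Ac", cfg)

    def test_generated_batches_converge_to_reference_dictionaries(self, reference_set):
        # total-variation distance between the reference N dictionary and the
        # residue frequencies of an accepted generated batch
        rng = np.random.default_rng(123)
        freqs = build_frequency_dictionaries(reference_set)
        cfg = GeneratorConfig(batch_size=10_000)
        batch = generate_accepted_batch(freqs, reference_set, "N", cfg, rng)
        pooled = "".join(s[1:] for s in batch)
        observed = {aa: pooled.count(aa) / len(pooled) for aa in set(pooled)}
        tv = 0.5 * sum(
            abs(freqs.d_n.get(aa, 0.0) - observed.get(aa, 0.0))
            for aa in set(freqs.d_n) | set(observed)
        )
        assert tv < 0.05


class TestAssembly:
    def test_length_filter_discards_33_and_keeps_32(self):
        n, h, c = "M" + "K" * 9, "L" * 12, "S" * 5 + "AKA"
        ac = "AEK"
        assert len(n + h + c + ac) == 33
        records = assemble_sps([n], [h], [c], [ac])
        assert records == []
        shorter = assemble_sps(["M" + "K" * 8], [h], [c], [ac])
        assert len(shorter) == 1 and len(shorter[0].aa_seq) == 32

    def test_minimum_assembly_is_kept_with_correct_boundaries(self):
        records = assemble_sps(["MK"], ["L" * 9], ["SSSS" + "AKA"], ["AEK"])
        rec = records[0]
        assert (rec.n_end, rec.h_end, rec.c_end) == (2, 11, 18)
        assert extract_region(rec, "Ac") == "AEK"

    def test_mismatched_batch_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal sizes"):
            assemble_sps(["MK"], ["L" * 9] * 2, ["SSSSAKA"], ["AEK"])


class TestRetroTranslation:
    def test_round_trip_identity(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(10):
            seq = "M" + "".join(rng.choice(aas, size=rng.integers(5, 25)))
            assert str(Seq(retro_translate(seq)).translate()) == seq

    def test_met_maps_to_atg(self):
        assert retro_translate("M") == "ATG"

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            retro_translate("MX")


class TestDesignCandidates:
    def test_candidates_are_sorted_and_better_than_average(self, reference_set):
        from spscreen import (
            CorrelationAPSelector,
            EfficiencyRegressor,
            SPFeatureEncoder,
            TRUTH_FUNCTIONS,
            score_library,
            simulate_screen,
        )

        rng = np.random.default_rng(17)
        truth = TRUTH_FUNCTIONS["default"]
        table, _ = simulate_screen(reference_set, truth, rng=rng)
        scores, _ = score_library(table)
        encoder = SPFeatureEncoder().fit()
        X = encoder.transform(reference_set)
        selector = CorrelationAPSelector().fit(X)
        reduced = selector.transform(X)
        model = EfficiencyRegressor(n_estimators=30, random_state=0).fit(
            reduced, scores["wa"].reindex(reduced.index)
        )
        cfg = GeneratorConfig(batch_size=400, max_batch_attempts=40)
        out = design_candidates(
            reference_set, model, encoder, n_select=25, config=cfg,
            rng=np.random.default_rng(3), selected_features=selector.selected_features_,
        )
        assert len(out) == 25
        assert list(out["predicted_wa"]) == sorted(out["predicted_wa"])
        # selected candidates should truly secrete better than the pool average
        def true_wa(row):
            rec = SPRecord(
                id=row["id"], aa_seq=row["aa_seq"],
                n_end=row["n_end"], h_end=row["h_end"], c_end=row["c_end"],
            )
            return truth(rec)

        pool = design_candidates(
            reference_set, model, encoder, n_select=10_000, config=cfg,
            rng=np.random.default_rng(3), selected_features=selector.selected_features_,
        )
        assert pool["predicted_wa"].head(25).mean() < pool["predicted_wa"].mean()
        selected_truth = out.apply(true_wa, axis=1).mean()
        pool_truth = pool.apply(true_wa, axis=1).mean()
        assert selected_truth < pool_truth
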