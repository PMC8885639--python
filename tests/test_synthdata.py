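"""The synthetic world: determinism, planted signal, sampling sanity."""

import numpy as np
import pandas as pd
import pytest

from crossomics import (
    SimConfig,
    generate_abundance,
    generate_detection,
    generate_predictor_tables,
    generate_universe,
)
from crossomics.synthdata import SimConfigError, write_dataset


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline_detect_prob": 1.5},
            {"term_size_range": (20, 10)},
            {"term_size_range": (10, 2000)},  # term larger than universe
            {"abundance_log_sd": -1.0},
            {"planted_terms": ((99, "depleted", 0.1),)},  # index out of range
            {"planted_terms": ((0, "sideways", 0.1),)},
            {"frac_both": 0.5},  # exceeds min(frac_membrane, frac_secreted)
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimConfigError):
            SimConfig(**kwargs)

    def test_zero_sd_is_a_legal_null_configuration(self):
        cfg = SimConfig(abundance_log_sd=0.0, seed=1)
        bundle = generate_abundance(generate_universe(cfg))
        assert np.allclose(
            bundle.true_abundance["A"], bundle.true_abundance["B"]
        )


class TestDeterminism:
    def test_same_seed_same_world(self):
        cfg = SimConfig(n_genes=300, n_terms=10, seed=7)
        u1, u2 = generate_universe(cfg), generate_universe(cfg)
        pd.testing.assert_frame_equal(u1.genes, u2.genes)
        assert u1.gene_sets.sets == u2.gene_sets.sets
        p1, p2 = generate_detection(u1), generate_detection(u2)
        assert [p.genes for p in p1] == [p.genes for p in p2]

    def test_files_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimConfig(n_genes=200, n_terms=8, seed=3)
        for d in ("one", "two"):
            uni = generate_universe(cfg)
            write_dataset(
                tmp_path / d,
                uni,
                generate_detection(uni),
                generate_abundance(uni),
                generate_predictor_tables(uni),
            )
        for f1 in sorted((tmp_path / "one").iterdir()):
            f2 = tmp_path / "two" / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_substreams_isolated(self):
        """Reconfiguring the abundance stage must not move detection draws."""
        base = SimConfig(n_genes=300, n_terms=10, seed=5)
        alt = SimConfig(n_genes=300, n_terms=10, seed=5, abundance_log_mean=4.0)
        d_base = generate_detection(generate_universe(base))
        d_alt = generate_detection(generate_universe(alt))
        assert [p.genes for p in d_base] == [p.genes for p in d_alt]


class TestUniverse:
    def test_degenerate_size_range_fixes_term_size(self):
        uni = generate_universe(SimConfig(n_terms=20, term_size_range=(10, 10), seed=2))
        assert {len(gs.genes) for gs in uni.gene_sets.sets.values()} == {10}

    def test_ground_truth_covers_generated_objects(self, default_universe):
        uni = default_universe
        assert set(uni.truth.term_direction) == set(uni.gene_sets.sets)
        assert list(uni.truth.gene_log2_fc.index) == list(uni.gene_ids)
        assert len(uni.truth.membrane) == uni.config.n_genes

    def test_lengths_positive(self, default_universe):
        assert (default_universe.genes["protein_length_aa"] > 0).all()
        assert (default_universe.genes["gene_length_nt"] > 0).all()


class TestDetection:
    def test_certain_detection_returns_full_catalog(self):
        cfg = SimConfig(n_genes=150, baseline_detect_prob=1.0, n_datasets=2, seed=4)
        uni = generate_universe(cfg)
        for p in generate_detection(uni):
            assert p.genes == frozenset(uni.gene_ids)

    def test_zero_detection_returns_empty_profiles(self):
        cfg = SimConfig(n_genes=150, baseline_detect_prob=0.0, n_datasets=2, seed=4)
        for p in generate_detection(generate_universe(cfg)):
            assert not p.genes

    def test_detected_count_within_binomial_bounds(self):
        n = 10_000
        cfg = SimConfig(
            n_genes=n, n_terms=0, baseline_detect_prob=0.8, n_datasets=1, seed=9
        )
        profile = generate_detection(generate_universe(cfg))[0]
        sd = np.sqrt(n * 0.8 * 0.2)
        assert abs(len(profile) - 0.8 * n) <= 3 * sd

    def test_planted_depletion_hits_override_rate(self):
        """Mean detected fraction of the planted term's genes tracks the
        override probability over many datasets (Monte-Carlo)."""
        cfg = SimConfig(
            term_size_range=(50, 50),
            planted_terms=((0, "depleted", 0.1),),
            n_datasets=60,
            seed=13,
        )
        uni = generate_universe(cfg)
        members = uni.gene_sets.sets["T000"].genes
        fracs = [
            len(p.genes & members) / len(members) for p in generate_detection(uni)
        ]
        n_draws = len(members) * len(fracs)
        tol = 3 * np.sqrt(0.1 * 0.9 / n_draws)
        assert np.mean(fracs) == pytest.approx(0.1, abs=tol)
        baseline_terms = set(uni.gene_sets.sets) - {"T000"}
        some_baseline = uni.gene_sets.sets[sorted(baseline_terms)[0]].genes
        base_fracs = [
            len(p.genes & some_baseline) / len(some_baseline)
            for p in generate_detection(uni)
        ]
        assert np.mean(fracs) < np.mean(base_fracs)  # strictly lower than baseline


class TestAbundance:
    def test_counts_are_nonnegative_integers(self, default_universe):
        bundle = generate_abundance(default_universe)
        for table in (bundle.spectral_counts, bundle.fragment_counts):
            arr = table.counts.to_numpy()
            assert (arr >= 0).all()
            assert np.issubdtype(arr.dtype, np.integer)

    def test_planted_fold_change_recovered_at_depth(self):
        """A gene planted at log2FC = -2 in B shows a ~0.25 B/A count ratio."""
        cfg = SimConfig(
            n_genes=400,
            planted_fc_genes=((7, -2.0),),
            rna_depth=5.0,  # deep sequencing so Poisson noise is small
            seed=17,
        )
        uni = generate_universe(cfg)
        bundle = generate_abundance(uni)
        gid = uni.genes.index[7]
        ratio = (
            bundle.fragment_counts.counts.loc[gid, "B"]
            / bundle.fragment_counts.counts.loc[gid, "A"]
        )
        assert ratio == pytest.approx(0.25, rel=0.15)
        others = bundle.fragment_counts.counts.drop(index=gid)
        med = (others["B"] / others["A"].clip(lower=1)).median()
        assert med == pytest.approx(1.0, rel=0.1)

    def test_expected_counts_proportional_to_abundance_times_length(self):
        cfg = SimConfig(n_genes=2000, rna_depth=2.0, seed=23)
        uni = generate_universe(cfg)
        bundle = generate_abundance(uni)
        expected = (
            bundle.true_abundance["A"]
            * uni.genes["gene_length_nt"]
            * cfg.rna_depth
        )
        observed = bundle.fragment_counts.counts["A"]
        # pooled Poisson: total observed within 4 sd of total expectation
        tot = expected.sum()
        assert abs(observed.sum() - tot) < 4 * np.sqrt(tot)


class TestPredictors:
    def test_no_membrane_truth_no_tm_calls_without_error(self):
        cfg = SimConfig(frac_membrane=0.0, frac_secreted=0.2, frac_both=0.0,
                        predictor_error_rate=0.0, seed=31)
        uni = generate_universe(cfg)
        ev = generate_predictor_tables(uni)
        assert (ev["tmhmm_tm_count"] == 0).all()
        assert (ev["phobius_tm_count"] == 0).all()
        assert not (ev["wolfpsort_loc"] == "plasma_membrane").any()

    def test_true_membrane_always_has_tm_evidence_when_noiseless(self):
        cfg = SimConfig(seed=37, predictor_error_rate=0.0)
        uni = generate_universe(cfg)
        ev = generate_predictor_tables(uni).set_index("protein_id")
        mem = uni.truth.membrane
        assert (ev.loc[mem, "tmhmm_tm_count"] >= 1).all()

    def test_union_sensitivity_with_predictor_noise(self):
        """With 5% per-predictor error, >= 1 - e^2 of true membrane proteins
        keep at least one TM call (TMHMM and Phobius err independently)."""
        cfg = SimConfig(n_genes=4000, predictor_error_rate=0.05, seed=41)
        uni = generate_universe(cfg)
        ev = generate_predictor_tables(uni).set_index("protein_id")
        mem = uni.truth.membrane
        hit = (
            (ev.loc[mem, "tmhmm_tm_count"] >= 1)
            | (ev.loc[mem, "phobius_tm_count"] >= 1)
            | (ev.loc[mem, "wolfpsort_loc"] == "plasma_membrane")
        )
        assert hit.mean() >= 1 - 0.05**2 - 0.01
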