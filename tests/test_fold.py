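import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpfold.fold import (
    EnergyModel,
    SequenceError,
    enumerate_structures,
    normalize_sequence,
    partition_function,
    prob_interval_unpaired,
)

from conftest import random_rna
from oracles import count_structures


class TestNormalization:
    def test_t_maps_to_u_and_case_folds(self):
        assert normalize_sequence("acgt") == "ACGU"

    @pytest.mark.parametrize("bad", ["ACGN", "ACG-", "", "AXU"])
    def test_rejects_non_acgu(self, bad):
        with pytest.raises(SequenceError):
            normalize_sequence(bad)

    def test_dna_and_rna_spellings_fold_identically(self, model):
        assert (
            partition_function("GGGATTTCCC", model).log_Z
            == partition_function("GGGAUUUCCC", model).log_Z
        )


class TestPartitionFunction:
    def test_pair_free_sequences_have_unit_partition(self, model):
        # no canonical pair is possible in poly-A
        r = partition_function("AAAAA", model)
        assert r.Z == 1.0 and r.G == 0.0

    def test_min_hairpin_loop_forbids_short_range_pair(self, model):
        # GC could pair but the loop would have 0 unpaired bases
        assert partition_function("GC", model).Z == 1.0

    def test_single_admissible_pair(self, model):
        # GAAAC: open chain + one G-C pair at -3 kcal/mol
        z = partition_function("GAAAC", model).Z
        assert z == pytest.approx(1.0 + math.exp(3.0 / model.kT), rel=1e-12)

    def test_constraint_out_of_range_raises(self, model):
        with pytest.raises(IndexError):
            partition_function("GAAAC", model, constraints=[5])

    def test_matches_enumeration_on_toy(self, model):
        z_enum = sum(
            math.exp(-e / model.kT) for _, e in enumerate_structures("GGGAAAACCC", model)
        )
        assert partition_function("GGGAAAACCC", model).Z == pytest.approx(
            z_enum, rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_on_random_sequences(self, seed, model, stack_model):
        """DP equals brute-force enumeration, with and without constraints."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 17))
        seq = random_rna(rng, n)
        cons = list(np.flatnonzero(rng.random(n) < 0.25))
        for m in (model, stack_model):
            z_enum = sum(
                math.exp(-e / m.kT) for _, e in enumerate_structures(seq, m, cons)
            )
            z_dp = partition_function(seq, m, cons).Z
            assert z_dp == pytest.approx(z_enum, rel=1e-9)

    def test_overflow_fallback_handles_gc_rich_long_sequences(self, model):
        # a 401-nt near-perfect helix saturates float64 without rescaling
        g = partition_function("G" * 200 + "AAAAA" + "C" * 200, model).G
        assert math.isfinite(g) and g < -500


class TestConstraintMonotonicity:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_forcing_a_base_unpaired_never_increases_z(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_rna(rng, int(rng.integers(10, 31)))
        model = EnergyModel()
        cons: list[int] = []
        prev = partition_function(seq, model).log_Z
        for pos in rng.permutation(len(seq))[:5]:
            cons.append(int(pos))
            cur = partition_function(seq, model, cons).log_Z
            assert cur <= prev + 1e-12
            prev = cur


class TestProbIntervalUnpaired:
    def test_unstructured_sequence_is_fully_open(self, model):
        assert prob_interval_unpaired("AAAAAAA", (0, 7), model) == 1.0

    def test_empty_interval_probability_is_one(self, model):
        assert prob_interval_unpaired("GGGAAAACCC", (4, 4), model) == 1.0

    def test_matches_enumeration_ratio(self, model):
        seq = "GGGAAAACCC"
        z0 = sum(math.exp(-e / model.kT) for _, e in enumerate_structures(seq, model))
        zc = sum(
            math.exp(-e / model.kT)
            for _, e in enumerate_structures(seq, model, constraints=range(3, 7))
        )
        assert prob_interval_unpaired(seq, (3, 7), model) == pytest.approx(
            zc / z0, rel=1e-9
        )

    def test_nesting_larger_interval_is_less_likely_open(self, model):
        rng = np.random.default_rng(3)
        seq = random_rna(rng, 30)
        p_outer = prob_interval_unpaired(seq, (5, 15), model)
        p_inner = prob_interval_unpaired(seq, (7, 12), model)
        assert 0 < p_outer <= p_inner <= 1

    @pytest.mark.parametrize("interval", [(5, 3), (-1, 4), (0, 99)])
    def test_bad_intervals_raise(self, interval, model):
        with pytest.raises(IndexError):
            prob_interval_unpaired("GGGAAAACCC", interval, model)


class TestEnumeration:
    def test_pair_free_only_for_polya(self, model):
        assert len(enumerate_structures("AAAA", model)) == 1

    def test_gaaac_has_exactly_two_structures(self, model):
        structures = enumerate_structures("GAAAC", model)
        assert sorted(s for s, _ in structures) == [(), ((0, 4),)]

    @pytest.mark.parametrize(
        "seq", ["GGAAACC", "GGGAAAACCC", "GCGCAAAGCGC", "AUAUGGAAAACCAU"]
    )
    def test_count_agrees_with_independent_recurrence(self, seq, model):
        assert len(enumerate_structures(seq, model)) == count_structures(seq)

    def test_refuses_long_sequences(self, model):
        with pytest.raises(ValueError):
            enumerate_structures("A" * 26, model)


class TestViennaBackend:
    """Smoke tests of the Turner-parameter adapter (comparative, not exact)."""

    def test_ensemble_free_energy_is_negative_for_hairpin(self):
        pytest.importorskip("RNA")
        m = EnergyModel(backend="vienna")
        g = partition_function("GGGGGAAAAAAACCCCC", m).G
        assert g < 0

    def test_unpaired_probability_reflects_hairpin_structure(self):
        pytest.importorskip("RNA")
        m = EnergyModel(backend="vienna")
        helix = "GGGGGAAAAAAACCCCC"
        p_stem = prob_interval_unpaired(helix, (0, 5), m)
        p_loop = prob_interval_unpaired(helix, (6, 11), m)
        assert 0 < p_stem < p_loop <= 1
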