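import itertools
import math

import numpy as np
import pytest

from snpfold.binding import (
    AffinityTable,
    BindingMode,
    affinity_ratio,
    ddG,
    effective_kd,
    opening_free_energy,
)
from snpfold.fold import BASES, prob_interval_unpaired

from conftest import make_table, random_rna
from oracles import kd_eff_bound_states


class TestOpeningFreeEnergy:
    def test_unstructured_footprint_costs_nothing(self, model):
        r = opening_free_energy("AAAAAAA", (0, 7), model)
        assert r.p_open == 1.0 and r.dG_open == 0.0

    def test_dg_is_minus_kt_log_p(self, model):
        seq = "GGGGAAAAAAACCCC"
        r = opening_free_energy(seq, (2, 9), model)
        assert r.dG_open == pytest.approx(-model.kT * math.log(r.p_open), rel=1e-12)
        assert 0 < r.p_open < 1 and r.dG_open > 0

    def test_matches_unpaired_probability(self, model):
        seq = "GGGGAAAAAAACCCC"
        r = opening_free_energy(seq, (2, 9), model)
        assert r.p_open == pytest.approx(
            prob_interval_unpaired(seq, (2, 9), model), rel=1e-12
        )


class TestDdG:
    def test_identical_alleles_give_zero(self, model):
        assert ddG("GGGAAAACCC", "GGGAAAACCC", (3, 7), model) == 0.0

    def test_polya_context_gives_zero(self, model):
        wt = "A" * 21
        mut = wt[:10] + "C" + wt[11:]
        assert ddG(wt, mut, (2, 9), model) == 0.0

    def test_antisymmetry(self, model):
        rng = np.random.default_rng(5)
        for _ in range(10):
            wt = random_rna(rng, 31)
            pos = int(rng.integers(0, 31))
            alt = str(rng.choice([b for b in BASES if b != wt[pos]]))
            mut = wt[:pos] + alt + wt[pos + 1 :]
            fwd = ddG(wt, mut, (10, 17), model)
            rev = ddG(mut, wt, (10, 17), model)
            assert abs(fwd + rev) <= 1e-12

    def test_rejects_multi_position_differences(self, model):
        with pytest.raises(ValueError):
            ddG("AAAAAAAA", "CCAAAAAA", (0, 4), model)


class TestAffinityTable:
    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError):
            AffinityTable({"AAA": 1.0}, k=3)

    def test_nonpositive_kd_rejected(self):
        kd = {"".join(t): 1.0 for t in itertools.product(BASES, repeat=2)}
        kd["AA"] = 0.0
        with pytest.raises(ValueError):
            AffinityTable(kd, k=2)

    def test_tsv_round_trip_is_bit_exact(self, tmp_path, table3):
        path = tmp_path / "table.tsv"
        t = make_table(3, fill=0.1 + 1 / 3, special={"UUU": math.inf, "AAA": 7e-23})
        t.to_tsv(path)
        back = AffinityTable.from_tsv(path)
        assert back.kd == t.kd  # exact float equality, inf included

    def test_scaled_copy(self, table3):
        s = table3.scaled(3.0)
        assert s["ACG"] == table3["ACG"] * 3.0


class TestEffectiveKd:
    def test_single_accessible_motif_recovers_table_kd(self, model):
        motif = "ACAAACA"  # A/C only: no canonical pair with poly-A or itself
        seq = "A" * 10 + motif + "A" * 10
        table = make_table(7, fill=math.inf, special={motif: 10.0})
        assert effective_kd(seq, table, model) == pytest.approx(10.0, rel=1e-12)

    def test_two_disjoint_motif_copies_halve_kd(self, model):
        motif = "ACAAACA"
        seq = "A" * 5 + motif + "A" * 7 + motif + "A" * 5
        table = make_table(7, fill=math.inf, special={motif: 10.0})
        assert effective_kd(seq, table, model) == pytest.approx(5.0, rel=1e-12)

    def test_fully_open_limit_is_harmonic_sum(self, model, table3):
        seq = "ACAACCACA"  # admits no canonical pair
        inv = sum(1.0 / table3[seq[i : i + 3]] for i in range(len(seq) - 2))
        assert effective_kd(seq, table3, model) == pytest.approx(1.0 / inv, rel=1e-12)

    def test_table_scale_invariance(self, model, table3):
        rng = np.random.default_rng(8)
        seq = random_rna(rng, 20)
        k1 = effective_kd(seq, table3, model)
        k2 = effective_kd(seq, table3.scaled(2.5), model)
        assert k2 == pytest.approx(2.5 * k1, rel=1e-12)

    def test_bounds(self, model, table3):
        rng = np.random.default_rng(9)
        for _ in range(5):
            seq = random_rna(rng, 16)
            keff = effective_kd(seq, table3, model)
            kmers = [seq[i : i + 3] for i in range(len(seq) - 2)]
            lower = 1.0 / sum(1.0 / table3[w] for w in kmers)
            upper = min(
                table3[seq[i : i + 3]]
                / prob_interval_unpaired(seq, (i, i + 3), model)
                for i in range(len(seq) - 2)
            )
            assert lower - 1e-12 <= keff <= upper + 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bound_state_enumeration_oracle(self, seed, model, table3):
        """Dilute-limit closed form vs explicit bound-state statistics."""
        rng = np.random.default_rng(seed)
        seq = random_rna(rng, int(rng.integers(10, 17)))
        oracle = kd_eff_bound_states(seq, table3, model)
        assert effective_kd(seq, table3, model) == pytest.approx(oracle, rel=1e-9)
        mode = BindingMode.single_site(int(rng.integers(0, len(seq) - 2)), 3)
        oracle_ss = kd_eff_bound_states(seq, table3, model, mode)
        assert effective_kd(seq, table3, model, mode) == pytest.approx(
            oracle_ss, rel=1e-9
        )

    def test_all_nonbinders_give_infinite_kd(self, model):
        table = make_table(3, fill=math.inf)
        assert effective_kd("AAAAAA", table, model) == math.inf


class TestAffinityRatio:
    def test_unstructured_context_is_neutral(self, model, table3):
        # A<->C substitution in a pair-free window with a uniform table:
        # no structure change and no sequence preference, so ratio 1
        table = make_table(3, fill=5.0)
        ref = "ACAACCACA"
        alt = "ACAAACACA"
        assert affinity_ratio(ref, alt, table, model) == pytest.approx(1.0, rel=1e-12)

    def test_reciprocity(self, model, table3):
        rng = np.random.default_rng(21)
        ref = random_rna(rng, 25)
        pos = 12
        alt_base = str(rng.choice([b for b in BASES if b != ref[pos]]))
        alt = ref[:pos] + alt_base + ref[pos + 1 :]
        fwd = affinity_ratio(ref, alt, table3, model)
        rev = affinity_ratio(alt, ref, table3, model)
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_stem_switch_direction(self, model):
        from snpfold.simulate import gen_affinity_table, gen_planted_switch

        table = gen_affinity_table(seed=1)
        for seed in range(3):
            sw = gen_planted_switch(seed, "gt", L=101)
            mode = BindingMode.single_site(sw.motif_interval[0], 7)
            r = affinity_ratio(sw.sequence, sw.alt_sequence, table, model, mode)
            assert r > 1.0

    def test_single_site_ratio_consistent_with_ddg(self, model):
        """With a sequence-independent table, kT*ln(ratio) equals ddG."""
        table = make_table(7, fill=20.0)
        rng = np.random.default_rng(4)
        ref = random_rna(rng, 41)
        pos = 20
        alt_base = str(rng.choice([b for b in BASES if b != ref[pos]]))
        alt = ref[:pos] + alt_base + ref[pos + 1 :]
        interval = (5, 12)
        mode = BindingMode.single_site(5, 7)
        r = affinity_ratio(ref, alt, table, model, mode)
        assert model.kT * math.log(r) == pytest.approx(
            ddG(ref, alt, interval, model), abs=1e-9
        )
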