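"""Energy terms, annealing design and protocol comparison."""

import numpy as np
import pytest

import rescue
from rescue import (
    AnnealSchedule,
    ParameterError,
    Profile,
    coupling_term,
    design_sequences,
    enumerate_exact,
    native_bias_term,
    profile_term,
    protocol_comparison,
    sample_model,
)
from conftest import make_toy_model


class TestTerms:
    def test_zero_weight_contributes_nothing(self, toy_model):
        t = coupling_term(toy_model, 0.0)
        assert t.full(np.array([0, 0, 0])) == 0.0

    def test_coupling_energy_is_minus_cs(self, toy_model):
        t = coupling_term(toy_model, 1.0)
        assert t.full(np.array([0, 0, 0])) == pytest.approx(-3.0)

    def test_profile_hand_sums(self):
        prof = Profile(scores=np.arange(60).reshape(3, 20).astype(float))
        t = profile_term(prof, 2.0)
        t.bind("ACDEFGHIKLMNPQRSTVWY", 3)
        states = np.array([0, 1, 19])  # A, C, Y -> scores 0, 21, 59
        assert t.full(states) == pytest.approx(-2.0 * (0 + 21 + 59))
        assert t.delta(states, 2, 0) == pytest.approx(-2.0 * (40 - 59))

    def test_profile_all_zero(self):
        prof = Profile(scores=np.zeros((4, 20)))
        t = profile_term(prof, 3.0)
        t.bind("ACDEFGHIKLMNPQRSTVWY", 4)
        assert t.full(np.array([3, 1, 4, 1])) == 0.0

    def test_native_bias_counts_matches(self):
        nat = np.array([0, 1, 2, 3])
        t = native_bias_term(nat, 2.0)
        assert t.full(nat) == -8.0
        assert t.full(np.array([4, 4, 4, 4])) == 0.0
        assert t.full(np.array([0, 1, 4, 4])) == -4.0

    def test_negative_weight_rejected(self, toy_model):
        with pytest.raises(ParameterError):
            coupling_term(toy_model, -1.0)

    @pytest.mark.parametrize("term_kind", ["coupling", "profile", "native"])
    def test_delta_consistency_along_mutation_path(self, term_kind):
        # incremental updates along a random path reproduce full recompute
        rng = np.random.default_rng(7)
        m = sample_model(8, 5, 6, seed=9)
        if term_kind == "coupling":
            t = coupling_term(m, 1.3)
        elif term_kind == "profile":
            prof = Profile(scores=rng.normal(0, 1, (8, 20)))
            t = profile_term(prof, 0.7)
            t.bind(m.alphabet, 8)
        else:
            t = native_bias_term(rng.integers(0, 5, 8), 1.1)
        states = rng.integers(0, 5, 8)
        t.init_cache(states)
        energy = t.full(states)
        for _ in range(60):
            pos = int(rng.integers(8))
            new = int(rng.integers(5))
            energy += t.delta(states, pos, new)
            t.commit(states, pos, new)
            states[pos] = new
        t2 = type(t).__new__(type(t))
        t2.__dict__.update(t.__dict__)
        t2.init_cache(states)
        assert energy == pytest.approx(t.full(states), abs=1e-9)


class TestSchedule:
    def test_temperatures_positive_non_increasing(self):
        temps = AnnealSchedule(steps=100).temperatures(10)
        assert len(temps) == 100
        assert np.all(temps > 0)
        assert np.all(np.diff(temps) <= 0)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            AnnealSchedule(t_initial=0.0)
        with pytest.raises(ParameterError):
            AnnealSchedule(t_initial=0.1, t_final=1.0)


class TestDesign:
    def test_dominant_native_bias_recovers_native(self):
        m = sample_model(6, 4, 4, seed=1)
        nat = np.array([0, 1, 2, 3, 0, 1])
        designs = design_sequences([native_bias_term(nat, 1000.0)],
                                   6, m.alphabet, n_designs=3, seed=0)
        assert all(d.sequence == m.decode(nat) for d in designs)

    def test_tiny_landscape_matches_enumeration(self):
        # L=4, q=3: exhaustive argmax of cs over all 81 sequences
        m = sample_model(4, 3, 3, seed=2)
        ex = enumerate_exact(m)
        best_cs = ex.cs_values.max()
        res = design_sequences([coupling_term(m, 1.0)], 4, m.alphabet,
                               n_designs=2, seed=3, model=m)
        assert -res[0].total_energy == pytest.approx(best_cs)

    def test_same_seed_bit_stable(self):
        m = sample_model(6, 4, 4, seed=4)
        kwargs = dict(length=6, alphabet=m.alphabet, n_designs=4, seed=5,
                      model=m)
        a = design_sequences([coupling_term(m, 1.0)], **kwargs)
        b = design_sequences([coupling_term(m, 1.0)], **kwargs)
        assert [d.sequence for d in a] == [d.sequence for d in b]
        assert [d.total_energy for d in a] == [d.total_energy for d in b]

    def test_breakdown_sums_to_total_and_is_reproducible(self):
        m = sample_model(6, 4, 4, seed=6)
        nat = m.decode(np.zeros(6, dtype=int))
        designs = design_sequences(
            [coupling_term(m, 0.8), native_bias_term(m.encode(nat), 0.3)],
            6, m.alphabet, n_designs=2, seed=7, model=m, native=nat)
        for d in designs:
            assert sum(d.breakdown.values()) == pytest.approx(
                d.total_energy, abs=1e-9)
            t = coupling_term(m, 0.8)
            assert t.full(d.states) == pytest.approx(
                d.breakdown["coupling"], abs=1e-9)

    def test_frozen_positions_untouched(self):
        m = sample_model(8, 4, 5, seed=8)
        start = np.zeros(8, dtype=int)
        designs = design_sequences([coupling_term(m, 1.0)], 8, m.alphabet,
                                   n_designs=2, seed=9, start=start,
                                   designable={2, 3, 4})
        for d in designs:
            assert d.sequence[:2] == m.decode(start[:2])
            assert d.sequence[5:] == m.decode(start[5:])

    def test_empty_designable_set_raises(self):
        m = sample_model(4, 3, 2, seed=0)
        with pytest.raises(ParameterError):
            design_sequences([coupling_term(m, 1.0)], 4, m.alphabet,
                             designable=set())

    def test_results_sorted_by_energy(self):
        m = sample_model(6, 4, 5, seed=10)
        designs = design_sequences([coupling_term(m, 1.0)], 6, m.alphabet,
                                   n_designs=5, seed=11)
        energies = [d.total_energy for d in designs]
        assert energies == sorted(energies)

    def test_gap_never_designed(self):
        m = sample_model(6, 21, 5, seed=12)
        designs = design_sequences([coupling_term(m, 1.0)], 6, m.alphabet,
                                   n_designs=3, seed=13)
        assert all("-" not in d.sequence for d in designs)


class TestProtocols:
    def test_report_shape_and_rows(self):
        bench = rescue.make_benchmark(10, 4, 6, M=100, seed=1)
        profile = rescue.profile_from_alignment(bench.alignment)
        ensembles, rep = protocol_comparison(
            bench.model, bench.native, profile=profile, n_designs=3, seed=2)
        assert set(ensembles) == {"plain", "profile", "favornative",
                                  "rescue"}
        assert len(rep) == 4 * 3

    def test_mean_crs_non_decreasing_in_coupling_weight(self):
        # averaged over 5 seeds on fixed benchmarks, a stronger coupling
        # bias never lowers mean ensemble crs on the rising flank
        rows = []
        for seed in range(5):
            bench = rescue.make_benchmark(20, 8, 15, M=200, seed=seed)
            sw = rescue.weight_sweep(bench.model, bench.native,
                                     weights=(0.02, 0.1, 0.5),
                                     n_designs=6, seed=seed + 10)
            rows.append(list(sw.mean_crs))
        avg = np.mean(rows, axis=0)
        assert np.all(np.diff(avg) >= 0)

    def test_coupling_protocol_beats_plain_on_nsr(self):
        # natives are low-energy sequences of the true model, so coupling-
        # biased design recovers more native residues than unbiased design
        vals = {"plain": [], "rescue": []}
        for seed in range(3):
            bench = rescue.make_benchmark(16, 6, 12, M=160, seed=40 + seed)
            _, rep = protocol_comparison(
                bench.model, bench.native, n_designs=6, seed=seed,
                protocols=("plain", "rescue"))
            for p in vals:
                vals[p].append(rep[rep.protocol == p].nsr.mean())
        assert np.mean(vals["rescue"]) > np.mean(vals["plain"])
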