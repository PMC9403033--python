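"""Feature extraction, mutation threading, prediction, unit conversion."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ppaffinity as ppa
from ppaffinity.dataset import ComplexFeaturizer
from ppaffinity.environment import classify_exposure, relative_sas
from ppaffinity.errors import MutationMismatchError
from ppaffinity.model import (
    FeatureVector,
    N_COMBINED_CLASSES,
    N_INTERFACIAL_CATEGORIES,
    N_NONINTERFACIAL_CATEGORIES,
    combined_class,
    interfacial_index,
    interfacial_pair_from_index,
    noninterfacial_index,
)

from conftest import brute_force_contacts


class TestCategoryEncoding:
    def test_interfacial_index_is_a_bijection(self):
        seen = set()
        for i in range(N_COMBINED_CLASSES):
            for j in range(i, N_COMBINED_CLASSES):
                idx = interfacial_index(i, j)
                assert 0 <= idx < N_INTERFACIAL_CATEGORIES
                assert idx not in seen
                seen.add(idx)
                assert interfacial_pair_from_index(idx) == (i, j)
        assert len(seen) == N_INTERFACIAL_CATEGORIES == 1830

    def test_interfacial_index_unordered(self):
        assert interfacial_index(7, 42) == interfacial_index(42, 7)

    def test_noninterfacial_space_size(self):
        idx = {
            noninterfacial_index(aa, ss, e)
            for aa in "ACDEFGHIKLMNPQRSTVWY"
            for ss in "HSL"
            for e in "BE"
        }
        assert idx == set(range(N_NONINTERFACIAL_CATEGORIES))
        assert N_NONINTERFACIAL_CATEGORIES == 120


def brute_force_features(cplx, featurizer, mutations=()):
    """Recompute the feature vector from raw coordinates and maps."""
    structure = ppa.thread_mutations(cplx, mutations) if mutations else cplx
    residues = {r.key: r for r in structure.residues}
    ss = featurizer.ss
    sas = featurizer._sas_map(structure)
    itf, nitf = {}, {}
    pairs = brute_force_contacts(structure, 5.0)
    members = set()
    for pair in pairs:
        a, b = sorted(pair)
        members |= {a, b}
        ca = combined_class(residues[a].aa_type, ss[a])
        cb = combined_class(residues[b].aa_type, ss[b])
        idx = interfacial_index(ca, cb)
        itf[idx] = itf.get(idx, 0) + 1
    for key, res in residues.items():
        if key in members:
            continue
        rel = relative_sas(res.aa_type, sas[key].sas_complex)
        idx = noninterfacial_index(res.aa_type, ss[key], classify_exposure(rel))
        nitf[idx] = nitf.get(idx, 0) + 1
    return itf, nitf


class TestExtractFeatures:
    def test_no_interface_means_only_noninterfacial(self):
        cplx, _ = ppa.make_complex(ppa.FixtureSpec(seed=7, interface_width=50.0), 0)
        fz = ComplexFeaturizer(cplx, n_points=120)
        fv = fz.features()
        assert fv.interfacial == {}
        assert fv.n_noninterfacial == len(cplx.residues)

    def test_matches_brute_force_oracle(self, small_fixture_complex):
        fz = ComplexFeaturizer(small_fixture_complex, n_points=120)
        fv = fz.features()
        itf, nitf = brute_force_features(small_fixture_complex, fz)
        assert fv.interfacial == itf
        assert fv.noninterfacial == nitf

    def test_count_conservation(self, small_fixture_complex):
        fz = ComplexFeaturizer(small_fixture_complex, n_points=120)
        fv = fz.features()
        n_interfacial = len(fz.contacts.interfacial_residues)
        assert fv.n_noninterfacial + n_interfacial == len(small_fixture_complex.residues)

    def test_roundtrip_serialization(self, small_fixture_complex):
        fz = ComplexFeaturizer(small_fixture_complex, n_points=120)
        fv = fz.features()
        buf = io.StringIO()
        fv.to_tsv(buf)
        buf.seek(0)
        back = FeatureVector.from_tsv(buf)
        assert back.complex_id == fv.complex_id
        assert back.interfacial == fv.interfacial
        assert back.noninterfacial == fv.noninterfacial


class TestThreadMutations:
    def test_empty_mutation_list_is_identity(self, small_fixture_complex):
        fz = ComplexFeaturizer(small_fixture_complex, n_points=120)
        assert fz.features(()).interfacial == fz.features().interfacial

    def test_wild_type_mismatch_raises(self, small_fixture_complex):
        res = small_fixture_complex.residues[0]
        wrong_wt = "W" if res.aa_type != "W" else "Y"
        mut = ppa.Mutation(res.chain_id, res.seq_number, wrong_wt, "G")
        with pytest.raises(MutationMismatchError):
            ppa.thread_mutations(small_fixture_complex, [mut])

    def test_geometry_is_retained(self, small_fixture_complex):
        res = small_fixture_complex.residues[0]
        target = "G" if res.aa_type != "G" else "A"
        mut = ppa.Mutation(res.chain_id, res.seq_number, res.aa_type, target)
        threaded = ppa.thread_mutations(small_fixture_complex, [mut])
        assert threaded.residues[0].aa_type == target
        np.testing.assert_array_equal(
            threaded.residues[0].atoms[0].position,
            small_fixture_complex.residues[0].atoms[0].position,
        )

    def test_single_mutation_changes_only_local_categories(self, small_fixture_complex):
        fz = ComplexFeaturizer(small_fixture_complex, n_points=120)
        base = fz.features()
        # pick a non-interfacial residue
        res = next(
            r for r in small_fixture_complex.residues
            if r.key not in fz.contacts.interfacial_residues
        )
        target = "A" if res.aa_type != "A" else "V"
        mutated = fz.features((ppa.Mutation(res.chain_id, res.seq_number, res.aa_type,
                                            target, res.insertion_code),))
        assert mutated.interfacial == base.interfacial
        diff = {
            k: mutated.noninterfacial.get(k, 0) - base.noninterfacial.get(k, 0)
            for k in set(base.noninterfacial) | set(mutated.noninterfacial)
        }
        changed = {k: v for k, v in diff.items() if v != 0}
        assert sum(changed.values()) == 0
        assert len(changed) in (0, 2)  # one category loses, another gains

    def test_double_mutant_delta_is_sum_of_singles_when_remote(self, small_fixture_complex):
        fz = ComplexFeaturizer(small_fixture_complex, n_points=120)
        contacts5 = ppa.detect_contacts(small_fixture_complex, 5.0)
        non_if = [
            r for r in small_fixture_complex.residues
            if r.key not in contacts5.interfacial_residues
        ]
        r1, r2 = non_if[0], non_if[-1]
        m1 = ppa.Mutation(r1.chain_id, r1.seq_number, r1.aa_type,
                          "A" if r1.aa_type != "A" else "V", r1.insertion_code)
        m2 = ppa.Mutation(r2.chain_id, r2.seq_number, r2.aa_type,
                          "S" if r2.aa_type != "S" else "T", r2.insertion_code)

        def counts(features):
            return features.noninterfacial

        base = counts(fz.features())
        single1 = counts(fz.features((m1,)))
        single2 = counts(fz.features((m2,)))
        double = counts(fz.features((m1, m2)))
        keys = set(base) | set(single1) | set(single2) | set(double)
        for k in keys:
            delta_double = double.get(k, 0) - base.get(k, 0)
            delta_sum = (single1.get(k, 0) - base.get(k, 0)) + (single2.get(k, 0) - base.get(k, 0))
            assert delta_double == delta_sum


class TestPredictAffinity:
    def test_zero_weights_give_zero(self, small_fixture_complex):
        fz = ComplexFeaturizer(small_fixture_complex, n_points=120)
        assert ppa.predict_affinity(fz.features(), ppa.WeightVector.zeros()) == 0.0

    def test_wn_zero_uses_only_interfacial_term(self, small_fixture_complex):
        fz = ComplexFeaturizer(small_fixture_complex, n_points=120)
        fv = fz.features()
        rng = np.random.default_rng(0)
        weights = ppa.WeightVector.random(rng, w_n=0.0)
        expected = sum(c * weights.w_itf[i] for i, c in fv.interfacial.items())
        assert ppa.predict_affinity(fv, weights) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_dot_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_itf = rng.integers(0, 8)
        n_nitf = rng.integers(0, 8)
        fv = FeatureVector(
            "h",
            {int(k): int(c) for k, c in zip(
                rng.choice(1830, size=n_itf, replace=False), rng.integers(1, 5, n_itf))},
            {int(k): int(c) for k, c in zip(
                rng.choice(120, size=n_nitf, replace=False), rng.integers(1, 5, n_nitf))},
        )
        weights = ppa.WeightVector.random(rng, w_n=float(rng.uniform(0, 1)))
        total = 0.0
        for idx, count in fv.interfacial.items():
            total += count * weights.w_itf[idx]
        acc = 0.0
        for idx, count in fv.noninterfacial.items():
            acc += count * weights.w_nitf[idx]
        total += weights.w_n * acc
        assert ppa.predict_affinity(fv, weights) == pytest.approx(total, abs=1e-12)


class TestKdToDg:
    def test_one_molar_is_zero(self):
        assert ppa.kd_to_dg(1.0) == 0.0

    def test_nanomolar_closed_form(self):
        assert ppa.kd_to_dg(1e-9, 298.0) == pytest.approx(
            0.0019872 * 298.0 * math.log(1e-9), abs=1e-12
        )

    def test_halving_kd_strengthens_by_rt_ln2(self):
        d = ppa.kd_to_dg(1e-6) - ppa.kd_to_dg(5e-7)
        assert d == pytest.approx(0.0019872 * 298.0 * math.log(2.0), abs=1e-12)

    def test_nonpositive_kd_raises(self):
        with pytest.raises(ValueError):
            ppa.kd_to_dg(0.0)


class TestWeightSerialization:
    def test_roundtrip(self):
        rng = np.random.default_rng(5)
        weights = ppa.WeightVector.random(rng, w_n=0.35)
        buf = io.StringIO()
        weights.to_tsv(buf)
        buf.seek(0)
        back = ppa.WeightVector.from_tsv(buf)
        np.testing.assert_array_equal(back.w_itf, weights.w_itf)
        np.testing.assert_array_equal(back.w_nitf, weights.w_nitf)
        assert back.w_n == weights.w_n


class TestMutationParsing:
    @pytest.mark.parametrize("text,expected", [
        ("AL33G", ("A", "L", 33, "", "G")),
        ("BW12A", ("B", "W", 12, "", "A")),
        ("AD100aE", ("A", "D", 100, "a", "E")),
    ])
    def test_parse(self, text, expected):
        m = ppa.parse_mutation(text)
        assert (m.chain_id, m.wild_aa, m.seq_number, m.insertion_code, m.mutant_aa) == expected

    def test_rejects_garbage(self):
        with pytest.raises(ValueError):
            ppa.parse_mutation("notamutation")
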