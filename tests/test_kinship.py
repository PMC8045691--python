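"""Tabular partial relationship matrices and genotypic variances."""

import numpy as np
import pytest

import polyblup as pb
from polyblup.kinship import COMPONENTS, ONE_BREED, VarianceComponents
from polyblup.pedigree import Individual, Pedigree

from conftest import random_pedigree


class TestChainCoefficients:
    """Hand-derived recursion values on the canonical backcross chain."""

    def test_unrelated_founders_have_zero_offdiagonals(self, chain_kinship):
        for q in COMPONENTS:
            assert chain_kinship.coefficient(q, "D1", "V0") == 0
            assert chain_kinship.coefficient(q, "V0", "V1") == 0

    def test_f1_diagonals(self, chain_kinship):
        assert chain_kinship.coefficient("D", "F1") == pytest.approx(0.5)
        assert chain_kinship.coefficient("T", "F1") == pytest.approx(0.5)
        assert chain_kinship.coefficient("V", "F1") == pytest.approx(0.5)
        # both parents purebred: no segregation at the F1
        assert chain_kinship.coefficient("DV", "F1") == 0
        assert chain_kinship.coefficient("TV", "F1") == 0

    def test_bc1_segregation_diagonals(self, chain_kinship):
        # crossbred parent F1 has f_D = f_T = f_V = 1/2:
        # a_DV = 2*(1/2)*(1/2) = 1/2, a_TV = 4*(1/2)*(1/2) = 1
        assert chain_kinship.coefficient("DV", "BC1") == pytest.approx(0.5)
        assert chain_kinship.coefficient("TV", "BC1") == pytest.approx(1.0)

    def test_synthetic_diagonal(self, chain_kinship):
        assert chain_kinship.coefficient("D", "S1") == pytest.approx(1.0)
        assert chain_kinship.coefficient("T", "S1") == pytest.approx(1.0)
        assert chain_kinship.coefficient("V", "S1") == 0


def test_onebreed_matches_hand_tabular_values():
    # three-generation purebred pedigree, classical numerator matrix
    ped = Pedigree([
        Individual("P1", None, None, "V"),
        Individual("P2", None, None, "V"),
        Individual("P3", None, None, "V"),
        Individual("C1", "P1", "P2", "V"),
        Individual("C2", "P1", "P3", "V"),
        Individual("X", "C1", "C2", "V"),
    ])
    pk = pb.build_partial_matrices(ped)
    a = pk.onebreed
    i = {v: k for k, v in enumerate(ped.ids)}
    assert a[i["C1"], i["C2"]] == pytest.approx(0.25)
    assert a[i["X"], i["X"]] == pytest.approx(1.125)
    assert a[i["X"], i["C1"]] == pytest.approx(0.625)
    assert a[i["X"], i["P1"]] == pytest.approx(0.5)
    # on an all-V pedigree the V component equals the one-breed matrix
    np.testing.assert_allclose(pk.components["V"], a)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_psd_on_support(seed):
    pk = pb.build_partial_matrices(random_pedigree(seed))
    for q in COMPONENTS + (ONE_BREED,):
        _, sub = pk.restricted(q)
        if sub.size == 0:
            continue
        ev = np.linalg.eigvalsh(sub)
        assert ev.min() >= -1e-8 * max(ev.max(), 1.0)


@pytest.mark.parametrize("seed", [0, 5])
def test_component_sum_identity(seed):
    # sum_Q a_Q(i,i) sigma2_Q equals the genotypic-variance total for
    # arbitrary non-negative components
    ped = random_pedigree(seed)
    pk = pb.build_partial_matrices(ped)
    rng = np.random.default_rng(seed)
    vc = VarianceComponents(*rng.uniform(0, 2, 5))
    gv = pb.genotypic_variance(ped, vc, pk)
    sig = vc.genetic
    expected = sum(np.diag(pk.components[q]) * sig[q] for q in COMPONENTS)
    np.testing.assert_allclose(gv["total"].to_numpy(), expected)
    np.testing.assert_allclose(
        gv["total"], gv["additive"] + gv["segregation"])


def test_unrelated_chain_diagonals_equal_fractions(chain_ped, chain_kinship):
    # with unrelated non-inbred parents the pure-component diagonal of a
    # derivative reduces to its breed fraction
    fr = pb.breed_fractions(chain_ped)
    for ct in ("F1", "BC1", "BC2", "BC3"):
        for q in ("D", "T", "V"):
            assert chain_kinship.coefficient(q, ct) == pytest.approx(
                fr.loc[ct, f"f_{q}"])


def test_genotypic_variance_published_means(chain_ped, chain_kinship,
                                            sawyt_vc):
    gv = pb.genotypic_variance(chain_ped, sawyt_vc, chain_kinship)
    assert gv.loc["F1", "additive"] == pytest.approx(0.7055)
    assert gv.loc["F1", "segregation"] == 0
    assert gv.loc["BC1", "additive"] == pytest.approx(0.44375)
    assert gv.loc["BC1", "segregation"] == pytest.approx(0.4075)
    assert gv.loc["BC1", "total"] == pytest.approx(0.85125)
    # a non-inbred pure founder's total is exactly its breed variance
    assert gv.loc["D1", "total"] == pytest.approx(sawyt_vc.sigma2_D)
    assert gv.loc["V0", "total"] == pytest.approx(sawyt_vc.sigma2_V)


def test_negative_variance_rejected():
    with pytest.raises(ValueError):
        VarianceComponents(-0.1, 0.5, 0.5)


class TestSDoublingModes:
    def test_literal_doubles_s_entries(self, chain_ped):
        printed = pb.build_partial_matrices(chain_ped, s_doubling="printed")
        literal = pb.build_partial_matrices(chain_ped, s_doubling="literal")
        assert printed.coefficient("D", "S1") == pytest.approx(1.0)
        assert literal.coefficient("D", "S1") == pytest.approx(2.0)
        assert printed.coefficient("D", "S1", "D1") == pytest.approx(0.5)
        assert literal.coefficient("D", "S1", "D1") == pytest.approx(1.0)
        # entries not touching the doubling agree: V component identical
        np.testing.assert_allclose(printed.components["V"],
                                   literal.components["V"])
        # F1's own diagonal is insensitive to the rule
        assert literal.coefficient("D", "F1") == pytest.approx(
            printed.coefficient("D", "F1"))

    def test_invalid_mode_rejected(self, chain_ped):
        with pytest.raises(ValueError):
            pb.build_partial_matrices(chain_ped, s_doubling="bogus")


class TestTripletIO:
    def test_roundtrip_bitwise(self, tmp_path, chain_kinship):
        chain_kinship.write(tmp_path / "k")
        again = pb.read_matrices(tmp_path / "k")
        assert again.ids == chain_kinship.ids
        for q in COMPONENTS:
            np.testing.assert_array_equal(again.components[q],
                                          chain_kinship.components[q])
        np.testing.assert_array_equal(again.onebreed, chain_kinship.onebreed)

    def test_rewrite_is_identical(self, tmp_path, chain_kinship):
        chain_kinship.write(tmp_path / "a")
        chain_kinship.write(tmp_path / "b")
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_alien_id_rejected(self, tmp_path, chain_kinship):
        chain_kinship.write(tmp_path / "k")
        target = tmp_path / "k" / "A_D.txt"
        target.write_text(target.read_text() + "GHOST,D1,0.5\n")
        with pytest.raises(ValueError, match="GHOST"):
            pb.read_matrices(tmp_path / "k")

    def test_empty_support_roundtrip(self, tmp_path):
        # no synthetic ancestry at all: segregation supports are empty
        ped = Pedigree([
            Individual("V1", None, None, "V"),
            Individual("V2", None, None, "V"),
            Individual("X", "V1", "V2", "V"),
        ])
        pk = pb.build_partial_matrices(ped)
        assert not pk.support("DV").any()
        pk.write(tmp_path / "k")
        again = pb.read_matrices(tmp_path / "k")
        assert (again.components["DV"] == 0).all()
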