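"""Sørensen partition: pairwise/multi-site/temporal components and UPGMA."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import summitveg as sv
from summitveg.beta import (
    average_linkage_cluster,
    component_distance_matrix,
    multisite_partition,
    pair_counts,
    pairwise_partition,
    temporal_partition,
)
from summitveg.community import CommunityMatrix, build_matrix
from summitveg.errors import DomainError, MatchingError, ValidationError
from conftest import random_incidence


def part_of(a, b, c):
    return pairwise_partition(sv.PairCounts(a, b, c))


class TestPairCounts:
    def test_identical_sites(self):
        v = np.ones(5)
        assert pair_counts(v, v) == sv.PairCounts(5, 0, 0)

    def test_disjoint_sites(self):
        assert pair_counts([1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]) == sv.PairCounts(0, 3, 3)

    def test_hand_set_arithmetic(self):
        # site1 = {X,Y,Z}, site2 = {Y,Z,W,V}
        species = ["X", "Y", "Z", "W", "V"]
        s1 = [1, 1, 1, 0, 0]
        s2 = [0, 1, 1, 1, 1]
        assert pair_counts(s1, s2) == sv.PairCounts(2, 1, 2)

    def test_both_empty_rejected(self):
        with pytest.raises(DomainError):
            pair_counts([0, 0], [0, 0])


class TestPairwisePartition:
    @pytest.mark.parametrize(
        "a,b,c,expected",
        [
            (5, 0, 0, (0.0, 0.0, 0.0)),
            (0, 3, 3, (1.0, 1.0, 0.0)),
            (3, 4, 0, (0.4, 0.0, 0.4)),
            (2, 2, 1, (3 / 7, 1 / 3, 3 / 7 - 1 / 3)),
        ],
    )
    def test_hand_evaluations(self, a, b, c, expected):
        p = part_of(a, b, c)
        assert (p.bsor, p.bsim, p.bsne) == pytest.approx(expected, abs=1e-15)

    def test_eq4_product_form_agrees(self):
        # bsne = (|b-c|/(2a+b+c)) * (a/(a+min(b,c)))
        for a, b, c in [(2, 2, 1), (1, 5, 2), (4, 0, 3), (3, 3, 3)]:
            p = part_of(a, b, c)
            prod = (abs(b - c) / (2 * a + b + c)) * (a / (a + min(b, c)))
            assert p.bsne == pytest.approx(prod, abs=1e-12)

    def test_empty_side_is_error(self):
        with pytest.raises(DomainError):
            sv.PairCounts(0, 0, 4)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(derandomize=True, max_examples=300)
    def test_additivity_bounds_symmetry(self, a, b, c):
        if a + b == 0 or a + c == 0:
            return
        p = part_of(a, b, c)
        q = part_of(a, c, b)
        assert abs(p.bsor - (p.bsim + p.bsne)) < 1e-12
        assert 0.0 <= p.bsim <= p.bsor <= 1.0
        assert (p.bsor, p.bsim, p.bsne) == (q.bsor, q.bsim, q.bsne)
        if b == c:
            assert p.bsne == pytest.approx(0.0, abs=1e-12)
        if min(b, c) == 0 and a > 0:
            assert p.bsim == 0.0


class TestMultisite:
    def test_two_sites_reduce_to_pairwise(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = random_incidence(rng, 2, 12)
            multi = multisite_partition(m)
            pair = pairwise_partition(pair_counts(m[0], m[1]))
            assert multi.bsor == pytest.approx(pair.bsor, abs=1e-12)
            assert multi.bsim == pytest.approx(pair.bsim, abs=1e-12)
            assert multi.bsne == pytest.approx(pair.bsne, abs=1e-12)

    def test_identical_sites_zero(self):
        m = np.tile(np.array([1, 1, 0, 1, 0, 1], dtype=bool), (4, 1))
        p = multisite_partition(m)
        assert (p.bsor, p.bsim, p.bsne) == (0.0, 0.0, 0.0)

    def test_nested_chain_is_pure_nestedness(self):
        # S1 ⊃ S2 ⊃ S3 ⊃ S4 with richness 8, 6, 4, 2
        m = np.zeros((4, 8), dtype=bool)
        for i, k in enumerate((8, 6, 4, 2)):
            m[i, :k] = True
        p = multisite_partition(m)
        assert p.bsim == 0.0
        assert p.bsne == pytest.approx(p.bsor, abs=1e-15)
        # frozen value from the exhaustive-pair brute force: sum_min=0,
        # sum_max=2+4+6+2+4+2=20, A=(8+6+4+2)-8=12
        assert p.bsor == pytest.approx(20 / 44, abs=1e-15)

    def test_empty_site_named(self):
        vals = pd.DataFrame([[1, 1], [0, 0]], index=["good", "bare"], columns=["a", "b"], dtype=float)
        sites = pd.DataFrame({"summit_id": ["g", "b"]}, index=["good", "bare"])
        with pytest.raises(DomainError, match="bare"):
            multisite_partition(CommunityMatrix(vals, sites, "incidence"))

    @given(st.integers(0, 2**31 - 1), st.integers(3, 8), st.integers(4, 15))
    @settings(derandomize=True, max_examples=100)
    def test_site_permutation_invariance(self, seed, n_sites, n_species):
        rng = np.random.default_rng(seed)
        m = random_incidence(rng, n_sites, n_species)
        p = multisite_partition(m)
        q = multisite_partition(m[rng.permutation(n_sites)])
        assert p.bsor == pytest.approx(q.bsor, abs=1e-12)
        assert p.bsim == pytest.approx(q.bsim, abs=1e-12)

    def test_cross_check_against_vegan(self, tmp_path):
        """Independent oracle: vegan's multi-site Sørensen triplet."""
        rng = np.random.default_rng(5)
        m = random_incidence(rng, 6, 12).astype(int)
        csv = tmp_path / "m.csv"
        pd.DataFrame(m).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.csv("{csv}"))
            r <- nestedbetasor(m)
            cat(sprintf("%.12f %.12f %.12f", r[["turnover"]], r[["nestedness"]], r[["sorensen"]]))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        bsim_r, bsne_r, bsor_r = map(float, out.stdout.split())
        p = multisite_partition(m)
        assert p.bsim == pytest.approx(bsim_r, abs=1e-10)
        assert p.bsne == pytest.approx(bsne_r, abs=1e-10)
        assert p.bsor == pytest.approx(bsor_r, abs=1e-10)


class TestTemporal:
    def _matrices(self, rows1, rows2, species=6):
        def build(rows, year):
            vals = pd.DataFrame(rows, dtype=float,
                                index=[f"GUL1:{a}:{year}" for a in ("N", "S")[: len(rows)]],
                                columns=[f"sp{i}" for i in range(species)])
            sites = pd.DataFrame(
                {"summit_id": "GUL1", "aspect": list("NS")[: len(rows)], "year": year},
                index=vals.index,
            )
            return CommunityMatrix(vals, sites, "incidence")
        return build(rows1, 2014), build(rows2, 2018)

    def test_identical_years_zero(self):
        m1, m2 = self._matrices([[1, 1, 1, 0, 0, 0]], [[1, 1, 1, 0, 0, 0]])
        (part,) = temporal_partition(m1, m2).values()
        assert (part.bsor, part.bsim, part.bsne) == (0.0, 0.0, 0.0)

    def test_pure_loss_is_pure_nestedness(self):
        # losing 2 of 6 species, no gains: zero turnover, positive nestedness
        m1, m2 = self._matrices([[1, 1, 1, 1, 1, 1]], [[1, 1, 1, 1, 0, 0]])
        (part,) = temporal_partition(m1, m2).values()
        assert part.bsim == 0.0
        assert part.bsne == pytest.approx(2 / 10, abs=1e-12) and part.bsne > 0

    def test_equal_swap_is_pure_turnover(self):
        m1, m2 = self._matrices([[1, 1, 1, 1, 0, 0]], [[1, 1, 0, 0, 1, 1]])
        (part,) = temporal_partition(m1, m2).values()
        assert part.bsne == pytest.approx(0.0, abs=1e-12)
        assert part.bsim > 0

    def test_orphan_site_listed(self):
        m1, m2 = self._matrices([[1, 1, 1, 0, 0, 0], [1, 0, 1, 0, 1, 0]], [[1, 1, 1, 0, 0, 0]])
        with pytest.raises(MatchingError, match="GUL1:S"):
            temporal_partition(m1, m2)


class TestDistanceMatrixAndClustering:
    def test_identical_sites_zero_matrix(self):
        vals = pd.DataFrame([[1, 1, 0], [1, 1, 0]], index=["s1", "s2"],
                            columns=list("abc"), dtype=float)
        sites = pd.DataFrame({"summit_id": ["x", "y"]}, index=vals.index)
        dm = component_distance_matrix(CommunityMatrix(vals, sites, "incidence"), "bsor")
        assert (dm.to_numpy() == 0).all()

    def test_disjoint_sites_full_turnover(self):
        vals = pd.DataFrame(np.eye(3), index=list("pqr"), columns=list("abc"))
        sites = pd.DataFrame({"summit_id": list("pqr")}, index=vals.index)
        dm = component_distance_matrix(CommunityMatrix(vals, sites, "incidence"), "bsim")
        off = dm.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off == 1.0).all()

    def test_nested_chain_zero_turnover_matrix(self):
        m = np.zeros((4, 8))
        for i, k in enumerate((8, 6, 4, 2)):
            m[i, :k] = 1.0
        vals = pd.DataFrame(m, index=list("wxyz"), columns=[f"s{i}" for i in range(8)])
        sites = pd.DataFrame({"summit_id": list("wxyz")}, index=vals.index)
        dm = component_distance_matrix(CommunityMatrix(vals, sites, "incidence"), "bsim")
        assert (dm.to_numpy() == 0).all()

    def test_two_leaves_merge_at_distance(self):
        d = pd.DataFrame([[0, 0.37], [0.37, 0]], index=["a", "b"], columns=["a", "b"])
        dend = average_linkage_cluster(d)
        assert dend.merge_heights.tolist() == [pytest.approx(0.37)]
        assert dend.to_newick() == "(a:0.185,b:0.185);"

    def test_three_site_hand_upgma(self):
        d = pd.DataFrame(
            [[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]],
            index=list("abc"), columns=list("abc"),
        )
        dend = average_linkage_cluster(d)
        assert dend.merge_heights.tolist() == pytest.approx([0.1, 0.5])

    def test_ultrametric_fixed_point(self):
        d = pd.DataFrame(
            [[0, 0.2, 0.6, 0.6],
             [0.2, 0, 0.6, 0.6],
             [0.6, 0.6, 0, 0.4],
             [0.6, 0.6, 0.4, 0]],
            index=list("abcd"), columns=list("abcd"),
        )
        dend = average_linkage_cluster(d)
        coph = dend.cophenetic()
        assert np.allclose(coph.loc[list("abcd"), list("abcd")].to_numpy(), d.to_numpy())

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            average_linkage_cluster(d)

    def test_newick_parses_and_is_ultrametric(self, default_survey, summit_table):
        import dendropy

        observations, _, _ = default_survey
        m = build_matrix(observations, grouping="aspect", year_filter=2014,
                         mode="incidence", summits=summit_table)
        dend = average_linkage_cluster(component_distance_matrix(m, "bsim"))
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert len(depths) == len(m.values)
        assert max(depths) - min(depths) < 1e-9
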