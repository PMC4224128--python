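"""Entropy decomposition: profiles, partitioning, refinement, filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oligodyn as od
from oligodyn.oligotyping import (
    DecompositionConfig,
    build_counts_matrix,
    collapse_reads,
    column_entropy,
    decompose_family,
    filter_min_substantive_abundance,
    initial_decompose,
    normalize_percent,
    refine,
)


def _reads(seqs_with_counts):
    """Expand {sequence: count} into a one-sample read dict."""
    reads = []
    for s, c in seqs_with_counts.items():
        reads.extend([s] * c)
    return {"s1": reads}


class TestColumnEntropy:
    def test_monomorphic_column_is_zero(self):
        h = column_entropy(["AAAA", "AAAA", "AAAA"])
        assert np.all(h == 0.0)

    def test_uniform_four_symbols_is_two_bits(self):
        h = column_entropy(["A", "C", "G", "T"])
        assert h[0] == pytest.approx(2.0)

    def test_three_to_one_split_matches_formula(self):
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        h = column_entropy(["A", "A", "A", "C"])
        assert h[0] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        counts=st.lists(
            st.tuples(st.sampled_from("ACGTN"), st.integers(1, 50)),
            min_size=1,
            max_size=5,
            unique_by=lambda t: t[0],
        )
    )
    def test_agrees_with_direct_histogram(self, counts):
        # oracle: direct -sum(p log2 p) over the symbol histogram
        reads = [sym for sym, c in counts for _ in range(c)]
        total = len(reads)
        p = np.array([c for _, c in counts]) / total
        expected = float(-(p * np.log2(p)).sum())
        assert column_entropy(reads)[0] == pytest.approx(expected, abs=1e-12)

    def test_weighted_counts_equal_expanded_reads(self):
        seqs = ["ACGT", "AGGT", "ACGA"]
        counts = [5, 3, 2]
        expanded = [s for s, c in zip(seqs, counts) for _ in range(c)]
        assert np.allclose(
            column_entropy(seqs, counts), column_entropy(expanded), atol=1e-12
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            column_entropy([])


class TestInitialDecompose:
    def test_identical_reads_form_one_group(self):
        reads = _reads({"ACGTACGT": 10})
        profile = column_entropy(["ACGTACGT"] * 10)
        oset = initial_decompose(reads, profile, DecompositionConfig())
        assert len(oset.oligotypes) == 1
        assert oset.oligotypes[0].total_count == 10

    def test_single_polymorphic_position_splits_in_two(self):
        base = "A" * 40
        other = base[:20] + "C" + base[21:]
        reads = _reads({base: 5, other: 5})
        profile = column_entropy([base] * 5 + [other] * 5)
        assert profile[20] == pytest.approx(1.0)
        with pytest.warns(UserWarning, match="polymorphic"):
            oset = initial_decompose(reads, profile, DecompositionConfig())
        assert len(oset.oligotypes) == 2
        assert {o.label for o in oset.oligotypes} == {"A", "C"}

    def test_partition_matches_brute_force_grouping(self, rng):
        # planted variation at positions 10 and 77 (0-based); oracle groups
        # reads exhaustively by their (pos10, pos77) base pair
        base = list("".join(rng.choice(list("ACGT"), size=100)))
        variants = []
        for b10, b77 in [("A", "A"), ("A", "C"), ("C", "A"), ("C", "C"), ("G", "T"), ("T", "G")]:
            v = base.copy()
            v[10], v[77] = b10, b77
            variants.append("".join(v))
        counts = {v: 10 + i for i, v in enumerate(variants)}
        reads = _reads(counts)
        all_reads = [s for s, c in counts.items() for _ in range(c)]
        profile = column_entropy(all_reads)
        oset = initial_decompose(reads, profile, DecompositionConfig())
        expected = {}
        for s in counts:
            expected.setdefault(s[10] + s[77], set()).add(s)
        got = {o.label: set(o.members) for o in oset.oligotypes}
        assert got == expected
        assert all(o.component_positions == (10, 77) for o in oset.oligotypes)


class TestRefine:
    def test_monomorphic_groups_are_a_fixed_point(self):
        reads = _reads({"AAAA": 6, "CCCC": 4})
        profile = column_entropy(["AAAA"] * 6 + ["CCCC"] * 4)
        oset = initial_decompose(reads, profile, DecompositionConfig())
        refined = refine(oset, DecompositionConfig())
        assert [(o.label, o.component_positions) for o in refined.oligotypes] == [
            (o.label, o.component_positions) for o in oset.oligotypes
        ]

    def test_hidden_position_split_after_one_pass(self):
        # two sub-variants hidden behind the initial components
        a = "AAGGAAAAAA"
        b = "AAGGAAAATA"  # differs at position 8 only
        c = "CCGGAAAAAA"
        reads = _reads({a: 6, b: 6, c: 12})
        all_reads = [s for s, n in [(a, 6), (b, 6), (c, 12)] for _ in range(n)]
        oset = initial_decompose(reads, column_entropy(all_reads), DecompositionConfig())
        # positions 0 and 8 carry the entropy; group (a,b) shares position 0
        refined = refine(oset, DecompositionConfig())
        labels = {frozenset(o.members) for o in refined.oligotypes}
        assert labels == {frozenset({a}), frozenset({b}), frozenset({c})}

    def test_refinement_only_splits_never_merges(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(8)]
        counts = {s: int(n) for s, n in zip(seqs, rng.integers(5, 40, size=8))}
        reads = _reads(counts)
        all_reads = [s for s, c in counts.items() for _ in range(c)]
        oset = initial_decompose(reads, column_entropy(all_reads), DecompositionConfig())
        refined = refine(oset, DecompositionConfig())
        prior = [set(o.members) for o in oset.oligotypes]
        for o in refined.oligotypes:
            containers = [p for p in prior if set(o.members) <= p]
            assert len(containers) == 1

    def test_converged_components_match_minimal_distinguishing_set(self):
        # 8 variants spanning all two-base combinations of 3 planted positions;
        # oracle: exhaustive search for the smallest distinguishing position set
        base = list("A" * 50)
        planted = [7, 21, 38]
        variants = []
        for combo in itertools.product("AG", repeat=3):
            v = base.copy()
            for pos, b in zip(planted, combo):
                v[pos] = b
            variants.append("".join(v))
        counts = {v: 20 for v in variants}
        reads = _reads(counts)
        oset = decompose_family(
            "fam", reads, DecompositionConfig(min_substantive_abundance=1)
        )
        assert len(oset.oligotypes) == 8
        assert all(set(o.component_positions) == set(planted) for o in oset.oligotypes)

        minimal = None
        for k in range(1, 4):
            for subset in itertools.combinations(range(50), k):
                labels = {tuple(v[p] for p in subset) for v in variants}
                if len(labels) == len(variants):
                    minimal = subset
                    break
            if minimal:
                break
        assert len(minimal) == len(oset.oligotypes[0].component_positions)

    def test_label_consistency_invariant(self, toy_dataset):
        mf = od.read_manifest(toy_dataset["manifest"])
        from oligodyn.prep import prepare
        from oligodyn.pipeline import classify_readset_families

        readset, _ = prepare(mf, toy_dataset["dir"], od.PrepConfig(seed=0))
        per_family, _ = classify_readset_families(readset.reads, toy_dataset["panel"])
        for fam, reads in per_family.items():
            oset = decompose_family(fam, reads, DecompositionConfig(min_substantive_abundance=50))
            for o in oset.oligotypes:
                for m in o.members:
                    assert "".join(m[p] for p in o.component_positions) == o.label


class TestMFilter:
    def _oset(self, counts_by_label):
        reads = _reads(counts_by_label)
        all_reads = [s for s, c in counts_by_label.items() for _ in range(c)]
        return initial_decompose(reads, column_entropy(all_reads), DecompositionConfig())

    def test_threshold_is_inclusive_at_exactly_m(self):
        a, b = "A" * 20, "C" * 20
        oset = self._oset({a: 500, b: 499})
        out = filter_min_substantive_abundance(oset, DecompositionConfig())
        assert [o.members for o in out.oligotypes] == [[a]]
        assert out.discarded_read_count == 499

    def test_random_sets_match_brute_force_recount(self, rng):
        # oracle: direct recount of each group's maximum member abundance
        for _ in range(5):
            seqs = ["".join(rng.choice(list("ACGT"), size=15)) for _ in range(6)]
            counts = {s: int(n) for s, n in zip(seqs, rng.integers(1, 200, size=6))}
            oset = self._oset(counts)
            M = 75
            out = filter_min_substantive_abundance(
                oset, DecompositionConfig(min_substantive_abundance=M)
            )
            expected = {
                o.label for o in oset.oligotypes if max(o.member_counts) >= M
            }
            assert {o.label for o in out.oligotypes} == expected


class TestMatrices:
    def _manifest(self, sample_ids):
        return pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": "sub",
                "day": range(len(sample_ids)),
                "path": "x.fasta",
                "n_reads": 1,
            }
        )

    def test_single_family_single_sample_identity(self):
        oset = decompose_family(
            "fam", _reads({"AAAA": 7, "CCCC": 3}), DecompositionConfig(min_substantive_abundance=1)
        )
        m = build_counts_matrix([oset], self._manifest(["s1"]))
        assert m.shape == (2, 1)
        assert sorted(m["s1"].tolist()) == [3, 7]

    def test_concatenation_row_count_and_column_sums(self, toy_dataset):
        mf = od.read_manifest(toy_dataset["manifest"])
        from oligodyn.prep import prepare
        from oligodyn.pipeline import classify_readset_families

        readset, _ = prepare(mf, toy_dataset["dir"], od.PrepConfig(seed=0))
        per_family, _ = classify_readset_families(readset.reads, toy_dataset["panel"])
        cfg = DecompositionConfig(min_substantive_abundance=1)
        osets = [decompose_family(f, per_family[f], cfg) for f in sorted(per_family)]
        m = build_counts_matrix(osets, mf)
        assert m.shape[0] == sum(len(o.oligotypes) for o in osets)
        # oracle: column sums equal per-sample retained (classified) totals
        for sid in mf["sample_id"]:
            retained = sum(len(per_family[f][sid]) for f in per_family)
            assert m[sid].sum() == retained

    def test_duplicate_ids_rejected(self):
        oset = decompose_family(
            "fam", _reads({"AAAA": 7}), DecompositionConfig(min_substantive_abundance=1)
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_counts_matrix([oset, oset], self._manifest(["s1"]))

    def test_percent_normalization(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [0, 0]}, index=["a", "b"])
        pct, zero = normalize_percent(counts)
        assert pct["s1"].tolist() == [25.0, 75.0]
        assert pct["s2"].tolist() == [0.0, 0.0]
        assert zero == ["s2"]

    def test_nonzero_columns_sum_to_100(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, size=(6, 8)))
        counts.columns = [str(c) for c in counts.columns]
        pct, zero = normalize_percent(counts)
        for c in pct.columns:
            if c not in zero:
                assert pct[c].sum() == pytest.approx(100.0, abs=1e-6)


class TestCollapse:
    def test_collapse_preserves_totals(self, rng):
        reads = {"s1": ["AAAA", "AAAA", "CCCC"], "s2": ["CCCC"]}
        members, table = collapse_reads(reads)
        assert sorted(members) == ["AAAA", "CCCC"]
        assert table.to_numpy().sum() == 4
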