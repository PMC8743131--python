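"""Reading, validation, instrument selection, clumping and proxy lookup."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrpipe.errors import ConfigurationError, DataError
from mrpipe.sumstats import (LDTable, Variant, clump, find_proxy, read_sumstats,
                             select_instruments, write_sumstats)

from conftest import make_sumstats


class TestVariant:
    def test_valid(self):
        v = Variant("rs1", "1", 1000, "A", "G", eaf=0.3)
        assert not v.effect_allele == v.other_allele

    @pytest.mark.parametrize("kwargs", [
        dict(effect_allele="A", other_allele="A"),
        dict(effect_allele="I", other_allele="D"),
        dict(position=0),
        dict(eaf=1.5),
    ])
    def test_invariant_breach(self, kwargs):
        base = dict(variant_id="rs1", chromosome="1", position=100,
                    effect_allele="A", other_allele="G")
        base.update(kwargs)
        with pytest.raises(DataError):
            Variant(**base)


class TestReadSumstats:
    def test_round_trip(self, tmp_path):
        ss = make_sumstats(variant_ids=["rs1", "rs2", "rs3"],
                           betas=[0.1, -0.2, 0.05], n=[1000] * 3)
        path = tmp_path / "trait.tsv"
        write_sumstats(ss, path)
        back = read_sumstats(path, trait_id="trait")
        assert len(back) == 3
        assert back.variant_ids == ["rs1", "rs2", "rs3"]
        np.testing.assert_allclose(back.table["beta"], ss.table["beta"])

    def test_gzip_transparent(self, tmp_path):
        import gzip
        content = "SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\nrs1\t1\t100\tA\tG\t0.1\t0.01\t1e-10\n"
        path = tmp_path / "t.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(content)
        assert len(read_sumstats(path)) == 1

    def test_missing_se_row_dropped(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\n"
                        "rs1\t1\t100\tA\tG\t0.1\t0.01\t1e-10\n"
                        "rs2\t1\t200\tA\tG\t0.1\t\t1e-10\n"
                        "rs3\t1\t300\tA\tG\t0.1\t0.02\t1e-9\n")
        assert read_sumstats(path).variant_ids == ["rs1", "rs3"]

    def test_duplicate_variant_raises(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\n"
                        "rs1\t1\t100\tA\tG\t0.1\t0.01\t1e-10\n"
                        "rs1\t1\t100\tA\tG\t0.1\t0.01\t1e-10\n")
        with pytest.raises(DataError, match="rs1"):
            read_sumstats(path)

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tBETA\tSE\tP\nrs1\t1\t100\tA\t0.1\t0.01\t1e-10\n")
        with pytest.raises(ConfigurationError):
            read_sumstats(path)

    def test_pvalue_validation(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\n"
                        "rs1\t1\t100\tA\tG\t0.1\t0.01\t0.9\n")  # z = 10 but p = 0.9
        with pytest.raises(DataError):
            read_sumstats(path, validate_pvalues=True)
        assert len(read_sumstats(path)) == 1  # off by default


class TestSelectInstruments:
    def setup_method(self):
        self.ss = make_sumstats(variant_ids=["rs1", "rs2", "rs3"],
                                pvalues=[1e-9, 1e-7, 0.3])

    def test_genome_wide_threshold(self):
        assert select_instruments(self.ss, 5e-8).variant_ids == ["rs1"]

    def test_relaxed_threshold_gains_instruments(self):
        assert select_instruments(self.ss, 5e-7).variant_ids == ["rs1", "rs2"]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_threshold_precondition(self, bad):
        with pytest.raises(ConfigurationError):
            select_instruments(self.ss, bad)

    @given(st.floats(min_value=1e-12, max_value=0.99),
           st.floats(min_value=1e-12, max_value=0.99))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, t1, t2):
        lo, hi = sorted([t1, t2])
        a = set(select_instruments(self.ss, lo).variant_ids)
        b = set(select_instruments(self.ss, hi).variant_ids)
        assert a <= b


def _greedy_oracle(pvalues, chroms, positions, r2, threshold, window_bp):
    """Lexicographically-first maximal compatible subset in p-value order.

    Brute-force enumeration over all subsets; independent of the clump
    implementation.
    """
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: (pvalues[i], f"rs{i + 1}"))

    def compatible(i, j):
        if chroms[i] != chroms[j] or abs(positions[i] - positions[j]) > window_bp:
            return True
        return r2.get(tuple(sorted((i, j))), 0.0) < threshold

    rank = {v: k for k, v in enumerate(order)}
    best = None
    for size in range(n + 1):
        for combo in itertools.combinations(range(n), size):
            if not all(compatible(a, b) for a, b in itertools.combinations(combo, 2)):
                continue
            # maximality: no outside variant can still be added
            if not all(any(not compatible(o, c) for c in combo)
                       for o in range(n) if o not in combo):
                continue
            ranks = tuple(sorted(rank[i] for i in combo))
            if best is None or ranks < best:
                best = ranks
    return {order[r] for r in best} if best else set()


class TestClump:
    def _three_variant_case(self):
        ss = make_sumstats(variant_ids=["v1", "v2", "v3"],
                           pvalues=[1e-10, 1e-9, 1e-8],
                           positions=[1_000_000, 1_010_000, 1_020_000])
        ld = LDTable({("v1", "v2"): 0.5, ("v1", "v3"): 0.001, ("v2", "v3"): 0.002})
        return ss, ld

    def test_hand_executed_greedy_pass(self):
        ss, ld = self._three_variant_case()
        assert clump(ss, ld).variant_ids == ["v1", "v3"]

    def test_no_ld_keeps_everything_sorted_by_pvalue(self):
        ss = make_sumstats(variant_ids=["a", "b", "c"], pvalues=[0.3, 1e-9, 1e-5],
                           positions=[1, 2, 3])
        out = clump(ss, LDTable())
        assert out.variant_ids == ["b", "c", "a"]

    def test_cross_chromosome_pairs_ignored(self):
        ss = make_sumstats(variant_ids=["x", "y"], pvalues=[1e-10, 1e-9],
                           chromosomes=["1", "2"], positions=[100, 100])
        ld = LDTable({("x", "y"): 0.99})
        assert set(clump(ss, ld).variant_ids) == {"x", "y"}

    def test_outside_window_pairs_ignored(self):
        ss = make_sumstats(variant_ids=["x", "y"], pvalues=[1e-10, 1e-9],
                           positions=[1, 20_000_001])
        ld = LDTable({("x", "y"): 0.99})
        assert set(clump(ss, ld, window_kb=10_000).variant_ids) == {"x", "y"}

    def test_idempotent(self):
        ss, ld = self._three_variant_case()
        once = clump(ss, ld)
        twice = clump(once, ld)
        assert once.variant_ids == twice.variant_ids

    def test_output_maximal(self):
        ss, ld = self._three_variant_case()
        accepted = clump(ss, ld)
        rejected = set(ss.variant_ids) - set(accepted.variant_ids)
        for r in rejected:
            assert any(ld.r2(r, a) >= 0.01 for a in accepted.variant_ids)

    @pytest.mark.parametrize("bad_kwargs", [dict(r2_threshold=0.0),
                                            dict(r2_threshold=1.0),
                                            dict(window_kb=0)])
    def test_preconditions(self, bad_kwargs):
        ss, ld = self._three_variant_case()
        with pytest.raises(ConfigurationError):
            clump(ss, ld, **bad_kwargs)

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_enumeration(self, data):
        n = data.draw(st.integers(min_value=1, max_value=7))
        pvalues = data.draw(st.lists(
            st.floats(min_value=1e-12, max_value=0.05), min_size=n, max_size=n,
            unique=True))
        chroms = data.draw(st.lists(st.sampled_from(["1", "2"]), min_size=n, max_size=n))
        positions = data.draw(st.lists(st.integers(min_value=1, max_value=30_000_000),
                                       min_size=n, max_size=n, unique=True))
        r2 = {}
        for i in range(n):
            for j in range(i + 1, n):
                if data.draw(st.booleans()):
                    r2[(i, j)] = data.draw(st.floats(min_value=0.0, max_value=1.0))
        ids = [f"rs{i + 1}" for i in range(n)]
        ss = make_sumstats(variant_ids=ids, pvalues=pvalues, chromosomes=chroms,
                           positions=positions)
        ld = LDTable({(ids[i], ids[j]): v for (i, j), v in r2.items()})
        got = set(clump(ss, ld, 0.01, 10_000).variant_ids)
        expect = {ids[i] for i in _greedy_oracle(pvalues, chroms, positions,
                                                 r2, 0.01, 10_000_000)}
        assert got == expect


class TestFindProxy:
    def test_best_partner_wins(self):
        candidates = make_sumstats(variant_ids=["p1", "p2", "p3"])
        ld = LDTable({("t", "p1"): 0.95, ("t", "p2"): 0.92, ("t", "p3"): 0.5})
        assert find_proxy("t", candidates, ld, 0.9) == "p1"

    def test_no_qualifying_candidate(self):
        candidates = make_sumstats(variant_ids=["p1", "p2"])
        ld = LDTable({("t", "p1"): 0.9, ("t", "p2"): 0.5})
        assert find_proxy("t", candidates, ld, 0.9) is None  # strict inequality

    def test_target_already_present_returns_itself(self):
        candidates = make_sumstats(variant_ids=["t", "p1"])
        ld = LDTable({("t", "p1"): 0.99})
        assert find_proxy("t", candidates, ld, 0.9) == "t"

    def test_partner_absent_from_candidates_skipped(self):
        candidates = make_sumstats(variant_ids=["p2"])
        ld = LDTable({("t", "p1"): 0.99, ("t", "p2"): 0.93})
        assert find_proxy("t", candidates, ld, 0.9) == "p2"


class TestLDTable:
    def test_symmetry_and_defaults(self):
        ld = LDTable({("a", "b"): 0.7})
        assert ld.r2("b", "a") == 0.7
        assert ld.r2("a", "a") == 1.0
        assert ld.r2("a", "zzz") == 0.0

    def test_file_round_trip(self, tmp_path):
        ld = LDTable({("a", "b"): 0.7, ("a", "c"): 0.25})
        path = tmp_path / "ld.tsv"
        ld.write(path)
        back = LDTable.read(path)
        assert back.r2("c", "a") == 0.25
        assert len(back) == 2
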