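import itertools
import math

import numpy as np
import pytest

from phenofun.funfam import (
    DomainHit,
    FamilyGOTable,
    HitParseError,
    associate_family_go,
    build_feature_matrix,
    cathpredict,
    filter_hits,
    parse_domtbl,
    resolve_hits,
)
from phenofun.ontology import GeneAnnotationSet

from conftest import make_graph

# two domain rows in genuine hmmsearch --domtblout layout (23+ columns)
DOMTBL = """#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord
# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target
#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------
prot1                -            450 FF0001               -            200   1.2e-20   70.5   0.0   1   1   2.1e-22   3.2e-10   68.1   0.0     1   198    10   205     8   210 0.95 -
prot1                -            450 FF0002               -            150     5e-08   40.2   0.1   1   1   8.8e-10   6.6e-06   38.0   0.1     3   149   240   390   235   395 0.90 -
"""


def brute_force_resolve(hits, tolerance=0):
    """Oracle: exhaustive subset search for the max-bit non-overlapping set."""
    def compatible(subset):
        for a, b in itertools.combinations(subset, 2):
            if min(a.stop, b.stop) - max(a.start, b.start) + 1 > tolerance:
                return False
        return True

    best = 0.0
    for r in range(len(hits) + 1):
        for subset in itertools.combinations(hits, r):
            if compatible(subset):
                best = max(best, sum(h.bitscore for h in subset))
    return best


class TestParse:
    def test_domtbl_dialect(self, tmp_path):
        p = tmp_path / "hits.domtbl"
        p.write_text(DOMTBL)
        hits = parse_domtbl(p)
        assert len(hits) == 2
        h = hits[0]
        assert (h.protein, h.family) == ("prot1", "FF0001")
        assert h.evalue == pytest.approx(3.2e-10)  # per-domain independent E-value
        assert h.bitscore == pytest.approx(68.1)
        assert (h.start, h.stop) == (8, 210)  # envelope coordinates

    def test_comment_only_file(self, tmp_path):
        p = tmp_path / "empty.domtbl"
        p.write_text("# nothing here\n\n")
        assert parse_domtbl(p) == []

    def test_tsv_dialect_and_column_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("prot1\tFF1\t3.2e-10\t50.0\t1\t100\n")
        assert parse_domtbl(p)[0].evalue == pytest.approx(3.2e-10)
        p.write_text("prot1\tFF1\t3.2e-10\n")
        with pytest.raises(HitParseError, match=":1"):
            parse_domtbl(p)


class TestFilter:
    def test_strict_threshold(self):
        hits = [
            DomainHit("p", "f1", 1e-3, 10, 1, 5),
            DomainHit("p", "f2", 9.9e-4, 10, 1, 5),
        ]
        kept = filter_hits(hits)
        assert [h.family for h in kept] == ["f2"]

    def test_empty_input(self):
        assert filter_hits([]) == []


class TestResolve:
    def test_disjoint_kept(self):
        hits = [DomainHit("p", "a", 1e-9, 30, 1, 50), DomainHit("p", "b", 1e-9, 25, 60, 100)]
        assert len(resolve_hits(hits)) == 2

    def test_dominated_overlap(self):
        hits = [DomainHit("p", "a", 1e-9, 50, 1, 100), DomainHit("p", "b", 1e-9, 40, 1, 100)]
        out = resolve_hits(hits)
        assert [h.family for h in out] == ["a"]

    def test_chain_prefers_sum(self):
        a = DomainHit("p", "A", 1e-9, 30, 1, 100)
        b = DomainHit("p", "B", 1e-9, 35, 50, 150)
        c = DomainHit("p", "C", 1e-9, 30, 120, 200)
        out = resolve_hits([a, b, c])
        assert {h.family for h in out} == {"A", "C"}

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValueError):
            resolve_hits([DomainHit("p", "a", 1e-9, 1, 1, 5), DomainHit("q", "b", 1e-9, 1, 1, 5)])

    @pytest.mark.parametrize("tolerance", [0, 5])
    def test_matches_bruteforce_on_random_instances(self, tolerance):
        rng = np.random.default_rng(42 + tolerance)
        for _ in range(100):
            n = int(rng.integers(1, 13))
            hits = []
            for i in range(n):
                start = int(rng.integers(1, 300))
                stop = start + int(rng.integers(10, 120))
                hits.append(
                    DomainHit("p", f"f{i}", float(10 ** rng.uniform(-20, -4)),
                              float(rng.integers(10, 100)), start, stop)
                )
            got = resolve_hits(hits, overlap_tolerance=tolerance)
            # chosen set must be valid and achieve the oracle optimum
            for a, b in itertools.combinations(got, 2):
                assert min(a.stop, b.stop) - max(a.start, b.start) + 1 <= tolerance
            assert sum(h.bitscore for h in got) == pytest.approx(
                brute_force_resolve(hits, tolerance)
            )


class TestFeatureMatrix:
    def test_neg_log10_entries(self):
        hits = [DomainHit("p", "f", 1e-6, 10, 1, 5)]
        fm = build_feature_matrix(hits)
        assert fm.to_dense()[0, 0] == pytest.approx(6.0)

    def test_best_hit_per_pair(self):
        hits = [DomainHit("p", "f", 1e-4, 10, 1, 5), DomainHit("p", "f", 1e-8, 9, 10, 20)]
        fm = build_feature_matrix(hits)
        assert fm.to_dense()[0, 0] == pytest.approx(8.0)

    def test_sparsity(self):
        hits = [
            DomainHit(f"p{i}", f"f{j}", 1e-5, 10, 1, 5)
            for i, j in [(0, 0), (0, 1), (1, 2), (2, 3), (3, 0), (4, 1)]
        ]
        fm = build_feature_matrix(hits, proteins=[f"p{i}" for i in range(5)],
                                  families=[f"f{j}" for j in range(4)])
        assert fm.sparsity == pytest.approx(1 - 6 / 20)

    def test_entries_exceed_three_after_default_filter(self):
        rng = np.random.default_rng(5)
        hits = [
            DomainHit(f"p{i}", "f", float(10 ** rng.uniform(-12, -1)), 10, 1, 5)
            for i in range(50)
        ]
        fm = build_feature_matrix(filter_hits(hits))
        assert (fm.matrix.data > 3).all()


class TestAssociateFamilyGO:
    @pytest.fixture()
    def graph(self):
        return make_graph([("T", "R", "is_a")])

    def test_proportion_rule(self, graph):
        ann = GeneAnnotationSet({m: [("T", "IDA")] for m in ["m1", "m2", "m3"]})
        table = associate_family_go({"F": ["m1", "m2", "m3", "m4"]}, ann, graph)
        assert table.table["F"]["T"] == (3, 4, 0.75)

    def test_excluded_evidence_codes(self, graph):
        ann = GeneAnnotationSet({"m1": [("T", "NAS")], "m2": [("T", "IDA")]})
        table = associate_family_go({"F": ["m1", "m2"]}, ann, graph)
        assert table.table["F"]["T"][0] == 1  # NAS record dropped

    def test_keyword_curated_iea_kept(self, graph):
        ann = GeneAnnotationSet(
            {"m1": [("T", "IEA:UniProtKB-KW")], "m2": [("T", "IEA")]}
        )
        table = associate_family_go({"F": ["m1", "m2"]}, ann, graph)
        assert table.table["F"]["T"][0] == 1  # plain IEA dropped, keyword IEA kept

    def test_ancestors_included(self, graph):
        ann = GeneAnnotationSet({"m1": [("T", "IDA")]})
        table = associate_family_go({"F": ["m1"]}, ann, graph)
        assert table.table["F"]["R"] == (1, 1, 1.0)

    def test_empty_family_error(self, graph):
        with pytest.raises(ValueError):
            associate_family_go({"F": []}, GeneAnnotationSet(), graph)


class TestCathPredict:
    def _tables(self):
        cath = FamilyGOTable({"FFA": {"T1": (9, 10, 0.9), "T2": (1, 20, 0.05)},
                              "FFB": {"T3": (1, 2, 0.5)}})
        pfam = FamilyGOTable({"PFX": {"T4": (1, 2, 0.5)}})
        return cath, pfam

    def test_low_probability_dropped(self):
        cath, pfam = self._tables()
        hits = [DomainHit("p", "FFA", 1e-9, 80, 1, 100)]
        out = cathpredict(hits, [], cath, pfam)
        assert list(out["term"]) == ["T1"]
        assert out["score"].iloc[0] == 0.9

    def test_best_bit_family_only(self):
        cath, pfam = self._tables()
        hits = [
            DomainHit("p", "FFA", 1e-9, 80, 1, 100),
            DomainHit("p", "FFB", 1e-9, 75, 1, 100),
        ]
        out = cathpredict(hits, [], cath, pfam)
        assert set(out["family"]) == {"FFA"}

    def test_pfam_fallback(self):
        cath, pfam = self._tables()
        pfam_hits = [DomainHit("p", "PFX", 1e-9, 60, 1, 100)]
        out = cathpredict([], pfam_hits, cath, pfam)
        assert list(out["term"]) == ["T4"]
        assert set(out["library"]) == {"pfam"}

    def test_no_significant_hit_emits_nothing(self):
        cath, pfam = self._tables()
        hits = [DomainHit("p", "FFA", 0.5, 80, 1, 100)]  # insignificant
        out = cathpredict(hits, [], cath, pfam)
        assert len(out) == 0

    def test_scores_within_pmin_one(self):
        cath, pfam = self._tables()
        hits = [DomainHit("p", "FFA", 1e-9, 80, 1, 100),
                DomainHit("q", "FFB", 1e-9, 50, 1, 100)]
        out = cathpredict(hits, [], cath, pfam, pmin=0.1)
        assert ((out["score"] >= 0.1) & (out["score"] <= 1.0)).all()
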