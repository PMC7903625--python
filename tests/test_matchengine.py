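import itertools

import numpy as np
import pytest

from varbench.errors import (ConfigurationError, InconsistentClusterError,
                             ReferenceMismatchError)
from varbench.matchengine import (ClusterPair, cluster_variants,
                                  decompose_multiallelic,
                                  haplotype_spellings, match_clusters,
                                  normalize_variant, classify)
from varbench.reference import DictReference
from varbench.stratify import merge
from varbench.vcfio import VariantRecord

from conftest import make_variant


# ---------------------------------------------------------------------------
# independent oracles

def apply_variant(seq, pos, ref, alt):
    assert seq[pos - 1: pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]


def oracle_leftmost_parsimonious(seq, pos, ref, alt):
    """Closed-form left-most parsimonious representation.

    Diff the reference against the mutated sequence: maximal common
    suffix, then maximal common prefix, then a left anchor base when one
    core allele empties. Independent of the iterative-shift algorithm.
    """
    mutated = apply_variant(seq, pos, ref, alt)
    s, t = seq, mutated
    nsuf = 0
    while (nsuf < min(len(s), len(t))
           and s[len(s) - 1 - nsuf] == t[len(t) - 1 - nsuf]):
        nsuf += 1
    npre = 0
    while npre < min(len(s), len(t)) - nsuf and s[npre] == t[npre]:
        npre += 1
    r = s[npre: len(s) - nsuf]
    a = t[npre: len(t) - nsuf]
    if r and a:
        return npre + 1, r, a
    assert npre >= 1, "indel at contig start needs a right anchor"
    return npre, s[npre - 1: len(s) - nsuf], t[npre - 1: len(t) - nsuf]


def oracle_cluster_labels(truth, query, chrom, span, ref_seq):
    """Exhaustive phasing enumeration + span-spelling comparison.

    Straight-line reimplementation of the matching contract used to
    cross-check the engine on small clusters.
    """
    def spell(assign, members):
        haps = ([], [])
        for v, where in zip(members, assign):
            for h in where:
                haps[h].append(v)
        out = []
        for hap in haps:
            cursor, parts = span[0], []
            for v in sorted(hap, key=lambda x: x.start0):
                if v.start0 < cursor:
                    return None
                parts.append(ref_seq.fetch(chrom, cursor, v.start0))
                parts.append(v.alt)
                cursor = v.end0
            parts.append(ref_seq.fetch(chrom, cursor, span[1]))
            out.append("".join(parts))
        return tuple(sorted(out))

    def spellings(members):
        options = []
        for v in members:
            if v.genotype == (1, 1):
                options.append([(0, 1)])
            elif v.phased:
                options.append([(0,) if v.genotype[0] == 1 else (1,)])
            else:
                options.append([(0,), (1,)])
        pairs = set()
        for assign in itertools.product(*options):
            p = spell(assign, members)
            if p is not None:
                pairs.add(p)
        return pairs

    if not truth:
        return {(id(v), "query"): "FP" for v in query}
    if not query:
        return {(id(v), "truth"): "FN" for v in truth}
    ts, qs = spellings(truth), spellings(query)
    if ts and qs and ts & qs:
        out = {(id(v), "truth"): "TP" for v in truth}
        out.update({(id(v), "query"): "TP" for v in query})
        return out
    # exact fallback with the genotype-mismatch rule
    out = {}
    unused = list(query)
    for t in truth:
        match = next((q for q in unused if (q.pos, q.ref, q.alt)
                      == (t.pos, t.ref, t.alt)), None)
        if match is not None:
            unused.remove(match)
            if sorted(match.genotype) == sorted(t.genotype):
                out[(id(t), "truth")] = "TP"
                out[(id(match), "query")] = "TP"
            else:
                out[(id(t), "truth")] = "FN"
                out[(id(match), "query")] = "FP"
        else:
            out[(id(t), "truth")] = "FN"
    for q in unused:
        out[(id(q), "query")] = "FP"
    return out


# ---------------------------------------------------------------------------
# normalization

class TestNormalize:
    def test_snp_already_parsimonious(self, dict_ref):
        v = make_variant(pos=10, ref="C", alt="A")
        assert normalize_variant(v, dict_ref) is v

    def test_homopolymer_deletion_left_aligns(self):
        ref = DictReference({"chr1": "CATTTTG"})
        v = make_variant(pos=4, ref="TT", alt="T")
        n = normalize_variant(v, ref)
        assert (n.pos, n.ref, n.alt) == \
            oracle_leftmost_parsimonious("CATTTTG", 4, "TT", "T")
        assert (n.pos, n.ref, n.alt) == (2, "AT", "A")

    def test_prefix_trim_shifts_position(self):
        ref = DictReference({"chr1": "N" * 9 + "ACGTNNNN"})
        v = make_variant(pos=10, ref="ACGT", alt="ACGA")
        n = normalize_variant(v, ref)
        assert (n.pos, n.ref, n.alt) == (13, "T", "A")

    def test_reference_mismatch_names_site(self, dict_ref):
        v = make_variant(pos=10, ref="T", alt="A")  # actual base is C
        with pytest.raises(ReferenceMismatchError, match="chr1:10"):
            normalize_variant(v, dict_ref)

    def test_agrees_with_bruteforce_and_is_idempotent(self):
        rng = np.random.default_rng(42)
        bases = "ACGT"
        for _ in range(400):
            seq = "".join(rng.choice(list(bases), size=60))
            ref = DictReference({"chr1": seq})
            pos = int(rng.integers(6, 40))
            kind = rng.integers(0, 3)
            if kind == 0:      # SNP, possibly suffix-padded
                r = seq[pos - 1]
                a = [b for b in bases if b != r][rng.integers(0, 3)]
            elif kind == 1:    # deletion
                size = int(rng.integers(1, 6))
                r = seq[pos - 1: pos + size]
                a = seq[pos - 1]
            else:              # insertion
                size = int(rng.integers(1, 6))
                r = seq[pos - 1]
                a = r + "".join(rng.choice(list(bases), size=size))
            if rng.random() < 0.5:  # shared-suffix padding
                nxt = seq[pos - 1 + len(r)]
                r, a = r + nxt, a + nxt
            v = make_variant(pos=pos, ref=r, alt=a)
            n = normalize_variant(v, ref)
            assert (n.pos, n.ref, n.alt) == \
                oracle_leftmost_parsimonious(seq, pos, r, a)
            n2 = normalize_variant(n, ref)
            assert (n2.pos, n2.ref, n2.alt) == (n.pos, n.ref, n.alt)


# ---------------------------------------------------------------------------
# decomposition

class TestDecompose:
    def test_het_alt_pair_splits(self):
        v = VariantRecord(chrom="chr1", pos=100, ref="A", alts=("G", "T"),
                          genotype=(1, 2))
        parts = decompose_multiallelic(v)
        assert [(p.alt, p.genotype) for p in parts] == \
            [("G", (1, 0)), ("T", (0, 1))]

    def test_biallelic_unchanged(self):
        v = make_variant(pos=100, ref="A", alt="G")
        assert decompose_multiallelic(v) == [v]

    def test_uncarried_allele_dropped(self):
        v = VariantRecord(chrom="chr1", pos=100, ref="A", alts=("G", "T"),
                          genotype=(1, 1))
        parts = decompose_multiallelic(v)
        assert [(p.alt, p.genotype) for p in parts] == [("G", (1, 1))]

    def test_hom_ref_emits_nothing(self):
        v = make_variant(pos=100, ref="A", alt="G", gt=(0, 0))
        assert decompose_multiallelic(v) == []

    def test_dangling_allele_index_rejected(self):
        v = VariantRecord(chrom="chr1", pos=100, ref="A", alts=("G",),
                          genotype=(1, 2))
        with pytest.raises(ValueError):
            decompose_multiallelic(v)


# ---------------------------------------------------------------------------
# clustering

class TestCluster:
    def test_same_site_pairs(self):
        t = [make_variant(pos=100)]
        q = [make_variant(pos=100)]
        pairs = cluster_variants(t, q)
        assert len(pairs) == 1
        assert len(pairs[0].truth) == 1 and len(pairs[0].query) == 1

    def test_mnp_and_its_snps_share_a_cluster(self):
        t = [make_variant(pos=5, ref="AC", alt="GT")]
        q = [make_variant(pos=5, ref="A", alt="G"),
             make_variant(pos=6, ref="C", alt="T")]
        pairs = cluster_variants(t, q, window=10)
        assert len(pairs) == 1
        assert len(pairs[0].truth) == 1 and len(pairs[0].query) == 2

    def test_distant_variants_split(self):
        t = [make_variant(pos=100)]
        q = [make_variant(pos=200)]
        pairs = cluster_variants(t, q, window=50)
        assert len(pairs) == 2

    def test_oversized_cluster_splits_at_largest_gap(self):
        t = [make_variant(pos=p) for p in (100, 105, 130, 135)]
        pairs = cluster_variants(t, [], window=40, max_cluster_size=2)
        assert len(pairs) == 2
        assert all(p.split_flagged for p in pairs)
        assert [len(p.truth) for p in pairs] == [2, 2]


# ---------------------------------------------------------------------------
# haplotype spelling

class TestSpellings:
    def test_hom_deletion_single_pair(self):
        ref = DictReference({"chr1": "ATTG"})
        v = make_variant(pos=2, ref="TT", alt="T", gt=(1, 1))
        got = haplotype_spellings([v], "chr1", (0, 4), ref)
        assert got == frozenset({("ATG", "ATG")})

    def test_two_unphased_hets_give_cis_and_trans(self):
        ref = DictReference({"chr1": "ACAC"})
        v1 = make_variant(pos=1, ref="A", alt="G")
        v2 = make_variant(pos=3, ref="A", alt="T")
        got = haplotype_spellings([v1, v2], "chr1", (0, 4), ref)
        cis = tuple(sorted(("GCTC", "ACAC")))
        trans = tuple(sorted(("GCAC", "ACTC")))
        assert got == frozenset({cis, trans})

    def test_mnp_equals_component_snps_when_hom(self):
        ref = DictReference({"chr1": "NACN"})
        mnp = make_variant(pos=2, ref="AC", alt="GT", gt=(1, 1))
        s1 = make_variant(pos=2, ref="A", alt="G", gt=(1, 1))
        s2 = make_variant(pos=3, ref="C", alt="T", gt=(1, 1))
        span = (0, 4)
        assert haplotype_spellings([mnp], "chr1", span, ref) \
            == haplotype_spellings([s1, s2], "chr1", span, ref)

    def test_phased_hets_fix_the_phase(self):
        ref = DictReference({"chr1": "ACAC"})
        v1 = make_variant(pos=1, ref="A", alt="G", gt=(1, 0), phased=True)
        v2 = make_variant(pos=3, ref="A", alt="T", gt=(1, 0), phased=True)
        got = haplotype_spellings([v1, v2], "chr1", (0, 4), ref)
        assert got == frozenset({tuple(sorted(("GCTC", "ACAC")))})

    def test_overlapping_hom_alleles_inconsistent(self):
        ref = DictReference({"chr1": "AAAA"})
        v1 = make_variant(pos=1, ref="AA", alt="A", gt=(1, 1))
        v2 = make_variant(pos=2, ref="AA", alt="A", gt=(1, 1))
        with pytest.raises(InconsistentClusterError):
            haplotype_spellings([v1, v2], "chr1", (0, 4), ref)


# ---------------------------------------------------------------------------
# cluster matching

class TestMatchClusters:
    def _pair(self, truth, query, span=(0, 10)):
        chrom = (truth or query)[0].chrom
        return ClusterPair(chrom=chrom, span=span, truth=tuple(truth),
                           query=tuple(query))

    def test_mnp_matches_component_snps(self):
        ref = DictReference({"chr1": "NACNNNNNNN"})
        t = [make_variant(pos=2, ref="AC", alt="GT", gt=(1, 1))]
        q = [make_variant(pos=2, ref="A", alt="G", gt=(1, 1)),
             make_variant(pos=3, ref="C", alt="T", gt=(1, 1))]
        labels = match_clusters(self._pair(t, q), ref)
        assert [(role, lab) for _, role, lab in labels] == \
            [("truth", "TP"), ("query", "TP"), ("query", "TP")]

    def test_genotype_mismatch_costs_fn_and_fp(self):
        ref = DictReference({"chr1": "NACNNNNNNN"})
        t = [make_variant(pos=2, ref="A", alt="G", gt=(1, 1))]
        q = [make_variant(pos=2, ref="A", alt="G", gt=(0, 1))]
        labels = {(role): lab for _, role, lab
                  in match_clusters(self._pair(t, q), ref)}
        assert labels == {"truth": "FN", "query": "FP"}

    def test_one_sided_clusters(self):
        ref = DictReference({"chr1": "NACNNNNNNN"})
        q = [make_variant(pos=2, ref="A", alt="G")]
        assert [(r, l) for _, r, l
                in match_clusters(self._pair([], q), ref)] == [("query", "FP")]
        t = [make_variant(pos=2, ref="A", alt="G")]
        assert [(r, l) for _, r, l
                in match_clusters(self._pair(t, []), ref)] == [("truth", "FN")]

    def test_agrees_with_exhaustive_enumeration(self):
        """Engine vs independent brute force on random small clusters."""
        rng = np.random.default_rng(7)
        bases = "ACGT"
        for trial in range(300):
            seq = "".join(rng.choice(list(bases), size=80))
            ref = DictReference({"chr1": seq})

            def rand_members(n):
                out = []
                positions = sorted(rng.choice(np.arange(10, 50), size=n,
                                              replace=False))
                for pos in map(int, positions):
                    r = seq[pos - 1]
                    if rng.random() < 0.7:
                        a = [b for b in bases if b != r][rng.integers(0, 3)]
                    elif rng.random() < 0.5:
                        size = int(rng.integers(1, 4))
                        r = seq[pos - 1: pos + size]
                        a = seq[pos - 1]
                    else:
                        size = int(rng.integers(1, 4))
                        a = r + "".join(rng.choice(list(bases), size=size))
                    gt = (1, 1) if rng.random() < 0.4 else (0, 1)
                    out.append(make_variant(pos=pos, ref=r, alt=a, gt=gt))
                return out

            truth = rand_members(int(rng.integers(0, 5)))
            query = rand_members(int(rng.integers(0, 5)))
            if not truth and not query:
                continue
            for pair in cluster_variants(truth, query, window=60):
                got = {(id(v), role): lab
                       for v, role, lab in match_clusters(pair, ref)}
                want = oracle_cluster_labels(list(pair.truth),
                                             list(pair.query), pair.chrom,
                                             pair.span, ref)
                assert got == want, f"trial {trial}"


# ---------------------------------------------------------------------------
# end-to-end classify

class TestClassify:
    def _region(self):
        return merge([("chr1", 0, 120)])

    def test_matching_snp_inside_region(self, dict_ref):
        t = [make_variant(pos=10, ref="C", alt="A")]
        q = [make_variant(pos=10, ref="C", alt="A")]
        res = classify(t, q, None, self._region(), dict_ref)
        c = res.counts.by_type["SNP"]
        assert (c.tp_truth, c.tp_query, c.fp, c.fn) == (1, 1, 0, 0)

    def test_query_outside_roi_is_unk(self, dict_ref):
        q = [make_variant(pos=10, ref="C", alt="A")]
        t = [make_variant(pos=15, ref="G", alt="A")]
        roi = merge([("chr1", 11, 120)])   # footprint of pos 10 outside
        res = classify(t, q, None, roi, dict_ref)
        labels = {(cv.role, cv.label) for cv in res.classified}
        assert ("query", "UNK") in labels
        c = res.counts.by_type["SNP"]
        assert (c.tp_query, c.fp) == (0, 0)

    def test_empty_evaluation_region_rejected(self, dict_ref):
        with pytest.raises(ConfigurationError):
            classify([], [], merge([("chr1", 0, 10)]),
                     merge([("chr1", 50, 60)]), dict_ref)

    def test_disjoint_contig_namespaces_rejected(self, dict_ref):
        t = [make_variant(chrom="1", pos=10, ref="C", alt="A")]
        with pytest.raises(ConfigurationError, match="namespace"):
            classify(t, [], None, self._region(), dict_ref)

    def test_labels_partition_records(self, classify_fixture):
        from varbench.synthdata import FixtureConfig
        _, res = classify_fixture(FixtureConfig(seed=19, n_mnp_pairs=2,
                                                perturb_pad_rate=0.3))
        for role, side_tp, side_err in (("truth", "tp_truth", "fn"),
                                        ("query", "tp_query", "fp")):
            recs = [cv for cv in res.classified if cv.role == role
                    and cv.label != "UNK"]
            ok = {"TP", "FN"} if role == "truth" else {"TP", "FP"}
            assert {cv.label for cv in recs} <= ok
            tallied = sum(getattr(c, side_tp) + getattr(c, side_err)
                          for c in res.counts.by_type.values())
            assert tallied == len(recs)

    def test_swapping_truth_and_query_swaps_fp_and_fn(self, dict_ref):
        t = [make_variant(pos=10, ref="C", alt="A"),
             make_variant(pos=40, ref="A", alt="G")]   # FN in forward run
        q = [make_variant(pos=10, ref="C", alt="A"),
             make_variant(pos=70, ref="C", alt="T")]   # FP in forward run
        region = merge([("chr1", 0, 120)])
        fwd = classify(t, q, None, region, dict_ref).counts.by_type["SNP"]
        rev = classify(q, t, None, region, dict_ref).counts.by_type["SNP"]
        assert (fwd.fp, fwd.fn) == (rev.fn, rev.fp)
        assert (fwd.tp_truth, fwd.tp_query) == (rev.tp_query, rev.tp_truth)

    def test_non_pass_query_excluded_by_default(self, dict_ref):
        q = [make_variant(pos=10, ref="C", alt="A", filters=("LowQual",))]
        res = classify([], q, None, self._region(), dict_ref)
        assert res.counts.by_type["SNP"].fp == 0
        res = classify([], q, None, self._region(), dict_ref,
                       pass_only=False)
        assert res.counts.by_type["SNP"].fp == 1
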