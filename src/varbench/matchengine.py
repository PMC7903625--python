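"""Haplotype-aware comparison of query calls against a truth set.

Two callsets can describe the same underlying haplotype with different VCF
records: an MNP versus its constituent SNPs, an InDel placed anywhere along
a repeat run, alleles padded with shared reference bases. Naive site-by-site
comparison miscounts all of these. The engine here classifies calls the way
haplotype-aware comparators (hap.py, vcfeval) do:

1. *normalize* every record to its parsimonious, left-most representation;
2. *decompose* multi-allelic sites into biallelic records;
3. *cluster* nearby truth and query records (transitive closure of
   footprint proximity within ``cluster_window``);
4. *enumerate* the local haplotype sequence pairs each cluster's genotypes
   can spell (``2^(h-1)`` phasings for ``h`` unphased hets);
5. call the whole cluster concordant — truth members TP, query members
   TP — when the two spelling sets intersect, and otherwise fall back to
   exact representation matching.

Records whose normalized footprint leaves the evaluation region
(high-confidence ∩ ROI) are labeled UNK and never counted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from collections.abc import Sequence

from .errors import (ConfigurationError, InconsistentClusterError,
                     ReferenceMismatchError)
from .reference import ReferenceAccessor
from .stratify import RegionSet, intersect
from .vcfio import ClassifiedVariant, VariantRecord

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 30
DEFAULT_MAX_CLUSTER = 8


def normalize_variant(v: VariantRecord,
                      ref_seq: ReferenceAccessor) -> VariantRecord:
    """Reduce a biallelic record to its parsimonious, left-most form.

    Shared trailing then leading bases are trimmed (keeping at least one
    base on each side for InDels) and length-changing variants are
    left-aligned by iterated left shift, the standard vt/bcftools-norm
    algorithm. Idempotent. Raises :class:`ReferenceMismatchError` when the
    REF allele disagrees with the reference sequence.
    """
    r, a = v.ref, v.alt
    seen = ref_seq.fetch(v.chrom, v.start0, v.end0)
    if seen != r:
        raise ReferenceMismatchError(
            f"{v}: REF {r!r} but reference has {seen!r}")
    pos = v.pos
    while True:
        if len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            r, a = r[:-1], a[:-1]
            continue
        # left-extend so the shared last base can be dropped (left shift)
        if r[-1] == a[-1] and (len(r) == 1 or len(a) == 1) and pos > 1:
            prev = ref_seq.fetch(v.chrom, pos - 2, pos - 1)
            r, a = prev + r[:-1], prev + a[:-1]
            pos -= 1
            continue
        break
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    if r == a:
        raise ReferenceMismatchError(f"{v}: REF equals ALT after trimming")
    if (r, a, pos) == (v.ref, v.alt, v.pos):
        return v
    return VariantRecord(chrom=v.chrom, pos=pos, ref=r, alts=(a,),
                         genotype=v.genotype, phased=v.phased,
                         filters=v.filters, sample_id=v.sample_id)


def decompose_multiallelic(v: VariantRecord) -> list[VariantRecord]:
    """Split a multi-allelic record into biallelic records.

    One record per alternate allele actually carried by the genotype, with
    the genotype recoded onto {0, 1} (``1/2`` becomes two het records).
    Alleles not carried are dropped, as are ``0/0`` genotypes.
    """
    if max(v.genotype) > len(v.alts):
        raise ValueError(f"{v}: GT references allele {max(v.genotype)} "
                         f"but only {len(v.alts)} ALT allele(s)")
    carried = sorted(set(v.genotype) - {0})
    out = []
    for idx in carried:
        gt = tuple(1 if g == idx else 0 for g in v.genotype)
        out.append(VariantRecord(
            chrom=v.chrom, pos=v.pos, ref=v.ref, alts=(v.alts[idx - 1],),
            genotype=gt, phased=v.phased, filters=v.filters,
            sample_id=v.sample_id))
    return out


@dataclass(frozen=True)
class VariantCluster:
    """Nearby variants of one role sharing a reference span."""

    chrom: str
    span: tuple[int, int]          # 0-based half-open, covers all footprints
    members: tuple[VariantRecord, ...]
    split_flagged: bool = False


@dataclass(frozen=True)
class ClusterPair:
    chrom: str
    span: tuple[int, int]
    truth: tuple[VariantRecord, ...]
    query: tuple[VariantRecord, ...]
    split_flagged: bool = False

    def cluster(self, role: str) -> VariantCluster:
        members = self.truth if role == "truth" else self.query
        return VariantCluster(self.chrom, self.span, members,
                              self.split_flagged)


def cluster_variants(truth: Sequence[VariantRecord],
                     query: Sequence[VariantRecord],
                     window: int = DEFAULT_WINDOW,
                     max_cluster_size: int = DEFAULT_MAX_CLUSTER,
                     ) -> list[ClusterPair]:
    """Group truth and query records into paired proximity clusters.

    Transitive closure: two records (of either role) whose reference
    footprints are separated by fewer than ``window`` bases share a
    cluster. Clusters whose per-role member count exceeds
    ``max_cluster_size`` are split at the largest internal gap (left-most
    on ties) and flagged.
    """
    tagged = [(v, "truth") for v in truth] + [(v, "query") for v in query]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start0, t[0].end0,
                               t[1], t[0].alts))
    groups: list[list[tuple[VariantRecord, str]]] = []
    cur_chrom, cur_end = None, None
    for item in tagged:
        v = item[0]
        if v.chrom == cur_chrom and v.start0 - cur_end < window:
            groups[-1].append(item)
            cur_end = max(cur_end, v.end0)
        else:
            groups.append([item])
            cur_chrom, cur_end = v.chrom, v.end0
    pairs: list[ClusterPair] = []
    for grp in groups:
        pairs.extend(_split_group(grp, max_cluster_size))
    return pairs


def _split_group(group: list[tuple[VariantRecord, str]],
                 max_size: int, flagged: bool = False) -> list[ClusterPair]:
    n_truth = sum(1 for _, role in group if role == "truth")
    n_query = len(group) - n_truth
    if (n_truth <= max_size and n_query <= max_size) or len(group) < 2:
        return [_make_pair(group, flagged)]
    # split at the largest internal gap; left-most wins ties
    gaps = [group[i + 1][0].start0 - group[i][0].end0
            for i in range(len(group) - 1)]
    cut = max(range(len(gaps)), key=lambda i: (gaps[i], -i)) + 1
    left, right = group[:cut], group[cut:]
    return (_split_group(left, max_size, True)
            + _split_group(right, max_size, True))


def _make_pair(group: list[tuple[VariantRecord, str]],
               flagged: bool) -> ClusterPair:
    chrom = group[0][0].chrom
    start = min(v.start0 for v, _ in group)
    end = max(v.end0 for v, _ in group)
    truth = tuple(v for v, role in group if role == "truth")
    query = tuple(v for v, role in group if role == "query")
    return ClusterPair(chrom=chrom, span=(max(0, start - 1), end + 1),
                       truth=truth, query=query, split_flagged=flagged)


def _spell_haplotype(alleles: Sequence[VariantRecord], chrom: str,
                     span: tuple[int, int],
                     ref_seq: ReferenceAccessor) -> str:
    """Apply a consistent allele set to the reference span."""
    cursor = span[0]
    parts = []
    for v in sorted(alleles, key=lambda x: x.start0):
        if v.start0 < cursor:
            raise InconsistentClusterError(
                f"overlapping alleles on one haplotype near {chrom}:{v.pos}")
        parts.append(ref_seq.fetch(chrom, cursor, v.start0))
        parts.append(v.alt)
        cursor = v.end0
    parts.append(ref_seq.fetch(chrom, cursor, span[1]))
    return "".join(parts)


def haplotype_spellings(members: Sequence[VariantRecord], chrom: str,
                        span: tuple[int, int], ref_seq: ReferenceAccessor,
                        ) -> frozenset[tuple[str, str]]:
    """Enumerate the distinct unordered haplotype-sequence pairs.

    Every phase assignment consistent with the genotypes is spelled
    (phased het members keep their stated phase; unphased hets are free;
    hom-alt members sit on both haplotypes). Assignments that place
    overlapping alleles on one haplotype are skipped; if *no* assignment
    is consistent, :class:`InconsistentClusterError` is raised.
    """
    fixed0, fixed1, free = [], [], []
    for v in members:
        g = v.genotype
        if g == (1, 1):
            fixed0.append(v)
            fixed1.append(v)
        elif v.phased:
            (fixed0 if g[0] == 1 else fixed1).append(v)
        else:
            free.append(v)
    pairs = set()
    for bits in itertools.product((0, 1), repeat=len(free)):
        hap0 = fixed0 + [v for v, b in zip(free, bits) if b == 0]
        hap1 = fixed1 + [v for v, b in zip(free, bits) if b == 1]
        try:
            s0 = _spell_haplotype(hap0, chrom, span, ref_seq)
            s1 = _spell_haplotype(hap1, chrom, span, ref_seq)
        except InconsistentClusterError:
            continue
        pairs.add(tuple(sorted((s0, s1))))
    if not pairs:
        raise InconsistentClusterError(
            f"no consistent phasing for cluster at {chrom}:{span}")
    return frozenset(pairs)


def haplotype_sequences(members: Sequence[VariantRecord], chrom: str,
                        span: tuple[int, int], ref_seq: ReferenceAccessor,
                        ) -> frozenset[str]:
    """All single-haplotype spellings reachable by some consistent phasing."""
    seqs = set()
    for pair in haplotype_spellings(members, chrom, span, ref_seq):
        seqs.update(pair)
    return frozenset(seqs)


def match_clusters(pair: ClusterPair, ref_seq: ReferenceAccessor,
                   ) -> list[tuple[VariantRecord, str, str]]:
    """Label every member of a paired cluster TP, FP or FN.

    Concordance is haplotype-level: if some phasing of the truth cluster
    and some phasing of the query cluster spell the same unordered pair of
    local haplotype sequences, all members on both sides are TP. One-sided
    clusters are FP (query-only) or FN (truth-only). Discordant two-sided
    clusters fall back to exact representation matching, where a site
    match with a genotype mismatch costs one FN *and* one FP.

    Returns ``(record, role, label)`` triples.
    """
    if not pair.truth and not pair.query:
        return []
    if not pair.truth:
        return [(v, "query", "FP") for v in pair.query]
    if not pair.query:
        return [(v, "truth", "FN") for v in pair.truth]
    try:
        t_spell = haplotype_spellings(pair.truth, pair.chrom, pair.span,
                                      ref_seq)
        q_spell = haplotype_spellings(pair.query, pair.chrom, pair.span,
                                      ref_seq)
        if t_spell & q_spell:
            return ([(v, "truth", "TP") for v in pair.truth]
                    + [(v, "query", "TP") for v in pair.query])
    except InconsistentClusterError as exc:
        log.warning("cluster %s:%s inconsistent (%s); "
                    "falling back to exact matching",
                    pair.chrom, pair.span, exc)
    return _match_exact(pair)


def _match_exact(pair: ClusterPair) -> list[tuple[VariantRecord, str, str]]:
    out: list[tuple[VariantRecord, str, str]] = []
    by_site: dict[tuple, list[VariantRecord]] = {}
    for q in pair.query:
        by_site.setdefault((q.chrom, q.pos, q.ref, q.alt), []).append(q)
    for t in pair.truth:
        candidates = by_site.get((t.chrom, t.pos, t.ref, t.alt))
        if candidates:
            q = candidates.pop(0)
            if sorted(q.genotype) == sorted(t.genotype):
                out.append((t, "truth", "TP"))
                out.append((q, "query", "TP"))
            else:  # right allele, wrong zygosity: miss plus spurious call
                out.append((t, "truth", "FN"))
                out.append((q, "query", "FP"))
        else:
            out.append((t, "truth", "FN"))
    for rest in by_site.values():
        out.extend((q, "query", "FP") for q in rest)
    return out


@dataclass
class ClassificationResult:
    classified: list[ClassifiedVariant]
    evaluation_region: RegionSet
    counts: "object" = None          # metrics.CountsTable, attached by classify
    n_clusters: int = 0
    n_split_flagged: int = 0


def _prepare(records: Sequence[VariantRecord],
             ref_seq: ReferenceAccessor) -> list[VariantRecord]:
    out = []
    for v in records:
        for b in decompose_multiallelic(v):
            out.append(normalize_variant(b, ref_seq))
    out.sort(key=lambda v: (v.chrom, v.start0, v.end0, v.alts))
    return out


def classify(truth: Sequence[VariantRecord],
             query: Sequence[VariantRecord],
             confident: RegionSet | None,
             roi: RegionSet,
             ref_seq: ReferenceAccessor, *,
             window: int = DEFAULT_WINDOW,
             max_cluster_size: int = DEFAULT_MAX_CLUSTER,
             pass_only: bool = True,
             binning=None) -> ClassificationResult:
    """End-to-end comparison of a query callset against a truth set.

    The evaluation region is ``confident ∩ roi`` when confidence regions
    are supplied, else ``roi``. Records are decomposed, normalized, and
    restricted: a record whose normalized footprint is not fully inside
    the evaluation region is labeled UNK and excluded from every tally.
    Remaining records are clustered and matched; tallies are split by
    variant type and InDel size bin (see :mod:`varbench.metrics`).
    """
    from . import metrics  # local import; metrics does not import us

    region = intersect(confident, roi) if confident is not None else roi
    if not region:
        raise ConfigurationError("evaluation region is empty")
    if truth or query:
        rec_chroms = {v.chrom for v in truth} | {v.chrom for v in query}
        if not rec_chroms & set(region.chroms()):
            raise ConfigurationError(
                f"contig namespaces disjoint: records on "
                f"{sorted(rec_chroms)}, region on {region.chroms()} "
                f"(consider chr_harmonize)")

    if pass_only:
        query = [v for v in query if v.is_pass]
    truth_n = _prepare(truth, ref_seq)
    query_n = _prepare(query, ref_seq)

    def eligible(v: VariantRecord) -> bool:
        return region.contains_interval(v.chrom, v.start0, v.end0)

    truth_in = [v for v in truth_n if eligible(v)]
    query_in = [v for v in query_n if eligible(v)]
    unk = ([(v, "truth") for v in truth_n if not eligible(v)]
           + [(v, "query") for v in query_n if not eligible(v)])

    pairs = cluster_variants(truth_in, query_in, window, max_cluster_size)
    classified: list[ClassifiedVariant] = []
    n_flagged = 0
    for pair in pairs:
        n_flagged += pair.split_flagged
        for rec, role, label in match_clusters(pair, ref_seq):
            classified.append(_classified(rec, role, label))
    for rec, role in unk:
        classified.append(_classified(rec, role, "UNK"))
    classified.sort(key=lambda c: (c.record.chrom, c.record.pos,
                                   c.record.ref, c.record.alts, c.role))

    result = ClassificationResult(
        classified=classified, evaluation_region=region,
        n_clusters=len(pairs), n_split_flagged=n_flagged)
    result.counts = metrics.tally(classified, region.total_bases,
                                  binning=binning)
    return result


def _classified(rec: VariantRecord, role: str, label: str) -> ClassifiedVariant:
    from .metrics import indel_size
    return ClassifiedVariant(record=rec, role=role, label=label,
                             vtype=rec.variant_type(),
                             indel_size=indel_size(rec))
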