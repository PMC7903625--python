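"""Presence/absence verification of named clinically relevant variants.

A clinical validation asserts specific variants (e.g. the GeT-RM reference
cell-line pathogenic calls) and asks whether the assay's query VCF detects
each of them. Detection must be robust to representation differences, so
each assertion is checked with the same haplotype machinery as the
benchmark comparison: the assertion is normalized, clustered with nearby
query calls, and declared detected when some phasing of the query cluster
spells a haplotype carrying the asserted allele. Genotype is not required
to match unless the assertion specifies one.
"""

from __future__ import annotations

from pathlib import Path
from collections.abc import Sequence

import pandas as pd

from .matchengine import (DEFAULT_WINDOW, cluster_variants,
                          haplotype_sequences, haplotype_spellings,
                          normalize_variant, _prepare, _spell_haplotype)
from .errors import InconsistentClusterError
from .reference import ReferenceAccessor
from .vcfio import TruthAssertion, VariantRecord


def _assertion_record(a: TruthAssertion) -> VariantRecord:
    return VariantRecord(chrom=a.chrom, pos=a.pos, ref=a.ref,
                         alts=(a.alt,), genotype=a.genotype or (0, 1),
                         sample_id=a.sample_id)


def verify_variant(assertion: TruthAssertion,
                   query: Sequence[VariantRecord],
                   ref_seq: ReferenceAccessor, *,
                   window: int = DEFAULT_WINDOW) -> bool:
    """True if a haplotype-equivalent call exists in the query.

    The assertion and the query records within ``window`` bp are clustered;
    the query cluster's phasings are enumerated and the assertion counts as
    detected when one query haplotype spells exactly the assertion's
    alternate sequence over the shared span. With an assertion genotype,
    the full unordered haplotype pair must match instead.
    """
    target = normalize_variant(_assertion_record(assertion), ref_seq)
    pairs = cluster_variants([target], list(query), window=window)
    pair = next(p for p in pairs if target in p.truth)
    if not pair.query:
        return False
    if assertion.genotype is None:
        want = _spell_haplotype([target], pair.chrom, pair.span, ref_seq)
        try:
            return want in haplotype_sequences(pair.query, pair.chrom,
                                               pair.span, ref_seq)
        except InconsistentClusterError:
            return any(q.pos == target.pos and q.ref == target.ref
                       and q.alt == target.alt for q in pair.query)
    try:
        want_pair = haplotype_spellings([target], pair.chrom, pair.span,
                                        ref_seq)
        got = haplotype_spellings(pair.query, pair.chrom, pair.span, ref_seq)
        return bool(want_pair & got)
    except InconsistentClusterError:
        return False


def verify_variants(assertions: Sequence[TruthAssertion],
                    query: Sequence[VariantRecord],
                    ref_seq: ReferenceAccessor, *,
                    window: int = DEFAULT_WINDOW,
                    path: str | Path | None = None) -> pd.DataFrame:
    """Verdict table for a batch of truth assertions.

    One row per assertion: sample, locus, alleles, whether detection was
    expected, the Yes/No verdict, and whether verdict and expectation
    agree. Query records are decomposed and normalized once up front.
    """
    query_n = _prepare(query, ref_seq)
    rows = []
    for a in assertions:
        detected = verify_variant(a, query_n, ref_seq, window=window)
        rows.append({
            "sample": a.sample_id,
            "chrom": a.chrom,
            "pos": a.pos,
            "ref": a.ref,
            "alt": a.alt,
            "expected": "Yes" if a.expected else "No",
            "detected": "Yes" if detected else "No",
            "concordant": "Yes" if detected == a.expected else "No",
        })
    df = pd.DataFrame(rows)
    if path:
        df.to_csv(path, sep="\t", index=False)
    return df
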