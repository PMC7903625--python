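"""Reading and writing the formats a benchmarking run touches.

VCF (v4.1+) carries the query and truth callsets; BED carries confidence
regions and regions of interest; a headered TSV carries clinical
truth-variant assertions; the comparison result is written back out as an
annotated two-sample VCF in the hap.py output convention (TRUTH/QUERY
columns with per-sample ``BD`` decision and ``BVT`` variant-type tags).

VCF positions are 1-based; BED intervals 0-based half-open. Those are the
format standards and every coordinate conversion in the package happens at
this boundary.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

from .errors import ConfigurationError, ParseError
from .stratify import RegionSet, merge

log = logging.getLogger(__name__)

LABELS = ("TP", "FP", "FN", "UNK")
VARIANT_TYPES = ("SNP", "MNP", "INDEL")


@dataclass(frozen=True)
class VariantRecord:
    """One variant call; after decomposition, the atom of comparison.

    ``pos`` is 1-based (VCF convention). ``alts`` holds every alternate
    allele as read; decomposition reduces records to a single carried
    alternate, after which ``alt`` is the allele and genotype indices are
    restricted to {0 (ref), 1 (alt)}.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int]
    phased: bool = False
    filters: frozenset[str] = field(default_factory=frozenset)
    sample_id: str = ""

    @property
    def alt(self) -> str:
        if len(self.alts) != 1:
            raise ValueError(
                f"multi-allelic record at {self.chrom}:{self.pos} not decomposed")
        return self.alts[0]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_pass(self) -> bool:
        return not self.filters or self.filters == {"PASS"}

    @property
    def start0(self) -> int:
        """0-based start of the reference footprint."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the reference footprint."""
        return self.pos - 1 + len(self.ref)

    def variant_type(self) -> str:
        return variant_type(self.ref, self.alt)

    def __str__(self) -> str:  # compact site notation for logs/errors
        return f"{self.chrom}:{self.pos} {self.ref}>{','.join(self.alts)}"


def variant_type(ref: str, alt: str) -> str:
    """SNP (1↔1), MNP (n↔n, n>1) or INDEL (length-changing)."""
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "INDEL"


@dataclass(frozen=True)
class TruthAssertion:
    """A clinically relevant variant whose presence/absence is asserted."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    expected: bool = True
    genotype: tuple[int, int] | None = None


@dataclass(frozen=True)
class ClassifiedVariant:
    """A comparison result: one record plus its role and decision label."""

    record: VariantRecord
    role: str                 # "truth" | "query"
    label: str                # TP | FP | FN | UNK
    vtype: str                # SNP | MNP | INDEL
    indel_size: int           # |len(alt) - len(ref)|; 0 for SNP/MNP

    def __post_init__(self) -> None:
        if self.role not in ("truth", "query"):
            raise ValueError(f"bad role {self.role!r}")
        if self.label not in LABELS:
            raise ValueError(f"bad label {self.label!r}")


class VcfRecords(list):
    """List of :class:`VariantRecord` plus read statistics."""

    n_dropped_missing_gt: int = 0


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def read_vcf(path: str | Path, sample_id: str | None = None, *,
             pass_only: bool = False,
             chr_harmonize: bool = False) -> VcfRecords:
    """Read a VCF into sorted :class:`VariantRecord` objects.

    Multi-allelic sites pass through intact (``alts`` keeps every allele)
    for later decomposition. Records with missing genotypes (``./.``) are
    dropped; the drop count is logged and kept on the returned list as
    ``n_dropped_missing_gt``. With ``pass_only`` records failing FILTER are
    excluded. ``chr_harmonize`` strips a ``chr`` prefix from contig names.

    Raises :class:`ParseError` on malformed input and
    :class:`ConfigurationError` when ``sample_id`` names an absent sample.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: cannot parse VCF: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if sample_id is not None:
            if sample_id not in samples:
                raise ConfigurationError(
                    f"{path}: sample {sample_id!r} absent "
                    f"(has {samples or 'no samples'})")
            sample = sample_id
        elif len(samples) == 1:
            sample = samples[0]
        else:
            raise ConfigurationError(
                f"{path}: multi-sample VCF, a sample_id is required "
                f"(has {samples})")

        out = VcfRecords()
        dropped = 0
        for lineno, rec in enumerate(vf, start=1):
            try:
                parsed = _parse_record(rec, sample, chr_harmonize)
            except ParseError:
                raise
            except Exception as exc:
                raise ParseError(
                    f"{path}: bad record #{lineno} at "
                    f"{rec.chrom}:{rec.pos}: {exc}") from exc
            if parsed is None:
                dropped += 1
                continue
            if pass_only and not parsed.is_pass:
                continue
            out.append(parsed)
    out.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alts))
    out.n_dropped_missing_gt = dropped
    if dropped:
        log.info("%s: dropped %d record(s) with missing genotype",
                 path, dropped)
    return out


def _parse_record(rec: pysam.VariantRecord, sample: str,
                  chr_harmonize: bool) -> VariantRecord | None:
    if rec.alts is None:
        return None  # no ALT: nothing to compare
    gt = rec.samples[sample].get("GT")
    if gt is None or all(a is None for a in gt):
        return None
    if any(a is None for a in gt):
        return None  # half-calls treated as missing
    if len(gt) == 1:
        gt = (gt[0], gt[0])  # haploid call treated as hom
    if len(gt) != 2:
        raise ParseError(f"ploidy {len(gt)} unsupported")
    alts = tuple(a.upper() for a in rec.alts)
    for a in alts + (rec.ref,):
        if not a or set(a) - set("ACGTN"):
            raise ParseError(f"non-nucleotide allele {a!r}")
    if max(gt) > len(alts):
        raise ParseError(f"GT references allele {max(gt)} but "
                         f"only {len(alts)} ALT allele(s) present")
    chrom = _strip_chr(rec.chrom) if chr_harmonize else rec.chrom
    return VariantRecord(
        chrom=chrom,
        pos=rec.pos,
        ref=rec.ref.upper(),
        alts=alts,
        genotype=(gt[0], gt[1]),
        phased=rec.samples[sample].phased,
        filters=frozenset(rec.filter.keys()),
        sample_id=sample,
    )


def read_bed(path: str | Path, *, chr_harmonize: bool = False) -> RegionSet:
    """Read a BED3+ file into a merged, sorted :class:`RegionSet`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = _strip_chr(fields[0]) if chr_harmonize else fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {start}-{end}")
            intervals.append((chrom, start, end))
    return merge(intervals)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    """Write contigs to FASTA (fixture-scale references)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_assertions(path: str | Path) -> list[TruthAssertion]:
    """Read a headered TSV of truth assertions.

    Required columns: sample, chrom, pos, ref, alt. Optional: genotype
    (e.g. ``0/1``), expected (yes/no, default yes).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            pos = int(row["pos"])
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 1}: bad pos") from exc
        ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
        if not ref or not alt or set(ref + alt) - set("ACGTN"):
            raise ParseError(f"{path}: row {i + 1}: bad alleles")
        gt = None
        if "genotype" in df.columns and pd.notna(row.get("genotype")):
            parts = str(row["genotype"]).replace("|", "/").split("/")
            gt = (int(parts[0]), int(parts[1]))
        expected = True
        if "expected" in df.columns and pd.notna(row.get("expected")):
            expected = str(row["expected"]).strip().lower() in (
                "yes", "true", "1", "y")
        out.append(TruthAssertion(
            sample_id=str(row["sample"]), chrom=str(row["chrom"]),
            pos=pos, ref=ref, alt=alt, expected=expected, genotype=gt))
    return out


def write_assertions(assertions: Sequence[TruthAssertion],
                     path: str | Path) -> None:
    rows = [{
        "sample": a.sample_id, "chrom": a.chrom, "pos": a.pos,
        "ref": a.ref, "alt": a.alt,
        "genotype": "" if a.genotype is None else "/".join(map(str, a.genotype)),
        "expected": "yes" if a.expected else "no",
    } for a in assertions]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_vcf(records: Sequence[VariantRecord], path: str | Path,
              contigs: dict[str, int], sample: str) -> None:
    """Write single-sample records as a sorted VCF (fixture-scale)."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    out = pysam.VariantFile(str(path), "w", header=header)
    with out:
        for v in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref,
                                                r.alts)):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref,) + v.alts,
                                 filter=sorted(v.filters) or "PASS")
            rec.samples[sample]["GT"] = v.genotype
            rec.samples[sample].phased = v.phased
            out.write(rec)


# ---------------------------------------------------------------------------
# annotated comparison VCF (hap.py-style TRUTH/QUERY columns)

def _annotated_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("BD", 1, "String",
                       "Decision for call (TP/FP/FN/UNK)")
    header.formats.add("BVT", 1, "String",
                       "High-level variant type (SNP|MNP|INDEL)")
    header.add_sample("TRUTH")
    header.add_sample("QUERY")
    return header


def write_annotated_vcf(records: Iterable[ClassifiedVariant],
                        path: str | Path,
                        contigs: dict[str, int]) -> None:
    """Write classified records as a two-sample (TRUTH, QUERY) VCF.

    Truth and query records at the same normalized site (chrom, pos, ref,
    alt) share one line; a side with no record at that site gets a missing
    genotype and ``BD`` ``.``. Output is coordinate-sorted and round-trips
    through :func:`read_annotated_vcf`.
    """
    by_site: dict[tuple, dict[str, ClassifiedVariant]] = {}
    for cv in records:
        r = cv.record
        site = (r.chrom, r.pos, r.ref, r.alt)
        slot = by_site.setdefault(site, {})
        if cv.role in slot:
            raise ValueError(f"duplicate {cv.role} record at {r}")
        slot[cv.role] = cv

    header = _annotated_header(contigs)
    out = pysam.VariantFile(str(path), "w", header=header)
    with out:
        for site in sorted(by_site):
            chrom, pos, ref, alt = site
            slot = by_site[site]
            rec = out.new_record(contig=chrom, start=pos - 1,
                                 alleles=(ref, alt), filter="PASS")
            for sample, role in (("TRUTH", "truth"), ("QUERY", "query")):
                cv = slot.get(role)
                if cv is None:
                    rec.samples[sample]["GT"] = (None, None)
                    rec.samples[sample]["BD"] = "."
                    rec.samples[sample]["BVT"] = "."
                    continue
                rec.samples[sample]["GT"] = cv.record.genotype
                rec.samples[sample].phased = cv.record.phased
                rec.samples[sample]["BD"] = cv.label
                rec.samples[sample]["BVT"] = cv.vtype
            out.write(rec)


def read_annotated_vcf(path: str | Path) -> list[ClassifiedVariant]:
    """Read a VCF written by :func:`write_annotated_vcf` back into objects."""
    out: list[ClassifiedVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for sample, role in (("TRUTH", "truth"), ("QUERY", "query")):
                fmt = rec.samples[sample]
                gt = fmt.get("GT")
                label = fmt.get("BD")
                if gt is None or all(a is None for a in gt) \
                        or label in (None, ".", ""):
                    continue
                vr = VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref.upper(),
                    alts=(rec.alts[0].upper(),),
                    genotype=(gt[0], gt[1]), phased=fmt.phased,
                    filters=frozenset(rec.filter.keys()), sample_id=sample)
                size = abs(len(vr.alt) - len(vr.ref))
                out.append(ClassifiedVariant(
                    record=vr, role=role, label=label,
                    vtype=fmt.get("BVT") or vr.variant_type(),
                    indel_size=size))
    return out


def write_metrics_table(rows: Sequence["object"], path: str | Path) -> None:
    """Write per-stratum metrics as a TSV (see metrics.MetricsResult).

    Raises :class:`ConfigurationError` on an empty report.
    """
    if not rows:
        raise ConfigurationError("metrics report has no rows")
    records = [r.as_row() for r in rows]
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
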