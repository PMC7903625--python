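"""Deterministic generator of desk-scale benchmarking fixtures.

Full-genome truth sets are far too large for unit testing, so every other
module is exercised against synthetic fixtures generated here: a toy
reference, a truth/query VCF pair with *planted* TP/FP/FN structure,
confidence and ROI BEDs, and a truth-assertion table. Because the intended
label of every planted record is known, the generator's ledger is an exact
oracle for the classifier and the metrics.

Planted structure:

* concordant SNPs and InDels (per size bin), optionally *re-represented*
  in the query — shared-base allele padding, right-shifted deletions
  inside planted homopolymer runs, and adjacent truth SNP pairs spelled as
  one query MNP — without changing the implied haplotypes;
* query-only records (intended FP), truth-only records (intended FN), and
  query records outside the ROI (intended UNK);
* genotypes drawn het/hom by a configurable mix.

Identical config + seed ⇒ byte-identical output files. Sub-streams of the
generator are derived per concern from one ``SeedSequence`` so adding one
output kind does not reshuffle the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .reference import DictReference
from .stratify import RegionSet, merge
from .vcfio import (TruthAssertion, VariantRecord, write_assertions,
                    write_bed, write_fasta, write_vcf)

BASES = np.array(list("ACGT"))


@dataclass
class FixtureConfig:
    """Knobs of the fixture generator; defaults are the study conditions."""

    seed: int = 0
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 24000})
    n_snp_tp: int = 50
    n_mnp_pairs: int = 0
    n_indel_tp: dict[str, int] = field(default_factory=lambda: {
        "1-10": 8, "11-20": 4, "21-50": 2, ">50": 1})
    n_homopolymer_shift: int = 0
    n_fp: int = 5
    n_fn: int = 3
    n_unk: int = 2
    het_fraction: float = 0.6
    perturb_pad_rate: float = 0.0
    min_spacing: int = 120
    sample_id: str = "SYNTH"


@dataclass
class PlantedRecord:
    """Ledger entry: what was planted and what label classify must give."""

    kind: str                # snp_tp | mnp_pair | indel_tp | homopolymer | fp | fn | unk
    chrom: str
    pos: int
    vtype: str
    size_bin: str            # "" for non-InDels
    truth: list[VariantRecord] = field(default_factory=list)
    query: list[VariantRecord] = field(default_factory=list)
    perturbation: str = ""


@dataclass
class FixtureManifest:
    """Paths, planted-truth ledger and expected tallies for one fixture."""

    config: FixtureConfig
    paths: dict[str, Path]
    records: list[PlantedRecord]
    sequences: dict[str, str]
    confident: RegionSet
    roi: RegionSet

    @property
    def reference(self) -> DictReference:
        return DictReference(self.sequences)

    def expected_counts(self) -> dict:
        """Oracle tallies by variant type and InDel size bin.

        Keys mirror ``metrics.CountsTable``: ``by_type`` and
        ``indel_by_bin``, each mapping to dicts with tp_truth, tp_query,
        fp, fn, truth_total.
        """
        def zero():
            return {"tp_truth": 0, "tp_query": 0, "fp": 0, "fn": 0,
                    "truth_total": 0}

        by_type = {t: zero() for t in ("SNP", "MNP", "INDEL")}
        by_bin: dict[str, dict] = {}

        def bump(vtype, size_bin, key, n=1):
            by_type[vtype][key] += n
            if vtype == "INDEL":
                by_bin.setdefault(size_bin, zero())[key] += n

        # types are those of the *normalized* records classify will see:
        # pad perturbations normalize back, so truth-side intent rules;
        # a joined MNP stays an MNP on the query side.
        for p in self.records:
            kind, b = p.kind, p.size_bin
            if kind == "unk":
                continue
            if kind == "snp_tp":
                bump("SNP", b, "truth_total")
                bump("SNP", b, "tp_truth")
                bump("SNP", b, "tp_query")
            elif kind == "mnp_pair":
                bump("SNP", b, "truth_total", 2)
                bump("SNP", b, "tp_truth", 2)
                bump("MNP", b, "tp_query")
            elif kind in ("indel_tp", "homopolymer"):
                bump("INDEL", b, "truth_total")
                bump("INDEL", b, "tp_truth")
                bump("INDEL", b, "tp_query")
            elif kind == "fp":
                bump(p.vtype, b, "fp")
            elif kind == "fn":
                bump(p.vtype, b, "truth_total")
                bump(p.vtype, b, "fn")
        return {"by_type": by_type, "indel_by_bin": by_bin}

    def n_unk(self) -> int:
        return sum(len(p.query) + len(p.truth)
                   for p in self.records if p.kind == "unk")


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, size=n)])


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def generate_fixture(cfg: FixtureConfig, outdir: str | Path,
                     ) -> FixtureManifest:
    """Generate one fixture under ``outdir`` and return its manifest.

    Raises :class:`ConfigurationError` when the contigs are too small to
    hold the requested variants at the required spacing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.seed)
    rng_seq, rng_place, rng_allele, rng_gt, rng_perturb = (
        np.random.default_rng(s) for s in root.spawn(5))

    # --- region geometry: confident ⊃ roi; evaluation region = roi here
    confident = merge((c, 60, length - 60)
                      for c, length in cfg.contig_lengths.items())
    roi = merge((c, 100, length - 100)
                for c, length in cfg.contig_lengths.items())

    # --- build the worklist of planted items
    items: list[tuple] = []
    items += [("snp_tp",)] * cfg.n_snp_tp
    items += [("mnp_pair",)] * cfg.n_mnp_pairs
    for label, n in cfg.n_indel_tp.items():
        items += [("indel_tp", label)] * n
    items += [("homopolymer",)] * cfg.n_homopolymer_shift
    items += [("fp",)] * cfg.n_fp
    items += [("fn",)] * cfg.n_fn
    order = rng_place.permutation(len(items))
    items = [items[i] for i in order]

    # --- slots: fixed raster plus bounded jitter keeps clusters apart
    slots: list[tuple[str, int]] = []
    for chrom, length in cfg.contig_lengths.items():
        lo, hi = 160, length - 160
        n_slots = max(0, (hi - lo) // cfg.min_spacing)
        for i in range(n_slots):
            base = lo + i * cfg.min_spacing
            slots.append((chrom, base + int(rng_place.integers(0, 20))))
    if len(items) > len(slots):
        raise ConfigurationError(
            f"contigs too small: {len(items)} variants requested but only "
            f"{len(slots)} slots at spacing {cfg.min_spacing}")
    slots = slots[:len(items)]

    sequences = {c: _rand_seq(rng_seq, n)
                 for c, n in cfg.contig_lengths.items()}

    planted: list[PlantedRecord] = []
    for (chrom, pos), item in zip(slots, items):
        planted.append(_plant(item, chrom, pos, sequences[chrom], cfg,
                              rng_allele, rng_gt, rng_perturb))

    # --- UNK: query-only records outside the ROI (inside [L-90, L-70))
    for chrom, length in cfg.contig_lengths.items():
        for i in range(cfg.n_unk):
            pos = length - 90 + 30 * i
            if pos + 5 >= length:
                raise ConfigurationError("contig too small for UNK records")
            seq = sequences[chrom]
            v = VariantRecord(chrom=chrom, pos=pos, ref=seq[pos - 1],
                              alts=(_other_base(rng_allele, seq[pos - 1]),),
                              genotype=(0, 1), sample_id=cfg.sample_id)
            planted.append(PlantedRecord(kind="unk", chrom=chrom, pos=pos,
                                         vtype="SNP", size_bin="",
                                         query=[v]))
        break  # UNK records only on the first contig

    seq_str = {c: "".join(s) for c, s in sequences.items()}
    truth = [v for p in planted for v in p.truth]
    query = [v for p in planted for v in p.query]

    paths = {
        "reference": outdir / "ref.fa",
        "truth_vcf": outdir / "truth.vcf",
        "query_vcf": outdir / "query.vcf",
        "confident_bed": outdir / "confident.bed",
        "roi_bed": outdir / "roi.bed",
        "assertions": outdir / "assertions.tsv",
        "ledger": outdir / "planted.json",
    }
    write_fasta(seq_str, paths["reference"])
    write_vcf(truth, paths["truth_vcf"], cfg.contig_lengths, cfg.sample_id)
    write_vcf(query, paths["query_vcf"], cfg.contig_lengths, cfg.sample_id)
    write_bed(confident, paths["confident_bed"])
    write_bed(roi, paths["roi_bed"])

    assertions = [
        TruthAssertion(sample_id=cfg.sample_id, chrom=v.chrom, pos=v.pos,
                       ref=v.ref, alt=v.alt)
        for p in planted if p.kind == "snp_tp" for v in p.truth][:3]
    write_assertions(assertions, paths["assertions"])
    _write_ledger(planted, paths["ledger"])

    return FixtureManifest(config=cfg, paths=paths, records=planted,
                           sequences=seq_str, confident=confident, roi=roi)


def _genotype(rng: np.random.Generator,
              het_fraction: float) -> tuple[int, int]:
    return (0, 1) if rng.random() < het_fraction else (1, 1)


def _plant(item: tuple, chrom: str, pos: int, seq: list[str],
           cfg: FixtureConfig, rng_allele: np.random.Generator,
           rng_gt: np.random.Generator,
           rng_perturb: np.random.Generator) -> PlantedRecord:
    kind = item[0]
    sid = cfg.sample_id
    gt = _genotype(rng_gt, cfg.het_fraction)

    if kind in ("snp_tp", "fp", "fn"):
        ref = seq[pos - 1]
        v = VariantRecord(chrom=chrom, pos=pos, ref=ref,
                          alts=(_other_base(rng_allele, ref),),
                          genotype=gt, sample_id=sid)
        p = PlantedRecord(kind=kind, chrom=chrom, pos=pos, vtype="SNP",
                          size_bin="")
        if kind != "fp":
            p.truth.append(v)
        if kind != "fn":
            q = v
            if kind == "snp_tp" and rng_perturb.random() < cfg.perturb_pad_rate:
                q = _pad_representation(v, seq, rng_perturb)
                p.perturbation = "pad"
            p.query.append(q)
        return p

    if kind == "mnp_pair":
        # truth: two adjacent SNPs (same genotype); query: one MNP
        r1, r2 = seq[pos - 1], seq[pos]
        a1, a2 = _other_base(rng_allele, r1), _other_base(rng_allele, r2)
        t1 = VariantRecord(chrom=chrom, pos=pos, ref=r1, alts=(a1,),
                           genotype=gt, sample_id=sid)
        t2 = VariantRecord(chrom=chrom, pos=pos + 1, ref=r2, alts=(a2,),
                           genotype=gt, sample_id=sid)
        q = VariantRecord(chrom=chrom, pos=pos, ref=r1 + r2, alts=(a1 + a2,),
                          genotype=gt, sample_id=sid)
        return PlantedRecord(kind=kind, chrom=chrom, pos=pos, vtype="MNP",
                             size_bin="", truth=[t1, t2], query=[q],
                             perturbation="mnp_join")

    if kind == "indel_tp":
        label = item[1]
        size = _sample_size(label, rng_allele)
        v = _make_indel(chrom, pos, size, seq, gt, sid, rng_allele)
        q = v
        perturbation = ""
        if rng_perturb.random() < cfg.perturb_pad_rate:
            q = _pad_representation(v, seq, rng_perturb)
            perturbation = "pad"
        return PlantedRecord(kind=kind, chrom=chrom, pos=pos, vtype="INDEL",
                             size_bin=label, truth=[v], query=[q],
                             perturbation=perturbation)

    if kind == "homopolymer":
        # deletion inside a planted T-run; query right-shifted along the run
        size = int(rng_allele.integers(1, 7))           # bin 1-10
        run = size + 4
        seq[pos - 1] = "A"                              # anchor, != run base
        for i in range(run):
            seq[pos + i] = "T"
        seq[pos + run] = "G"                            # run terminator
        truth = VariantRecord(chrom=chrom, pos=pos, ref="A" + "T" * size,
                              alts=("A",), genotype=gt, sample_id=sid)
        k = int(rng_perturb.integers(1, run - size + 1))
        query = VariantRecord(chrom=chrom, pos=pos + k,
                              ref="T" * (size + 1), alts=("T",),
                              genotype=gt, sample_id=sid)
        return PlantedRecord(kind=kind, chrom=chrom, pos=pos, vtype="INDEL",
                             size_bin="1-10", truth=[truth], query=[query],
                             perturbation=f"right_shift_{k}")

    raise AssertionError(f"unknown item kind {kind!r}")


def _sample_size(label: str, rng: np.random.Generator) -> int:
    lo, hi = {"1-10": (1, 10), "11-20": (11, 20),
              "21-50": (21, 50), ">50": (51, 58)}[label]
    return int(rng.integers(lo, hi + 1))


def _make_indel(chrom: str, pos: int, size: int, seq: list[str],
                gt: tuple[int, int], sid: str,
                rng: np.random.Generator) -> VariantRecord:
    anchor = seq[pos - 1]
    if rng.random() < 0.5:  # deletion
        ref = anchor + "".join(seq[pos:pos + size])
        alt = anchor
    else:                   # insertion
        ref = anchor
        alt = anchor + "".join(BASES[rng.integers(0, 4, size=size)])
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=(alt,),
                         genotype=gt, sample_id=sid)


def _pad_representation(v: VariantRecord, seq: list[str],
                        rng: np.random.Generator) -> VariantRecord:
    """Equivalent unnormalized spelling: shared prefix or suffix base."""
    if rng.random() < 0.5 and v.pos > 2:
        prev = seq[v.pos - 2]
        return dataclasses.replace(v, pos=v.pos - 1, ref=prev + v.ref,
                                   alts=(prev + v.alt,))
    nxt = seq[v.end0]
    return dataclasses.replace(v, ref=v.ref + nxt, alts=(v.alt + nxt,))


def _write_ledger(planted: list[PlantedRecord], path: Path) -> None:
    def vr(v: VariantRecord) -> dict:
        return {"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                "alt": v.alts[0], "gt": list(v.genotype)}

    data = [{
        "kind": p.kind, "chrom": p.chrom, "pos": p.pos, "vtype": p.vtype,
        "size_bin": p.size_bin, "perturbation": p.perturbation,
        "truth": [vr(v) for v in p.truth],
        "query": [vr(v) for v in p.query],
    } for p in planted]
    path.write_text(json.dumps(data, indent=1) + "\n")


# ---------------------------------------------------------------------------
# GeT-RM clinical-variant fixture

#: The six validated pathogenic variants (GRCh37), remapped onto short toy
#: contigs: each contig keeps the chromosome name and the position keeps
#: its final digits (offset recorded below).
GETRM_OFFSETS = {"15": 91_310_000, "17": 41_276_000,
                  "13": 32_914_000, "10": 43_609_000}

GETRM_VARIANTS = [
    # (sample, chrom, GRCh37 pos, ref, alt)
    ("NA04408", "15", 91_310_152, "TATC", "T"),
    ("NA04408", "15", 91_310_156, "T", "TA"),
    ("NA04408", "15", 91_310_158, "A", "ATTC"),
    ("NA14090", "17", 41_276_044, "ACT", "A"),
    ("NA14170", "13", 32_914_437, "GT", "G"),
    ("NA16658", "10", 43_609_103, "G", "T"),
]

_GETRM_CONTIG_LEN = {"15": 400, "17": 300, "13": 600, "10": 300}


def plant_getrm_fixture(outdir: str | Path, *,
                         drop: tuple[str, int] | None = None,
                         ) -> FixtureManifest:
    """Build the GeT-RM clinical-variant fixture.

    A toy reference spans the six validated pathogenic loci (offsets in
    :data:`GETRM_OFFSETS`), the query VCF carries all six variants, and
    the assertions TSV asserts their presence. ``drop=(chrom, local_pos)``
    omits one variant from the query, which must flip exactly that
    verdict. Deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(20210224)
    sequences = {c: _rand_seq(rng, n) for c, n in _GETRM_CONTIG_LEN.items()}

    local = []
    for sample, chrom, gpos, ref, alt in GETRM_VARIANTS:
        pos = gpos - GETRM_OFFSETS[chrom]
        seq = sequences[chrom]
        for i, base in enumerate(ref):
            seq[pos - 1 + i] = base
        # guard bases so the planted alleles normalize in place
        if pos >= 2 and len(ref) != len(alt):
            seq[pos - 2] = _other_base(rng, ref[-1])
        local.append((sample, chrom, pos, ref, alt))

    records, assertions, planted = [], [], []
    for sample, chrom, pos, ref, alt in local:
        v = VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=(alt,),
                          genotype=(0, 1), sample_id="GETRM")
        assertions.append(TruthAssertion(sample_id=sample, chrom=chrom,
                                         pos=pos, ref=ref, alt=alt))
        if drop == (chrom, pos):
            continue
        records.append(v)
        planted.append(PlantedRecord(
            kind="snp_tp" if len(ref) == len(alt) else "indel_tp",
            chrom=chrom, pos=pos,
            vtype=v.variant_type(),
            size_bin="1-10" if len(ref) != len(alt) else "",
            query=[v]))

    seq_str = {c: "".join(s) for c, s in sequences.items()}
    confident = merge((c, 0, n) for c, n in _GETRM_CONTIG_LEN.items())
    paths = {
        "reference": outdir / "ref.fa",
        "query_vcf": outdir / "query.vcf",
        "assertions": outdir / "assertions.tsv",
        "confident_bed": outdir / "confident.bed",
    }
    write_fasta(seq_str, paths["reference"])
    write_vcf(records, paths["query_vcf"], _GETRM_CONTIG_LEN, "GETRM")
    write_assertions(assertions, paths["assertions"])
    write_bed(confident, paths["confident_bed"])

    cfg = FixtureConfig(seed=20210224,
                        contig_lengths=dict(_GETRM_CONTIG_LEN),
                        n_snp_tp=0, n_fp=0, n_fn=0, n_unk=0,
                        n_indel_tp={}, sample_id="GETRM")
    return FixtureManifest(config=cfg, paths=paths, records=planted,
                           sequences=seq_str, confident=confident,
                           roi=confident)
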