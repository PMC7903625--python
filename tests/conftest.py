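import pytest

from varbench import matchengine, vcfio
from varbench.reference import DictReference, FastaReference
from varbench.synthdata import generate_fixture
from varbench.vcfio import VariantRecord


def make_variant(chrom="chr1", pos=1, ref="A", alt="G", gt=(0, 1),
                 phased=False, sample="S1", filters=()):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=(alt,),
                         genotype=gt, phased=phased,
                         filters=frozenset(filters), sample_id=sample)


@pytest.fixture
def dict_ref():
    """In-memory reference with a hand-readable contig."""
    #        1234567890123456789012345678901234567890
    seq = "GCATTTTGACGTACGTACGTAACCGGTTACGATCGATCGA" * 3
    return DictReference({"chr1": seq})


@pytest.fixture
def classify_fixture(tmp_path):
    """Generate a fixture, run classify end-to-end through file I/O."""

    def _run(cfg, **classify_kwargs):
        manifest = generate_fixture(cfg, tmp_path / f"fx{cfg.seed}")
        truth = vcfio.read_vcf(manifest.paths["truth_vcf"])
        query = vcfio.read_vcf(manifest.paths["query_vcf"])
        confident = vcfio.read_bed(manifest.paths["confident_bed"])
        roi = vcfio.read_bed(manifest.paths["roi_bed"])
        ref = FastaReference(str(manifest.paths["reference"]))
        result = matchengine.classify(truth, query, confident, roi, ref,
                                      **classify_kwargs)
        return manifest, result

    return _run


def counts_tuple(c):
    return (c.tp_truth, c.tp_query, c.fp, c.fn, c.truth_total)


def expected_tuple(e):
    return (e["tp_truth"], e["tp_query"], e["fp"], e["fn"],
            e["truth_total"])
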