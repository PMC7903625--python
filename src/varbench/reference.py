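"""Reference-sequence access.

Normalization and haplotype spelling both need random access to reference
bases. Two backends share one interface: a pyfaidx-backed FASTA accessor for
real files and a dict-backed in-memory accessor for fixtures and tests.
Both return uppercase sequence (soft-masked lowercase is uppercased before
any comparison) over 0-based half-open coordinates.
"""

from __future__ import annotations

from pyfaidx import Fasta


class ReferenceAccessor:
    """Uppercase random access to reference contigs, 0-based half-open."""

    def fetch(self, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError

    def contig_length(self, chrom: str) -> int:
        raise NotImplementedError


class FastaReference(ReferenceAccessor):
    """Reference backed by an (indexed) FASTA file via pyfaidx."""

    def __init__(self, path: str):
        self._fasta = Fasta(path, as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} not in reference")
        return str(self._fasta[chrom][start:end])

    def contig_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())


class DictReference(ReferenceAccessor):
    """In-memory reference; the fixture generator's native backend."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"contig {chrom!r} not in reference")
        return self._seqs[chrom][start:end]

    def contig_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def contigs(self) -> list[str]:
        return list(self._seqs)
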