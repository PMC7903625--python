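"""Benchmarking metrics from classification tallies and region base counts.

For one stratum (sample × region × variant type × InDel size bin):

    precision       = TP_query / (TP_query + FP)
    recall          = TP_truth / (TP_truth + FN)
    TN              = region bases − (TP + FP + FN)
    total negatives = TN + FP
    NPA             = TN / total negatives        (specificity surrogate)

all rendered as percentages. TP is counted twice: over query records (the
precision numerator) and over truth records (the recall numerator); the two
differ only when representation splits match one truth record to several
query records or vice versa.

Undefined ratios (0/0) are reported as unavailable, never as 0 or 100.
Full-precision values are stored; rendering rounds half-up to 2 decimals,
with an integer option for NPA (which in clinical-exome-sized regions is
indistinguishable from 100 at 2 decimals anyway).

InDel sizes bin as 1–10, 11–20, 21–50 and >50 bp by default; coarser
report bins (e.g. 1–20) are produced by summing counts and recomputing —
never by averaging percentages.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .vcfio import ClassifiedVariant, VariantRecord


# ---------------------------------------------------------------------------
# sizes and bins

def indel_size(v: VariantRecord) -> int:
    """Length change |len(alt) − len(ref)|; 0 marks SNP/MNP records."""
    return abs(len(v.alt) - len(v.ref))


@dataclass(frozen=True)
class SizeBinning:
    """Ordered, disjoint InDel size ranges covering every size ≥ 1.

    ``edges`` holds inclusive ``(lo, hi)`` pairs; the final ``hi`` of
    ``None`` means open-ended.
    """

    edges: tuple[tuple[int, int | None], ...] = (
        (1, 10), (11, 20), (21, 50), (51, None))

    def __post_init__(self) -> None:
        lo_expected = 1
        for lo, hi in self.edges:
            if lo != lo_expected:
                raise ConfigurationError(
                    f"size bins must tile sizes >= 1; gap before {lo}")
            if hi is not None and hi < lo:
                raise ConfigurationError(f"bad bin {lo}-{hi}")
            lo_expected = (hi + 1) if hi is not None else None
            if lo_expected is None:
                break
        if lo_expected is not None:
            raise ConfigurationError("last size bin must be open-ended")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(_bin_label(lo, hi) for lo, hi in self.edges)

    def assign(self, size: int) -> str:
        if size < 1:
            raise ValueError("InDel size must be >= 1 (0 is SNP/MNP)")
        for lo, hi in self.edges:
            if size >= lo and (hi is None or size <= hi):
                return _bin_label(lo, hi)
        raise AssertionError("unreachable: bins cover all sizes >= 1")

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "SizeBinning":
        return cls(tuple(_parse_bin_label(l) for l in labels))


def _bin_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"


def _parse_bin_label(label: str) -> tuple[int, int | None]:
    label = label.strip()
    m = re.fullmatch(r">\s*(\d+)", label)
    if m:
        return (int(m.group(1)) + 1, None)
    m = re.fullmatch(r"(\d+)\s*[-–]\s*(\d+)", label)
    if m:
        return (int(m.group(1)), int(m.group(2)))
    raise ConfigurationError(f"cannot parse size bin {label!r}")


DEFAULT_BINNING = SizeBinning()
ALL_INDELS = "All Indels"


def assign_bin(size: int, binning: SizeBinning = DEFAULT_BINNING) -> str:
    """Unique bin label whose inclusive range contains ``size``."""
    return binning.assign(size)


# ---------------------------------------------------------------------------
# confusion counts

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN tallies for one stratum plus its region base count."""

    tp_truth: int = 0
    tp_query: int = 0
    fp: int = 0
    fn: int = 0
    truth_total: int = 0
    total_bases: int = 0

    @property
    def tn(self) -> int:
        return self.total_bases - (self.tp_query + self.fp + self.fn)

    @property
    def total_negatives(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.total_bases != other.total_bases:
            raise ValueError("cannot sum strata with different base counts")
        return ConfusionCounts(
            tp_truth=self.tp_truth + other.tp_truth,
            tp_query=self.tp_query + other.tp_query,
            fp=self.fp + other.fp, fn=self.fn + other.fn,
            truth_total=self.truth_total + other.truth_total,
            total_bases=self.total_bases)


@dataclass(frozen=True)
class MetricsResult:
    """Derived metrics for one stratum; percentages at full precision."""

    counts: ConfusionCounts
    precision: float | None
    recall: float | None
    npa: float | None
    tn: int
    total_negatives: int
    sample: str = ""
    region: str = ""
    vtype: str = ""
    size_bin: str = ""

    def as_row(self, *, round_digits: int = 2,
               npa_render: str = "int") -> dict:
        """Flat dict for the TSV report (published-table style rendering)."""
        c = self.counts
        if self.npa is None:
            npa = "NA"
        elif npa_render == "int":
            npa = str(int(_round_half_up(self.npa, 0)))
        else:
            npa = _fmt(self.npa, round_digits)
        return {
            "sample": self.sample, "region": self.region,
            "variant_type": self.vtype, "size_bin": self.size_bin,
            "total_bases": c.total_bases, "truth_total": c.truth_total,
            "TP": c.tp_query, "TP_truth": c.tp_truth,
            "FP": c.fp, "FN": c.fn, "TN": self.tn,
            "NPA": npa,
            "precision": _fmt(self.precision, round_digits),
            "recall": _fmt(self.recall, round_digits),
        }


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float | None, digits: int) -> str:
    return "NA" if x is None else f"{_round_half_up(x, digits):.{digits}f}"


def compute_metrics(c: ConfusionCounts, *, sample: str = "",
                    region: str = "", vtype: str = "",
                    size_bin: str = "") -> MetricsResult:
    """Precision, recall, TN, total negatives and NPA from raw tallies.

    Raises :class:`ConfigurationError` when derived TN is negative (the
    tallies exceed the region size, an input inconsistency).
    """
    tn = c.tn
    if c.total_bases > 0 and tn < 0:
        raise ConfigurationError(
            f"negative TN: counts exceed region size ({c})")
    precision = (100.0 * c.tp_query / (c.tp_query + c.fp)
                 if c.tp_query + c.fp > 0 else None)
    recall = (100.0 * c.tp_truth / (c.tp_truth + c.fn)
              if c.tp_truth + c.fn > 0 else None)
    total_neg = tn + c.fp
    npa = 100.0 * tn / total_neg if c.total_bases > 0 and total_neg > 0 else None
    return MetricsResult(counts=c, precision=precision, recall=recall,
                         npa=npa, tn=tn, total_negatives=total_neg,
                         sample=sample, region=region, vtype=vtype,
                         size_bin=size_bin)


# ---------------------------------------------------------------------------
# tallying classified records

@dataclass
class CountsTable:
    """Per-stratum tallies from one classification run."""

    by_type: dict[str, ConfusionCounts] = field(default_factory=dict)
    indel_by_bin: dict[str, ConfusionCounts] = field(default_factory=dict)
    total_bases: int = 0
    binning: SizeBinning = DEFAULT_BINNING

    @property
    def all_indels(self) -> ConfusionCounts:
        return self.by_type.get(
            "INDEL", ConfusionCounts(total_bases=self.total_bases))


def tally(classified: Iterable[ClassifiedVariant], total_bases: int,
          binning: SizeBinning | None = None) -> CountsTable:
    """Tally TP/FP/FN by variant type and InDel size bin.

    UNK records are ignored. TP is tallied on the query side for precision
    and on the truth side for recall; truth_total counts all non-UNK truth
    records in the stratum.
    """
    binning = binning or DEFAULT_BINNING
    acc: dict[tuple[str, str], dict[str, int]] = {}

    def bump(vtype: str, size_bin: str, key: str, n: int = 1) -> None:
        d = acc.setdefault((vtype, size_bin), {
            "tp_truth": 0, "tp_query": 0, "fp": 0, "fn": 0, "truth_total": 0})
        d[key] += n

    for cv in classified:
        if cv.label == "UNK":
            continue
        size_bin = binning.assign(cv.indel_size) if cv.vtype == "INDEL" else ""
        if cv.role == "truth":
            bump(cv.vtype, size_bin, "truth_total")
            bump(cv.vtype, size_bin, "tp_truth" if cv.label == "TP" else "fn")
        else:
            bump(cv.vtype, size_bin, "tp_query" if cv.label == "TP" else "fp")

    table = CountsTable(total_bases=total_bases, binning=binning)
    for vtype in ("SNP", "MNP", "INDEL"):
        cells = [v for (t, _), v in acc.items() if t == vtype]
        table.by_type[vtype] = _counts_from(cells, total_bases)
    for label in binning.labels:
        cells = [v for (t, b), v in acc.items()
                 if t == "INDEL" and b == label]
        table.indel_by_bin[label] = _counts_from(cells, total_bases)
    return table


def _counts_from(cells: list[dict[str, int]],
                 total_bases: int) -> ConfusionCounts:
    return ConfusionCounts(
        tp_truth=sum(c["tp_truth"] for c in cells),
        tp_query=sum(c["tp_query"] for c in cells),
        fp=sum(c["fp"] for c in cells),
        fn=sum(c["fn"] for c in cells),
        truth_total=sum(c["truth_total"] for c in cells),
        total_bases=total_bases)


def merge_bins(per_bin: Mapping[str, ConfusionCounts],
               target_labels: Sequence[str],
               base_binning: SizeBinning = DEFAULT_BINNING,
               ) -> dict[str, ConfusionCounts]:
    """Sum per-bin counts into coarser report bins.

    Every target range must be expressible as a union of consecutive base
    bins (e.g. 1–20 from 1–10 and 11–20); metrics are then recomputed from
    the summed counts, never averaged.
    """
    out: dict[str, ConfusionCounts] = {}
    for label in target_labels:
        lo, hi = _parse_bin_label(label)
        parts = []
        covered_lo = None
        for (blo, bhi), blabel in zip(base_binning.edges,
                                      base_binning.labels):
            inside = blo >= lo and (hi is None or (bhi is not None and bhi <= hi))
            if inside:
                if covered_lo is None:
                    covered_lo = blo
                parts.append((blo, bhi, blabel))
        if not parts or covered_lo != lo or (
                hi is not None and parts[-1][1] != hi) or (
                hi is None and parts[-1][1] is not None):
            raise ConfigurationError(
                f"target bin {label!r} is not a union of base bins "
                f"{list(base_binning.labels)}")
        total = None
        for _, _, blabel in parts:
            c = per_bin.get(blabel)
            if c is None:
                raise ConfigurationError(f"missing base bin {blabel!r}")
            total = c if total is None else total + c
        out[label] = total
    return out


# ---------------------------------------------------------------------------
# InDel size spectrum

def spectrum_histogram(classified: Iterable[ClassifiedVariant],
                       binning: SizeBinning | None = None,
                       tsv_path: str | Path | None = None,
                       plot_path: str | Path | None = None) -> pd.DataFrame:
    """Per-bin, per-label InDel counts; optionally written as TSV and plot.

    The counts equal the per-bin ConfusionCounts used for the metrics (TP
    shown on the truth side, consistent with a truth-anchored histogram;
    FP is query-side by definition).
    """
    binning = binning or DEFAULT_BINNING
    rows = {label: {"TP": 0, "FP": 0, "FN": 0} for label in binning.labels}
    for cv in classified:
        if cv.vtype != "INDEL" or cv.label == "UNK":
            continue
        b = binning.assign(cv.indel_size)
        if cv.role == "truth" and cv.label in ("TP", "FN"):
            rows[b][cv.label] += 1
        elif cv.role == "query" and cv.label == "FP":
            rows[b]["FP"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "size_bin"
    if tsv_path:
        df.to_csv(tsv_path, sep="\t")
    if plot_path:
        _plot_spectrum(df, plot_path)
    return df


def _plot_spectrum(df: pd.DataFrame, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    df.plot.bar(ax=ax, color={"TP": "#2b8cbe", "FP": "#e34a33",
                              "FN": "#636363"})
    ax.set_xlabel("InDel size (bp)")
    ax.set_ylabel("count")
    ax.set_title("InDel size spectrum")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# consolidated multi-sample report

def md5sum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def consolidate(results: Sequence[MetricsResult],
                merged_results: Sequence[MetricsResult] = (),
                verification: pd.DataFrame | None = None,
                input_files: Mapping[str, str | Path] | None = None,
                config_echo: Mapping | None = None,
                path: str | Path | None = None, *,
                npa_render: str = "int") -> str:
    """Assemble the final multi-sample validation report.

    Deterministic: identical inputs give a byte-identical report. The
    provenance header records the toolkit version, the configuration and
    an MD5 checksum per input file.
    """
    from . import __version__

    if not results:
        raise ConfigurationError("no metrics to consolidate")
    lines: list[str] = []
    lines.append("# Analytical validation report")
    lines.append(f"# varbench {__version__}")
    if config_echo:
        for k in sorted(config_echo):
            lines.append(f"# config {k} = {config_echo[k]}")
    if input_files:
        for name in sorted(input_files):
            lines.append(f"# input {name} md5={md5sum(input_files[name])}")
    lines.append("")

    def block(title: str, rows: Sequence[MetricsResult]) -> None:
        if not rows:
            return
        lines.append(f"## {title}")
        df = pd.DataFrame([r.as_row(npa_render=npa_render) for r in rows])
        lines.append(df.to_csv(sep="\t", index=False).rstrip("\n"))
        lines.append("")

    block("Benchmarking metrics", results)
    block("Merged-bin metrics", merged_results)
    if verification is not None and len(verification):
        lines.append("## Truth-variant verification")
        lines.append(verification.to_csv(sep="\t", index=False).rstrip("\n"))
        lines.append("")
    text = "\n".join(lines)
    if path:
        Path(path).write_text(text)
    return text
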