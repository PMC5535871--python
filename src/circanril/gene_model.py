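"""Ordered exon/intron model of a gene locus on genomic coordinates.

The central object is :class:`GeneModel`: an ordered list of labelled exons
(canonical exons carry integer ordinals ``1..n``; novel exons such as ``4N1``
carry intermediate rational ordinals; the alternative terminal exons ``13a``
and ``13b`` both map to ordinal 13) together with the introns derived from
consecutive canonical exons.  Intron ``i`` is the gap between canonical exon
``i`` and canonical exon ``i+1`` in gene order, so a model with ``n``
canonical exons has exactly ``n - 1`` introns.

All internal coordinates are 0-based half-open.  GTF (1-based inclusive) and
BED (0-based half-open) dialects are converted at the file boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "ExonRecord",
    "IntronRecord",
    "GeneModel",
    "derive_introns",
    "load_gene_model",
    "write_gtf",
    "anril_gene_model",
]

_NOVEL_LABEL = re.compile(r"^(\d+)N(\d+)$")
_VARIANT_LABEL = re.compile(r"^(\d+)[a-z]$")


class GeneModelError(ValueError):
    """Raised for malformed annotations or inconsistent exon layouts."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GeneModelError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def parse_ordinal(label: str) -> Fraction:
    """Map an exon label to its rational position in gene order.

    Canonical labels ("7") map to integers.  Novel labels ("4N1") fall in the
    open interval between the flanking canonical ordinals, ordered by their
    novel index.  Variant terminal exons ("13a"/"13b") share the canonical
    ordinal of their position.
    """
    if label.isdigit():
        return Fraction(int(label))
    m = _NOVEL_LABEL.match(label)
    if m:
        k, j = int(m.group(1)), int(m.group(2))
        # monotone in j and strictly inside (k, k+1)
        return Fraction(k) + Fraction(j, j + 1)
    m = _VARIANT_LABEL.match(label)
    if m:
        return Fraction(int(m.group(1)))
    raise GeneModelError(f"cannot derive gene-order position from exon label {label!r}")


@dataclass(frozen=True)
class ExonRecord:
    """A labelled exon; ``interval`` may be absent for label-only models."""

    label: str
    ordinal: Fraction
    interval: GenomicInterval | None = None
    variant_of: str | None = None  # transcript variant for "13a"/"13b" style labels

    @property
    def is_canonical(self) -> bool:
        return self.ordinal.denominator == 1 and self.label.isdigit()


@dataclass(frozen=True)
class IntronRecord:
    """Intron ``index`` lies between canonical exons ``index`` and ``index+1``."""

    index: int
    interval: GenomicInterval | None = None
    length: int = 0


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    exons: list[ExonRecord] = field(default_factory=list)
    introns: list[IntronRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.exons]
        if len(labels) != len(set(labels)):
            raise GeneModelError(f"duplicate exon labels in model {self.gene_id}")
        ords = [e.ordinal for e in self.exons]
        if any(b <= a for a, b in zip(ords, ords[1:])):
            raise GeneModelError("exon ordinals must be strictly increasing in gene order")

    # -- lookups ---------------------------------------------------------
    @property
    def canonical_exons(self) -> list[ExonRecord]:
        return [e for e in self.exons if e.is_canonical]

    @property
    def n_canonical(self) -> int:
        return len(self.canonical_exons)

    @property
    def chrom(self) -> str | None:
        for e in self.exons:
            if e.interval is not None:
                return e.interval.chrom
        return None

    def exon(self, label: str) -> ExonRecord:
        for e in self.exons:
            if e.label == label:
                return e
        raise KeyError(f"exon {label!r} not in model {self.gene_id}")

    def has_exon(self, label: str) -> bool:
        return any(e.label == label for e in self.exons)

    def ordinal(self, label: str) -> Fraction:
        """Gene-order position of a label; falls back to the label grammar for
        novel exons that are absent from the model (catalogue-only labels)."""
        for e in self.exons:
            if e.label == label:
                return e.ordinal
        ordn = parse_ordinal(label)  # raises GeneModelError on unknown grammar
        lo, hi = self.exons[0].ordinal, self.exons[-1].ordinal
        if not (lo <= ordn <= hi):
            raise GeneModelError(
                f"exon label {label!r} lies outside gene model {self.gene_id}"
            )
        return ordn

    def intron(self, index: int) -> IntronRecord:
        for i in self.introns:
            if i.index == index:
                return i
        raise KeyError(f"intron {index} not in model {self.gene_id}")

    @property
    def span(self) -> GenomicInterval:
        ivs = [e.interval for e in self.exons if e.interval is not None]
        if not ivs:
            raise GeneModelError("model has no exon intervals")
        return GenomicInterval(
            ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs), self.strand
        )


def derive_introns(exons: Sequence[ExonRecord]) -> list[IntronRecord]:
    """Introns between consecutive canonical exons.

    Requires >= 2 canonical exons with intervals; exons must not overlap or
    abut (a zero-length intron is a malformed model).
    """
    canon = [e for e in exons if e.is_canonical]
    if len(canon) < 2:
        raise GeneModelError("need at least two canonical exons to derive introns")
    if any(e.interval is None for e in canon):
        raise GeneModelError("cannot derive introns without exon intervals")
    strand = canon[0].interval.strand  # type: ignore[union-attr]
    # gene order == genomic order on +, reversed on -
    genomic = canon if strand == "+" else list(reversed(canon))
    introns: list[IntronRecord] = []
    for a, b in zip(genomic, genomic[1:]):
        ia, ib = a.interval, b.interval
        assert ia is not None and ib is not None
        if ib.start <= ia.end:
            raise GeneModelError(
                f"exons {a.label!r} and {b.label!r} overlap or abut "
                f"({ia.start}-{ia.end} vs {ib.start}-{ib.end})"
            )
        index = int(min(a.ordinal, b.ordinal))
        iv = GenomicInterval(ia.chrom, ia.end, ib.start, strand)
        introns.append(IntronRecord(index=index, interval=iv, length=len(iv)))
    introns.sort(key=lambda r: r.index)
    return introns


def _build_model(
    gene_id: str,
    strand: str,
    intervals: list[GenomicInterval],
    labels: list[str] | None = None,
) -> GeneModel:
    order = sorted(range(len(intervals)), key=lambda k: intervals[k].start)
    if strand == "-":
        order = order[::-1]
    if labels is None:
        labels = [str(i + 1) for i in range(len(intervals))]
        exons = [
            ExonRecord(labels[rank], Fraction(rank + 1), intervals[k])
            for rank, k in enumerate(order)
        ]
    else:
        exons = [
            ExonRecord(labels[k], parse_ordinal(labels[k]), intervals[k])
            for k in order
        ]
    model = GeneModel(gene_id=gene_id, strand=strand, exons=exons)
    model.introns = derive_introns(model.exons)
    return model


def _load_from_gtf(path: Path, gene_id: str) -> GeneModel:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    have_labels = True
    seen: set[tuple[int, int]] = set()
    strand = "+"
    for feat in db.all_features():
        if feat.featuretype != "exon":
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid != gene_id:
            continue
        key = (feat.start - 1, feat.end)
        if key in seen:  # same exon from another transcript line
            continue
        seen.add(key)
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        intervals.append(GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand))
        lab = feat.attributes.get("exon_label", [None])[0]
        if lab is None:
            have_labels = False
        labels.append(lab)  # type: ignore[arg-type]
    if not intervals:
        raise GeneModelError(f"gene {gene_id!r} not found in {path}")
    if len(intervals) < 2:
        raise GeneModelError(f"gene {gene_id!r} has a single exon; no introns to model")
    return _build_model(gene_id, strand, intervals, labels if have_labels else None)


def _load_from_bed12(path: Path, gene_id: str) -> GeneModel:
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise GeneModelError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
        if f[3] != gene_id:
            continue
        chrom, chrom_start, strand = f[0], int(f[1]), f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if not (len(sizes) == len(starts) == n_blocks):
            raise GeneModelError(f"{path}:{lineno}: blockCount does not match block lists")
        if n_blocks < 2:
            raise GeneModelError(f"gene {gene_id!r} has a single exon; no introns to model")
        intervals = [
            GenomicInterval(chrom, chrom_start + s, chrom_start + s + sz, strand)
            for s, sz in zip(starts, sizes)
        ]
        return _build_model(gene_id, strand, intervals)
    raise GeneModelError(f"gene {gene_id!r} not found in {path}")


def load_gene_model(annotation_path: str | Path, gene_id: str) -> GeneModel:
    """Load a gene model from a GTF/GFF3 file or a BED12 file.

    Exon labels are taken from an ``exon_label`` attribute when every exon
    carries one, otherwise exons are numbered 1..n in gene order (respecting
    strand).  Raises :class:`GeneModelError` if the gene is missing or has a
    single exon.
    """
    path = Path(annotation_path)
    suffix = path.suffix.lower()
    if suffix in (".bed", ".bed12"):
        return _load_from_bed12(path, gene_id)
    return _load_from_gtf(path, gene_id)


def write_gtf(model: GeneModel, path: str | Path, source: str = "circanril") -> None:
    """Write the model's exons as GTF (1-based inclusive), one line per exon."""
    lines = []
    exons = sorted(
        (e for e in model.exons if e.interval is not None),
        key=lambda e: e.interval.start,  # type: ignore[union-attr]
    )
    for e in exons:
        iv = e.interval
        assert iv is not None
        attrs = (
            f'gene_id "{model.gene_id}"; transcript_id "{model.gene_id}.1"; '
            f'exon_label "{e.label}";'
        )
        lines.append(
            "\t".join(
                [iv.chrom, source, "exon", str(iv.start + 1), str(iv.end), ".",
                 iv.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def anril_gene_model() -> GeneModel:
    """The bundled 19-exon model of the ANRIL (CDKN2B-AS1) locus, chr9 (+).

    Exon boundaries that coincide with the splice sites printed in the
    published skipped-exon event coordinates are anchored to those values;
    the remaining boundaries (exon 1, exon 2 start, exon 4 end, exon 5,
    exon 6 start, exon 13 end, exon 17 end, exon 19 end) are synthetic
    fill-ins, chosen to be consistent with the anchored sites.  The bundled
    file documents which is which.
    """
    ref = resources.files("circanril.data") / "anril_19exon_model.synthetic.gtf"
    with resources.as_file(ref) as path:
        return load_gene_model(path, "CDKN2B-AS1")
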