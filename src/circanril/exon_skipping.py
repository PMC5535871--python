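"""Skipped-exon (SE) events and exon-skipping-derived circle candidates.

Under the lariat model of circRNA biogenesis, an exon-skipping event whose
flanking splice sites span a run of exons could release that run as a
circle.  An SE event is written in the SUPPA-style identifier dialect

    GENE;SE:chrom:e1-s2:e2-s3:strand

where ``e1`` is the end of the upstream flanking exon, ``s2``/``e2`` bound
the skipped exon and ``s3`` starts the downstream flanking exon (ends are
half-open, matching the internal 0-based convention).  The candidate circle
exon set of an event is every canonical exon of the gene model lying
strictly within the open interval ``(e1, s3)``; a candidate "completely
matches" an observed circle when the exon sets are equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .gene_model import GeneModel
from .isoform_catalogue import Catalogue, CircIsoform

__all__ = [
    "SkippedExonEvent",
    "SkippingError",
    "parse_se_event",
    "format_se_event",
    "read_se_events",
    "anril_se_events",
    "potential_circ_exons",
    "match_skipping_to_catalogue",
]

_SE_RE = re.compile(
    r"^(?P<gene>[^;]+);SE:(?P<chrom>[^:]+):(?P<a>\d+)-(?P<b>\d+)"
    r":(?P<c>\d+)-(?P<d>\d+):(?P<strand>[+-])$"
)


class SkippingError(ValueError):
    pass


@dataclass(frozen=True)
class SkippedExonEvent:
    gene: str
    chrom: str
    e1_end: int      # end of upstream flanking exon
    e2_start: int    # skipped exon bounds
    e2_end: int
    e3_start: int    # start of downstream flanking exon
    strand: str

    def __post_init__(self) -> None:
        if not self.e1_end < self.e2_start < self.e2_end < self.e3_start:
            raise SkippingError(
                f"SE coordinates must be strictly ordered "
                f"e1_end < e2_start < e2_end < e3_start, got "
                f"{self.e1_end}:{self.e2_start}-{self.e2_end}:{self.e3_start}"
            )


def parse_se_event(text: str) -> SkippedExonEvent:
    """Parse one SE identifier like
    ``"CDKN2B-AS1;SE:chr9:22029593-22032673:22032985-22046316:+"``."""
    m = _SE_RE.match(text.strip())
    if not m:
        raise SkippingError(f"cannot parse SE event {text!r}")
    return SkippedExonEvent(
        gene=m.group("gene"),
        chrom=m.group("chrom"),
        e1_end=int(m.group("a")),
        e2_start=int(m.group("b")),
        e2_end=int(m.group("c")),
        e3_start=int(m.group("d")),
        strand=m.group("strand"),
    )


def format_se_event(event: SkippedExonEvent) -> str:
    return (
        f"{event.gene};SE:{event.chrom}:{event.e1_end}-{event.e2_start}"
        f":{event.e2_end}-{event.e3_start}:{event.strand}"
    )


def read_se_events(path: str | Path) -> list[SkippedExonEvent]:
    """One SE identifier per line; ``#`` lines are comments."""
    events = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            events.append(parse_se_event(line))
        except SkippingError as exc:
            raise SkippingError(f"{path}:{lineno}: {exc}") from exc
    return events


def anril_se_events() -> list[SkippedExonEvent]:
    """The bundled SE events reported at the ANRIL locus."""
    ref = resources.files("circanril.data") / "anril_se_events.txt"
    with resources.as_file(ref) as path:
        return read_se_events(path)


def potential_circ_exons(event: SkippedExonEvent, model: GeneModel) -> tuple[str, ...]:
    """Canonical exons of the model positioned within the event's flanking
    splice sites — the exon set an exon-skipping-derived circle would carry.

    Containment is ``exon.start >= e1_end and exon.end <= e3_start``; the
    result is always a contiguous run of canonical exon labels in gene order.
    """
    chrom = model.chrom
    if chrom is not None and chrom != event.chrom:
        raise SkippingError(
            f"event on {event.chrom} does not match model chromosome {chrom}"
        )
    out = []
    for exon in model.canonical_exons:
        iv = exon.interval
        if iv is None:
            raise SkippingError("gene model lacks exon intervals")
        if iv.start >= event.e1_end and iv.end <= event.e3_start:
            out.append(exon.label)
    return tuple(out)


def match_skipping_to_catalogue(
    candidates: Sequence[tuple[SkippedExonEvent, tuple[str, ...]]],
    cat: Catalogue,
) -> list[tuple[SkippedExonEvent, CircIsoform]]:
    """Observed isoforms whose cycle exon set equals a candidate set exactly.

    Junctions are ignored for the reported match (a skipping-derived circle
    of exons ``a..b`` forces junction ``(b, a)`` anyway); empty candidate
    sets never match.  Returns (event, isoform) pairs.
    """
    matches = []
    for iso in cat.deduplicated().all_isoforms():
        cycle_set = frozenset(iso.cycle)
        for event, labels in candidates:
            if labels and frozenset(labels) == cycle_set:
                matches.append((event, iso))
    return matches
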