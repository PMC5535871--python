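"""Circular-isoform catalogues: parsing, canonicalization and statistics.

A circular isoform is written as the exon path seen by an outward-facing
primer, e.g. ``"4-5-6-9-10-4 (10-4)"``: the first and last labels coincide
(the path wraps around the circle) and the bracketed pair is the reported
back-splice junction in donor-acceptor order.  Because the same circle can be
detected from different primer rows, paths are rotations of one another;
:func:`canonicalize` rotates every circle so that the back-splice acceptor
exon comes first and the donor exon last, which makes circle identity a plain
tuple comparison.

Two isoforms are equal iff their canonical cycles and junctions are equal;
circles with the same exon set but different junctions stay distinct.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from math import ceil, floor
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .gene_model import GeneModel, GeneModelError, parse_ordinal

__all__ = [
    "CircIsoform",
    "Catalogue",
    "CatalogueError",
    "parse_isoform_path",
    "derive_junction",
    "canonicalize",
    "read_catalogue",
    "nzm_catalogue",
    "common_isoforms",
    "exon_abundance",
    "pre_spliced_introns",
    "intron_inclusion",
    "junction_tally",
    "junction_intron_usage",
]

Junction = tuple[str, str]  # (donor exon label, acceptor exon label)

_PATH_RE = re.compile(r"^(?P<path>\S+)(?:\s+\((?P<junction>[^()]+)\))?\s*$")
_PAREN_NOVEL = re.compile(r"^(\d+)\(N(\d+)\)$")


class CatalogueError(ValueError):
    """Raised for malformed isoform strings or empty catalogues."""


def _normalize_label(token: str) -> str:
    """``"4(N1)"`` and ``"4N1"`` are the same novel-exon label."""
    m = _PAREN_NOVEL.match(token)
    if m:
        return f"{m.group(1)}N{m.group(2)}"
    return token


def _validate_label(token: str) -> str:
    token = _normalize_label(token)
    try:
        parse_ordinal(token)
    except GeneModelError as exc:
        raise CatalogueError(f"unknown exon label {token!r}") from exc
    return token


@dataclass(frozen=True, eq=False)
class CircIsoform:
    """A canonical circular isoform.

    ``raw_path`` is the path as written (first label == last label);
    ``cycle`` is the rotation-normalized exon cycle (acceptor first, donor
    last, wrap implicit); ``junction`` is (donor, acceptor).  Equality and
    hashing use ``(cycle, junction)`` only, so the same circle found in two
    cell lines or from two primer rows compares equal.
    """

    cell_line: str
    raw_path: tuple[str, ...]
    cycle: tuple[str, ...]
    junction: Junction
    primer_row: str | None = None
    warnings: tuple[str, ...] = ()

    @property
    def identity(self) -> tuple[tuple[str, ...], Junction]:
        return (self.cycle, self.junction)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CircIsoform):
            return NotImplemented
        return self.identity == other.identity

    def __hash__(self) -> int:
        return hash(self.identity)

    def __repr__(self) -> str:  # compact: "[4-5-6] (6-4)"
        return f"CircIsoform({'-'.join(self.cycle)} ({self.junction[0]}-{self.junction[1]}))"


def derive_junction(raw_path: Sequence[str]) -> Junction:
    """Junction implied by the written path: the wrap from the second-to-last
    label back to the first label.  ``[4,5,6,7,4] -> (7,4)``."""
    if len(raw_path) < 2:
        raise CatalogueError("a circle path needs at least two labels")
    return (raw_path[-2], raw_path[0])


def _rotate_to_acceptor(cycle: tuple[str, ...], acceptor: str) -> tuple[str, ...]:
    k = cycle.index(acceptor)
    return cycle[k:] + cycle[:k]


def canonicalize(iso: CircIsoform) -> CircIsoform:
    """Rotate the cycle so the acceptor exon is first and the donor last.

    Idempotent; rotation-invariant: all rotations of the same circle with the
    same junction map to one canonical form.
    """
    donor, acceptor = iso.junction
    if acceptor not in iso.cycle or donor not in iso.cycle:
        raise CatalogueError(
            f"junction {iso.junction} uses labels absent from cycle {iso.cycle}"
        )
    cycle = _rotate_to_acceptor(iso.cycle, acceptor)
    if cycle[-1] != donor and len(cycle) > 1:
        raise CatalogueError(
            f"junction {iso.junction} is not a wrap point of cycle {iso.cycle}"
        )
    return replace(iso, cycle=cycle)


def parse_isoform_path(
    text: str,
    cell_line: str,
    primer_row: str | None = None,
    junction_order: str = "donor-acceptor",
) -> CircIsoform:
    """Parse one catalogue entry like ``"4-5-6-9-10-4 (10-4)"``.

    The bracketed junction, when present, is trusted as the junction call
    whenever it names a valid wrap point of the written cycle (the circle is
    rotated to it and any disagreement with the written wrap is recorded as a
    warning).  A bracket that cannot be a wrap point of the cycle (unknown
    label, or labels not cyclically adjacent) is itself recorded as a warning
    and the junction derived from the written path is kept.

    ``junction_order`` selects the bracket dialect: ``"donor-acceptor"``
    (catalogue tables, ``(14-5)`` = donor 14, acceptor 5) or
    ``"acceptor-donor"`` (prose style, ``5-14`` = the same junction).
    """
    if junction_order not in ("donor-acceptor", "acceptor-donor"):
        raise CatalogueError(f"unknown junction_order {junction_order!r}")
    m = _PATH_RE.match(text.strip())
    if not m:
        raise CatalogueError(f"cannot parse isoform entry {text!r}")
    labels = [_validate_label(tok) for tok in m.group("path").split("-")]
    if len(labels) < 2:
        raise CatalogueError(f"circle path {text!r} has fewer than two labels")
    if labels[0] != labels[-1]:
        raise CatalogueError(
            f"malformed circle {text!r}: first label {labels[0]!r} != last {labels[-1]!r}"
        )
    raw_path = tuple(labels)
    cycle = raw_path[:-1]
    if len(set(cycle)) != len(cycle):
        raise CatalogueError(f"cycle {text!r} repeats an interior exon label")
    derived = derive_junction(raw_path)
    warnings: list[str] = []
    junction = derived
    bracket = m.group("junction")
    if bracket is not None:
        parts = [_validate_label(tok) for tok in bracket.strip().split("-")]
        if len(parts) != 2:
            raise CatalogueError(f"cannot parse junction annotation {bracket!r}")
        if junction_order == "acceptor-donor":
            parts = parts[::-1]
        annotated: Junction = (parts[0], parts[1])
        if annotated != derived:
            if _is_wrap_point(cycle, annotated):
                warnings.append(
                    f"annotated junction {annotated} differs from written wrap "
                    f"{derived}; using annotation"
                )
                junction = annotated
            else:
                warnings.append(
                    f"annotated junction {annotated} is not a wrap point of "
                    f"cycle {cycle}; keeping derived junction {derived}"
                )
    iso = CircIsoform(
        cell_line=cell_line,
        raw_path=raw_path,
        cycle=cycle,
        junction=junction,
        primer_row=primer_row,
        warnings=tuple(warnings),
    )
    return canonicalize(iso)


def _is_wrap_point(cycle: tuple[str, ...], junction: Junction) -> bool:
    donor, acceptor = junction
    if donor not in cycle or acceptor not in cycle:
        return False
    if len(cycle) == 1:
        return donor == acceptor
    k = cycle.index(donor)
    return cycle[(k + 1) % len(cycle)] == acceptor


# ---------------------------------------------------------------------------
# catalogues


@dataclass
class Catalogue:
    """Per-cell-line collections of circular isoforms (raw or deduplicated)."""

    entries: dict[str, list[CircIsoform]] = field(default_factory=dict)

    def add(self, iso: CircIsoform) -> None:
        self.entries.setdefault(iso.cell_line, []).append(iso)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.entries)

    def line(self, cell_line: str) -> list[CircIsoform]:
        return self.entries[cell_line]

    def all_isoforms(self) -> Iterator[CircIsoform]:
        for isoforms in self.entries.values():
            yield from isoforms

    def deduplicated(self, rule: str = "canonical") -> "Catalogue":
        """Merge identical isoforms within each cell line.

        ``rule="canonical"`` (default) treats isoforms as identical when their
        canonical ``(cycle, junction)`` coincide; ``rule="none"`` keeps every
        written entry.  The published total of 37 isoforms is not recoverable
        from the printed catalogue under an obvious rule, so the rule is a
        visible knob rather than a hard-coded constant.
        """
        if rule == "none":
            return Catalogue({k: list(v) for k, v in self.entries.items()})
        if rule != "canonical":
            raise CatalogueError(f"unknown deduplication rule {rule!r}")
        out = Catalogue()
        for cell_line, isoforms in self.entries.items():
            seen: dict[tuple, CircIsoform] = {}
            for iso in isoforms:
                if iso.identity not in seen:
                    seen[iso.identity] = iso
            out.entries[cell_line] = list(seen.values())
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def read_catalogue(path: str | Path, junction_order: str = "donor-acceptor") -> Catalogue:
    """Read a catalogue TSV with columns cell_line, primer_row, isoform_path
    (lines starting with ``#`` are comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"cell_line", "isoform_path"}
    if not required.issubset(df.columns):
        raise CatalogueError(
            f"{path}: catalogue needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise CatalogueError(f"{path}: catalogue file contains no isoform entries")
    cat = Catalogue()
    for idx, row in df.iterrows():
        try:
            iso = parse_isoform_path(
                str(row["isoform_path"]),
                cell_line=str(row["cell_line"]),
                primer_row=str(row["primer_row"]) if "primer_row" in df.columns else None,
                junction_order=junction_order,
            )
        except CatalogueError as exc:
            raise CatalogueError(f"{path}: entry {idx + 1}: {exc}") from exc
        cat.add(iso)
    return cat


def nzm_catalogue() -> Catalogue:
    """The bundled NZM7/NZM37 melanoma circANRIL catalogue (raw entries)."""
    ref = resources.files("circanril.data") / "nzm_circ_catalogue.tsv"
    with resources.as_file(ref) as path:
        return read_catalogue(path)


# ---------------------------------------------------------------------------
# statistics


def _sort_key(iso: CircIsoform) -> tuple[Fraction, Fraction]:
    donor, acceptor = iso.junction
    return (parse_ordinal(acceptor), parse_ordinal(donor))


def common_isoforms(a: Iterable[CircIsoform], b: Iterable[CircIsoform]) -> list[CircIsoform]:
    """Isoforms present in both collections under canonical equality,
    ordered by acceptor then donor ordinal."""
    shared = set(a) & set(b)
    return sorted(shared, key=_sort_key)


@dataclass(frozen=True)
class ExonAbundance:
    counts: dict[str, int]
    relative: dict[str, float]  # counts / max count, in [0, 1]


def exon_abundance(isoforms: Sequence[CircIsoform]) -> ExonAbundance:
    """Per-exon occurrence counts over a set of isoforms, scaled so the most
    abundant exon has relative abundance 1.0."""
    if not isoforms:
        raise CatalogueError("cannot compute exon abundance of an empty catalogue")
    counts: Counter[str] = Counter()
    for iso in isoforms:
        counts.update(set(iso.cycle))
    top = max(counts.values())
    relative = {label: c / top for label, c in counts.items()}
    return ExonAbundance(counts=dict(counts), relative=relative)


def pre_spliced_introns(iso: CircIsoform, model: GeneModel) -> set[int]:
    """Introns contained in the unspliced precursor of a circle: the genomic
    segment from its acceptor-side-most to its donor-side-most exon.

    Returns ``{i : floor(min ordinal) <= i < ceil(max ordinal)}`` clipped to
    the model's canonical intron range.
    """
    ordinals = [model.ordinal(label) for label in iso.cycle]
    lo = floor(min(ordinals))
    hi = ceil(max(ordinals))
    n = model.n_canonical
    return {i for i in range(lo, hi) if 1 <= i <= n - 1}


@dataclass(frozen=True)
class IntronInclusion:
    counts: dict[int, int]          # isoforms whose precursor spans the intron
    scaled: dict[int, float]        # counts / max count
    scaled_length: dict[int, float] | None  # intron length / max length


def intron_inclusion(cat: Catalogue, model: GeneModel) -> IntronInclusion:
    """Per-intron inclusion counts over a deduplicated catalogue, with counts
    and intron lengths each scaled by their maximum into [0, 1]."""
    isoforms = list(cat.deduplicated().all_isoforms())
    counts = {i.index: 0 for i in model.introns}
    for iso in isoforms:
        for idx in pre_spliced_introns(iso, model):
            counts[idx] = counts.get(idx, 0) + 1
    top = max(counts.values()) if counts else 0
    scaled = {i: (c / top if top else 0.0) for i, c in counts.items()}
    scaled_length = None
    lengths = {i.index: i.length for i in model.introns if i.interval is not None}
    if lengths:
        lmax = max(lengths.values())
        scaled_length = {i: length / lmax for i, length in lengths.items()}
    return IntronInclusion(counts=counts, scaled=scaled, scaled_length=scaled_length)


def junction_tally(cat: Catalogue) -> dict[Junction, Counter]:
    """Distinct back-splice junctions with per-cell-line isoform counts."""
    tally: dict[Junction, Counter] = {}
    for cell_line, isoforms in cat.entries.items():
        for iso in isoforms:
            tally.setdefault(iso.junction, Counter())[cell_line] += 1
    return tally


def junction_intron_usage(
    isoforms: Iterable[CircIsoform], model: GeneModel, convention: str = "either"
) -> dict[int, int]:
    """How many distinct junctions use each intron's splice sites.

    A back-splice junction (donor exon d, acceptor exon a) uses the donor
    site that normally feeds intron ``floor(ordinal(d))`` and the acceptor
    site that normally drains intron ``ceil(ordinal(a)) - 1``.  The published
    phrasing "junctions that involved introns" has no recoverable definition,
    so the convention is explicit: ``"donor"``, ``"acceptor"`` or
    ``"either"`` (a junction counts for an intron if either site touches it).
    """
    if convention not in ("donor", "acceptor", "either"):
        raise CatalogueError(f"unknown convention {convention!r}")
    n = model.n_canonical
    usage = {i.index: 0 for i in model.introns}
    junctions = {iso.junction for iso in isoforms}
    for donor, acceptor in junctions:
        touched: set[int] = set()
        if convention in ("donor", "either"):
            i = floor(model.ordinal(donor))
            if 1 <= i <= n - 1:
                touched.add(i)
        if convention in ("acceptor", "either"):
            i = ceil(model.ordinal(acceptor)) - 1
            if 1 <= i <= n - 1:
                touched.add(i)
        for i in touched:
            usage[i] = usage.get(i, 0) + 1
    return usage
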