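"""Intronic repeat elements and inverted-repeat-driven junction prediction.

The biogenesis model under test: two Alu-class repeats sitting in different
introns, one the (approximate) reverse complement of the other, can base-pair
in the pre-mRNA and bracket a back-splice.  An inverted pair in introns
``(i, j)`` with ``i < j`` brackets the circle of exons ``i+1 .. j`` and hence
predicts the back-splice junction (donor exon ``j``, acceptor exon ``i+1``);
``j == i + 1`` predicts a single-exon circle.  Observed junctions are then
partitioned into those a predicted junction explains and the rest.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .alignment import AlignmentScoring, align_global, reverse_complement
from .gene_model import GeneModel, GenomicInterval

__all__ = [
    "RepeatElement",
    "InvertedRepeatPair",
    "JunctionPrediction",
    "RepeatAnalysisError",
    "read_repeats",
    "write_repeats",
    "assign_repeats_to_features",
    "FeatureAssignment",
    "find_inverted_pairs",
    "predict_junctions",
    "classify_observed_junctions",
    "correlate_repeat_count_with_length",
]

Junction = tuple[str, str]

# UCSC rmsk table: 17 columns, genoStart 0-based half-open.
_RMSK_COLS = 17
_RMSK_NOBIN_COLS = 16


class RepeatAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatElement:
    """A strand-aware repeat annotation (e.g. one AluSx copy)."""

    name: str
    interval: GenomicInterval
    repeat_class: str = ""
    family: str = ""

    @property
    def strand(self) -> str:
        return self.interval.strand

    def matches_class(self, pattern: str) -> bool:
        rx = re.compile(pattern)
        return any(
            rx.search(s) for s in (self.name, self.repeat_class, self.family)
        )


def _parse_rmsk_line(fields: Sequence[str]) -> RepeatElement:
    if len(fields) == _RMSK_COLS:
        fields = fields[1:]  # drop leading bin column
    chrom, start, end, _left, strand = fields[4], fields[5], fields[6], fields[7], fields[8]
    name, rclass, rfam = fields[9], fields[10], fields[11]
    strand = "+" if strand not in ("+", "-") else strand
    return RepeatElement(
        name=name,
        interval=GenomicInterval(chrom, int(start), int(end), strand),
        repeat_class=rclass,
        family=rfam,
    )


def _parse_bed6_line(fields: Sequence[str]) -> RepeatElement:
    chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
    return RepeatElement(
        name=name,
        interval=GenomicInterval(chrom, int(start), int(end), strand),
        repeat_class=name,
        family=name,
    )


def read_repeats(
    path: str | Path,
    region: GenomicInterval | None = None,
    class_filter: str | None = None,
) -> list[RepeatElement]:
    """Read repeat elements from a UCSC rmsk TSV (16/17 columns) or BED6.

    Keeps only repeats overlapping ``region`` (when given) and whose name,
    class or family matches the ``class_filter`` regex (when given, e.g.
    ``"Alu"``).  The layout is sniffed per file; an unrecognized line raises
    with its line number.
    """
    reps: list[RepeatElement] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:
            fields = line.split()
        try:
            if len(fields) in (_RMSK_COLS, _RMSK_NOBIN_COLS):
                rep = _parse_rmsk_line(fields)
            elif 4 <= len(fields) <= 6:
                rep = _parse_bed6_line(fields)
            else:
                raise RepeatAnalysisError(f"{len(fields)} columns")
        except (ValueError, IndexError) as exc:
            raise RepeatAnalysisError(
                f"{path}:{lineno}: unrecognized repeat record layout ({exc}): {line!r}"
            ) from exc
        if region is not None and not rep.interval.overlaps(region):
            continue
        if class_filter is not None and not rep.matches_class(class_filter):
            continue
        reps.append(rep)
    return reps


def write_repeats(reps: Iterable[RepeatElement], path: str | Path) -> None:
    """Write repeats as a binless 16-column rmsk-style TSV."""
    lines = []
    for r in reps:
        iv = r.interval
        lines.append(
            "\t".join(
                [
                    "0", "0", "0", "0",  # swScore, milliDiv, milliDel, milliIns
                    iv.chrom, str(iv.start), str(iv.end), "0",
                    iv.strand, r.name, r.repeat_class, r.family,
                    "0", "0", "0", "0",  # repStart, repEnd, repLeft, id
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# assignment to gene features


@dataclass
class FeatureAssignment:
    """Repeats assigned to introns/exons plus those straddling boundaries."""

    by_intron: dict[int, list[RepeatElement]]
    by_exon: dict[str, list[RepeatElement]]
    unassigned: list[RepeatElement]

    @property
    def intron_counts(self) -> dict[int, int]:
        return {i: len(v) for i, v in self.by_intron.items()}

    @property
    def exon_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.by_exon.items()}


def _overlap_frac(rep: GenomicInterval, feat: GenomicInterval) -> float:
    if rep.chrom != feat.chrom:
        return 0.0
    ov = min(rep.end, feat.end) - max(rep.start, feat.start)
    return max(ov, 0) / len(rep)


def assign_repeats_to_features(
    reps: Iterable[RepeatElement],
    model: GeneModel,
    min_overlap_frac: float = 1.0,
) -> FeatureAssignment:
    """Assign each repeat to the intron or exon containing at least
    ``min_overlap_frac`` of its length (default: full containment).

    Repeats overlapping the locus but clearing the threshold in no single
    feature (boundary straddlers) are reported in ``unassigned``.  A repeat
    is assigned to at most one feature: the one with the largest overlap
    fraction among those clearing the threshold.
    """
    if not 0 < min_overlap_frac <= 1:
        raise RepeatAnalysisError("min_overlap_frac must be in (0, 1]")
    by_intron: dict[int, list[RepeatElement]] = {i.index: [] for i in model.introns}
    by_exon: dict[str, list[RepeatElement]] = {
        e.label: [] for e in model.exons if e.interval is not None
    }
    unassigned: list[RepeatElement] = []
    features: list[tuple[str, int | str, GenomicInterval]] = []
    for intron in model.introns:
        if intron.interval is not None:
            features.append(("intron", intron.index, intron.interval))
    for exon in model.exons:
        if exon.interval is not None:
            features.append(("exon", exon.label, exon.interval))
    for rep in reps:
        best: tuple[float, str, int | str] | None = None
        for kind, key, iv in features:
            frac = _overlap_frac(rep.interval, iv)
            if frac >= min_overlap_frac and (best is None or frac > best[0]):
                best = (frac, kind, key)
        if best is None:
            unassigned.append(rep)
        elif best[1] == "intron":
            by_intron[best[2]].append(rep)  # type: ignore[index]
        else:
            by_exon[best[2]].append(rep)  # type: ignore[index]
    return FeatureAssignment(by_intron=by_intron, by_exon=by_exon, unassigned=unassigned)


# ---------------------------------------------------------------------------
# inverted pairs and junction prediction


@dataclass(frozen=True)
class InvertedRepeatPair:
    """Two repeats in distinct introns whose reverse-complement alignment
    clears the acceptance threshold."""

    intron_i: int
    intron_j: int
    rep_a: RepeatElement
    rep_b: RepeatElement
    score: float

    def __post_init__(self) -> None:
        if self.intron_i >= self.intron_j:
            raise RepeatAnalysisError("inverted pair requires intron_i < intron_j")


def _fetch(genome, interval: GenomicInterval) -> str:
    """Sequence for an interval from a pyfaidx.Fasta or a plain mapping of
    chromosome name to sequence string."""
    chrom_seq = genome[interval.chrom]
    if hasattr(chrom_seq, "seq") or not isinstance(chrom_seq, str):
        seq = str(chrom_seq[interval.start : interval.end])
    else:
        seq = chrom_seq[interval.start : interval.end]
    if len(seq) < len(interval):
        raise RepeatAnalysisError(
            f"genome sequence shorter than annotated repeat at "
            f"{interval.chrom}:{interval.start}-{interval.end}"
        )
    return seq.upper()


def find_inverted_pairs(
    reps_by_intron: Mapping[int, Sequence[RepeatElement]],
    genome,
    scoring: AlignmentScoring | None = None,
) -> list[InvertedRepeatPair]:
    """All cross-intron repeat pairs whose reverse-complement global
    alignment scores at least ``scoring.min_score``.

    For introns ``i < j`` and repeats ``a`` in ``i``, ``b`` in ``j``, the
    score is ``align_global(seq(a), revcomp(seq(b)))`` on genomic forward
    sequences; the global score is symmetric in pair order.  Same-intron
    pairs are never considered (they cannot bracket a back-splice).
    """
    if scoring is None:
        scoring = AlignmentScoring()
    indices = sorted(k for k, v in reps_by_intron.items() if len(v) > 0)
    pairs: list[InvertedRepeatPair] = []
    for ai, i in enumerate(indices):
        for j in indices[ai + 1 :]:
            for rep_a in reps_by_intron[i]:
                for rep_b in reps_by_intron[j]:
                    seq_a = _fetch(genome, rep_a.interval)
                    seq_b = _fetch(genome, rep_b.interval)
                    score = align_global(seq_a, reverse_complement(seq_b), scoring)
                    if score >= scoring.min_score:
                        pairs.append(
                            InvertedRepeatPair(
                                intron_i=i, intron_j=j,
                                rep_a=rep_a, rep_b=rep_b, score=score,
                            )
                        )
    return pairs


@dataclass(frozen=True)
class JunctionPrediction:
    """Back-splice junction a set of inverted pairs could generate."""

    donor_exon: str
    acceptor_exon: str
    supporting_pairs: tuple[InvertedRepeatPair, ...]

    @property
    def junction(self) -> Junction:
        return (self.donor_exon, self.acceptor_exon)


def junction_for_intron_pair(
    intron_i: int, intron_j: int, model: GeneModel | None = None
) -> Junction:
    """Inverted repeats in introns ``(i, j)``, ``i < j``, bracket the circle
    of exons ``i+1 .. j``: donor exon ``j``, acceptor exon ``i+1``."""
    if intron_i >= intron_j:
        raise RepeatAnalysisError("intron pair must satisfy i < j")
    donor, acceptor = str(intron_j), str(intron_i + 1)
    if model is not None:
        donor = model.canonical_exons[intron_j - 1].label
        acceptor = model.canonical_exons[intron_i].label
    return (donor, acceptor)


def predict_junctions(
    pairs: Iterable[InvertedRepeatPair], model: GeneModel | None = None
) -> list[JunctionPrediction]:
    """Group inverted pairs by intron pair and emit one junction prediction
    per intron pair; one supporting pair suffices."""
    grouped: dict[Junction, list[InvertedRepeatPair]] = defaultdict(list)
    for pair in pairs:
        grouped[junction_for_intron_pair(pair.intron_i, pair.intron_j, model)].append(pair)
    preds = [
        JunctionPrediction(donor_exon=d, acceptor_exon=a, supporting_pairs=tuple(v))
        for (d, a), v in grouped.items()
    ]
    preds.sort(key=lambda p: (p.acceptor_exon, p.donor_exon))
    return preds


def classify_observed_junctions(
    observed: Iterable[Junction],
    predicted: Iterable[JunctionPrediction | Junction],
) -> tuple[set[Junction], set[Junction]]:
    """Partition observed junctions into (explained, unexplained) by exact
    junction membership in the predicted set."""
    obs = set(observed)
    pred: set[Junction] = set()
    for p in predicted:
        pred.add(p.junction if isinstance(p, JunctionPrediction) else tuple(p))
    explained = obs & pred
    return explained, obs - explained


def correlate_repeat_count_with_length(
    lengths: Sequence[float], counts: Sequence[float]
) -> dict[str, float]:
    """Rank (Spearman) and linear (Pearson) correlation of per-intron repeat
    counts with intron lengths, with two-sided p-values."""
    lengths = np.asarray(lengths, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(lengths) != len(counts):
        raise RepeatAnalysisError("lengths and counts must be the same length")
    if len(lengths) < 3:
        raise RepeatAnalysisError("need at least 3 introns to correlate")
    if np.ptp(lengths) == 0 or np.ptp(counts) == 0:
        raise RepeatAnalysisError("correlation undefined for constant input")
    rho, rho_p = stats.spearmanr(lengths, counts)
    r, r_p = stats.pearsonr(lengths, counts)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "pearson_r": float(r),
        "pearson_p": float(r_p),
    }
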