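"""Seeded synthetic loci and circle catalogues with known biogenesis labels.

The generator emulates the structure this package analyses: a multi-exon
locus (19 exons by default) whose introns span a wide length range, with
Alu-length (300 bp) repeat elements planted in introns — some as planned
reverse-complement pairs across intron pairs, some as unrelated random
sequences — plus a circle catalogue whose entries are labelled by the
mechanism that generated them (``"alu"``: contiguous runs bracketed by a
planted inverted pair; ``"skipping"``: runs equal to a generated
skipped-exon event's candidate set; ``"random"``: exon subsets whose
junctions avoid both).  Every output is a plain-text file that re-parses
through this package's own readers, so the whole pipeline is testable
end-to-end with known ground truth and no downloads.

Identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np

from .alignment import reverse_complement
from .gene_model import ExonRecord, GeneModel, GenomicInterval, derive_introns, write_gtf
from .isoform_catalogue import Catalogue, CircIsoform, canonicalize
from .exon_skipping import SkippedExonEvent, format_se_event
from .repeat_analysis import RepeatElement, junction_for_intron_pair, write_repeats

__all__ = [
    "SimulationConfig",
    "SimulatedLocus",
    "SimulatedCatalogue",
    "SimulationError",
    "simulate_locus",
    "simulate_catalogue",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Dimensions and plans for one simulated dataset.

    Defaults mimic the modelled locus: 19 exons; log-normal intron lengths
    whose central mass spans roughly two orders of magnitude (so the
    "long intron, many repeats" regime is representable); 300 bp Alu-length
    repeats; one planted inverted pair across introns (1, 6) at zero
    divergence; a mixed catalogue of repeat-driven, skipping-compatible and
    random circles.
    """

    n_exons: int = 19
    exon_len_median: float = 150.0
    exon_len_sigma: float = 0.5
    intron_len_median: float = 1500.0
    intron_len_sigma: float = 1.15
    min_exon_length: int = 60
    min_intron_length: int = 700
    repeat_length: int = 300
    # planted inverted pairs: (intron_i, intron_j, divergence fraction)
    inverted_pairs: tuple[tuple[int, int, float], ...] = ((1, 6, 0.0),)
    # unrelated random Alu-length repeats per intron: {intron index: count}
    background_repeats: dict[int, int] = field(default_factory=dict)
    n_alu_circles: int = 4
    n_skipping_circles: int = 3
    n_random_circles: int = 5
    flank: int = 500
    chrom: str = "chrSim"
    gene_id: str = "SIMGENE"
    cell_line: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise SimulationError("need at least two exons")
        for i, j, div in self.inverted_pairs:
            if not 1 <= i < j <= self.n_exons - 1:
                raise SimulationError(f"invalid intron pair ({i}, {j})")
            if not 0.0 <= div <= 1.0:
                raise SimulationError(f"divergence must be in [0, 1], got {div}")
        if min(
            (c for c in (self.n_alu_circles, self.n_skipping_circles,
                         self.n_random_circles)), default=0,
        ) < 0:
            raise SimulationError("circle counts must be >= 0")


@dataclass
class SimulatedLocus:
    config: SimulationConfig
    model: GeneModel
    genome: dict[str, str]
    repeats: list[RepeatElement]
    truth: dict


@dataclass
class SimulatedCatalogue:
    catalogue: Catalogue
    mechanisms: dict[str, str]          # "a-b-c-a (c-a)" path -> mechanism label
    se_events: list[SkippedExonEvent]
    truth: dict


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of positions with a different base."""
    if divergence == 0.0:
        return seq
    chars = np.array(list(seq))
    k = int(round(divergence * len(seq)))
    pos = rng.choice(len(seq), size=k, replace=False)
    for p in pos:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def simulate_locus(config: SimulationConfig) -> SimulatedLocus:
    """Lay out exons and introns, synthesize the genomic sequence and plant
    the configured repeats, returning the model, genome and rmsk-style track
    plus a ground-truth record.

    Raises :class:`SimulationError` when a planted repeat cannot fit inside
    its intron (repeat longer than the intron, or too many repeats for the
    intron length).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_exons
    exon_lens = np.maximum(
        rng.lognormal(np.log(cfg.exon_len_median), cfg.exon_len_sigma, n).astype(int),
        cfg.min_exon_length,
    )
    intron_lens = np.maximum(
        rng.lognormal(np.log(cfg.intron_len_median), cfg.intron_len_sigma, n - 1).astype(int),
        cfg.min_intron_length,
    )

    # how many repeats each intron must host
    planned: dict[int, list[tuple[str, str]]] = {}  # intron -> [(name, seq)]
    for k, (i, j, div) in enumerate(cfg.inverted_pairs):
        seq = "".join(rng.choice(_BASES, size=cfg.repeat_length))
        planned.setdefault(i, []).append((f"SIM_ALU_p{k}a", seq))
        planned.setdefault(j, []).append(
            (f"SIM_ALU_p{k}b", _mutate(reverse_complement(seq), div, rng))
        )
    for i, count in sorted(cfg.background_repeats.items()):
        if not 1 <= i <= n - 1:
            raise SimulationError(f"background repeat intron {i} out of range")
        for r in range(count):
            seq = "".join(rng.choice(_BASES, size=cfg.repeat_length))
            planned.setdefault(i, []).append((f"SIM_ALU_r{i}_{r}", seq))

    pad = 10
    for i, items in planned.items():
        need = len(items) * (cfg.repeat_length + 2 * pad)
        if need > intron_lens[i - 1]:
            raise SimulationError(
                f"cannot place {len(items)} repeat(s) of {cfg.repeat_length} bp "
                f"in intron {i} of length {int(intron_lens[i - 1])}"
            )

    # exon/intron coordinates on the + strand
    pos = cfg.flank
    exon_ivs: list[GenomicInterval] = []
    intron_ivs: list[GenomicInterval] = []
    for k in range(n):
        exon_ivs.append(GenomicInterval(cfg.chrom, pos, pos + int(exon_lens[k])))
        pos += int(exon_lens[k])
        if k < n - 1:
            intron_ivs.append(GenomicInterval(cfg.chrom, pos, pos + int(intron_lens[k])))
            pos += int(intron_lens[k])
    total = pos + cfg.flank

    seq_arr = rng.choice(_BASES, size=total)

    repeats: list[RepeatElement] = []
    truth_repeats = []
    for i in sorted(planned):
        items = planned[i]
        iv = intron_ivs[i - 1]
        slot = len(iv) // len(items)
        for k, (name, rep_seq) in enumerate(items):
            lo = iv.start + k * slot + pad
            hi = iv.start + (k + 1) * slot - cfg.repeat_length - pad
            start = int(rng.integers(lo, max(hi, lo + 1)))
            seq_arr[start : start + cfg.repeat_length] = list(rep_seq)
            rep = RepeatElement(
                name=name,
                interval=GenomicInterval(cfg.chrom, start, start + cfg.repeat_length),
                repeat_class="SINE",
                family="Alu",
            )
            repeats.append(rep)
            truth_repeats.append({"name": name, "intron": i,
                                  "start": start, "end": start + cfg.repeat_length})

    exons = [
        ExonRecord(str(k + 1), Fraction(k + 1), exon_ivs[k]) for k in range(n)
    ]
    model = GeneModel(gene_id=cfg.gene_id, strand="+", exons=exons)
    model.introns = derive_introns(model.exons)

    truth = {
        "seed": cfg.seed,
        "inverted_pairs": [
            {"intron_i": i, "intron_j": j, "divergence": div,
             "predicted_junction": list(junction_for_intron_pair(i, j))}
            for i, j, div in cfg.inverted_pairs
        ],
        "repeats": truth_repeats,
    }
    genome = {cfg.chrom: "".join(seq_arr)}
    return SimulatedLocus(config=cfg, model=model, genome=genome,
                          repeats=repeats, truth=truth)


def _circle(model: GeneModel, labels: list[str], cell_line: str,
            mechanism: str) -> CircIsoform:
    donor, acceptor = labels[-1], labels[0]
    iso = CircIsoform(
        cell_line=cell_line,
        raw_path=tuple(labels) + (labels[0],),
        cycle=tuple(labels),
        junction=(donor, acceptor),
        primer_row=mechanism,
    )
    return canonicalize(iso)


def simulate_catalogue(config: SimulationConfig, locus: SimulatedLocus) -> SimulatedCatalogue:
    """Generate the planned circle catalogue for a simulated locus.

    Repeat-driven circles are the contiguous exon runs bracketed by planted
    inverted pairs; skipping-compatible circles equal the candidate set of a
    generated SE event; random circles are exon subsets re-sampled until
    their junction collides with neither mechanism.  Requires at least one
    planted pair when ``n_alu_circles > 0``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)  # independent of locus layout
    model = locus.model
    n = cfg.n_exons
    cat = Catalogue()
    mechanisms: dict[str, str] = {}
    se_events: list[SkippedExonEvent] = []
    truth_circles = []

    def register(iso: CircIsoform, mechanism: str) -> None:
        cat.add(iso)
        path = "-".join(iso.raw_path)
        key = f"{path} ({iso.junction[0]}-{iso.junction[1]})"
        mechanisms[key] = mechanism
        truth_circles.append({"path": path, "junction": list(iso.junction),
                              "mechanism": mechanism})

    if cfg.n_alu_circles > 0 and not cfg.inverted_pairs:
        raise SimulationError("repeat-driven circles requested but no inverted pairs planted")
    alu_junctions = {
        junction_for_intron_pair(i, j) for i, j, _ in cfg.inverted_pairs
    }
    for k in range(cfg.n_alu_circles):
        i, j, _ = cfg.inverted_pairs[k % len(cfg.inverted_pairs)]
        labels = [str(e) for e in range(i + 1, j + 1)]
        register(_circle(model, labels, cfg.cell_line, "alu"), "alu")

    skipping_sets: set[frozenset[str]] = set()
    for _ in range(cfg.n_skipping_circles):
        # a run a..b with both flanking exons present in the model
        a = int(rng.integers(2, n - 1))
        b = int(rng.integers(a, n - 1))
        ex = {e.label: e.interval for e in model.canonical_exons}
        event = SkippedExonEvent(
            gene=cfg.gene_id,
            chrom=cfg.chrom,
            e1_end=ex[str(a - 1)].end,
            e2_start=ex[str(a)].start,
            e2_end=ex[str(a)].end,
            e3_start=ex[str(b + 1)].start,
            strand="+",
        )
        se_events.append(event)
        labels = [str(e) for e in range(a, b + 1)]
        skipping_sets.add(frozenset(labels))
        register(_circle(model, labels, cfg.cell_line, "skipping"), "skipping")

    for _ in range(cfg.n_random_circles):
        for _try in range(1000):
            size = int(rng.integers(2, 6))
            subset = sorted(rng.choice(np.arange(1, n + 1), size=size, replace=False))
            labels = [str(e) for e in subset]
            junction = (labels[-1], labels[0])
            if junction in alu_junctions or frozenset(labels) in skipping_sets:
                continue
            register(_circle(model, labels, cfg.cell_line, "random"), "random")
            break
        else:  # pragma: no cover - would need a pathological config
            raise SimulationError("could not sample a non-colliding random circle")

    truth = dict(locus.truth)
    truth["circles"] = truth_circles
    truth["se_events"] = [format_se_event(e) for e in se_events]
    return SimulatedCatalogue(catalogue=cat, mechanisms=mechanisms,
                              se_events=se_events, truth=truth)


def write_dataset(locus: SimulatedLocus, simcat: SimulatedCatalogue,
                  outdir: str | Path) -> dict[str, Path]:
    """Write the six dataset files (FASTA, GTF, rmsk TSV, SE events,
    catalogue TSV, ground-truth JSON); byte-deterministic for a given
    config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = locus.config
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "model.gtf",
        "repeats": outdir / "repeats.rmsk.tsv",
        "events": outdir / "se_events.txt",
        "catalogue": outdir / "catalogue.tsv",
        "truth": outdir / "ground_truth.json",
    }
    chrom, seq = next(iter(locus.genome.items()))
    with open(paths["genome"], "w") as fh:
        fh.write(f">{chrom}\n")
        for k in range(0, len(seq), 60):
            fh.write(seq[k : k + 60] + "\n")
    write_gtf(locus.model, paths["annotation"])
    write_repeats(locus.repeats, paths["repeats"])
    with open(paths["events"], "w") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        for event in simcat.se_events:
            fh.write(format_se_event(event) + "\n")
    with open(paths["catalogue"], "w") as fh:
        fh.write(f"# seed={cfg.seed}\n")
        fh.write("cell_line\tprimer_row\tisoform_path\n")
        for iso in simcat.catalogue.all_isoforms():
            path_str = "-".join(iso.raw_path)
            fh.write(
                f"{iso.cell_line}\t{iso.primer_row}\t"
                f"{path_str} ({iso.junction[0]}-{iso.junction[1]})\n"
            )
    paths["truth"].write_text(json.dumps(simcat.truth, indent=2, sort_keys=True) + "\n")
    return paths
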