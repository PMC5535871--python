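from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import settings

import circanril as ca

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def anril_model() -> ca.GeneModel:
    return ca.anril_gene_model()


@pytest.fixture(scope="session")
def nzm_raw() -> ca.Catalogue:
    """Bundled melanoma catalogue, raw entries (primer-route duplicates kept)."""
    return ca.nzm_catalogue()


@pytest.fixture(scope="session")
def nzm(nzm_raw) -> ca.Catalogue:
    return nzm_raw.deduplicated()


def make_model(intervals: list[tuple[int, int]], strand: str = "+",
               chrom: str = "chrT", gene_id: str = "TOY") -> ca.GeneModel:
    """Toy model from (start, end) pairs given in genomic order."""
    pairs = intervals if strand == "+" else list(reversed(intervals))
    exons = [
        ca.ExonRecord(str(k + 1), Fraction(k + 1),
                      ca.GenomicInterval(chrom, s, e, strand))
        for k, (s, e) in enumerate(pairs)
    ]
    model = ca.GeneModel(gene_id=gene_id, strand=strand, exons=exons)
    model.introns = ca.derive_introns(model.exons)
    return model


@pytest.fixture
def toy_model() -> ca.GeneModel:
    return make_model([(100, 200), (300, 400), (500, 650)])


def brute_force_align(a: str, b: str, sc: ca.AlignmentScoring) -> float:
    """Exhaustive enumeration of all global alignments with affine-aware
    scoring; independent of the DP implementation.  Only for tiny inputs."""
    best = [float("-inf")]

    def rec(i: int, j: int, score: float, state: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = sc.match if (a[i] == b[j] and a[i] in "ACGT") else sc.mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            pen = sc.gap_extend + (sc.gap_open if state != "X" else 0)
            rec(i + 1, j, score + pen, "X")
        if j < len(b):
            pen = sc.gap_extend + (sc.gap_open if state != "Y" else 0)
            rec(i, j + 1, score + pen, "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


@pytest.fixture(scope="session")
def brute_aligner():
    return brute_force_align
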