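"""Bundled example data: printed count tables and synthetic sequence/pedigree fixtures.

The stiff-person-syndrome count table is the published printed
distribution.  The two gene-region sequences and the four-generation
family pedigree are **synthetic** stand-ins: the published figures they
correspond to are not distributed as machine-readable sequence, so the
fixtures are constructed to satisfy every textual constraint instead
(hotspot counts and categories, mutated positions, codon arithmetic,
generation sizes).  Positions, spacing and background composition beyond
those constraints are arbitrary.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .distributions import EventDistribution
from .hotspots import RGYW_CLASSES, AnnotatedSequence, HotspotAnnotation, MutationRecord
from .pedigree import Pedigree
from .synthgen import _BASES, MotifPackingError, _scan_violations

__all__ = [
    "sps_distribution",
    "plb1_exon33_synthetic",
    "copa_exon8_9_synthetic",
    "family_pedigree",
    "FAMILY_OBSERVED_AFFECTED",
    "FAMILY_ANTIBODY_POSITIVE",
    "COPA_OTHER_MOTIFS",
]


def sps_distribution() -> EventDistribution:
    """Published stiff-person-syndrome distribution of additional
    autoimmune diseases: 38 persons with one, 11 with two, 4 with three,
    2 with four and 1 with five (56 persons, 85 events; zero-truncated)."""
    return EventDistribution(
        {1: 38, 2: 11, 3: 4, 4: 2, 5: 1},
        zero_included=False,
        label="stiff-person syndrome AAIDs",
    )


# ---------------------------------------------------------------------------
# planted-sequence builder (deterministic; reuses the synthgen walk)
# ---------------------------------------------------------------------------


def _planted_sequence(
    seq_id: str,
    coord_offset: int,
    length: int,
    features: list[tuple[int, str, str]],
    seed: int,
    gc_min_len: int = 9,
    forbidden_literals: tuple[str, ...] = (),
    max_iters: int = 5000,
) -> AnnotatedSequence:
    """Fixed-position variant of the synthgen planting walk.

    ``features``: (0-based start index, text, kind) with kind one of
    ``exact`` / ``mismatch`` (4-mer RGYW cores), ``other`` (literal
    motif), ``gc`` (GC run) or ``fixed`` (frozen bases, unannotated).
    The background is resampled until no unplanned exact/one-mismatch
    RGYW window, long GC run or forbidden literal remains.
    """
    rng = np.random.default_rng(seed)
    seq = [""] * length
    background = np.ones(length, dtype=bool)
    planted_cores: set[int] = set()
    planted_runs: list[tuple[int, int]] = []
    literal_starts: dict[str, set[int]] = {lit: set() for lit in forbidden_literals}
    for start, text, kind in features:
        for k, b in enumerate(text):
            seq[start + k] = b
            background[start + k] = False
        if kind in ("exact", "mismatch"):
            planted_cores.add(start)
        elif kind == "gc":
            planted_runs.append((start, start + len(text)))
        if text in literal_starts:
            literal_starts[text].add(start)
    bg_idx = np.flatnonzero(background)
    for j, b in zip(bg_idx, rng.choice(_BASES, size=bg_idx.size)):
        seq[j] = str(b)
    for _ in range(max_iters):
        bad = set(_scan_violations(seq, planted_cores, planted_runs, background, gc_min_len))
        s = "".join(seq)
        for lit, allowed in literal_starts.items():
            start = s.find(lit)
            while start != -1:
                if start not in allowed:
                    bad.update(j for j in range(start, start + len(lit)) if background[j])
                start = s.find(lit, start + 1)
        if not bad:
            return AnnotatedSequence(id=seq_id, sequence=s, coord_offset=coord_offset)
        for j, b in zip(sorted(bad), rng.choice(_BASES, size=len(bad))):
            seq[j] = str(b)
    raise MotifPackingError(f"fixture walk for {seq_id} failed to converge")


# ---------------------------------------------------------------------------
# PLB1 exon-33-like region
# ---------------------------------------------------------------------------

_PLB1_OFFSET = 2233  # CDS coordinate of the first base (codon 745, base 1)
_PLB1_LENGTH = 66  # codons 745-766


def plb1_exon33_synthetic() -> tuple[AnnotatedSequence, list[HotspotAnnotation]]:
    """Synthetic stand-in for the PLB1 exon-33 CDS region.

    Encodes the textual constraints: exactly two exact-RGYW hotspots,
    the second with display span TGGCT (flank T + core GGCT) straddling
    codon 755 (GGC), so the germline mutation G>C at CDS 2263 gives
    G755R and turns the locus into TCGCT.  Returns the sequence (with
    the mutation attached) and the ground-truth hotspot annotations.
    """
    features = [
        (10, "AGCT", "exact"),  # first hotspot, CDS 2243-2246
        (29, "T", "fixed"),  # 5' flank of the second hotspot
        (30, "GGCT", "exact"),  # second hotspot, CDS 2263-2266 (codon 755 = GGC)
    ]
    seq = _planted_sequence(
        "PLB1_exon33_synthetic", _PLB1_OFFSET, _PLB1_LENGTH, features, seed=20331
    )
    seq.mutations = [MutationRecord(position=2263, ref="G", alt="C", label="G755R")]
    truth = [
        HotspotAnnotation(2243, 2246, "exact_rgyw", "AGCT", seq.sequence[9:14]),
        HotspotAnnotation(2263, 2266, "exact_rgyw", "GGCT", "TGGCT"),
    ]
    return seq, truth


# ---------------------------------------------------------------------------
# COPA exon-8/9-like region
# ---------------------------------------------------------------------------

_COPA_OFFSET = 661  # CDS coordinate of the first base
_COPA_LENGTH = 160

#: Literal motifs configured as the user-defined "other" hotspot category.
COPA_OTHER_MOTIFS = ("ATAC", "TGTG", "ACGT")


def copa_exon8_9_synthetic() -> tuple[AnnotatedSequence, list[HotspotAnnotation]]:
    """Synthetic stand-in for the 160-nt COPA exon-8/9 CDS region.

    Encodes the textual constraints: seven SHM hotspots in total, of
    which the first four (one-mismatch and "other" categories) have
    cores covering nucleotides 690, 698, 718, 719, 721 and 722; one
    GC-rich run of >= 9 bases; ten point mutations of which seven lie
    within the first four hotspots.
    """
    features = [
        (27, "GGTG", "mismatch"),  # H1, CDS 688-691 (covers 690)
        (35, "AGCG", "mismatch"),  # H2, CDS 696-699 (covers 698)
        (55, "ATAC", "other"),  # H3, CDS 716-719
        (59, "TGTG", "other"),  # H4, CDS 720-723
        (79, "GGCT", "exact"),  # H5, CDS 740-743
        (91, "TGCT", "mismatch"),  # H6, CDS 752-755
        (103, "ACGT", "other"),  # H7, CDS 764-767
        (120, "GCCGCCCCCC", "gc"),  # GC run, CDS 781-790
    ]
    seq = _planted_sequence(
        "COPA_exon8_9_synthetic",
        _COPA_OFFSET,
        _COPA_LENGTH,
        features,
        seed=8090,
        forbidden_literals=COPA_OTHER_MOTIFS,
    )
    alt_of = {"A": "G", "C": "T", "G": "C", "T": "A"}
    positions = [690, 698, 717, 718, 719, 721, 722, 665, 705, 795]
    seq.mutations = [
        MutationRecord(position=p, ref=seq.base_at(p), alt=alt_of[seq.base_at(p)])
        for p in positions
    ]
    truth = []
    for start, text, kind in features:
        if kind == "fixed":
            continue
        category = {"exact": "exact_rgyw", "mismatch": "mismatch_rgyw", "other": "other", "gc": "gc_rich"}[kind]
        truth.append(
            HotspotAnnotation(
                _COPA_OFFSET + start, _COPA_OFFSET + start + len(text) - 1, category, text, text
            )
        )
    return seq, truth


# ---------------------------------------------------------------------------
# four-generation family pedigree
# ---------------------------------------------------------------------------

#: Members observed with clinical disease in the family the fixture emulates.
FAMILY_OBSERVED_AFFECTED = ("II-2", "II-7", "III-3", "III-6", "III-11", "III-15", "IV-2", "IV-5")

#: Member with disease-typical antibodies but no clinical disease.
FAMILY_ANTIBODY_POSITIVE = "III-2"


def family_pedigree() -> Pedigree:
    """Synthetic four-generation family with monogenic, incompletely
    penetrant arthritis: one founder carrier, 12/19/9 at-risk members in
    generations II-IV (40 in all) and eight observed affected.

    Generation sizes match the published family; the assignment of
    children to couples is synthetic (the real structure is figure-only).
    """
    from .io import read_pedigree

    ref = resources.files("damageclock").joinpath("data/family_plb1_synthetic.ped")
    with resources.as_file(ref) as path:
        return read_pedigree(path)
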