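"""SHM-hotspot and GC-run scanning with mutation overlay.

Somatic hypermutation (SHM) hotspots — canonically the degenerate 4-mer
RGYW (R = A/G, G, Y = C/T, W = A/T) — and runs of >= 9 consecutive G/C
bases are treated as mutation-prone DNA.  This module scans user-supplied
sequences for exact RGYW cores, one-mismatch RGYW cores (exactly one of
the four positions violates its class) and configurable "other" motifs,
finds maximal GC-rich runs, overlays reported point mutations onto the
annotations, labels codon consequences, and renders the result as HTML,
TSV or BED.

Coordinates are 1-based inclusive in an external system anchored by
``coord_offset`` (the external coordinate of the sequence's first base,
e.g. a CDS position); BED output is the single 0-based half-open surface.
By display convention a hotspot is shown as five nucleotides: one 5'
flanking base plus the 4-mer core.  The core interval is authoritative
for membership tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "AnnotatedSequence",
    "HotspotAnnotation",
    "MutationRecord",
    "MutationValidationError",
    "scan_rgyw",
    "scan_gc_rich",
    "scan_other_motifs",
    "map_mutations",
    "MutationSummary",
    "codon_consequence",
    "render_annotation",
    "parse_annotation_tsv",
    "RGYW_CLASSES",
    "CATEGORY_PRIORITY",
]

VALID_BASES = frozenset("ACGT")

#: Positional base classes of the RGYW motif.
RGYW_CLASSES = (frozenset("AG"), frozenset("G"), frozenset("CT"), frozenset("AT"))

#: Membership priority when a mutation overlaps several annotations.
CATEGORY_PRIORITY = ("exact_rgyw", "mismatch_rgyw", "other", "gc_rich")

#: Display colours, following the convention purple/green/grey/yellow.
CATEGORY_COLOURS = {
    "exact_rgyw": "purple",
    "mismatch_rgyw": "green",
    "other": "grey",
    "gc_rich": "yellow",
}


@dataclass(frozen=True)
class HotspotAnnotation:
    """A hotspot interval in external 1-based inclusive coordinates."""

    start: int
    end: int
    category: str
    matched_text: str
    display_span: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.category not in CATEGORY_PRIORITY:
            raise ValueError(f"unknown category {self.category!r}")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class MutationRecord:
    """A point mutation in external 1-based coordinates (``ref > alt``)."""

    position: int
    ref: str
    alt: str
    label: str = ""
    in_hotspot: str | None = None

    def __post_init__(self) -> None:
        for b, name in ((self.ref, "ref"), (self.alt, "alt")):
            if len(b) != 1 or b not in VALID_BASES:
                raise ValueError(f"{name} must be a single A/C/G/T base, got {b!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are both {self.ref!r} at position {self.position}")


@dataclass
class AnnotatedSequence:
    """A nucleotide sequence with hotspot annotations and mapped mutations."""

    id: str
    sequence: str
    coord_offset: int = 1
    annotations: list[HotspotAnnotation] = field(default_factory=list)
    mutations: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if not seq:
            raise ValueError("empty sequence")
        if bad:
            raise ValueError(f"invalid bases in sequence {self.id!r}: {sorted(bad)}")
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coordinate helpers --------------------------------------------

    @property
    def first_position(self) -> int:
        return self.coord_offset

    @property
    def last_position(self) -> int:
        return self.coord_offset + len(self.sequence) - 1

    def index_of(self, position: int) -> int:
        """External 1-based position -> internal 0-based index."""
        i = position - self.coord_offset
        if not (0 <= i < len(self.sequence)):
            raise ValueError(
                f"position {position} outside sequence {self.id!r} "
                f"({self.first_position}-{self.last_position})"
            )
        return i

    def base_at(self, position: int) -> str:
        return self.sequence[self.index_of(position)]


class MutationValidationError(ValueError):
    """One or more mutation records disagree with the sequence."""

    def __init__(self, offending: list[str]) -> None:
        self.offending = offending
        super().__init__("mutation records disagree with sequence:\n  " + "\n  ".join(offending))


# ---------------------------------------------------------------------------
# scanners
# ---------------------------------------------------------------------------


def _rgyw_violations(window: str) -> int:
    return sum(base not in cls for base, cls in zip(window, RGYW_CLASSES))


def scan_rgyw(seq: AnnotatedSequence, max_mismatch: int = 0) -> list[HotspotAnnotation]:
    """All 4-mer windows within ``max_mismatch`` class violations of RGYW.

    Exact matches are reported as ``exact_rgyw`` even when
    ``max_mismatch=1``; windows with exactly one violation as
    ``mismatch_rgyw``.  Overlaps are allowed, scanning is 5'->3' on the
    given strand, and results are sorted by start.  The display span
    prepends the 5' flanking base where one exists.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    s = seq.sequence
    out: list[HotspotAnnotation] = []
    for i in range(len(s) - 3):
        window = s[i : i + 4]
        v = _rgyw_violations(window)
        if v > max_mismatch:
            continue
        category = "exact_rgyw" if v == 0 else "mismatch_rgyw"
        display = s[i - 1 : i + 4] if i > 0 else window
        out.append(
            HotspotAnnotation(
                start=seq.coord_offset + i,
                end=seq.coord_offset + i + 3,
                category=category,
                matched_text=window,
                display_span=display,
            )
        )
    return out


def scan_gc_rich(seq: AnnotatedSequence, min_len: int = 9) -> list[HotspotAnnotation]:
    """Maximal runs of consecutive G/C bases of length >= ``min_len``."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    s = seq.sequence
    out: list[HotspotAnnotation] = []
    i = 0
    while i < len(s):
        if s[i] in "GC":
            j = i
            while j < len(s) and s[j] in "GC":
                j += 1
            if j - i >= min_len:
                out.append(
                    HotspotAnnotation(
                        start=seq.coord_offset + i,
                        end=seq.coord_offset + j - 1,
                        category="gc_rich",
                        matched_text=s[i:j],
                        display_span=s[i:j],
                    )
                )
            i = j
        else:
            i += 1
    return out


def scan_other_motifs(seq: AnnotatedSequence, motifs: Iterable[str]) -> list[HotspotAnnotation]:
    """Exact occurrences of user-configured motifs, reported as ``other``.

    The "other" hotspot category is user-defined (default empty): motifs
    of any length, matched literally, overlaps allowed.
    """
    s = seq.sequence
    out: list[HotspotAnnotation] = []
    for motif in motifs:
        m = motif.upper()
        if not m or set(m) - VALID_BASES:
            raise ValueError(f"invalid motif {motif!r}")
        start = s.find(m)
        while start != -1:
            display = s[start - 1 : start + len(m)] if start > 0 else m
            out.append(
                HotspotAnnotation(
                    start=seq.coord_offset + start,
                    end=seq.coord_offset + start + len(m) - 1,
                    category="other",
                    matched_text=m,
                    display_span=display,
                )
            )
            start = s.find(m, start + 1)
    return sorted(out, key=lambda a: (a.start, a.end))


def annotate(
    seq: AnnotatedSequence,
    max_mismatch: int = 1,
    gc_min_len: int = 9,
    other_motifs: Iterable[str] = (),
) -> AnnotatedSequence:
    """Run all scanners and attach the merged, start-sorted annotations."""
    ann = scan_rgyw(seq, max_mismatch=max_mismatch)
    ann += scan_other_motifs(seq, other_motifs)
    ann += scan_gc_rich(seq, min_len=gc_min_len)
    seq.annotations = sorted(ann, key=lambda a: (a.start, a.end, CATEGORY_PRIORITY.index(a.category)))
    return seq


# ---------------------------------------------------------------------------
# mutation overlay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationSummary:
    """Per-category mutation counts plus membership in the first k hotspots."""

    n_mutations: int
    per_category: dict[str, int]
    n_outside: int
    rank_limit: int | None = None
    n_in_first_k: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_mutations": self.n_mutations,
            "per_category": dict(self.per_category),
            "n_outside": self.n_outside,
            "rank_limit": self.rank_limit,
            "n_in_first_k": self.n_in_first_k,
        }


def validate_mutations(seq: AnnotatedSequence) -> None:
    """Check every mutation's ref base against the sequence."""
    offending = []
    for m in seq.mutations:
        try:
            base = seq.base_at(m.position)
        except ValueError as exc:
            offending.append(str(exc))
            continue
        if base != m.ref:
            offending.append(f"position {m.position}: sequence has {base}, record says {m.ref}>{m.alt}")
    if offending:
        raise MutationValidationError(offending)


def map_mutations(
    seq: AnnotatedSequence, hotspot_rank_limit: int | None = None
) -> tuple[list[MutationRecord], MutationSummary]:
    """Resolve each mutation to its highest-priority overlapping annotation.

    Priority: exact_rgyw > mismatch_rgyw > other > gc_rich (core intervals
    authoritative).  With ``hotspot_rank_limit=k`` the summary also counts
    mutations falling inside the first ``k`` SHM hotspots (non-GC
    categories) in sequence order.
    """
    validate_mutations(seq)
    resolved: list[MutationRecord] = []
    per_category = {c: 0 for c in CATEGORY_PRIORITY}
    outside = 0
    for m in seq.mutations:
        hits = [a for a in seq.annotations if a.covers(m.position)]
        if hits:
            best = min(hits, key=lambda a: CATEGORY_PRIORITY.index(a.category))
            per_category[best.category] += 1
            resolved.append(replace(m, in_hotspot=best.category))
        else:
            outside += 1
            resolved.append(replace(m, in_hotspot=None))
    n_in_first_k = None
    if hotspot_rank_limit is not None:
        shm = [a for a in seq.annotations if a.category != "gc_rich"]
        shm.sort(key=lambda a: (a.start, a.end))
        first_k = shm[:hotspot_rank_limit]
        n_in_first_k = sum(
            1 for m in seq.mutations if any(a.covers(m.position) for a in first_k)
        )
    summary = MutationSummary(
        n_mutations=len(seq.mutations),
        per_category={c: n for c, n in per_category.items() if n},
        n_outside=outside,
        rank_limit=hotspot_rank_limit,
        n_in_first_k=n_in_first_k,
    )
    seq.mutations = resolved
    return resolved, summary


# ---------------------------------------------------------------------------
# codon consequences
# ---------------------------------------------------------------------------


def codon_consequence(cds: AnnotatedSequence, position: int, alt: str) -> str:
    """Amino-acid change label for a single-base substitution in a CDS.

    ``position`` is the 1-based CDS coordinate (``coord_offset`` anchors
    the sequence within the CDS); the codon index is ``ceil(position/3)``
    under the standard genetic code.  Returns ``<refAA><codon><altAA>``,
    with ``*`` for stop codons and the suffix ``(synonymous)`` when the
    amino acid is unchanged.
    """
    if alt not in VALID_BASES:
        raise ValueError(f"alt must be one of A/C/G/T, got {alt!r}")
    if position < 1:
        raise ValueError("CDS positions are 1-based")
    codon_index = (position + 2) // 3  # ceil(position / 3)
    codon_start = 3 * (codon_index - 1) + 1  # CDS coordinate of codon base 1
    for pos in range(codon_start, codon_start + 3):
        cds.index_of(pos)  # raises if the codon is not fully inside the sequence
    codon = "".join(cds.base_at(p) for p in range(codon_start, codon_start + 3))
    offset_in_codon = position - codon_start
    mutated = codon[:offset_in_codon] + alt + codon[offset_in_codon + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    label = f"{ref_aa}{codon_index}{alt_aa}"
    if ref_aa == alt_aa:
        label += " (synonymous)"
    return label


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _bed_lines(seq: AnnotatedSequence) -> list[str]:
    lines = []
    for a in seq.annotations:
        # BED: 0-based half-open, relative to the sequence record
        start0 = a.start - seq.coord_offset
        end0 = a.end - seq.coord_offset + 1
        lines.append(f"{seq.id}\t{start0}\t{end0}\t{a.category}")
    return lines


def _tsv_lines(seq: AnnotatedSequence) -> list[str]:
    lines = ["start\tend\tcategory\tmatched_text\tdisplay_span"]
    for a in seq.annotations:
        lines.append(f"{a.start}\t{a.end}\t{a.category}\t{a.matched_text}\t{a.display_span}")
    return lines


def _html_document(seq: AnnotatedSequence) -> str:
    # colour classes per category, mutations in red; plain sequence when unannotated
    css = "\n".join(
        f".{cat} {{ background-color: {col}; }}" for cat, col in CATEGORY_COLOURS.items()
    )
    mut_positions = {m.position for m in seq.mutations}
    spans = []
    for i, base in enumerate(seq.sequence):
        pos = seq.coord_offset + i
        hits = [a for a in seq.annotations if a.covers(pos)]
        classes = []
        if hits:
            best = min(hits, key=lambda a: CATEGORY_PRIORITY.index(a.category))
            classes.append(best.category)
        if pos in mut_positions:
            classes.append("mutation")
        if classes:
            spans.append(f'<span class="{" ".join(classes)}">{base}</span>')
        else:
            spans.append(base)
    body = "".join(spans)
    return (
        "<!DOCTYPE html>\n<html><head><style>\n"
        f"{css}\n.mutation {{ color: red; font-weight: bold; }}\n"
        "body { font-family: monospace; word-wrap: break-word; }\n"
        "</style></head>\n"
        f"<body><h3>{seq.id}</h3><p>{body}</p></body></html>\n"
    )


def render_annotation(seq: AnnotatedSequence, format: str = "tsv") -> str:
    """Render annotations as ``html``, ``tsv`` (1-based inclusive) or
    ``bed`` (0-based half-open)."""
    if format == "tsv":
        return "\n".join(_tsv_lines(seq)) + "\n"
    if format == "bed":
        return "".join(line + "\n" for line in _bed_lines(seq))
    if format == "html":
        return _html_document(seq)
    raise ValueError(f"unknown format {format!r}; choose html, tsv or bed")


def parse_annotation_tsv(text: str) -> list[HotspotAnnotation]:
    """Reparse the TSV produced by :func:`render_annotation` (round-trip)."""
    lines = [ln for ln in text.strip().splitlines() if ln]
    if not lines or not lines[0].startswith("start\t"):
        raise ValueError("not an annotation TSV (missing header)")
    out = []
    for ln in lines[1:]:
        start, end, category, matched, display = ln.split("\t")
        out.append(
            HotspotAnnotation(
                start=int(start), end=int(end), category=category,
                matched_text=matched, display_span=display,
            )
        )
    return out
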