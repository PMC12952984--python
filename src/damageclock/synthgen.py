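"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical model its consumer assumes:

* :func:`gen_aaid_cohort` — event-count cohorts drawn from the truncated
  geometric fractions (optionally zero-truncated), so estimator-recovery
  tests have known ground truth;
* :func:`gen_prevalence_series` — linear cumulative prevalence with an
  onset shift and additive Gaussian noise, monotonised (a cumulative
  series cannot decrease);
* :func:`gen_pedigree` — regular family trees with one founder carrier
  and married-in spouses;
* :func:`gen_sequence_with_motifs` — random DNA with planted exact-RGYW
  motifs, one-mismatch-RGYW motifs and GC-rich runs, whose background is
  resampled until it contains no unplanned hotspot (neither exact nor
  one-mismatch RGYW windows, nor long GC runs), so planted-recovery
  tests are exact rather than probabilistic.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .distributions import DEFAULT_TRUNCATION_P, EventDistribution
from .hotspots import RGYW_CLASSES, AnnotatedSequence, HotspotAnnotation
from .pedigree import Member, Pedigree
from .prevalence import PrevalenceSeries

__all__ = [
    "gen_aaid_cohort",
    "gen_prevalence_series",
    "gen_pedigree",
    "gen_sequence_with_motifs",
    "MotifPackingError",
]

_BASES = np.array(list("ACGT"))


class MotifPackingError(ValueError):
    """Planted features cannot be packed into the requested length."""


# ---------------------------------------------------------------------------
# event-count cohorts
# ---------------------------------------------------------------------------


def _truncated_geometric_fractions(X: float, truncation_P: int, zero_included: bool) -> tuple[np.ndarray, np.ndarray]:
    lo = 0 if zero_included else 1
    ps = np.arange(lo, truncation_P + 1)
    if X == 0.0:
        w = (ps == lo).astype(float)  # all mass at the lowest category
    else:
        w = X ** ps.astype(float)
    return ps, w / w.sum()


def gen_aaid_cohort(
    X: float,
    N: int,
    truncation_P: int = DEFAULT_TRUNCATION_P,
    zero_included: bool = True,
    seed: int | None = None,
    exact: bool = False,
    label: str = "",
) -> EventDistribution:
    """Cohort of ``N`` persons with geometric event counts at chance ``X``.

    ``exact=True`` returns the expectation-scale cohort instead of a
    random draw: expected counts ``N * f_p`` rounded by largest
    remainder so they still sum to ``N`` (useful for estimator-recovery
    checks without Monte Carlo noise).
    """
    if not (0.0 <= X <= 1.0):
        raise ValueError("X must lie in [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    ps, fr = _truncated_geometric_fractions(X, truncation_P, zero_included)
    if exact:
        raw = fr * N
        base = np.floor(raw).astype(int)
        short = N - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
        counts = base
    else:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(N, fr)
    return EventDistribution(
        {int(p): int(n) for p, n in zip(ps, counts) if n > 0 or (zero_included and p == 0)},
        zero_included=zero_included,
        label=label or f"synthetic cohort X={X} N={N}",
    )


# ---------------------------------------------------------------------------
# prevalence series
# ---------------------------------------------------------------------------


def gen_prevalence_series(
    slope: float,
    onset_shift: float = 0.0,
    noise_sd: float = 0.0,
    n_points: int = 40,
    t_min: float = 0.0,
    t_max: float = 60.0,
    seed: int | None = None,
    time_kind: str = "age-at-diagnosis",
    label: str = "",
) -> PrevalenceSeries:
    """Linear cumulative prevalence ``max(0, slope*(t - onset))`` plus noise.

    Gaussian noise (sd ``noise_sd``) is added, values are clamped to
    [0, 1] and monotonised with a running maximum so the result is a
    valid cumulative series.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if n_points < 2:
        raise ValueError("need at least two points")
    rng = np.random.default_rng(seed)
    t = np.linspace(t_min, t_max, n_points)
    c = np.clip(slope * (t - onset_shift), 0.0, 1.0)
    if noise_sd > 0:
        c = c + rng.normal(0.0, noise_sd, size=n_points)
    c = np.maximum.accumulate(np.clip(c, 0.0, 1.0))
    return PrevalenceSeries(
        t, c, time_kind=time_kind, label=label or f"synthetic series slope={slope:g} onset={onset_shift:g}"
    )


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


def gen_pedigree(
    generations: int, children_per_couple: int, seed: int | None = None
) -> Pedigree:
    """Regular family tree with one founder carrier.

    Generation 1 is the founder couple (carrier + married-in spouse,
    neither counted at risk); every blood member of the intermediate
    generations marries a non-carrier spouse and has
    ``children_per_couple`` children.  Blood descendants are at risk.
    The structure is deterministic; ``seed`` is accepted for interface
    uniformity.
    """
    if generations < 2:
        raise ValueError("need at least two generations")
    if children_per_couple < 1:
        raise ValueError("children_per_couple must be >= 1")
    members: list[Member] = [
        Member("G1-1", generation=1, at_risk=False),
        Member("G1-1s", generation=1, at_risk=False),
    ]
    married_in = ["G1-1s"]
    parents = [("G1-1", "G1-1s")]
    counter = 0
    for g in range(2, generations + 1):
        next_parents = []
        for father, mother in parents:
            for _ in range(children_per_couple):
                counter += 1
                cid = f"G{g}-{counter}"
                members.append(Member(cid, father=father, mother=mother, generation=g, at_risk=True))
                if g < generations:
                    sid = cid + "s"
                    members.append(Member(sid, generation=g, at_risk=False))
                    married_in.append(sid)
                    next_parents.append((cid, sid))
        parents = next_parents
    return Pedigree(members, founder_carriers=["G1-1"], married_in=married_in)


# ---------------------------------------------------------------------------
# motif-planted sequences
# ---------------------------------------------------------------------------

_MIN_GAP = 4  # background bases between planted features (and at both ends)


def _sample_exact_rgyw(rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(cls)) for cls in RGYW_CLASSES)


def _core_flankable(core: str) -> bool:
    """Whether both flanking windows of a planted 4-mer can be defused.

    A window shifted one base off the core keeps three core bases; if
    those three satisfy their window classes outright, the single
    background base cannot reach two violations (one choice yields an
    exact match, the other a one-mismatch match), so the planting is
    unsatisfiable.  Rejected patterns: suffix core[1:4] ~ [AG] G [CT]
    and prefix core[0:3] ~ G [CT] [AT].
    """
    if core[1] in "AG" and core[2] == "G" and core[3] in "CT":
        return False
    if core[0] == "G" and core[1] in "CT" and core[2] in "AT":
        return False
    return True


def _sample_mismatch_rgyw(rng: np.random.Generator) -> str:
    while True:
        core = list(_sample_exact_rgyw(rng))
        pos = int(rng.integers(0, 4))
        bad = sorted(set("ACGT") - RGYW_CLASSES[pos])
        core[pos] = str(rng.choice(bad))
        out = "".join(core)
        if _core_flankable(out):
            return out


def _gc_windows_ok(run: str) -> bool:
    """Every internal 4-window must violate >= 2 RGYW classes.

    (The W position is always violated inside a pure-GC run; this demands
    one more, so a scanner with one allowed mismatch stays silent.)
    """
    for i in range(len(run) - 3):
        window = run[i : i + 4]
        v = sum(b not in cls for b, cls in zip(window, RGYW_CLASSES))
        if v <= 1:
            return False
    return True


def _gc_suffix_ok(run: str) -> bool:
    """The run's last three bases must carry >= 2 violations themselves.

    In the window [run[-3:], flank] the W position is the flanking base,
    which must be A/T to terminate the run and therefore satisfies W; so
    positions R, G, Y (the run bases) must supply two violations on
    their own (R: base C; G: base C; Y: base G).
    """
    a, b, c = run[-3:]
    return (a == "C") + (b == "C") + (c == "G") >= 2


def _sample_gc_run(rng: np.random.Generator, length: int) -> str:
    for _ in range(1000):
        run = "".join(rng.choice(["G", "C"], size=length))
        if _gc_windows_ok(run) and _gc_suffix_ok(run):
            return run
    return "C" * length  # always satisfies both constraints


def _place_features(
    rng: np.random.Generator, length: int, sizes: list[int]
) -> list[int]:
    """Random non-overlapping starts with >= _MIN_GAP background between/around."""
    n = len(sizes)
    slack = length - sum(sizes) - _MIN_GAP * (n + 1)
    if slack < 0:
        raise MotifPackingError(
            f"cannot fit features of total length {sum(sizes)} with gaps into {length} nt"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    starts = []
    pos = _MIN_GAP
    prev_cut = 0
    for size, cut in zip(sizes, cuts):
        pos += int(cut) - prev_cut
        prev_cut = int(cut)
        starts.append(pos)
        pos += size + _MIN_GAP
    return starts


def _scan_violations(
    seq: list[str],
    planted_cores: set[int],
    planted_runs: list[tuple[int, int]],
    background: np.ndarray,
    gc_min_len: int,
) -> set[int]:
    """Background indices participating in any unplanned hotspot."""
    bad: set[int] = set()
    s = seq
    n = len(s)
    # unplanned exact / one-mismatch RGYW windows
    for i in range(n - 3):
        if i in planted_cores:
            continue
        v = 0
        for b, cls in zip(s[i : i + 4], RGYW_CLASSES):
            if b not in cls:
                v += 1
                if v > 1:
                    break
        if v <= 1:
            bad.update(j for j in range(i, i + 4) if background[j])
    # GC runs: any maximal run >= gc_min_len must coincide exactly with a planted run
    planted = set(planted_runs)
    i = 0
    while i < n:
        if s[i] in "GC":
            j = i
            while j < n and s[j] in "GC":
                j += 1
            if j - i >= gc_min_len and (i, j) not in planted:
                bad.update(k for k in range(i, j) if background[k])
            i = j
        else:
            i += 1
    return bad


def gen_sequence_with_motifs(
    length: int,
    n_exact: int = 0,
    n_mismatch: int = 0,
    n_gc_runs: int = 0,
    seed: int | None = None,
    gc_min_len: int = 9,
    coord_offset: int = 1,
    seq_id: str = "synthetic",
    max_iters: int = 2000,
    max_retries: int = 8,
) -> tuple[AnnotatedSequence, list[HotspotAnnotation]]:
    """Random sequence with planted motifs and a hotspot-free background.

    Returns the sequence plus the ground-truth annotations of the planted
    features (exact-RGYW cores, one-mismatch cores, GC runs).  The
    background is iteratively resampled (a constraint-walk: offending
    background bases of any unplanned exact/one-mismatch RGYW window or
    over-long GC run are redrawn) until scanners recover exactly the
    planted features; raises :class:`MotifPackingError` if the features
    cannot be packed or the walk fails to converge.
    """
    rng = np.random.default_rng(seed)
    kinds = ["exact"] * n_exact + ["mismatch"] * n_mismatch + ["gc"] * n_gc_runs
    for attempt in range(max_retries):
        order = rng.permutation(len(kinds)) if kinds else np.array([], dtype=int)
        shuffled = [kinds[i] for i in order]
        sizes = [gc_min_len if k == "gc" else 4 for k in shuffled]
        starts = _place_features(rng, length, sizes)
        seq = [""] * length
        background = np.ones(length, dtype=bool)
        planted_cores: set[int] = set()
        planted_runs: list[tuple[int, int]] = []
        truth: list[HotspotAnnotation] = []
        for kind, start, size in zip(shuffled, starts, sizes):
            if kind == "exact":
                text = _sample_exact_rgyw(rng)
                category = "exact_rgyw"
                planted_cores.add(start)
            elif kind == "mismatch":
                text = _sample_mismatch_rgyw(rng)
                category = "mismatch_rgyw"
                planted_cores.add(start)
            else:
                text = _sample_gc_run(rng, size)
                category = "gc_rich"
                planted_runs.append((start, start + size))
            for k, b in enumerate(text):
                seq[start + k] = b
                background[start + k] = False
            truth.append(
                HotspotAnnotation(
                    start=coord_offset + start,
                    end=coord_offset + start + size - 1,
                    category=category,
                    matched_text=text,
                    display_span=text,
                )
            )
        bg_idx = np.flatnonzero(background)
        draws = rng.choice(_BASES, size=bg_idx.size)
        for j, b in zip(bg_idx, draws):
            seq[j] = str(b)
        converged = False
        for _ in range(max_iters):
            bad = _scan_violations(seq, planted_cores, planted_runs, background, gc_min_len)
            if not bad:
                converged = True
                break
            redraw = rng.choice(_BASES, size=len(bad))
            for j, b in zip(sorted(bad), redraw):
                seq[j] = str(b)
        if converged:
            annotated = AnnotatedSequence(id=seq_id, sequence="".join(seq), coord_offset=coord_offset)
            truth.sort(key=lambda a: a.start)
            return annotated, truth
    raise MotifPackingError(
        f"background walk failed to converge after {max_retries} placements"
    )
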