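"""Two-hit (Knudson) onset and rarity calculus.

A monogenic disease with pseudo-dominant inheritance requires a germline
mutation on one allele plus a later somatic mutation of the wild-type
allele in the same cell.  With a per-locus critical-mutation interval of
``per_locus_interval`` years (default 100, the inferred somatic rate of
once every 100-150 years) and ``hotspot_count`` mutation-prone loci able
to cause disease, disease-initiating second hits arrive every
``interval / k`` years.  The rarity of an *independent* biallelic
coincidence (two de-novo hits, no germline mutation) is expressed in the
bookkeeping units "persons": ``susceptible_cells * interval**2``.

Note on units: cells x years^2 is not literally persons; the figure
reproduces the back-of-envelope rate bookkeeping (1 chance per cell per
interval per allele, over a ~100-year life) rather than a formal hazard
model.  ``RARITY_DIMENSION_NOTE`` carries this caveat and accompanies
the number in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TwoHitParams",
    "second_hit_interval",
    "biallelic_coincidence_rarity",
    "penetrance_by_age",
    "RARITY_DIMENSION_NOTE",
]

RARITY_DIMENSION_NOTE = (
    "rarity = susceptible_cells x per_locus_interval^2 is rate bookkeeping "
    "(one hit per allele per cell per interval over a lifetime of order the "
    "interval), not a dimensional hazard model; units 'persons' are nominal"
)


@dataclass(frozen=True)
class TwoHitParams:
    """Parameters of the two-hit calculus.

    per_locus_interval
        Years between critical somatic mutations at one locus on one
        allele (default 100).
    hotspot_count
        Number of mutation-prone loci (SHM hotspots) whose somatic
        mutation initiates disease.
    susceptible_cells
        Number of cells able to cause the disease through clonal
        expansion (default 10^6).
    """

    per_locus_interval: float = 100.0
    hotspot_count: int = 1
    susceptible_cells: float = 1e6

    def __post_init__(self) -> None:
        if self.per_locus_interval <= 0:
            raise ValueError("per_locus_interval must be positive")
        if self.hotspot_count < 1:
            raise ValueError("hotspot_count must be >= 1")
        if self.susceptible_cells < 1:
            raise ValueError("susceptible_cells must be >= 1")


def second_hit_interval(params: TwoHitParams) -> float:
    """Years between disease-initiating second hits: ``interval / k``.

    With k mutation-prone loci each sustaining a critical mutation once
    per ``per_locus_interval`` years, hits at *any* of them arrive k
    times as often (k=4 at 100 y/locus: every 25 years; k=7: every ~14).
    """
    return params.per_locus_interval / params.hotspot_count


def biallelic_coincidence_rarity(params: TwoHitParams) -> float:
    """Expected persons per independent double-hit event.

    ``susceptible_cells * per_locus_interval**2`` — at 10^6 cells and one
    mutation per 100 years per allele, one coincidence per 10^10 persons,
    i.e. less than once among all living people; hence the second hit in
    observed disease occurs at the same locus as an inherited first hit.
    See ``RARITY_DIMENSION_NOTE`` for the dimensional caveat.
    """
    return params.susceptible_cells * params.per_locus_interval**2


def penetrance_by_age(params: TwoHitParams, age: float, model: str = "linear") -> float:
    """Fraction of at-risk carriers affected by ``age``.

    ``linear`` (default): ``min(age * k / interval, 1)`` — the
    constant-incidence reading under which cumulative prevalence grows
    linearly (e.g. one event per 120 patient-years gives 33% at age 40).
    ``exponential``: ``1 - exp(-age * k / interval)``, the competing
    constant-hazard reading; the two agree to first order when
    ``age * k / interval`` is small.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    rate = age * params.hotspot_count / params.per_locus_interval
    if model == "linear":
        return min(rate, 1.0)
    if model == "exponential":
        return 1.0 - math.exp(-rate)
    raise ValueError(f"unknown model {model!r}; choose 'linear' or 'exponential'")
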