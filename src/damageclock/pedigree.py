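"""Dominant inheritance with incomplete penetrance on family pedigrees.

Model: a single founder carries the disease trait on one allele; each
child of a carrier inherits it with probability 1/2 (``transmission``);
spouses marrying into the family are assumed non-carriers (the trait is
extremely rare).  A carrier develops clinical disease with lifetime
chance ``X`` (incomplete penetrance), independently across members.

The distribution of the number of affected at-risk members is computed
two ways: exactly, by a generating-function recursion that convolves
subtree distributions conditional on each member's carrier state, and
stochastically by vectorised Monte Carlo.  Per-couple offspring
probabilities and generation-skip probabilities (an affected child of
two unaffected parents, the trait descending through a carrier parent)
come from the same carrier-state calculus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "Member",
    "Pedigree",
    "PenetranceModel",
    "PedigreeModel",
    "PedigreeFit",
    "PedigreeLoopWarning",
    "affected_count_pmf",
    "simulate_pedigree",
    "couple_offspring_pmf",
    "generation_skip_probability",
    "carrier_probabilities",
]


class PedigreeLoopWarning(UserWarning):
    """Pedigree structure does not permit the exact tree recursion."""


@dataclass(frozen=True)
class Member:
    id: str
    father: str | None = None
    mother: str | None = None
    generation: int = 1
    at_risk: bool = True


@dataclass(frozen=True)
class PenetranceModel:
    """Carrier -> disease chance ``X`` and carrier -> child transmission."""

    X: float
    transmission: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.X <= 1.0):
            raise ValueError(f"X must lie in [0, 1], got {self.X}")
        if not (0.0 <= self.transmission <= 1.0):
            raise ValueError(f"transmission must lie in [0, 1], got {self.transmission}")


@dataclass
class Pedigree:
    """Family graph with founder carrier status.

    ``founder_carriers`` have carrier status fixed true; ``married_in``
    members are assumed non-carriers.  Founders not named in either set
    are non-carriers.
    """

    members: dict[str, Member]
    founder_carriers: frozenset[str] = frozenset()
    married_in: frozenset[str] = frozenset()

    def __init__(
        self,
        members: Iterable[Member] | Mapping[str, Member],
        founder_carriers: Iterable[str] = (),
        married_in: Iterable[str] = (),
    ) -> None:
        if isinstance(members, Mapping):
            members = list(members.values())
        self.members = {m.id: m for m in members}
        self.founder_carriers = frozenset(founder_carriers)
        self.married_in = frozenset(married_in)
        self._validate()

    def _validate(self) -> None:
        if self.founder_carriers & self.married_in:
            raise ValueError("founder_carriers and married_in must be disjoint")
        unknown = (self.founder_carriers | self.married_in) - set(self.members)
        if unknown:
            raise ValueError(f"unknown member ids: {sorted(unknown)}")
        for m in self.members.values():
            for parent in (m.father, m.mother):
                if parent is not None and parent not in self.members:
                    raise ValueError(f"member {m.id}: parent {parent} not in pedigree")
        # acyclicity via topological order
        self.topological_order()

    def parents_of(self, member_id: str) -> list[str]:
        m = self.members[member_id]
        return [p for p in (m.father, m.mother) if p is not None]

    def children_of(self, member_id: str) -> list[str]:
        return [m.id for m in self.members.values() if member_id in (m.father, m.mother)]

    def founders(self) -> list[str]:
        return [m.id for m in self.members.values() if m.father is None and m.mother is None]

    def at_risk_ids(self) -> list[str]:
        return [m.id for m in self.members.values() if m.at_risk]

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 2:
                return
            if state.get(mid) == 1:
                raise ValueError(f"cycle in pedigree involving {mid}")
            state[mid] = 1
            for p in self.parents_of(mid):
                visit(p)
            state[mid] = 2
            order.append(mid)

        for mid in self.members:
            visit(mid)
        return order

    def blood_parent_map(self) -> dict[str, str | None]:
        """Each member's single in-lineage parent, or None for roots.

        The exact recursion requires every member to have at most one
        parent that can carry the trait (the other being married-in or
        absent).  Raises ``ValueError`` when that fails (inbreeding loop
        or two potential-carrier parents).
        """
        out: dict[str, str | None] = {}
        for m in self.members.values():
            carriers_possible = [
                p for p in self.parents_of(m.id) if p not in self.married_in
            ]
            if len(carriers_possible) > 1:
                raise ValueError(
                    f"member {m.id} has two potential-carrier parents; "
                    "tree recursion not applicable"
                )
            out[m.id] = carriers_possible[0] if carriers_possible else None
        return out


def carrier_probabilities(ped: Pedigree, model: PenetranceModel) -> dict[str, float]:
    """Marginal carrier probability per member under the transmission model."""
    t = model.transmission
    probs: dict[str, float] = {}
    for mid in ped.topological_order():
        m = ped.members[mid]
        if mid in ped.married_in:
            probs[mid] = 0.0
        elif m.father is None and m.mother is None:
            probs[mid] = 1.0 if mid in ped.founder_carriers else 0.0
        else:
            # child is a carrier if it inherits from either carrier parent
            p_not = 1.0
            for parent in ped.parents_of(mid):
                p_not *= 1.0 - t * probs[parent]
            probs[mid] = 1.0 - p_not
    return probs


# ---------------------------------------------------------------------------
# exact affected-count pmf (generating-function recursion)
# ---------------------------------------------------------------------------


def _subtree_pmf(
    ped: Pedigree,
    model: PenetranceModel,
    children_map: dict[str, list[str]],
    mid: str,
    carrier: bool,
    cache: dict[tuple[str, bool], np.ndarray],
) -> np.ndarray:
    key = (mid, carrier)
    if key in cache:
        return cache[key]
    m = ped.members[mid]
    p_affected = model.X if (carrier and m.at_risk) else 0.0
    own = np.array([1.0 - p_affected, p_affected]) if p_affected > 0 else np.array([1.0])
    pmf = own
    t = model.transmission
    for child in children_map[mid]:
        if carrier:
            child_pmf_c = _subtree_pmf(ped, model, children_map, child, True, cache)
            child_pmf_n = _subtree_pmf(ped, model, children_map, child, False, cache)
            n = max(len(child_pmf_c), len(child_pmf_n))
            mix = np.zeros(n)
            mix[: len(child_pmf_c)] += t * child_pmf_c
            mix[: len(child_pmf_n)] += (1.0 - t) * child_pmf_n
        else:
            mix = _subtree_pmf(ped, model, children_map, child, False, cache)
        pmf = np.convolve(pmf, mix)
    cache[key] = pmf
    return pmf


def affected_count_pmf(ped: Pedigree, model: PenetranceModel) -> np.ndarray:
    """Exact pmf of the number of affected at-risk members.

    Uses the subtree-convolution recursion on the blood-lineage tree.
    Pedigrees whose structure defeats the recursion (a member with two
    potential-carrier parents) fall back to Monte Carlo (10^6 replicates,
    fixed seed) with a :class:`PedigreeLoopWarning`.
    """
    try:
        blood = ped.blood_parent_map()
    except ValueError as exc:
        warnings.warn(f"{exc}; falling back to Monte Carlo", PedigreeLoopWarning)
        counts, _ = simulate_pedigree(ped, model, n_reps=1_000_000, seed=0)
        n_risk = len(ped.at_risk_ids())
        return np.bincount(counts, minlength=n_risk + 1) / len(counts)
    # lineage children: members whose blood parent is mid
    children_map: dict[str, list[str]] = {mid: [] for mid in ped.members}
    roots: list[str] = []
    for mid, parent in blood.items():
        if parent is None:
            roots.append(mid)
        else:
            children_map[parent].append(mid)
    cache: dict[tuple[str, bool], np.ndarray] = {}
    pmf = np.array([1.0])
    for root in roots:
        carrier = root in ped.founder_carriers
        pmf = np.convolve(pmf, _subtree_pmf(ped, model, children_map, root, carrier, cache))
    n_risk = len(ped.at_risk_ids())
    out = np.zeros(n_risk + 1)
    out[: len(pmf)] = pmf
    assert abs(out.sum() - 1.0) < 1e-12
    return out


def simulate_pedigree(
    ped: Pedigree, model: PenetranceModel, n_reps: int, seed: int | None = None
) -> tuple[np.ndarray, dict[str, float]]:
    """Monte Carlo affected counts plus per-member affection frequencies."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    t = model.transmission
    carrier: dict[str, np.ndarray] = {}
    for mid in order:
        m = ped.members[mid]
        if mid in ped.married_in:
            carrier[mid] = np.zeros(n_reps, dtype=bool)
        elif m.father is None and m.mother is None:
            carrier[mid] = np.full(n_reps, mid in ped.founder_carriers)
        else:
            got = np.zeros(n_reps, dtype=bool)
            for parent in ped.parents_of(mid):
                got |= carrier[parent] & (rng.random(n_reps) < t)
            carrier[mid] = got
    counts = np.zeros(n_reps, dtype=int)
    freqs: dict[str, float] = {}
    for mid in order:
        m = ped.members[mid]
        if not m.at_risk:
            freqs[mid] = 0.0
            continue
        affected = carrier[mid] & (rng.random(n_reps) < model.X)
        counts += affected
        freqs[mid] = float(affected.mean())
    return counts, freqs


def couple_offspring_pmf(n_children: int, model: PenetranceModel) -> np.ndarray:
    """Pmf of affected children for a couple with exactly one carrier parent.

    Each child is affected with chance ``transmission * X`` independently,
    so the count is Binomial(n_children, transmission * X).
    """
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    k = np.arange(n_children + 1)
    return stats.binom.pmf(k, n_children, model.transmission * model.X)


def generation_skip_probability(ped: Pedigree, model: PenetranceModel, member_id: str) -> float:
    """P(member affected, both parents unaffected, trait descending through them).

    Computed by exhaustive enumeration over carrier configurations of the
    member's ancestor closure (each configuration weighted by the
    transmission rules), so it is exact for any loop-free ancestry.
    """
    if member_id not in ped.members:
        raise ValueError(f"unknown member {member_id!r}")
    if not ped.parents_of(member_id):
        raise ValueError(f"member {member_id!r} has no in-pedigree parents")
    # ancestor closure including the member
    closure: set[str] = set()
    stack = [member_id]
    while stack:
        mid = stack.pop()
        if mid in closure:
            continue
        closure.add(mid)
        stack.extend(ped.parents_of(mid))
    ordered = [mid for mid in ped.topological_order() if mid in closure]
    t, X = model.transmission, model.X
    parents = set(ped.parents_of(member_id))
    total = 0.0
    for states in product([False, True], repeat=len(ordered)):
        state = dict(zip(ordered, states))
        prob = 1.0
        for mid in ordered:
            m = ped.members[mid]
            if mid in ped.married_in:
                p_carrier = 0.0
            elif m.father is None and m.mother is None:
                p_carrier = 1.0 if mid in ped.founder_carriers else 0.0
            else:
                p_not = 1.0
                for parent in ped.parents_of(mid):
                    p_parent = state[parent] if parent in state else 0.0
                    p_not *= 1.0 - t * p_parent
                p_carrier = 1.0 - p_not
            prob *= p_carrier if state[mid] else 1.0 - p_carrier
            if prob == 0.0:
                break
        if prob == 0.0 or not state[member_id]:
            continue
        # member affected; every at-risk carrier parent must be unaffected
        prob *= X
        for parent in parents:
            if state.get(parent, False) and ped.members[parent].at_risk:
                prob *= 1.0 - X
        if any(state.get(parent, False) for parent in parents):
            total += prob
    return total


# ---------------------------------------------------------------------------
# statsmodels-style wrapper
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeFit:
    """Exact affected-count distribution with summaries and MC cross-check."""

    pmf: np.ndarray = field(repr=False)
    expected_affected: float
    carrier_probs: dict[str, float] = field(repr=False)
    model: PenetranceModel = field(repr=False)
    n_at_risk: int

    def prob_between(self, lo: int, hi: int) -> float:
        return float(self.pmf[lo : hi + 1].sum())

    def prob_at_least(self, k: int) -> float:
        return float(self.pmf[k:].sum())

    @property
    def modal_count(self) -> int:
        return int(np.argmax(self.pmf))

    def to_dict(self) -> dict:
        return {
            "X": self.model.X,
            "transmission": self.model.transmission,
            "n_at_risk": self.n_at_risk,
            "expected_affected": self.expected_affected,
            "modal_count": self.modal_count,
            "pmf": self.pmf.tolist(),
        }

    def summary(self, observed: int | None = None) -> str:
        lines = [
            "Pedigree penetrance model",
            "=" * 25,
            f"at-risk members:    {self.n_at_risk}",
            f"carrier chance X:   {self.model.X:.4g}   transmission: {self.model.transmission:.2g}",
            f"expected affected:  {self.expected_affected:.2f}",
            f"modal count:        {self.modal_count}",
            f"P(4 <= affected <= 10): {self.prob_between(4, min(10, self.n_at_risk)):.3f}",
        ]
        if observed is not None:
            lines.append(f"P(affected = {observed}):  {self.pmf[observed]:.4f}")
        return "\n".join(lines)


class PedigreeModel:
    """Penetrance model bound to a pedigree; ``fit()`` runs the exact recursion."""

    def __init__(self, pedigree: Pedigree, model: PenetranceModel) -> None:
        self.pedigree = pedigree
        self.model = model

    def fit(self) -> PedigreeFit:
        pmf = affected_count_pmf(self.pedigree, self.model)
        probs = carrier_probabilities(self.pedigree, self.model)
        expected = sum(
            probs[mid] * self.model.X for mid in self.pedigree.at_risk_ids()
        )
        return PedigreeFit(
            pmf=pmf,
            expected_affected=float(expected),
            carrier_probs=probs,
            model=self.model,
            n_at_risk=len(self.pedigree.at_risk_ids()),
        )

    def simulate(self, n_reps: int, seed: int | None = None):
        return simulate_pedigree(self.pedigree, self.model, n_reps, seed)
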