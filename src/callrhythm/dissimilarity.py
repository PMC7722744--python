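"""Dissimilarities between daily rhythms.

The dissimilarity D between two rhythms is the Jensen–Shannon divergence,

    JSD(P, Q) = ½ KL(P ‖ M) + ½ KL(Q ‖ M),   M = (P + Q)/2,

and the distance actually used by the persistence test is its square root,
which is a metric.  With logarithms in base 2 (the default) both lie in
[0, 1].  Zero bins follow the usual convention 0·log(0/m) = 0; a mixture
bin M(t) can only vanish where both rhythms are zero, and such bins
contribute nothing.

Two kinds of distance feed the sign test:

* intra-individual ``y_i`` — the distance between one individual's rhythms
  in two successive periods (how much *they* changed);
* inter-individual ``x_{i,j}^{T_k}`` — the distance between two different
  individuals' rhythms within the same period (how different they are from
  the comparison population).

The log base rescales every dissimilarity by the same positive factor, so
the downstream sign comparisons are invariant to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import rel_entr

from .cdr_io import Mode
from .rhythm import DailyRhythm

__all__ = [
    "MissingProfileError",
    "PopulationTooSmallError",
    "DissimilaritySet",
    "jensen_shannon_divergence",
    "rhythm_distance",
    "index_rhythms",
    "intra_dissimilarity",
    "inter_dissimilarities",
    "compute_dissimilarity_set",
]

_NORM_TOL = 1e-8


class MissingProfileError(KeyError):
    """An individual has no rhythm for a requested period."""


class PopulationTooSmallError(ValueError):
    """Fewer than two individuals remain after exclusions."""


@dataclass(frozen=True)
class DissimilaritySet:
    """All dissimilarities needed to test one focal individual.

    ``y`` is the intra-individual dissimilarity between the two periods;
    ``x_a`` and ``x_b`` hold the inter-individual dissimilarities of the
    focal individual against each comparator within the first and second
    period respectively, ordered as ``comparator_ids``.
    """

    owner_id: str
    mode: Mode
    y: float
    x_a: np.ndarray
    x_b: np.ndarray
    comparator_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.x_a) != len(self.x_b) or len(self.x_a) != len(self.comparator_ids):
            raise ValueError("x_a, x_b and comparator_ids must have equal length")


def _as_distribution(p) -> np.ndarray:
    vec = np.asarray(getattr(p, "fractions", p), dtype=np.float64)
    if vec.ndim != 1:
        raise ValueError("a rhythm must be a 1-D probability vector")
    if (vec < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(vec.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"probability vector must sum to 1, got {vec.sum()}")
    return vec


def jensen_shannon_divergence(p, q, log_base: float = 2.0) -> float:
    """Jensen–Shannon divergence between two probability vectors.

    Accepts plain vectors or :class:`~callrhythm.rhythm.DailyRhythm`
    objects.  Bounded by ``log_base``-log of 2, i.e. by 1 for the default
    base 2; symmetric in its arguments.
    """
    if log_base <= 1:
        raise ValueError("log_base must exceed 1")
    pv, qv = _as_distribution(p), _as_distribution(q)
    if pv.shape != qv.shape:
        raise ValueError("vectors must have equal length")
    m = 0.5 * (pv + qv)
    # rel_entr handles the 0·log(0/m)=0 convention and flags m=0 with p>0
    div_nats = 0.5 * (rel_entr(pv, m).sum() + rel_entr(qv, m).sum())
    value = float(div_nats / math.log(log_base))
    # clip the tiny negative round-off possible at identical inputs
    return max(value, 0.0)


def rhythm_distance(p, q, log_base: float = 2.0) -> float:
    """Jensen–Shannon distance sqrt(JSD(P, Q)); a metric, in [0,1] base 2."""
    return math.sqrt(jensen_shannon_divergence(p, q, log_base=log_base))


def index_rhythms(rhythms: Iterable[DailyRhythm]) -> dict[tuple[str, str], DailyRhythm]:
    """Index rhythms by ``(owner_id, period)`` for fast lookup."""
    index: dict[tuple[str, str], DailyRhythm] = {}
    for r in rhythms:
        key = (r.owner_id, r.period)
        if key in index:
            raise ValueError(f"duplicate rhythm for {key}")
        index[key] = r
    return index


def _lookup(
    rhythms: Mapping[tuple[str, str], DailyRhythm] | Iterable[DailyRhythm],
    owner: str,
    period: str,
) -> DailyRhythm:
    if not isinstance(rhythms, Mapping):
        rhythms = index_rhythms(rhythms)
    try:
        return rhythms[(owner, period)]
    except KeyError:
        raise MissingProfileError(f"no rhythm for owner {owner!r} in period {period!r}") from None


def intra_dissimilarity(
    owner: str,
    period_a: str,
    period_b: str,
    rhythms: Mapping[tuple[str, str], DailyRhythm] | Iterable[DailyRhythm],
    log_base: float = 2.0,
) -> float:
    """Intra-individual dissimilarity y_i between two successive periods."""
    if not isinstance(rhythms, Mapping):
        rhythms = index_rhythms(rhythms)
    return rhythm_distance(
        _lookup(rhythms, owner, period_a),
        _lookup(rhythms, owner, period_b),
        log_base=log_base,
    )


def inter_dissimilarities(
    owner: str,
    period: str,
    rhythms: Mapping[tuple[str, str], DailyRhythm] | Iterable[DailyRhythm],
    comparators: Sequence[str] | None = None,
    log_base: float = 2.0,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Inter-individual dissimilarities of ``owner`` within one period.

    Returns the vector ``x_{i,j}^{T_k}`` over every comparator ``j != i``
    together with the comparator ids in matching order.  By default the
    comparators are all other owners with a rhythm in ``period``; pass
    ``comparators`` to fix the population (e.g. owners valid in *all*
    analysed periods).
    """
    if not isinstance(rhythms, Mapping):
        rhythms = index_rhythms(rhythms)
    focal = _lookup(rhythms, owner, period)
    if comparators is None:
        comparators = sorted({o for (o, p) in rhythms if p == period and o != owner})
    else:
        comparators = [c for c in comparators if c != owner]
    if not comparators:
        raise PopulationTooSmallError(
            f"no comparator individuals for owner {owner!r} in period {period!r}"
        )
    values = np.array(
        [rhythm_distance(focal, _lookup(rhythms, j, period), log_base=log_base) for j in comparators]
    )
    return values, tuple(comparators)


def compute_dissimilarity_set(
    owner: str,
    period_a: str,
    period_b: str,
    rhythms: Mapping[tuple[str, str], DailyRhythm] | Iterable[DailyRhythm],
    comparators: Sequence[str] | None = None,
    log_base: float = 2.0,
) -> DissimilaritySet:
    """Assemble y_i and the two inter-individual vectors for one focal owner."""
    if not isinstance(rhythms, Mapping):
        rhythms = index_rhythms(rhythms)
    y = intra_dissimilarity(owner, period_a, period_b, rhythms, log_base=log_base)
    x_a, ids_a = inter_dissimilarities(owner, period_a, rhythms, comparators, log_base=log_base)
    x_b, ids_b = inter_dissimilarities(owner, period_b, rhythms, ids_a, log_base=log_base)
    if ids_a != ids_b:
        raise PopulationTooSmallError(
            f"comparator populations differ between {period_a!r} and {period_b!r}; "
            "restrict to individuals valid in both periods"
        )
    mode = _lookup(rhythms, owner, period_a).mode
    return DissimilaritySet(
        owner_id=owner, mode=mode, y=y, x_a=x_a, x_b=x_b, comparator_ids=ids_a
    )
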