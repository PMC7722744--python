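"""Sign test of quantiles for circadian-rhythm persistence.

For a focal individual ``i`` observed over two successive periods in a
population of ``n`` individuals, the procedure compares the
intra-individual dissimilarity ``y_i`` with each of the ``2n - 2``
inter-individual dissimilarities ``x_{i,j}^{T_k}`` (``n - 1`` comparators
in each of the two periods):

    z_{i,j}^{T_k} = 1{ y_i - x_{i,j}^{T_k} > 0 }

A component equal to 1 is a *success*: that inter-individual dissimilarity
is strictly lower than the intra-individual one.  Under the null
hypothesis that a success has probability ``q`` (½ by default, the median
test), the number of successes N_i^+ follows Binomial(2n − 2, q).  A
*small* N_i^+ means the individual resembles their own past more than they
resemble anybody else, so the evidence for persistence is the lower tail:

    p_i = P(X <= N_i^+),   X ~ Binomial(2n − 2, q),

computed by exact summation of the binomial pmf.  The rhythm is declared
persistent when p_i < alpha.

For more than two periods the pairwise verdicts across consecutive period
pairs form a binary vector ``v`` of length N_T − 1 (1 = persistence) and a
second-level sign test asks whether persistence events dominate:
p = P(X >= Σv) for X ~ Binomial(N_T − 1, ½), upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, fsum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cdr_io import CallRecord, Mode, TimePartition, assign_periods, select_direction
from .dissimilarity import (
    DissimilaritySet,
    PopulationTooSmallError,
    compute_dissimilarity_set,
    index_rhythms,
)
from .rhythm import DailyRhythm, compute_rhythm, count_by_hour

log = logging.getLogger(__name__)

__all__ = [
    "PersistenceResult",
    "SequenceResult",
    "PopulationAnalysis",
    "comparison_vector",
    "sign_test_pvalue",
    "assess_pair",
    "assess_sequence",
    "analyze_population",
    "format_pvalue",
]


@dataclass(frozen=True)
class PersistenceResult:
    """Outcome of the two-period sign test for one individual and mode."""

    owner_id: str
    mode: Mode
    y: float
    z: np.ndarray
    n_plus: int
    n_comp: int
    q: float
    p_value: float
    alpha: float
    persistent: bool

    def __post_init__(self) -> None:
        if len(self.z) != self.n_comp:
            raise ValueError("comparison vector length must equal n_comp")
        if int(np.sum(self.z)) != self.n_plus:
            raise ValueError("n_plus must equal the number of successes in z")


@dataclass(frozen=True)
class SequenceResult:
    """Outcome of the multi-period trend test (N_T > 2) for one individual."""

    owner_id: str
    mode: Mode
    v: np.ndarray  # 1 = persistence between periods k and k+1
    per_pair_results: tuple[PersistenceResult, ...]
    p_value: float
    alpha: float
    trend_persistent: bool


def comparison_vector(y: float, x_a: Sequence[float], x_b: Sequence[float]) -> np.ndarray:
    """Binary success vector z_i comparing y_i with every x_{i,j}^{T_k}.

    Successes are *strict*: a tie (y equal to some x) counts as a failure,
    which is conservative for persistence.
    """
    x_a = np.asarray(x_a, dtype=np.float64)
    x_b = np.asarray(x_b, dtype=np.float64)
    if x_a.size == 0 or x_b.size == 0:
        raise ValueError("inter-individual dissimilarity vectors must be non-empty")
    if x_a.shape != x_b.shape:
        raise ValueError("the two period vectors must have equal length")
    x = np.concatenate([x_a, x_b])
    return (y - x > 0).astype(np.int8)


def sign_test_pvalue(n_plus: int, n_comp: int, q: float = 0.5) -> float:
    """Exact one-sided lower-tail binomial p-value P(X <= n_plus).

    ``X ~ Binomial(n_comp, q)``; the sum is evaluated term by term from the
    exact binomial coefficients (no normal approximation).
    """
    if not 0 <= n_plus <= n_comp:
        raise ValueError(f"need 0 <= n_plus <= n_comp, got {n_plus}, {n_comp}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie strictly in (0, 1), got {q}")
    if n_plus == n_comp:
        return 1.0
    terms = [comb(n_comp, k) * q**k * (1.0 - q) ** (n_comp - k) for k in range(n_plus + 1)]
    return min(fsum(terms), 1.0)


def _upper_tail_pvalue(successes: int, n: int, q: float = 0.5) -> float:
    """Exact upper-tail P(X >= successes) for X ~ Binomial(n, q)."""
    if successes <= 0:
        return 1.0
    terms = [comb(n, k) * q**k * (1.0 - q) ** (n - k) for k in range(successes, n + 1)]
    return min(fsum(terms), 1.0)


def assess_pair(
    owner: str,
    period_a: str,
    period_b: str,
    rhythms: Mapping[tuple[str, str], DailyRhythm] | Iterable[DailyRhythm],
    q: float = 0.5,
    alpha: float = 0.05,
    comparators: Sequence[str] | None = None,
    log_base: float = 2.0,
) -> PersistenceResult:
    """Run the full two-period sign test for one focal individual.

    Wires intra- and inter-individual dissimilarities into the comparison
    vector and the exact binomial test; ``n_comp = 2n − 2`` where ``n`` is
    the included population size.
    """
    if not isinstance(rhythms, Mapping):
        rhythms = index_rhythms(rhythms)
    dset = compute_dissimilarity_set(
        owner, period_a, period_b, rhythms, comparators, log_base=log_base
    )
    return _assess_from_set(dset, q=q, alpha=alpha)


def _assess_from_set(dset: DissimilaritySet, q: float, alpha: float) -> PersistenceResult:
    z = comparison_vector(dset.y, dset.x_a, dset.x_b)
    n_plus = int(z.sum())
    n_comp = len(z)
    p = sign_test_pvalue(n_plus, n_comp, q)
    return PersistenceResult(
        owner_id=dset.owner_id,
        mode=dset.mode,
        y=dset.y,
        z=z,
        n_plus=n_plus,
        n_comp=n_comp,
        q=q,
        p_value=p,
        alpha=alpha,
        persistent=p < alpha,
    )


def assess_sequence(
    owner: str,
    periods: Sequence[str],
    rhythms: Mapping[tuple[str, str], DailyRhythm] | Iterable[DailyRhythm],
    q: float = 0.5,
    alpha: float = 0.05,
    comparators: Sequence[str] | None = None,
    log_base: float = 2.0,
) -> SequenceResult:
    """Trend test across ``N_T > 2`` successive periods.

    Applies :func:`assess_pair` to every consecutive pair, collects the
    binary persistence verdicts ``v`` and tests whether persistence events
    dominate: exact upper-tail binomial P(X >= Σv), X ~ Binomial(N_T−1, ½).
    """
    if len(periods) < 3:
        raise ValueError("assess_sequence requires N_T >= 3 periods; use assess_pair")
    if not isinstance(rhythms, Mapping):
        rhythms = index_rhythms(rhythms)
    pair_results = tuple(
        assess_pair(owner, periods[k], periods[k + 1], rhythms, q=q, alpha=alpha,
                    comparators=comparators, log_base=log_base)
        for k in range(len(periods) - 1)
    )
    v = np.array([int(r.persistent) for r in pair_results], dtype=np.int8)
    p = _upper_tail_pvalue(int(v.sum()), len(v), 0.5)
    return SequenceResult(
        owner_id=owner,
        mode=pair_results[0].mode,
        v=v,
        per_pair_results=pair_results,
        p_value=p,
        alpha=alpha,
        trend_persistent=p < alpha,
    )


@dataclass
class PopulationAnalysis:
    """Per-individual results plus bookkeeping for one analysis run."""

    table: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)
    sequence_results: list[SequenceResult] = field(default_factory=list)
    dropped_records: int = 0


def _rhythms_for_mode(
    by_period: Mapping[str, Sequence[CallRecord]], mode: Mode
) -> tuple[dict[tuple[str, str], DailyRhythm], list[dict]]:
    """Build rhythms per (owner, period); record exclusions for empty periods."""
    owners = sorted({rec.owner_id for recs in by_period.values() for rec in recs})
    periods = list(by_period)
    rhythms: dict[tuple[str, str], DailyRhythm] = {}
    exclusions: list[dict] = []
    for owner in owners:
        owner_rhythms = {}
        empty_periods = []
        for label in periods:
            records = [r for r in select_direction(by_period[label], mode) if r.owner_id == owner]
            if not records:
                empty_periods.append(label)
                continue
            counts = count_by_hour(records, owner_id=owner, period=label, mode=mode)
            owner_rhythms[(owner, label)] = compute_rhythm(counts)
        if empty_periods:
            # excluded entirely (both as focal and comparator) for this mode
            exclusions.append(
                {"owner_id": owner, "mode": mode.value, "reason": f"no calls in period(s) {', '.join(empty_periods)}"}
            )
        else:
            rhythms.update(owner_rhythms)
    return rhythms, exclusions


def analyze_population(
    records: Sequence[CallRecord],
    partition: TimePartition,
    modes: Sequence[Mode | str] = (Mode.OUTGOING, Mode.INCOMING, Mode.TOTAL),
    q: float = 0.5,
    alpha: float = 0.05,
    bh_correct: bool = False,
    log_base: float = 2.0,
) -> PopulationAnalysis:
    """Run the persistence analysis for every individual and direction mode.

    For a two-period partition each (individual, mode) row holds the exact
    sign-test outcome; with more than two periods the pairwise tests are
    chained into the sequence trend test and both levels are reported.
    Individuals with an empty period for a mode are excluded from that
    mode's population entirely, shrinking ``n_comp`` for everyone.

    With ``bh_correct=True`` a Benjamini–Hochberg-adjusted p-value column
    is added per mode (the persistence verdict still uses the raw p-value,
    matching the per-individual reporting convention).
    """
    modes = [Mode(m) for m in modes]
    if not modes:
        raise ValueError("at least one direction mode is required")
    by_period, dropped = assign_periods(records, partition)
    periods = list(partition.labels)
    rows: list[dict] = []
    all_exclusions: list[dict] = []
    sequence_results: list[SequenceResult] = []

    for mode in modes:
        rhythms, exclusions = _rhythms_for_mode(by_period, mode)
        all_exclusions.extend(exclusions)
        included = sorted({o for (o, _p) in rhythms})
        if len(included) < 2:
            raise PopulationTooSmallError(
                f"mode {mode.value}: fewer than 2 individuals with calls in every period"
            )
        for owner in included:
            if partition.n_periods == 2:
                res = assess_pair(
                    owner, periods[0], periods[1], rhythms, q=q, alpha=alpha,
                    comparators=included, log_base=log_base,
                )
                rows.append(_result_row(res))
            else:
                seq = assess_sequence(
                    owner, periods, rhythms, q=q, alpha=alpha,
                    comparators=included, log_base=log_base,
                )
                sequence_results.append(seq)
                rows.append(_sequence_row(seq))

    table = pd.DataFrame(rows)
    if bh_correct and not table.empty:
        from scipy.stats import false_discovery_control

        table["p_value_bh"] = np.nan
        for mode in modes:
            mask = table["mode"] == mode.value
            table.loc[mask, "p_value_bh"] = false_discovery_control(
                table.loc[mask, "p_value"].to_numpy(), method="bh"
            )
    return PopulationAnalysis(
        table=table,
        exclusions=all_exclusions,
        sequence_results=sequence_results,
        dropped_records=len(dropped),
    )


def _result_row(res: PersistenceResult) -> dict:
    return {
        "individual": res.owner_id,
        "mode": res.mode.value,
        "y_i": res.y,
        "p_value": res.p_value,
        "p_value_sci": format_pvalue(res.p_value),
        "n_plus": res.n_plus,
        "n_comp": res.n_comp,
        "persistent": res.persistent,
    }


def _sequence_row(seq: SequenceResult) -> dict:
    return {
        "individual": seq.owner_id,
        "mode": seq.mode.value,
        "y_i": np.nan,
        "p_value": seq.p_value,
        "p_value_sci": format_pvalue(seq.p_value),
        "n_plus": int(seq.v.sum()),
        "n_comp": len(seq.v),
        "persistent": seq.trend_persistent,
    }


def format_pvalue(p: float) -> str:
    """Render a p-value at 3 significant figures in scientific notation,
    e.g. ``8.88E-16`` or ``1.00E+00``."""
    return f"{p:.2E}"
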