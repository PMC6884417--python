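"""Twin-pair lineage count statistics.

A twin pair is the two blastocysts grown from the separated blastomeres of
one bisected 2-cell embryo. Each blastocyst is scored by counting
CDX2-positive (trophectoderm), SOX17-positive (primitive endoderm) and
NANOG-positive (epiblast, EPI) cells. The statistics here quantify how
unequal the two halves are:

* per-layer C^high/C^low ratios (higher count over lower count, per pair);
* the fraction of blastocysts accumulating >= 4 EPI cells, the threshold
  regarded as necessary for post-blastocyst development, optionally after
  a >= 50 total cell filter;
* complete-pair vs singleton accounting of developmental endpoints and the
  Fisher exact allocation test against the all-totipotent expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ttest_ind

__all__ = [
    "PairRatio",
    "PairOutcomeSummary",
    "high_low_ratio",
    "pair_ratios",
    "ratio_medians",
    "epi_sufficiency",
    "pair_outcomes",
    "pair_concordance",
    "allocation_test",
    "survival_summary",
    "half_sum_vs_intact",
]

LAYERS = ("cdx2", "sox17", "nanog")


@dataclass
class PairRatio:
    """C^high/C^low for one pair and one germ layer.

    ``flag`` is ``"finite"`` when both counts are positive, ``"unbounded"``
    when the lower count is 0 but the higher is not (the ICM of one member
    contained no cells of that layer), and ``"undefined"`` when both are 0.
    Non-finite ratios are excluded from medians and tallied separately.
    """

    pair_id: object
    layer: str
    c_high: int
    c_low: int
    ratio: float  # nan when not finite
    flag: str


def _check_count(value, name: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (Integral, np.integer)):
        if isinstance(value, float) and float(value).is_integer():
            value = int(value)
        else:
            raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return int(value)


def high_low_ratio(count_a, count_b, pair_id=None, layer: str = "") -> PairRatio:
    """The arithmetic ratio of the higher count over the lower count.

    Symmetric in member order and always >= 1 when finite; balance shows
    as ratios near 1, imbalance as ratios well above 1.
    """
    a = _check_count(count_a, "count_a")
    b = _check_count(count_b, "count_b")
    hi, lo = max(a, b), min(a, b)
    if hi == 0:
        return PairRatio(pair_id, layer, hi, lo, float("nan"), "undefined")
    if lo == 0:
        return PairRatio(pair_id, layer, hi, lo, float("nan"), "unbounded")
    return PairRatio(pair_id, layer, hi, lo, hi / lo, "finite")


def pair_ratios(table: pd.DataFrame, layers: Sequence[str] = LAYERS) -> pd.DataFrame:
    """Per-pair, per-layer C^high/C^low ratios from a lineage count table.

    The table must have columns pair_id, member and one column per layer;
    rows with member == "intact" are ignored. Output columns: pair_id,
    layer, c_high, c_low, ratio, flag.
    """
    twins = table[table["member"] != "intact"]
    records = []
    for pid, grp in twins.groupby("pair_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"pair {pid!r} has {len(grp)} members, expected 2")
        for layer in layers:
            va, vb = grp[layer].tolist()
            r = high_low_ratio(va, vb, pair_id=pid, layer=layer)
            records.append(vars(r))
    return pd.DataFrame(records)


def ratio_medians(ratios: pd.DataFrame) -> pd.DataFrame:
    """Median finite ratio per layer, with tallies of non-finite pairs."""
    out = []
    for layer, grp in ratios.groupby("layer", sort=False):
        finite = grp[grp["flag"] == "finite"]["ratio"]
        out.append(
            dict(
                layer=layer,
                median_ratio=float(finite.median()) if len(finite) else float("nan"),
                n_finite=int(len(finite)),
                n_unbounded=int((grp["flag"] == "unbounded").sum()),
                n_undefined=int((grp["flag"] == "undefined").sum()),
            )
        )
    return pd.DataFrame(out).set_index("layer")


def epi_sufficiency(
    table: pd.DataFrame,
    threshold: int = 4,
    min_total: Optional[int] = None,
    group_by: str = "treatment",
) -> pd.DataFrame:
    """Proportion of blastocysts accumulating >= ``threshold`` EPI cells.

    Normalized to the number of blastocysts, not the number of cells,
    because the EPI threshold matters in absolute terms. ``min_total``
    applies the >= 50-cell style filter (on cdx2+sox17+nanog) before
    counting; a group left empty by the filter is absent from the result
    rather than reported as 0/0.
    """
    if len(table) == 0:
        raise ValueError("empty count table")
    df = table.copy()
    df["total"] = df[list(LAYERS)].sum(axis=1)
    if min_total is not None:
        df = df[df["total"] >= min_total]
    out = []
    for grp_label, grp in df.groupby(group_by, sort=False):
        n = len(grp)
        if n == 0:
            continue
        k = int((grp["nanog"] >= threshold).sum())
        out.append(dict(group=grp_label, n=n, n_sufficient=k, proportion=k / n))
    if not out:
        return pd.DataFrame(
            columns=["n", "n_sufficient", "proportion"],
            index=pd.Index([], name="group"),
        )
    return pd.DataFrame(out).set_index("group")


@dataclass
class PairOutcomeSummary:
    """Complete-pair / singleton accounting of per-pair endpoints."""

    n_pairs_total: int
    n_complete: int
    n_singleton: int
    n_neither: int
    pct_singleton_among_represented: float  # 100 * singleton / (complete + singleton)

    def __post_init__(self) -> None:
        assert self.n_complete + self.n_singleton + self.n_neither == self.n_pairs_total


def pair_outcomes(records: Sequence[tuple[bool, bool]]) -> PairOutcomeSummary:
    """Tally pairs by how many members reached the endpoint.

    ``records`` holds one (member_a, member_b) boolean pair per twin pair
    (e.g. "was born" / "formed a mature egg-cylinder structure"). The
    singleton percentage is computed among represented pairs only
    (complete + singleton), i.e. pairs with at least one success.
    """
    n_complete = n_singleton = n_neither = 0
    for rec in records:
        a, b = bool(rec[0]), bool(rec[1])
        if a and b:
            n_complete += 1
        elif a or b:
            n_singleton += 1
        else:
            n_neither += 1
    represented = n_complete + n_singleton
    pct = 100.0 * n_singleton / represented if represented else float("nan")
    return PairOutcomeSummary(
        n_pairs_total=len(records),
        n_complete=n_complete,
        n_singleton=n_singleton,
        n_neither=n_neither,
        pct_singleton_among_represented=pct,
    )


def pair_concordance(records: Sequence[tuple[bool, bool]]) -> dict[str, float]:
    """Concordance/discordance fractions for maturity-style endpoints.

    Returns fractions (of all pairs) of concordant-positive (both members
    mature), discordant (exactly one), and concordant-negative pairs.
    """
    s = pair_outcomes(records)
    n = s.n_pairs_total
    if n == 0:
        raise ValueError("no pairs")
    return {
        "concordant_positive": s.n_complete / n,
        "discordant": s.n_singleton / n,
        "concordant_negative": s.n_neither / n,
        "n_pairs": n,
    }


def allocation_test(
    observed: tuple[int, int], expected_alternative: tuple[int, int]
) -> float:
    """Two-sided Fisher exact test of a 2x2 allocation table.

    Typical use: observed (complete, singleton) pair allocation against the
    (n, 0) allocation expected if every pair were totipotent in both
    members. Two-sided by summation of table probabilities <= the observed
    table's probability (the conventional definition, as implemented by
    scipy).
    """
    a, b = _check_count(observed[0], "observed[0]"), _check_count(observed[1], "observed[1]")
    c = _check_count(expected_alternative[0], "expected[0]")
    d = _check_count(expected_alternative[1], "expected[1]")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def survival_summary(n_bisected: int, n_both_survived: int) -> float:
    """Percentage of bisections in which both blastomeres survived.

    Pooled ratio, rounded to one decimal (e.g. 1584/1624 -> 97.5).
    """
    nb = _check_count(n_bisected, "n_bisected")
    ns = _check_count(n_both_survived, "n_both_survived")
    if nb == 0:
        raise ValueError("n_bisected must be positive")
    if ns > nb:
        raise ValueError("survivors cannot exceed bisections")
    return round(100.0 * ns / nb, 1)


def half_sum_vs_intact(table: pd.DataFrame) -> tuple[float, float]:
    """Convenience t-test: per-pair (twin + co-twin) total vs intact totals.

    Returns (t, p). A non-significant result supports that bisection per se
    does not change the total cell yield.
    """
    df = table.copy()
    df["total"] = df[list(LAYERS)].sum(axis=1)
    twins = df[df["member"] != "intact"]
    intact = df[df["member"] == "intact"]["total"]
    if len(intact) == 0:
        raise ValueError("table has no intact controls")
    pair_sums = twins.groupby("pair_id")["total"].sum()
    t, p = ttest_ind(pair_sums, intact, equal_var=False)
    return float(t), float(p)
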