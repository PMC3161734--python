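"""Carbon-yield statistics over elementary flux modes.

For a mode with overall equation consuming carbon sources s1..sn and
producing a target amino acid, the carbon yield is

    Y = (net target production x target carbon count)
        / sum over consumed sources of (net consumption x source carbon count)

CO2 is never counted as a source, so Y < 1 means net CO2 release during
biosynthesis and Y > 1 means net (non-photosynthetic) CO2 incorporation.

Distributions are summarised three ways: over all modes; over the modes
that survive complete knockout of the regulated reactions; and weighted,
where modes affected by the regulator keep their yields but enter the
distribution with weight w_a (default 1/10, i.e. residual night-time
activity of 10%) while unaffected modes have weight 1.  Weighted quantiles
use the weighted empirical CDF with linear interpolation, which for
w_a = 1/10 is exactly the quantile of the sample with unaffected yields
replicated tenfold.  The weighted arithmetic mean is
sum(w_i y_i) / sum(w_i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .efm import EfmSet, affected_mask, overall_equation
from .network import MetabolicNetwork

__all__ = [
    "YieldRecord",
    "YieldDistributionSummary",
    "carbon_yield",
    "yield_records",
    "weighted_quantile",
    "summarise",
    "scenario_compare",
]


@dataclass(frozen=True)
class YieldRecord:
    mode_index: int
    target: str
    yield_value: Fraction
    affected: bool
    weight: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        if self.yield_value < 0:
            raise ValueError("carbon yield cannot be negative")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must lie in (0, 1]")


@dataclass(frozen=True)
class YieldDistributionSummary:
    target: str
    scheme: str
    n_modes: int
    n_affected: int
    minimum: float | None
    q1: float | None
    median: float | None
    q3: float | None
    maximum: float | None
    mean: float | None
    weighted_mean: float | None

    @property
    def infeasible(self) -> bool:
        return self.n_modes == 0

    def __post_init__(self) -> None:
        if self.n_modes:
            order = [self.minimum, self.q1, self.median, self.q3, self.maximum]
            assert all(a <= b + 1e-12 for a, b in zip(order, order[1:]))
            assert self.minimum - 1e-12 <= self.mean <= self.maximum + 1e-12
            assert self.minimum - 1e-12 <= self.weighted_mean <= self.maximum + 1e-12


def carbon_yield(
    mode_vector: Sequence[int],
    target: str,
    net: MetabolicNetwork,
    carbon_sources: Iterable[str] | None = None,
    reaction_ids: Sequence[str] | None = None,
) -> Fraction:
    """Exact rational carbon yield of one mode for ``target``.

    Raises if the mode does not net-produce the target or consumes no
    designated carbon source (such modes are excluded upstream by target
    classification).
    """
    sources = frozenset(
        carbon_sources if carbon_sources is not None else net.config.carbon_sources
    )
    if "CO2" in sources:
        raise ValueError("CO2 is not a designated carbon source")
    carbon = {m.id: m.carbon_count for m in net.metabolites}
    ov = overall_equation(mode_vector, net, reaction_ids)
    produced = ov.get(target, Fraction(0))
    if produced <= 0:
        raise ValueError(f"mode does not net-produce {target!r}")
    denom = sum(
        (-c * carbon[s] for s in sources if (c := ov.get(s, Fraction(0))) < 0),
        Fraction(0),
    )
    if denom <= 0:
        raise ValueError("mode consumes no designated carbon source")
    return produced * carbon[target] / denom


def yield_records(
    efms: EfmSet,
    target: str,
    regulated: Iterable[str],
    carbon_sources: Iterable[str] | None = None,
    w_affected: Fraction = Fraction(1, 10),
) -> list[YieldRecord]:
    """Yield record per mode of a target-classified EFM set."""
    aff = affected_mask(efms, regulated)
    return [
        YieldRecord(
            mode_index=i,
            target=target,
            yield_value=carbon_yield(v, target, efms.network, carbon_sources, efms.reaction_ids),
            affected=bool(aff[i]),
            weight=Fraction(w_affected) if aff[i] else Fraction(1),
        )
        for i, v in enumerate(efms.vectors)
    ]


# ---------------------------------------------------------------------------
# Weighted quantiles
# ---------------------------------------------------------------------------


def weighted_quantile(
    values: Sequence[Fraction | float],
    weights: Sequence[Fraction],
    q: Fraction,
) -> Fraction:
    """Quantile of the weight-replicated empirical distribution.

    Weights are rationals; scaling them by the LCM of their denominators
    gives integer replication counts, and the quantile is the linearly
    interpolated order statistic of that replicated sample (the common
    boxplot convention), computed without materialising it.  With weights
    in {1/10, 1} this equals the quantile of the explicit 10x/1x sample.
    """
    if not values:
        raise ValueError("empty sample")
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    ws = [Fraction(w) for w in weights]
    if any(w <= 0 for w in ws):
        raise ValueError("weights must be positive")
    scale = math.lcm(*(w.denominator for w in ws))
    counts = [int(w * scale) for w in ws]
    order = sorted(range(len(values)), key=lambda i: values[i])
    total = sum(counts)
    h = Fraction(q) * (total - 1)  # 0-based fractional index, linear interpolation
    i0 = math.floor(h)
    frac = h - i0

    def value_at(idx: int) -> Fraction:
        acc = 0
        for i in order:
            acc += counts[i]
            if idx < acc:
                return Fraction(values[i])
        return Fraction(values[order[-1]])

    v0 = value_at(i0)
    if frac == 0:
        return v0
    v1 = value_at(i0 + 1)
    return v0 + frac * (v1 - v0)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_EMPTY = dict(
    minimum=None, q1=None, median=None, q3=None, maximum=None, mean=None, weighted_mean=None
)


def summarise(
    records: Sequence[YieldRecord],
    scheme: str = "all",
    w_affected: Fraction = Fraction(1, 10),
    target: str = "",
) -> YieldDistributionSummary:
    """Distribution summary under one scheme.

    ``all``      - every mode, unit weights.
    ``knockout`` - unaffected modes only (complete night-time inactivation);
                   an empty result is reported as infeasible, not an error
                   (complete knockout leaves no arginine modes at all).
    ``weighted`` - all modes; affected modes weighted ``w_affected``.
    """
    if scheme not in {"all", "knockout", "weighted"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not 0 < w_affected <= 1:
        raise ValueError("w_affected must lie in (0, 1]")
    target = target or (records[0].target if records else "")
    n_aff = sum(r.affected for r in records)
    if scheme == "knockout":
        kept = [r for r in records if not r.affected]
        if not kept:
            return YieldDistributionSummary(target, scheme, 0, 0, **_EMPTY)
        ys = [r.yield_value for r in kept]
        ws = [Fraction(1)] * len(ys)
        n, n_a = len(kept), 0
    else:
        if not records:
            raise ValueError("empty record list is only allowed for the knockout scheme")
        ys = [r.yield_value for r in records]
        if scheme == "all":
            ws = [Fraction(1)] * len(ys)
        else:
            ws = [Fraction(w_affected) if r.affected else Fraction(1) for r in records]
        n, n_a = len(records), n_aff
    mean = sum(ys, Fraction(0)) / len(ys)
    wmean = sum((w * y for w, y in zip(ws, ys)), Fraction(0)) / sum(ws)
    qs = {
        name: float(weighted_quantile(ys, ws, q))
        for name, q in [
            ("minimum", Fraction(0)),
            ("q1", Fraction(1, 4)),
            ("median", Fraction(1, 2)),
            ("q3", Fraction(3, 4)),
            ("maximum", Fraction(1)),
        ]
    }
    return YieldDistributionSummary(
        target=target,
        scheme=scheme,
        n_modes=n,
        n_affected=n_a,
        mean=float(mean),
        weighted_mean=float(wmean),
        **qs,
    )


def scenario_compare(
    efms: EfmSet,
    regulated: Iterable[str],
    targets: Sequence[str] | None = None,
    schemes: Sequence[str] = ("all", "knockout", "weighted"),
    w_affected: Fraction = Fraction(1, 10),
    carbon_sources: Iterable[str] | None = None,
) -> pd.DataFrame:
    """One row per (target, scheme), with the headline-shift flags.

    ``mean_increases`` / ``max_not_increased`` compare a scheme against the
    ``all`` scheme of the same target: the characteristic night-time
    pattern is a rising mean with a non-rising maximum.
    """
    from .efm import classify_by_target

    net = efms.network
    targets = list(targets if targets is not None else net.config.targets)
    regulated = frozenset(regulated)
    rows = []
    for target in targets:
        sub = classify_by_target(efms, target, carbon_sources)
        recs = yield_records(sub, target, regulated, carbon_sources, w_affected)
        base = summarise(recs, "all", target=target) if recs else None
        for scheme in schemes:
            if not recs:
                s = YieldDistributionSummary(target, scheme, 0, 0, **_EMPTY)
            else:
                s = summarise(recs, scheme, w_affected, target=target)
            comparison_mean = s.weighted_mean if scheme == "weighted" else s.mean
            rows.append(
                {
                    "target": target,
                    "scheme": scheme,
                    "n_modes": s.n_modes,
                    "n_affected": s.n_affected,
                    "min": s.minimum,
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "max": s.maximum,
                    "mean": s.mean,
                    "weighted_mean": s.weighted_mean,
                    "mean_increases": (
                        None
                        if s.infeasible or base is None or scheme == "all"
                        else comparison_mean > base.mean
                    ),
                    "max_not_increased": (
                        None
                        if s.infeasible or base is None or scheme == "all"
                        else s.maximum <= base.maximum + 1e-12
                    ),
                }
            )
    return pd.DataFrame(rows)
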