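"""Per-record recovery-debt computation.

The recovery debt of one outcome measure is the area between the reference
level ``x_ref`` and the trajectory connecting ``x_start`` (recovery onset,
t = 0) to ``x_end`` (t = T). The transition is interpolated either with an
exponential ``x_start * exp(r t)`` (the default, recovery processes being
typically nonlinear) or with a straight line. Expressed per annum and as a
percentage of the reference, the debt ratio is a unit-free effect size that
can be pooled across heterogeneous outcome measures.

Five geometric cases arise for the (start, end, reference) triple:

``a``  recovering from below the reference (x_start <= x_end <= x_ref)
``b``  trajectory above the reference (values above x_ref, incl. upward
       crossings; excess is treated as a deficit via the inverse transform)
``c``  declining below the reference (x_end < x_start <= x_ref)
``d``  crossing the reference downward (x_start > x_ref >= x_end)
``e``  zero reference (x_ref == 0)

Values above the reference are reflected below it with Z = x_ref**2 / value,
which caps every debt ratio at a realistic recovery threshold of 100%. Zero
endpoints or a zero reference make the logarithmic rate undefined; a small
constant, chosen among nine candidate strategies by comparing the resulting
ratio distribution against the zero-free remainder of the database
(Mann-Whitney rank-sum tests), is added before the rate is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import OutcomeMeasure

SCENARIOS = ("a", "b", "c", "d", "e")

#: additive constants used by the five fixed zero-handling strategies (1-5)
FIXED_ZERO_CONSTANTS = (0.01, 0.05, 0.1, 0.5, 1.0)

ZERO_STRATEGY_LABELS = {
    1: "constant 0.01",
    2: "constant 0.05",
    3: "constant 0.1",
    4: "constant 0.5",
    5: "constant 1",
    6: "start of same decade",
    7: "median of same decade",
    8: "start of next decade",
    9: "median of next decade",
}


class UnusableRecordError(ValueError):
    """The record cannot yield a debt (e.g. start, end and reference all zero)."""


def classify_scenario(x_start: float, x_end: float, x_ref: float) -> str:
    """Classify the (start, end, reference) triple into scenario a-e.

    ``e`` whenever the reference is zero; ``b`` whenever the end value
    exceeds the reference (both-above and upward-crossing cases, which share
    the inverse-transform treatment of the exceeding values); ``d`` when the
    trajectory crosses the reference downward; otherwise ``a`` for
    non-decreasing and ``c`` for decreasing trajectories at or below the
    reference.
    """
    for name, v in (("x_start", x_start), ("x_end", x_end), ("x_ref", x_ref)):
        if not math.isfinite(v):
            raise ValueError(f"classify_scenario: {name} must be finite, got {v!r}")
    if x_ref == 0:
        return "e"
    if x_end > x_ref:
        return "b"
    if x_start > x_ref:
        return "d"
    return "a" if x_start <= x_end else "c"


def inverse_transform(value: float, x_ref: float) -> float:
    """Reflect a value above the reference to its equivalent deficit below.

    Returns ``x_ref**2 / value``: a multiplicative reflection about the
    reference with fixed point at ``value == x_ref``. Bounded below the
    reference exactly when the input exceeds it, so transformed records can
    never show more than a 100% deficit.
    """
    if value <= 0:
        raise ValueError("inverse_transform: value must be > 0 (apply zero handling first)")
    if x_ref <= 0:
        raise ValueError("inverse_transform: x_ref must be > 0")
    return x_ref * x_ref / value


def zero_constant(
    x_start: float, x_end: float, x_ref: float, strategy: int
) -> float:
    """Additive constant for zero-affected records under one of 9 strategies.

    Strategies 1-5 are the fixed constants 0.01, 0.05, 0.1, 0.5 and 1.
    Strategies 6-9 scale with the record: with m = max(|x_start|, |x_end|)
    (falling back to |x_ref| when both endpoints are zero) and m lying in the
    decade [10**k, 10**(k+1)), they return the start of that decade (6), its
    median 5*10**k (7), the start of the next decade up (8), or its median
    (9). E.g. m = 0.81 gives 0.1, 0.5, 1 and 5.
    """
    if strategy not in range(1, 10):
        raise ValueError(f"zero_constant: strategy must be in 1..9, got {strategy}")
    if strategy <= 5:
        return FIXED_ZERO_CONSTANTS[strategy - 1]
    m = max(abs(x_start), abs(x_end))
    if m == 0:
        m = abs(x_ref)
    if m == 0:
        raise UnusableRecordError("zero_constant: x_start, x_end and x_ref are all zero")
    k = math.floor(math.log10(m))
    return {6: 10.0**k, 7: 5 * 10.0**k, 8: 10.0 ** (k + 1), 9: 5 * 10.0 ** (k + 1)}[strategy]


@dataclass
class DebtResult:
    """The recovery debt of a single outcome measure."""

    scenario: str  # classification of the raw triple
    r: float  # exponential rate (1/years); 0 for flat or linear-only fits
    auc: float  # area under the (transformed) trajectory, metric-units * years
    rd_total: float  # x_ref*T - AUC, metric-units * years
    rd_per_annum: float  # rd_total / T, metric units
    ratio_pct: float  # 100 * per-annum debt / |reference|, in [0, 100]
    method: str  # "exponential" | "linear"
    transformed: bool  # inverse transform applied to >= 1 value
    zero_constant: Optional[float] = None  # additive constant used, if any
    flags: tuple[str, ...] = ()


def debt_ratio(rd_per_annum: float, x_ref: float) -> float:
    """Homogenize a per-annum debt to a percentage of the reference.

    ``100 * RDt / |x_ref|`` while the debt does not exceed the reference;
    when it does (RDt > |x_ref|) the same reflection principle used for
    values above the reference is applied, ``100 * |x_ref| / RDt``, keeping
    the ratio within the 100% threshold (both branches agree at the
    boundary). A negative per-annum debt clamps to 0.
    """
    if x_ref == 0:
        raise ValueError("debt_ratio: x_ref must be nonzero after preprocessing")
    a = abs(x_ref)
    if rd_per_annum < 0:
        return 0.0
    if rd_per_annum <= a:
        return 100.0 * rd_per_annum / a
    return 100.0 * a / rd_per_annum


def _preprocess(
    x_start: float, x_end: float, x_ref: float, c: Optional[float]
) -> tuple[float, float, float, str, bool, Optional[float], list[str]]:
    """Shared scenario/transform/zero pipeline for both interpolation methods.

    Returns the working triple (x_start', x_end', x_ref'), the raw-triple
    scenario label, the transformed flag, the constant actually used, and
    processing flags.
    """
    flags: list[str] = []
    scenario = classify_scenario(x_start, x_end, x_ref)
    used_c: Optional[float] = None

    if x_ref == 0:
        if x_start == 0 and x_end == 0:
            raise UnusableRecordError("x_start, x_end and x_ref are all zero")
        if c is None:
            raise UnusableRecordError("x_ref == 0 requires a zero-handling constant")
        x_start, x_end, x_ref = x_start + c, x_end + c, x_ref + c
        used_c = c
        flags.append("zero_ref_adjusted")

    transformed = False
    if x_ref > 0:
        if x_start <= x_ref < x_end:
            flags.append("upward_crossing")
        if x_start > x_ref:
            if x_start <= 0:  # cannot happen with x_ref > 0; defensive
                raise UnusableRecordError("nonpositive value above positive reference")
            x_start = inverse_transform(x_start, x_ref)
            transformed = True
        if x_end > x_ref:
            x_end = inverse_transform(x_end, x_ref)
            transformed = True
    else:
        flags.append("negative_reference")

    if x_start == 0 or x_end == 0:
        if c is None:
            raise UnusableRecordError("zero endpoint requires a zero-handling constant")
        x_start, x_end = x_start + c, x_end + c
        used_c = c
        flags.append("zero_endpoint_adjusted")

    return x_start, x_end, x_ref, scenario, transformed, used_c, flags


def exponential_debt(rec: OutcomeMeasure, c: Optional[float] = None) -> DebtResult:
    """Recovery debt of one record under exponential interpolation.

    The trajectory ``x_start' * exp(r t)`` with ``r = ln(x_end'/x_start')/T``
    passes through both (transformed) endpoints; its area over (0, T) is the
    closed form ``(x_end' - x_start') * T / ln(x_end'/x_start')`` (the
    logarithmic mean times T), with the limit ``x_start' * T`` for a flat
    trajectory. Declining trajectories simply give r < 0. If the working
    endpoints have opposite signs the logarithm is undefined and the linear
    formula is used instead (flagged).
    """
    xs, xe, xr, scenario, transformed, used_c, flags = _preprocess(
        rec.x_start, rec.x_end, rec.x_ref, c
    )
    T = rec.t_years
    if xs == xe:
        r, auc = 0.0, xs * T
        method = "exponential"
    elif xs * xe <= 0:
        flags.append("linear_fallback")
        r, auc = 0.0, (xs + xe) * T / 2.0
        method = "linear"
    else:
        r = math.log(xe / xs) / T
        auc = (xe - xs) * T / math.log(xe / xs)
        method = "exponential"
    rd = xr * T - auc
    rdt = rd / T
    ratio = debt_ratio(rdt, xr)
    if rdt < 0:
        flags.append("negative_debt_clamped")
    return DebtResult(
        scenario=scenario,
        r=r,
        auc=auc,
        rd_total=rd,
        rd_per_annum=rdt,
        ratio_pct=ratio,
        method=method,
        transformed=transformed,
        zero_constant=used_c,
        flags=tuple(flags),
    )


def linear_debt(rec: OutcomeMeasure, c: Optional[float] = None) -> DebtResult:
    """Recovery debt of one record under linear interpolation.

    Identical preprocessing (scenario classification, inverse transform,
    zero handling); the trajectory area is the trapezoid
    ``(x_start' + x_end') * T / 2``, so the per-annum debt is the reference
    minus the endpoint mean.
    """
    xs, xe, xr, scenario, transformed, used_c, flags = _preprocess(
        rec.x_start, rec.x_end, rec.x_ref, c
    )
    T = rec.t_years
    auc = (xs + xe) * T / 2.0
    rd = xr * T - auc
    rdt = rd / T
    ratio = debt_ratio(rdt, xr)
    if rdt < 0:
        flags.append("negative_debt_clamped")
    return DebtResult(
        scenario=scenario,
        r=0.0,
        auc=auc,
        rd_total=rd,
        rd_per_annum=rdt,
        ratio_pct=ratio,
        method="linear",
        transformed=transformed,
        zero_constant=used_c,
        flags=tuple(flags),
    )


def is_zero_affected(rec: OutcomeMeasure) -> bool:
    """True if the record needs a zero-handling constant (any of the triple is 0)."""
    return rec.x_ref == 0 or rec.x_start == 0 or rec.x_end == 0


def compute_debt(
    rec: OutcomeMeasure, method: str = "exponential", strategy: Optional[int] = None
) -> DebtResult:
    """Compute one record's debt, deriving the zero constant if needed."""
    c = None
    if is_zero_affected(rec):
        if strategy is None:
            raise UnusableRecordError(
                "record has zero values; a zero-handling strategy is required"
            )
        c = zero_constant(rec.x_start, rec.x_end, rec.x_ref, strategy)
    fn = exponential_debt if method == "exponential" else linear_debt
    return fn(rec, c)


@dataclass
class StrategyEntry:
    strategy: int
    label: str
    p_value: float
    selected: bool


@dataclass
class StrategyReport:
    """Mann-Whitney comparison of each zero-handling strategy vs the zero-free pool."""

    entries: list[StrategyEntry]
    n_zero_affected: int
    n_unaffected: int
    none_passed: bool = False

    @property
    def selected_strategy(self) -> int:
        return next(e.strategy for e in self.entries if e.selected)


def select_zero_strategy(
    records: Iterable[OutcomeMeasure], method: str = "exponential"
) -> StrategyReport:
    """Pick the zero-handling strategy whose ratios match the zero-free pool.

    For each of the nine strategies, the debt ratios of the zero-affected
    records (computed with that strategy's constant) are compared with the
    ratios of the unaffected records (computed with no constant) by a
    two-sided Mann-Whitney rank-sum test. The selected strategy is the one
    whose distribution is not distinguishable from the rest of the database
    (p > 0.05; ties broken by the largest p). If no strategy passes, the
    largest-p strategy is selected and the report is flagged.
    """
    recs = list(records)
    zero = [r for r in recs if is_zero_affected(r) and not (r.x_start == r.x_end == r.x_ref == 0)]
    clean = [r for r in recs if not is_zero_affected(r)]
    if not zero:
        raise ValueError("select_zero_strategy: no zero-affected records")
    if len(clean) < 20:
        raise ValueError(
            f"select_zero_strategy: need >= 20 unaffected records, got {len(clean)}"
        )
    ref_ratios = np.array([compute_debt(r, method).ratio_pct for r in clean])
    entries: list[StrategyEntry] = []
    for s in range(1, 10):
        ratios = np.array([compute_debt(r, method, strategy=s).ratio_pct for r in zero])
        p = mann_whitney_p(ratios, ref_ratios)
        entries.append(StrategyEntry(strategy=s, label=ZERO_STRATEGY_LABELS[s], p_value=p, selected=False))
    passing = [e for e in entries if e.p_value > 0.05]
    pool = passing if passing else entries
    best = max(pool, key=lambda e: e.p_value)
    best.selected = True
    return StrategyReport(
        entries=entries,
        n_zero_affected=len(zero),
        n_unaffected=len(clean),
        none_passed=not passing,
    )


def mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact enumeration for small untied samples (both n <= 20); otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 20 and len(y) <= 20
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


class RecoveryDebt:
    """Estimator computing debt-ratio effect sizes from outcome measures.

    scikit-learn-style: ``fit`` learns the zero-handling strategy from the
    database (unless one is fixed via ``zero_strategy``), ``transform`` maps
    records to a per-record result table.

    Parameters
    ----------
    method : {"exponential", "linear"}
        Interpolation used between the start and end values.
    zero_strategy : int in 1..9, optional
        Fix the zero-handling strategy instead of selecting it from data.

    Attributes
    ----------
    strategy_report_ : StrategyReport or None
        The per-strategy Mann-Whitney report (None when fixed or no zeros).
    zero_strategy_ : int or None
        The strategy applied to zero-affected records.
    """

    def __init__(self, method: str = "exponential", zero_strategy: Optional[int] = None):
        self.method = method
        self.zero_strategy = zero_strategy

    # minimal get/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {"method": self.method, "zero_strategy": self.zero_strategy}

    def set_params(self, **params) -> "RecoveryDebt":
        for k, v in params.items():
            if k not in ("method", "zero_strategy"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, records: Sequence[OutcomeMeasure], y=None) -> "RecoveryDebt":
        if self.method not in ("exponential", "linear"):
            raise ValueError(f"method must be 'exponential' or 'linear', got {self.method!r}")
        if self.zero_strategy is not None:
            self.zero_strategy_ = self.zero_strategy
            self.strategy_report_ = None
        elif any(is_zero_affected(r) for r in records):
            self.strategy_report_ = select_zero_strategy(records, self.method)
            self.zero_strategy_ = self.strategy_report_.selected_strategy
        else:
            self.strategy_report_ = None
            self.zero_strategy_ = None
        return self

    def transform(self, records: Sequence[OutcomeMeasure]) -> pd.DataFrame:
        """Per-record result table; unusable records appear with a flag and NaNs."""
        if not hasattr(self, "zero_strategy_"):
            raise RuntimeError("RecoveryDebt is not fitted; call fit first")
        rows = []
        for rec in records:
            base = {
                "outcome_id": rec.outcome_id,
                "study_id": rec.study_id,
                "metric": rec.metric,
                "submetric": rec.submetric,
                "ecosystem": rec.ecosystem,
                "disturbance": rec.disturbance,
                "t_years": rec.t_years,
                "variance": rec.variance,
            }
            try:
                res = compute_debt(rec, self.method, self.zero_strategy_)
            except UnusableRecordError as e:
                rows.append(
                    {
                        **base,
                        "scenario": None,
                        "method": None,
                        "transformed": False,
                        "zero_constant": None,
                        "r": np.nan,
                        "auc": np.nan,
                        "rd_per_annum": np.nan,
                        "ratio_pct": np.nan,
                        "flags": f"unusable: {e}",
                    }
                )
                continue
            rows.append(
                {
                    **base,
                    "scenario": res.scenario,
                    "method": res.method,
                    "transformed": res.transformed,
                    "zero_constant": res.zero_constant,
                    "r": res.r,
                    "auc": res.auc,
                    "rd_per_annum": res.rd_per_annum,
                    "ratio_pct": res.ratio_pct,
                    "flags": ";".join(res.flags),
                }
            )
        return pd.DataFrame(rows)

    def fit_transform(self, records: Sequence[OutcomeMeasure], y=None) -> pd.DataFrame:
        return self.fit(records).transform(records)
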