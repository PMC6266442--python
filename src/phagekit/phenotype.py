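"""Host-range spot-test scoring and one-step growth-curve statistics.

Spot tests score a strain by the deepest serial dilution (10^0, 10^-2,
10^-4, 10^-6) still showing lysis: "-" (none), "+" (10^0 only — often
lysis from without, i.e. clearing without productive infection), "++"
(to 10^-2), "+++" (to 10^-4), "++++" (to 10^-6). By default a strain
counts as *infected* only at "++" or better, excluding lysis from without.

One-step growth curves are summarized by the burst size, (final titer -
initial titer) / initial titer, and the latent period, operationalized as
the midpoint of the exponential rise: a 4-parameter logistic is fitted to
log10 titer versus time and its inflection time is reported. Between-
temperature differences are assessed by one-way ANOVA with Tukey's HSD
(Tukey-Kramer at unequal group sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DILUTION_LADDER",
    "SCORE_ORDER",
    "SpotTestRecord",
    "GrowthCurve",
    "BurstEstimate",
    "NoRiseError",
    "score_spot_test",
    "count_infected",
    "burst_size",
    "fit_log_logistic",
    "latent_period",
    "estimate_burst",
    "one_way_anova",
    "tukey_hsd",
    "q_critical",
    "read_spot_csv",
    "read_growth_csv",
]

DILUTION_LADDER = (0, -2, -4, -6)  # log10 dilution exponents tested
SCORE_ORDER = ("-", "+", "++", "+++", "++++")


class NoRiseError(ValueError):
    """Growth curve shows no titer rise; latent period undefined."""


def score_spot_test(infective: Sequence[bool]) -> str:
    """Symbolic spot score from per-dilution infectivity on the 4-step ladder.

    A non-contiguous pattern (e.g. lysis at 10^-4 but not 10^0) is
    biologically inconsistent; it is scored by the deepest infective
    dilution and a warning is emitted.
    """
    if len(infective) != len(DILUTION_LADDER):
        raise ValueError(f"expected {len(DILUTION_LADDER)} dilutions, got {len(infective)}")
    infective = [bool(x) for x in infective]
    if not any(infective):
        return "-"
    deepest = max(i for i, x in enumerate(infective) if x)
    if not all(infective[: deepest + 1]):
        warnings.warn(
            "non-contiguous spot pattern; scoring by deepest infective dilution",
            UserWarning,
            stacklevel=2,
        )
    return SCORE_ORDER[deepest + 1]


@dataclass
class SpotTestRecord:
    """Per-strain infectivity over the tested dilution ladder."""

    strain_id: str
    pathogenic: bool
    infective: tuple[bool, bool, bool, bool]
    score: str = field(init=False)

    def __post_init__(self):
        self.infective = tuple(bool(x) for x in self.infective)
        self.score = score_spot_test(self.infective)

    @classmethod
    def from_score(cls, strain_id: str, pathogenic: bool, score: str) -> "SpotTestRecord":
        if score not in SCORE_ORDER:
            raise ValueError(f"unknown score symbol {score!r}")
        depth = SCORE_ORDER.index(score)
        return cls(strain_id, pathogenic, tuple(i < depth for i in range(4)))


def count_infected(
    records: Iterable[SpotTestRecord], min_score: str = "++"
) -> tuple[int, int, int]:
    """(total, pathogenic, non-pathogenic) strains at or above ``min_score``.

    The default excludes "+" so that lysis from without does not count
    as infection.
    """
    if min_score not in SCORE_ORDER:
        raise ValueError(f"unknown score symbol {min_score!r}")
    floor = SCORE_ORDER.index(min_score)
    hit = [r for r in records if SCORE_ORDER.index(r.score) >= floor]
    pathogenic = sum(r.pathogenic for r in hit)
    return len(hit), pathogenic, len(hit) - pathogenic


@dataclass
class GrowthCurve:
    """Replicated (time, titer) series at one temperature."""

    temperature_C: float
    moi: float
    times_min: np.ndarray
    titers: np.ndarray  # shape (replicates, timepoints), PFU/mL

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.titers = np.atleast_2d(np.asarray(self.titers, dtype=float))
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.titers.shape[1] != self.times_min.size:
            raise ValueError("titer columns must match the time grid")
        if np.any(self.titers <= 0):
            raise ValueError("titers must be positive")

    @property
    def replicates(self) -> int:
        return self.titers.shape[0]


@dataclass(frozen=True)
class BurstEstimate:
    burst_size: float
    latent_period_min: float
    burst_sd: float  # dispersion across replicates
    latent_sd: float


def burst_size(initial_titer: float, final_titer: float) -> float:
    """(final - initial) / initial: new virions per infected cell."""
    if initial_titer <= 0:
        raise ValueError("initial titer must be positive")
    return (final_titer - initial_titer) / initial_titer


def _logistic(t, a, c, m, s):
    return a + c / (1.0 + np.exp(-(t - m) / s))


def fit_log_logistic(times: np.ndarray, titers: np.ndarray):
    """Fit log10 titer = a + c/(1+exp(-(t-m)/s)); returns (a, c, m, s).

    ``m`` is the inflection (midpoint) time; 10**a and 10**(a+c) are the
    pre- and post-rise plateaus.
    """
    y = np.log10(np.asarray(titers, dtype=float))
    t = np.asarray(times, dtype=float)
    rise = y.max() - y.min()
    if rise < 0.3:  # less than a 2x rise: nothing to fit
        raise NoRiseError("titer rise below 0.3 log10; no burst detected")
    half = y.min() + rise / 2.0
    above = np.nonzero(y >= half)[0]
    m0 = t[above[0]] if above.size else t[t.size // 2]
    p0 = [y.min(), rise, m0, max((t[-1] - t[0]) / 20.0, 1.0)]
    bounds = (
        [y.min() - 2.0, 0.05, t[0], 0.05],
        [y.max() + 2.0, 2.0 * rise + 1.0, t[-1], (t[-1] - t[0])],
    )
    try:
        popt, _ = optimize.curve_fit(
            _logistic, t, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"logistic fit failed to converge: {exc}") from exc
    return tuple(popt)


def latent_period(curve: GrowthCurve, method: str = "midpoint") -> float:
    """Latent period in minutes: middle of the exponential rise.

    ``method='midpoint'`` (default) returns the logistic inflection time of
    the replicate-mean curve; ``method='departure'`` returns the first
    sampling time whose fitted lysed fraction exceeds 5% of the rise.
    """
    mean_titer = curve.titers.mean(axis=0)
    a, c, m, s = fit_log_logistic(curve.times_min, mean_titer)
    if method == "midpoint":
        return float(m)
    if method == "departure":
        frac = 1.0 / (1.0 + np.exp(-(curve.times_min - m) / s))
        idx = np.nonzero(frac > 0.05)[0]
        return float(curve.times_min[idx[0]]) if idx.size else float(m)
    raise ValueError(f"unknown latent-period method {method!r}")


def estimate_burst(curve: GrowthCurve, endpoints: str = "plateau") -> BurstEstimate:
    """Burst size and latent period with replicate dispersion.

    ``endpoints='plateau'`` averages observed titers at times where the
    fitted titer sits within 5% of the lower/upper plateau;
    ``endpoints='single'`` uses the first and last sampling points,
    matching the simplest reading of "initial titer" and "final titer".
    """
    bursts, latents = [], []
    for rep in curve.titers:
        a, c, m, s = fit_log_logistic(curve.times_min, rep)
        yfit = _logistic(curve.times_min, a, c, m, s)
        if endpoints == "plateau":
            # plateau membership judged in titer space: fitted titer within
            # 5% of the relevant plateau
            pre = rep[yfit - a < np.log10(1.05)]
            post = rep[(a + c) - yfit < -np.log10(0.95)]
            initial = pre.mean() if pre.size else rep[0]
            final = post.mean() if post.size else rep[-1]
        elif endpoints == "single":
            initial, final = rep[0], rep[-1]
        else:
            raise ValueError(f"unknown endpoints mode {endpoints!r}")
        bursts.append(burst_size(initial, final))
        latents.append(m)
    bursts = np.asarray(bursts)
    latents = np.asarray(latents)
    ddof = 1 if len(bursts) > 1 else 0
    return BurstEstimate(
        burst_size=float(bursts.mean()),
        latent_period_min=float(latents.mean()),
        burst_sd=float(bursts.std(ddof=ddof)),
        latent_sd=float(latents.std(ddof=ddof)),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0  # no variation at all: zero signal
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance; F undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def tukey_hsd(
    groups: Sequence[Sequence[float]], alpha: float = 0.01
) -> pd.DataFrame:
    """All pairwise comparisons by Tukey's HSD (studentized range).

    Returns a frame with group indices, mean difference, adjusted p-value,
    and a significance flag at ``alpha``. Unequal group sizes use the
    Tukey-Kramer standard error.
    """
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": i,
                    "group_b": j,
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                    "significant": bool(res.pvalue[i, j] < alpha),
                }
            )
    return pd.DataFrame(rows)


def q_critical(k: int, df: int, alpha: float = 0.01) -> float:
    """Upper critical value of the studentized range distribution."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def read_spot_csv(path) -> list[SpotTestRecord]:
    """Read a spot-test CSV: strain_id, pathogenic, d0, d2, d4, d6."""
    df = pd.read_csv(path)
    required = ["strain_id", "pathogenic", "d0", "d2", "d4", "d6"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spot CSV missing columns: {missing}")
    return [
        SpotTestRecord(
            strain_id=str(r.strain_id),
            pathogenic=bool(r.pathogenic),
            infective=(bool(r.d0), bool(r.d2), bool(r.d4), bool(r.d6)),
        )
        for r in df.itertuples()
    ]


def read_growth_csv(path) -> list[GrowthCurve]:
    """Read growth CSV (temperature_C, replicate, time_min, titer_pfu_per_ml)."""
    df = pd.read_csv(path)
    required = ["temperature_C", "replicate", "time_min", "titer_pfu_per_ml"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"growth CSV missing columns: {missing}")
    curves = []
    for temp, sub in df.groupby("temperature_C"):
        piv = sub.pivot_table(
            index="replicate", columns="time_min", values="titer_pfu_per_ml"
        ).sort_index(axis=1)
        curves.append(
            GrowthCurve(
                temperature_C=float(temp),
                moi=float(sub["moi"].iloc[0]) if "moi" in sub else float("nan"),
                times_min=piv.columns.to_numpy(dtype=float),
                titers=piv.to_numpy(dtype=float),
            )
        )
    return curves
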