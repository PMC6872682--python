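"""Statistical layer of the study.

Descriptive angle tables by jaw and tooth category, Bland-Altman 95%
limits of agreement for repeatability, the tie-corrected Kruskal-Wallis
rank test, and the a-priori sample-size calculation for detecting a mean
paired difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DescriptiveRow",
    "LoAResult",
    "KruskalWallisResult",
    "SampleSizeSpec",
    "descriptive_by_category",
    "descriptive_table",
    "limits_of_agreement",
    "kruskal_wallis",
    "sample_size_mean_difference",
]

_TYPE_NAMES = {1: "central incisor", 2: "lateral incisor", 3: "canine"}
_JAW_NAMES = {1: "maxilla", 2: "mandible"}


@dataclass(frozen=True)
class DescriptiveRow:
    """One group row: n, mean (SD), median (range), all in degrees."""

    label: str
    n: int
    mean: float
    sd: float | None  # None when n < 2
    median: float
    min: float
    max: float

    def display(self) -> str:
        """Mean (SD) and median (range) formatted as in the study table
        (mean/median/range to 1 dp, SD to 2 dp)."""
        sd = "NA" if self.sd is None else f"{self.sd:.2f}"
        return (
            f"{self.label}: n={self.n} {self.mean:.1f} ({sd}) "
            f"{self.median:.1f} ({self.min:.1f} to {self.max:.1f})"
        )


@dataclass(frozen=True)
class LoAResult:
    """Bland-Altman agreement interval: mean difference +/- z * SD."""

    mean_diff: float
    sd_diff: float
    lower: float
    upper: float
    z: float


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float  # tie-corrected statistic
    df: int
    p_value: float
    method: str = "chi2"


@dataclass(frozen=True)
class SampleSizeSpec:
    alpha: float
    power: float
    sd: float
    delta: float
    n: int


def _one_group(values: np.ndarray, label: str) -> DescriptiveRow:
    v = np.asarray(values, float)
    return DescriptiveRow(
        label=label,
        n=len(v),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if len(v) >= 2 else None,
        median=float(np.median(v)),
        min=float(v.min()),
        max=float(v.max()),
    )


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table
    else:  # StudyTable
        df = table.to_dataframe()
    df = df[np.isfinite(df["angle_deg"])]
    if df.empty:
        raise ValueError("no finite angle values to summarise")
    return df


def descriptive_by_category(table, grouping: str = "jaw_type") -> list[DescriptiveRow]:
    """Descriptive statistics of the discrepancy angle per group.

    ``grouping``: ``'jaw_type'`` (jaw x tooth-type cells), ``'jaw'``
    (all teeth of each jaw) or ``'overall'``. Sample SD uses the n-1
    denominator; the median uses the midpoint convention for even n.
    Empty groups are omitted with a warning.
    """
    df = _as_frame(table)
    rows: list[DescriptiveRow] = []
    if grouping == "overall":
        return [_one_group(df["angle_deg"].to_numpy(), "overall")]
    if grouping == "jaw":
        keys = [(j,) for j in (1, 2)]
        get = lambda j: df[df.jaw == j]  # noqa: E731
        name = lambda j: _JAW_NAMES[j]  # noqa: E731
    elif grouping == "jaw_type":
        keys = [(j, t) for j in (1, 2) for t in (1, 2, 3)]
        get = lambda j, t: df[(df.jaw == j) & (df.tooth_type == t)]  # noqa: E731
        name = lambda j, t: f"{_JAW_NAMES[j]} {_TYPE_NAMES[t]}"  # noqa: E731
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    for key in keys:
        sub = get(*key)
        if sub.empty:
            warnings.warn(f"empty group {name(*key)!r} omitted", stacklevel=2)
            continue
        rows.append(_one_group(sub["angle_deg"].to_numpy(), name(*key)))
    return rows


def descriptive_table(table) -> list[DescriptiveRow]:
    """Full study layout: jaw x type cells, per-jaw totals, overall."""
    rows = descriptive_by_category(table, "jaw_type")
    rows += descriptive_by_category(table, "jaw")
    rows += descriptive_by_category(table, "overall")
    return rows


def limits_of_agreement(diffs, z: float = 1.959964) -> LoAResult:
    """Bland-Altman 95% limits of agreement of paired differences.

    mean +/- z * SD with the n-1 sample SD; z defaults to the two-sided
    95% normal quantile.
    """
    d = np.asarray(diffs, float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return LoAResult(mean, sd, mean - z * sd, mean + z * sd, z)


def kruskal_wallis(
    groups,
    method: str = "chi2",
    n_permutations: int = 10000,
    seed: int = 0,
) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis rank test across k groups.

    Midranks are assigned over the pooled sample; the statistic
    ``H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2`` is divided by the
    tie-correction factor ``1 - sum(t^3 - t)/(N^3 - N)``. The p-value
    comes from the chi-square approximation with k-1 degrees of freedom,
    or from a label-permutation null when ``method='permutation'``
    (recommended for very small groups).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise ValueError("need at least 3 values in total")
    if np.all(pooled == pooled[0]):
        raise ValueError("all values tied: statistic undefined")
    sizes = np.array([len(g) for g in groups])

    def statistic(values: np.ndarray) -> float:
        ranks = sps.rankdata(values)  # midranks
        N = len(values)
        start = 0
        H = 0.0
        for n_i in sizes:
            r = ranks[start : start + n_i]
            H += n_i * (r.mean() - (N + 1) / 2.0) ** 2
            start += n_i
        H *= 12.0 / (N * (N + 1))
        _, counts = np.unique(values, return_counts=True)
        correction = 1.0 - float(((counts**3 - counts).sum()) / (N**3 - N))
        return H / correction

    H = statistic(pooled)
    df = len(groups) - 1
    if method == "chi2":
        p = float(sps.chi2.sf(H, df))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            if statistic(rng.permutation(pooled)) >= H - 1e-12:
                count += 1
        p = (1.0 + count) / (1.0 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KruskalWallisResult(float(H), int(df), p, method)


def sample_size_mean_difference(
    alpha: float, power: float, sd: float, delta: float
) -> int:
    """Minimum n to detect a mean paired difference ``delta``.

    One-sample (paired-difference) normal-approximation formula
    ``n = ceil(((z_{1-alpha/2} + z_{power}) * sd / delta)^2)`` with a
    floor of 2.
    """
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    if sd <= 0 or delta <= 0:
        raise ValueError("sd and delta must be positive")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    n = math.ceil(((z_a + z_b) * sd / delta) ** 2)
    return max(int(n), 2)
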