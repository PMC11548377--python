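"""Relating vegetation coverage to environmental drivers.

Three pieces of machinery:

* ordinary least-squares fits of coverage against a driver (TP, TN,
  Z_M/Z_SD, water level), with R-squared and the two-sided t-test p-value
  on the slope;
* the underwater-light proxy Z_M/Z_SD (water depth over Secchi depth) and a
  disappearance flag — submerged vegetation is suppressed when the ratio
  exceeds a threshold (default 5.17 in this study's lake);
* a seasonal group comparison (mean +/- sd per season, pairwise Welch
  tests with Holm correction, compact letter display at alpha = 0.05),
  used e.g. for the TP contrast between seasons with and without submerged
  vegetation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnvRecord",
    "FitResult",
    "linear_fit",
    "zm_zsd_ratio",
    "flag_light_limitation",
    "seasonal_compare",
    "SAV_DISAPPEARANCE_RATIO",
]

#: Z_M/Z_SD above which submerged vegetation disappeared in this study
SAV_DISAPPEARANCE_RATIO = 5.17


@dataclass
class EnvRecord:
    """One dated water-quality observation.

    Concentrations in mg/L, depths in m.  Z_M >= Z_SD is deliberately not
    required: in turbid shallow water the Secchi disk may reach the bottom
    (Z_SD read as >= Z_M); values are stored as measured.
    """

    date: pd.Timestamp
    season: str
    TP: float
    TN: float
    Z_M: float
    Z_SD: float
    NH3N: float | None = None
    water_level: float | None = None

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        for name in ("TP", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be >= 0")
        if self.NH3N is not None and self.NH3N < 0:
            raise ValueError("NH3N concentration must be >= 0")


@dataclass
class FitResult:
    """OLS fit of y on x with inference on the slope."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t, n-2 df)."""
        t = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - t * self.stderr, self.slope + t * self.stderr)

    def significance(self) -> str:
        """Star convention: ** for p<0.01, * for p<0.05, ns otherwise."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "stderr": self.stderr,
        }


def linear_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Least-squares line y = a + b*x with R^2 and two-sided p for b != 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points for a fit with inference, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope is undefined (degenerate fit)")
    res = stats.linregress(x, y)
    # constant y: zero slope explains everything there is to explain — by
    # convention R^2 = 0 (no variance) and the slope test is uninformative
    if np.ptp(y) == 0:
        return FitResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                         p_value=1.0, n=len(x), stderr=0.0)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
        stderr=float(res.stderr),
    )


def zm_zsd_ratio(z_m: "float | EnvRecord", z_sd: float | None = None) -> float:
    """Water depth over Secchi depth — the underwater light-climate proxy.

    Accepts either an :class:`EnvRecord` or the two depths in metres.
    """
    if isinstance(z_m, EnvRecord):
        z_m, z_sd = z_m.Z_M, z_m.Z_SD
    if z_sd is None:
        raise TypeError("pass an EnvRecord or both z_m and z_sd")
    if z_sd <= 0:
        raise ValueError(f"Secchi depth must be positive, got {z_sd}")
    return z_m / z_sd


def flag_light_limitation(ratio: float, threshold: float = SAV_DISAPPEARANCE_RATIO) -> bool:
    """True when the light climate is beyond the SAV-disappearance point.

    Strict inequality: a ratio exactly at the threshold is not flagged.
    """
    if not np.isfinite(ratio):
        raise ValueError(f"ratio must be finite, got {ratio}")
    return ratio > threshold


def _compact_letter_display(
    groups: list[str], differ: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing no letter are exactly the pairs in ``differ``;
    non-differing pairs share at least one letter.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in differ:
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            sa, sb = s - {b}, s - {a}
            for t in (sa, sb):
                if not any(t <= u for u in letter_sets):
                    letter_sets.append(t)
    # deterministic ordering: by first group member's position
    order = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def seasonal_compare(
    values: pd.DataFrame,
    variable: str,
    group: str = "season",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group mean +/- sd with significance letters.

    Pairwise Welch two-sample t-tests, Holm-corrected across all pairs;
    two groups get distinct letters iff they differ at ``alpha`` after
    correction.  Groups with fewer than 2 observations are summarised but
    carry no letter.  Requires at least two testable groups.
    """
    from statsmodels.stats.multitest import multipletests

    if variable not in values.columns or group not in values.columns:
        raise ValueError(f"need columns {variable!r} and {group!r}")
    data = values[[group, variable]].dropna()
    names = list(dict.fromkeys(data[group]))  # first-appearance order
    samples = {g: data.loc[data[group] == g, variable].to_numpy(float) for g in names}
    testable = [g for g in names if len(samples[g]) >= 2]

    differ: set[tuple[str, str]] = set()
    if len(testable) >= 2:
        pairs = list(itertools.combinations(testable, 2))
        pvals = [
            stats.ttest_ind(samples[a], samples[b], equal_var=False).pvalue
            for a, b in pairs
        ]
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
        differ = {pair for pair, r in zip(pairs, reject) if r}
    letters = _compact_letter_display(testable, differ) if len(testable) >= 2 else {}

    rows = []
    for g in names:
        v = samples[g]
        rows.append(
            {
                group: g,
                "n": len(v),
                "mean": float(v.mean()) if len(v) else np.nan,
                "sd": float(v.std(ddof=1)) if len(v) >= 2 else np.nan,
                "letters": letters.get(g, ""),
            }
        )
    return pd.DataFrame(rows)
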