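"""Population statistics: Pearson correlation, OLS regression, one-way
ANOVA with Bonferroni post-hoc tests against the control group.

The statistics are computed from their closed forms — r as the sample
covariance over the product of sample standard deviations (the n vs n−1
convention cancels), F as the between/within mean-square ratio — with
scipy supplying only the F and t distribution tails.  Undefined results
(constant inputs, degenerate denominators) propagate as explicit ``None``
flags, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CHANNEL_A, CHANNEL_B, CYTOPLASM, NUCLEUS


@dataclass
class PairedSample:
    """Matched per-cell values of the two channels for one condition/compartment."""

    x: np.ndarray
    y: np.ndarray
    condition: str = ""
    compartment: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be matched 1D arrays")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("paired sample contains non-finite values")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float | None     # None when SS_tot = 0 (constant y)
    n: int


@dataclass
class AnovaResult:
    f: float | None             # None when all values identical (0/0)
    p: float | None
    df_between: int
    df_within: int
    group_means: dict[str, float] = field(default_factory=dict)
    group_sizes: dict[str, int] = field(default_factory=dict)


def pearson_r(sample: PairedSample) -> float | None:
    """Pearson correlation coefficient; ``None`` when x or y is constant."""
    if sample.n < 2:
        raise ValueError("correlation needs n ≥ 2")
    x, y = sample.x, sample.y
    dx, dy = x - x.mean(), y - y.mean()
    sxx, syy = float(dx @ dx), float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return None
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def linear_fit(sample: PairedSample) -> RegressionResult:
    """Ordinary least squares y = slope·x + intercept.

    ``r_squared = 1 − SS_res/SS_tot``; flagged ``None`` when y is
    constant (SS_tot = 0).  Constant x raises (vertical fit undefined).
    """
    if sample.n < 2:
        raise ValueError("regression needs n ≥ 2")
    x, y = sample.x, sample.y
    dx = x - x.mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise ValueError("constant x: vertical fit undefined")
    slope = float(dx @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    dy = y - y.mean()
    ss_tot = float(dy @ dy)
    r2 = None if ss_tot == 0.0 else float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    return RegressionResult(slope, intercept, r2, sample.n)


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across ≥2 groups (each n ≥ 2)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs ≥ 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n = {v.size} < 2")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    k = len(arrays)
    n_total = all_vals.size
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ssw = sum(float((v - v.mean()) @ (v - v.mean())) for v in arrays.values())
    dfb, dfw = k - 1, n_total - k
    means = {key: float(v.mean()) for key, v in arrays.items()}
    sizes = {key: int(v.size) for key, v in arrays.items()}
    if ssw == 0.0 and ssb == 0.0:
        return AnovaResult(None, None, dfb, dfw, means, sizes)
    if ssw == 0.0:
        return AnovaResult(float("inf"), 0.0, dfb, dfw, means, sizes)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), p, dfb, dfw, means, sizes)


def bonferroni_vs_control(groups: dict[str, np.ndarray], control_label: str,
                          welch: bool = False) -> dict[str, float]:
    """Bonferroni-adjusted two-sided t-test p-values of each group vs control.

    Classical equal-variance t-tests by default (``welch=True`` for the
    unequal-variance variant); adjusted p = min(1, m·p_raw) with m the
    number of comparisons.
    """
    if control_label not in groups:
        raise KeyError(f"control group {control_label!r} missing")
    control = np.asarray(groups[control_label], dtype=float)
    others = {k: np.asarray(v, dtype=float) for k, v in groups.items()
              if k != control_label}
    m = len(others)
    out: dict[str, float] = {}
    for label, vals in others.items():
        t, p = sps.ttest_ind(vals, control, equal_var=not welch)
        if np.isnan(p):       # zero pooled variance: identical constants → p = 1
            p = 1.0 if np.isclose(vals.mean(), control.mean()) else 0.0
        out[label] = float(min(1.0, m * p))
    return out


def significance_stars(p: float | None) -> str:
    """Convention: * p<0.05, ** p<0.01, *** p<0.001, 'ns' otherwise."""
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# table-level wrappers used by the pipeline
# ---------------------------------------------------------------------------

def _paired_values(measurements: pd.DataFrame, nc_table: pd.DataFrame,
                   condition: str, quantity: str,
                   value: str = "normalized") -> PairedSample:
    """Per-cell (channel A, channel B) pairs for one condition and quantity.

    ``quantity`` is ``"nc_ratio"`` or a compartment name.
    """
    if quantity == "nc_ratio":
        sub = nc_table[(nc_table["condition"] == condition) & nc_table["nc_defined"]]
        wide = sub.pivot_table(index=["field_id", "cell_id"], columns="channel",
                               values="nc_ratio", aggfunc="first").dropna()
    else:
        sub = measurements[(measurements["condition"] == condition)
                           & (measurements["compartment"] == quantity)]
        wide = sub.pivot_table(index=["field_id", "cell_id"], columns="channel",
                               values=value, aggfunc="first").dropna()
    if CHANNEL_A not in wide or CHANNEL_B not in wide:
        return PairedSample(np.empty(0), np.empty(0), condition, quantity)
    return PairedSample(wide[CHANNEL_A].to_numpy(), wide[CHANNEL_B].to_numpy(),
                        condition, quantity)


def correlation_table(measurements: pd.DataFrame, nc_table: pd.DataFrame,
                      conditions: list[str] | None = None,
                      value: str = "normalized",
                      min_n: int = 115) -> pd.DataFrame:
    """Grid of Pearson r per condition × {N/C ratio, nucleus, cytoplasm}.

    Values are pooled across replicates after per-replicate normalization.
    Conditions with n < ``min_n`` cells are computed anyway (n ≥ 3) and
    flagged ``low_n``.
    """
    import logging
    logger = logging.getLogger(__name__)
    if conditions is None:
        conditions = list(pd.unique(measurements["condition"]))
    rows = []
    for cond in conditions:
        for quantity in ("nc_ratio", NUCLEUS, CYTOPLASM):
            sample = _paired_values(measurements, nc_table, cond, quantity, value)
            r = pearson_r(sample) if sample.n >= 3 else None
            if 3 <= sample.n < min_n:
                logger.warning("condition %s/%s: only %d cells (expected ≥ %d)",
                               cond, quantity, sample.n, min_n)
            rows.append({"condition": cond, "quantity": quantity,
                         "r": np.nan if r is None else r, "n": sample.n,
                         "low_n": sample.n < min_n})
    return pd.DataFrame(rows)


def regression_table(measurements: pd.DataFrame, nc_table: pd.DataFrame,
                     conditions: list[str] | None = None,
                     value: str = "normalized") -> pd.DataFrame:
    """Slope, intercept and R² per condition × {N/C ratio, nucleus, cytoplasm}."""
    if conditions is None:
        conditions = list(pd.unique(measurements["condition"]))
    rows = []
    for cond in conditions:
        for quantity in ("nc_ratio", NUCLEUS, CYTOPLASM):
            sample = _paired_values(measurements, nc_table, cond, quantity, value)
            if sample.n < 2 or np.ptp(sample.x) == 0:
                rows.append({"condition": cond, "quantity": quantity,
                             "slope": np.nan, "intercept": np.nan,
                             "r_squared": np.nan, "n": sample.n})
                continue
            res = linear_fit(sample)
            rows.append({"condition": cond, "quantity": quantity,
                         "slope": res.slope, "intercept": res.intercept,
                         "r_squared": np.nan if res.r_squared is None
                         else res.r_squared, "n": res.n})
    return pd.DataFrame(rows)


def anova_vs_control_table(measurements: pd.DataFrame, control_condition: str,
                           value: str = "normalized",
                           unit: str = "replicate") -> pd.DataFrame:
    """ANOVA + Bonferroni vs control per channel × compartment.

    ``unit="replicate"`` (default) tests replicate means (n = number of
    experiments); ``unit="cell"`` tests single cells.
    """
    rows = []
    for (ch, comp), sub in measurements.groupby(["channel", "compartment"]):
        if unit == "replicate":
            per_unit = sub.groupby(["condition", "replicate"])[value].mean()
            groups = {c: per_unit.loc[c].to_numpy()
                      for c in per_unit.index.get_level_values(0).unique()}
        else:
            groups = {c: g[value].to_numpy() for c, g in sub.groupby("condition")}
        groups = {c: v for c, v in groups.items() if v.size >= 2}
        if len(groups) < 2 or control_condition not in groups:
            continue
        res = one_way_anova(groups)
        adj = bonferroni_vs_control(groups, control_condition)
        for cond in groups:
            p_adj = adj.get(cond, np.nan)
            rows.append({"channel": ch, "compartment": comp, "condition": cond,
                         "group_mean": res.group_means[cond],
                         "group_n": res.group_sizes[cond],
                         "anova_f": np.nan if res.f is None else res.f,
                         "anova_p": np.nan if res.p is None else res.p,
                         "p_adj_vs_control": p_adj,
                         "stars": significance_stars(
                             None if cond == control_condition else p_adj)})
    return pd.DataFrame(rows)
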