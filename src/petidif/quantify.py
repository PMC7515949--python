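"""Percent-injected-dose maps, regional tables and correlation reports.

Regional summaries use the seven-region brain scheme (left and right
hippocampus, cortex and thalamus, plus whole cerebellum).  Correlations
against reference binding values (ex vivo autoradiography in the real study,
phantom ground truth here) are Pearson R with the two-sided t-distribution
p-value (n-2 degrees of freedom), a Fisher-z 95% confidence interval and the
conventional significance stars; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DynamicImage, LabelAtlas

DEFAULT_REGIONS = (
    "hippocampus_left",
    "hippocampus_right",
    "cortex_left",
    "cortex_right",
    "thalamus_left",
    "thalamus_right",
    "cerebellum",
)


def percent_id_map(
    image: DynamicImage,
    injected_dose: float,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """%ID/cc map: duration-weighted mean concentration over a time window,
    scaled by 100/dose.  Default window: the last 30 min of the scan."""
    if injected_dose <= 0:
        raise ValueError("injected dose must be positive (Bq)")
    sched = image.schedule
    if window is None:
        window = (sched.total_duration - 1800.0, sched.total_duration)
    w0, w1 = window
    sel = (sched.mids >= w0) & (sched.mids <= w1)
    if not sel.any():
        raise ValueError("no frames fall inside the requested window")
    wts = sched.durations[sel]
    mean_conc = (image.voxels[..., sel] @ wts) / wts.sum()
    return mean_conc * 100.0 / injected_dose


def regional_means(
    values: np.ndarray,
    atlas: LabelAtlas,
    regions: tuple[str, ...] = DEFAULT_REGIONS,
    metric: str = "value",
) -> pd.DataFrame:
    """Mean/SD/voxel-count of a 3D parametric map per named atlas region."""
    if values.shape != atlas.labels.shape:
        raise ValueError("map shape does not match the atlas grid")
    rows = []
    for region in regions:
        m = atlas.mask_of(region)
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"region {region!r} is empty in the atlas")
        v = values[m]
        rows.append({"region": region, "metric": metric, "mean": float(v.mean()),
                     "sd": float(v.std()), "n": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    p: float
    n: int
    ci_low: float
    ci_high: float
    metric_pair: tuple[str, str]

    @property
    def stars(self) -> str:
        for thresh, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < thresh:
                return s
        return ""

    def __str__(self) -> str:
        a, b = self.metric_pair
        return (f"{a} vs {b}: R = {self.r:.3f}{self.stars} "
                f"(95% CI {self.ci_low:.3f}..{self.ci_high:.3f}, p = {self.p:.2e}, n = {self.n})")


def correlate_with_reference(
    values: dict[str, float] | pd.DataFrame,
    reference: dict[str, float],
    metric_pair: tuple[str, str] = ("PET", "reference"),
) -> CorrelationReport:
    """Pearson correlation of regional PET values against reference binding.

    Regions are matched by name; p is two-sided from the t distribution with
    n-2 df and the CI is the Fisher-z 95% interval.
    """
    if isinstance(values, pd.DataFrame):
        values = dict(zip(values["region"], values["mean"]))
    keys = [k for k in values if k in reference]
    n = len(keys)
    if n < 3:
        raise ValueError("need at least 3 matched regions")
    x = np.array([values[k] for k in keys], dtype=float)
    y = np.array([reference[k] for k in keys], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) < 1.0 and n > 3:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (r, r)
    return CorrelationReport(r=r, p=float(p), n=n, ci_low=ci[0], ci_high=ci[1],
                             metric_pair=metric_pair)


def method_comparison_report(
    method_values: dict[str, dict[str, float]],
    reference: dict[str, float],
) -> pd.DataFrame:
    """Per-method Pearson R against the reference regional binding values.

    ``method_values`` maps a method name (e.g. ``%ID raw``, ``V_T 10 it``) to
    its regional means.  Returns one row per method with R, p, stars and CI.
    """
    if len(method_values) < 2:
        raise ValueError("need at least 2 methods to compare")
    rows = []
    for method, vals in method_values.items():
        rep = correlate_with_reference(vals, reference, metric_pair=(method, "reference"))
        rows.append({"method": method, "r": rep.r, "p": rep.p, "stars": rep.stars,
                     "ci_low": rep.ci_low, "ci_high": rep.ci_high, "n": rep.n})
    return pd.DataFrame(rows)
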