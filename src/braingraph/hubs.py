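"""Hub identification by the mean + k*SD rule.

A region is a hub when its nodal measure (betweenness by default, following
common practice; degree, local efficiency or clustering are alternatives)
exceeds the network mean by k standard deviations.  Hubs can be identified
at a single density, or — to reduce threshold sensitivity — on the AUC or
FDA summary of each region's measure-vs-density curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HubTable", "identify_hubs", "hubs_from_curves",
           "DEFAULT_HUB_SD", "DEFAULT_HUB_MEASURE"]

DEFAULT_HUB_MEASURE = "betweenness"
DEFAULT_HUB_SD = 2.0


@dataclass
class HubTable:
    """Per-region measure values and hub flags."""

    region_labels: list
    values: np.ndarray
    is_hub: np.ndarray
    measure: str
    k: float
    mode: str = "at_density"
    cutoff: float = float("nan")

    @property
    def hubs(self) -> list:
        return [l for l, h in zip(self.region_labels, self.is_hub) if h]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.values, "is_hub": self.is_hub},
            index=self.region_labels,
        )


def identify_hubs(
    values: np.ndarray,
    k: float = DEFAULT_HUB_SD,
    region_labels=None,
    measure: str = DEFAULT_HUB_MEASURE,
    mode: str = "at_density",
) -> HubTable:
    """Flag regions whose measure exceeds mean + k * SD (sample SD, N-1).

    The comparison is strictly greater-than; with zero spread no region can
    be a hub (a warning is emitted).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a flat vector of at least 3 regional values")
    if not np.isfinite(v).all():
        raise ValueError("non-finite measure values")
    labels = (list(region_labels) if region_labels is not None
              else [f"roi-{i:03d}" for i in range(v.size)])
    if len(labels) != v.size:
        raise ValueError("region_labels length does not match values")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero spread across regions: no hubs", stacklevel=2)
        cutoff = float("inf")
    else:
        cutoff = v.mean() + k * sd
    return HubTable(labels, v, v > cutoff, measure, k, mode,
                    cutoff=float(cutoff) if np.isfinite(cutoff) else float("nan"))


def hubs_from_curves(
    curves: np.ndarray,
    densities: np.ndarray,
    mode: str = "auc",
    k: float = DEFAULT_HUB_SD,
    region_labels=None,
    measure: str = DEFAULT_HUB_MEASURE,
) -> HubTable:
    """Hub flags from per-region curve summaries.

    ``curves`` is a densities x regions array of one nodal measure; each
    region is summarized by the trapezoidal AUC (``mode="auc"``) or the plain
    sum (``mode="fda"``) of its own curve, then the mean + k*SD rule is
    applied to the summaries.
    """
    y = np.asarray(curves, dtype=float)
    x = np.asarray(densities, dtype=float)
    if y.ndim != 2 or y.shape[0] != x.size:
        raise ValueError("curves must be densities x regions")
    if x.size < 2:
        raise ValueError("need at least 2 densities for a curve summary")
    if mode == "auc":
        summary = np.trapezoid(y, x, axis=0)
    elif mode == "fda":
        summary = y.sum(axis=0)
    else:
        raise ValueError(f"unknown curve-summary mode: {mode!r}")
    return identify_hubs(summary, k, region_labels, measure, mode)
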