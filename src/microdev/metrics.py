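"""Histology quantification: stereological density, phagocytosis, clearance.

These are the count-based quantification formulas used to describe microglial
function during development:

* stereological density — cells counted in a confocal stack divided by the
  sampled volume (area x thickness), scaled by structure volume for totals;
* Ph index — percentage of apoptotic cells engulfed by microglia;
* clearance ratio — apoptotic cells per microglia (the apoptotic load);
* phagocytic capacity — proportion of microglia bearing >= 1 phagocytic pouch;
* un-engulfed fraction — percentage of the apoptotic load exceeding the
  population's engulfment capacity;
* clearance time — first-order disappearance time of a labeled apoptotic
  cohort between two fixed observation times;
* coupling index — engulfed-to-apoptotic ratio (1 = tight coupling between
  apoptosis and phagocytosis);
* Pearson correlation matrix across developmental metrics with the figure
  legends' significance tiers.

Inputs are counts, never images. Undefined ratios (zero denominators) return
NaN sentinels with a warning rather than raising, matching how such panels
are left blank in practice.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StackCount",
    "PhagocytosisTable",
    "stereology_density",
    "total_count",
    "ph_index",
    "clearance_ratio",
    "phagocytic_capacity",
    "unengulfed_fraction",
    "clearance_time",
    "coupling_index",
    "correlation_matrix",
    "significance_tier",
]


@dataclass(frozen=True)
class StackCount:
    """Cells counted in one imaging stack of known sampled volume."""

    cells_counted: int
    area: float  # mm^2
    thickness: float  # mm
    structure_volume: float | None = None  # mm^3, for totals

    def __post_init__(self) -> None:
        if self.cells_counted < 0:
            raise ValueError("cells_counted must be >= 0")
        if self.area <= 0 or self.thickness <= 0:
            raise ValueError("area and thickness must be > 0")


@dataclass(frozen=True)
class PhagocytosisTable:
    """Counts from one phagocytosis/proliferation quantification.

    ``pouch_histogram`` maps number-of-pouches -> number of microglia with
    that many pouches; it must account for every microglia. Unless per-pouch
    contents are supplied, each pouch is taken to hold one apoptotic cell.
    """

    n_microglia: int
    n_apoptotic: int
    n_apoptotic_engulfed: int
    pouch_histogram: Mapping[int, int] = field(default_factory=dict)
    n_proliferative: int = 0
    n_proliferative_and_phagocytic: int = 0

    def __post_init__(self) -> None:
        counts = dict(self.pouch_histogram)
        if any(v < 0 for v in (self.n_microglia, self.n_apoptotic,
                               self.n_apoptotic_engulfed, self.n_proliferative,
                               self.n_proliferative_and_phagocytic)):
            raise ValueError("counts must be non-negative")
        if self.n_apoptotic_engulfed > self.n_apoptotic:
            raise ValueError("engulfed apoptotic cells cannot exceed apoptotic cells")
        if counts:
            if any(k < 0 or v < 0 for k, v in counts.items()):
                raise ValueError("pouch histogram keys and counts must be >= 0")
            if sum(counts.values()) != self.n_microglia:
                raise ValueError("pouch histogram must account for every microglia")
            n_phag = self.n_phagocytic
            if self.n_proliferative_and_phagocytic > min(
                self.n_proliferative if self.n_proliferative else n_phag, n_phag
            ):
                raise ValueError(
                    "proliferative-and-phagocytic count exceeds its marginals"
                )

    @property
    def n_phagocytic(self) -> int:
        """Microglia with at least one phagocytic pouch."""
        return sum(v for k, v in self.pouch_histogram.items() if k >= 1)

    @property
    def total_pouches(self) -> int:
        return sum(k * v for k, v in self.pouch_histogram.items())


def stereology_density(sc: StackCount) -> float:
    """Cells per mm^3: counted cells over the stack volume (area x thickness)."""
    return sc.cells_counted / (sc.area * sc.thickness)


def total_count(density: float, structure_volume: float) -> float:
    """Total cells in the structure: density times structure volume."""
    if structure_volume <= 0:
        raise ValueError("structure_volume must be > 0")
    if density < 0:
        raise ValueError("density must be >= 0")
    return density * structure_volume


def _nan_warn(msg: str) -> float:
    warnings.warn(msg)
    return float("nan")


def ph_index(t: PhagocytosisTable) -> float:
    """Phagocytic (Ph) index: % of apoptotic cells engulfed by microglia."""
    if t.n_apoptotic == 0:
        return _nan_warn("Ph index undefined with zero apoptotic cells")
    return 100.0 * t.n_apoptotic_engulfed / t.n_apoptotic


def clearance_ratio(t: PhagocytosisTable) -> float:
    """Apoptotic load: apoptotic cells per microglia."""
    if t.n_microglia == 0:
        return _nan_warn("clearance ratio undefined with zero microglia")
    return t.n_apoptotic / t.n_microglia


def phagocytic_capacity(t: PhagocytosisTable) -> tuple[float, float]:
    """(% of microglia with >= 1 pouch, mean pouches per phagocytic microglia)."""
    if not t.pouch_histogram:
        raise ValueError("empty pouch histogram")
    if t.n_microglia == 0:
        return _nan_warn("capacity undefined with zero microglia"), float("nan")
    engaged = t.n_phagocytic
    pct = 100.0 * engaged / t.n_microglia
    mean_pouches = t.total_pouches / engaged if engaged else float("nan")
    return pct, mean_pouches


def unengulfed_fraction(
    load_ratio: float, engaged_fraction: float, mean_pouches: float = 1.0
) -> float:
    """Percentage of apoptotic cells left un-engulfed.

    Each microglia faces ``load_ratio`` apoptotic cells; a fraction
    ``engaged_fraction`` of microglia is phagocytic, each holding
    ``mean_pouches`` apoptotic cells, so the engulfed share is
    ``engaged_fraction * mean_pouches / load_ratio`` (capped at 1):

    ``100 * (1 - min(1, engaged_fraction * mean_pouches / load_ratio))``
    """
    if load_ratio <= 0:
        raise ValueError("load_ratio must be > 0")
    if not (0.0 <= engaged_fraction <= 1.0):
        raise ValueError("engaged_fraction must be in [0,1]")
    if mean_pouches < 1.0:
        raise ValueError("mean_pouches must be >= 1 (a phagocytic cell has a pouch)")
    return 100.0 * (1.0 - min(1.0, engaged_fraction * mean_pouches / load_ratio))


def clearance_time(n_t1: float, n_t2: float, dt: float) -> float:
    """First-order clearance time of a labeled apoptotic cohort.

    Assuming exponential disappearance between the two observation times,
    ``tau = dt / ln(n_t1 / n_t2)`` (hours when ``dt`` is in hours). Note the
    half-life identity ``tau * ln 2 = dt`` when the cohort halves over dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n_t2 <= 0 or n_t1 <= 0:
        raise ValueError("densities must be > 0")
    if n_t2 >= n_t1:
        raise ValueError("no decay between time points; clearance time undefined")
    return dt / float(np.log(n_t1 / n_t2))


def coupling_index(
    phagocytosis_total: float,
    apoptotic_total: float,
    control: tuple[float, float] | None = None,
) -> float:
    """Engulfed-to-apoptotic ratio; 1 means phagocytosis matches apoptosis.

    With a ``(phagocytosis, apoptosis)`` control pair, returns the
    treated/control ratio of ratios (control-normalized coupling).
    """
    if apoptotic_total <= 0:
        return _nan_warn("coupling undefined with zero apoptotic cells")
    value = phagocytosis_total / apoptotic_total
    if control is not None:
        c_ph, c_ap = control
        ref = coupling_index(c_ph, c_ap)
        value = value / ref
    return value


def significance_tier(p: float) -> str:
    """Figure-legend significance tiers: *** <0.001, ** <0.01, * <0.05, ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def correlation_matrix(
    mt: pd.DataFrame, holm: bool = False
) -> pd.DataFrame:
    """Pairwise Pearson correlations between developmental metrics over age.

    ``mt`` is long-format with columns ``age_days, metric_name, value`` (one
    value per age and metric). Each metric pair is correlated over the ages
    where both are present (>= 3 required); returns a tidy frame with columns
    ``metric_x, metric_y, n, r, r2, p, tier``. ``p`` comes from the exact
    t-transform with n-2 degrees of freedom; ``holm=True`` applies a Holm
    step-down adjustment across pairs before tiering. Constant series yield
    NaN sentinels.
    """
    required = {"age_days", "metric_name", "value"}
    if not required.issubset(mt.columns):
        raise ValueError(f"metric table must have columns {sorted(required)}")
    wide = mt.pivot_table(index="age_days", columns="metric_name", values="value")
    rows = []
    for mx, my in itertools.combinations(sorted(wide.columns), 2):
        pair = wide[[mx, my]].dropna()
        if len(pair) < 3:
            raise ValueError(f"need >= 3 paired ages for ({mx}, {my}), got {len(pair)}")
        x, y = pair[mx].to_numpy(), pair[my].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"constant series in pair ({mx}, {my}); correlation undefined")
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"metric_x": mx, "metric_y": my, "n": len(pair),
                     "r": r, "r2": r * r, "p": p})
    out = pd.DataFrame(rows)
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        adjusted = out["p"].copy()
        if mask.any():
            adjusted.loc[mask] = multipletests(out.loc[mask, "p"], method="holm")[1]
        out["p_adj"] = adjusted
        out["tier"] = [significance_tier(p) if np.isfinite(p) else "na"
                       for p in out["p_adj"]]
    else:
        out["tier"] = [significance_tier(p) if np.isfinite(p) else "na"
                       for p in out["p"]]
    return out
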