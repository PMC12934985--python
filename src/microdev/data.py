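"""Replicate-level developmental time series (the likelihood's data).

Long format: one row per (layer, age, replicate, observable) with
observables ``volume`` (mm^3), ``density`` (cells/mm^3) and ``pct_ki67``
(percent Ki67+ microglia).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

OBSERVABLES = ("volume", "density", "pct_ki67")

COLUMNS = ("region", "layer", "age_days", "replicate", "observable", "value")

__all__ = ["OBSERVABLES", "COLUMNS", "LayerTimeSeries", "wide_to_long"]


def wide_to_long(df: pd.DataFrame, region: str | None = None) -> "LayerTimeSeries":
    """Convert a wide table (one column per observable) to the long format.

    Expects columns ``layer, age_days, replicate`` plus any of ``volume``,
    ``density``, ``pct_ki67``; missing cells are dropped.
    """
    id_cols = ["layer", "age_days", "replicate"]
    missing = [c for c in id_cols if c not in df.columns]
    if missing:
        raise ValueError(f"wide table missing identifier columns {missing}")
    present = [c for c in OBSERVABLES if c in df.columns]
    if not present:
        raise ValueError(f"wide table has none of the observable columns {OBSERVABLES}")
    long = df.melt(
        id_vars=id_cols + (["region"] if "region" in df.columns else []),
        value_vars=present, var_name="observable", value_name="value",
    ).dropna(subset=["value"])
    if "region" not in long.columns:
        long["region"] = region or "unknown"
    return LayerTimeSeries(str(long["region"].iloc[0]), long)


@dataclass
class LayerTimeSeries:
    """Validated replicate observations of (volume, density, %Ki67) per layer."""

    region: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns and c != "region"]
        if missing:
            raise ValueError(f"time series missing columns: {missing}")
        if "region" in df.columns:
            regions = df["region"].unique()
            if len(regions) > 1:
                raise ValueError(f"expected a single region, got {list(regions)}")
        else:
            df = df.assign(region=self.region)
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        bad = df.index[~df["observable"].isin(OBSERVABLES)]
        if len(bad):
            raise ValueError(
                f"unknown observable at rows {list(bad[:5])}; expected one of {OBSERVABLES}"
            )
        if (df["age_days"] < 0).any():
            raise ValueError("ages must be >= 0 days")
        if (df["value"] < 0).any():
            rows = df.index[df["value"] < 0]
            raise ValueError(f"negative values at rows {list(rows[:5])}")
        key = ["layer", "age_days", "replicate", "observable"]
        if df.duplicated(subset=key).any():
            dupes = df[df.duplicated(subset=key, keep=False)].head()
            raise ValueError(f"duplicate (layer, age, replicate, observable) rows:\n{dupes}")
        for obs, group in df.groupby("observable"):
            if group["age_days"].nunique() < 2:
                raise ValueError(f"observable {obs!r} needs >= 2 distinct ages")
        self.frame = df

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def ages(self) -> np.ndarray:
        """Sorted unique observation ages (days)."""
        return np.sort(self.frame["age_days"].unique())

    def layers(self) -> list[str]:
        return sorted(self.frame["layer"].unique())

    def subset(self, observables) -> "LayerTimeSeries":
        sub = self.frame[self.frame["observable"].isin(list(observables))]
        return LayerTimeSeries(self.region, sub.copy())

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LayerTimeSeries":
        df = pd.read_csv(path)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        region = str(df["region"].iloc[0]) if len(df) else "unknown"
        return cls(region, df)
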