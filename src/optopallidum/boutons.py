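"""Axonal bouton (varicosity) density quantification.

ROI counts (233 x 173 um^2 ROIs by default) are converted to densities per
100 x 100 um^2; per-animal mediolateral profiles use the maximum density per
(animal, M/L position); and cross-structure normalization divides each
animal's maximum GP density by its maximum density in a reference structure
(striatum or STN), which cancels animal-to-animal differences in tracer
labeling efficacy.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "DensitySummary",
    "density_per_100um2",
    "add_density_column",
    "ml_profile",
    "normalized_ratio_summary",
    "compare_density_groups",
    "load_packaged_bouton_table",
]

ROI_WIDTH_UM = 233.0
ROI_HEIGHT_UM = 173.0


def density_per_100um2(count, roi_width: float = ROI_WIDTH_UM,
                       roi_height: float = ROI_HEIGHT_UM):
    """Convert an ROI bouton count to a density per 100 x 100 um^2:
    ``count * 1e4 / (roi_width * roi_height)``."""
    if roi_width <= 0 or roi_height <= 0:
        raise ValueError("ROI dimensions must be positive")
    c = np.asarray(count, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    out = c * 1e4 / (roi_width * roi_height)
    return float(out) if np.isscalar(count) else out


def add_density_column(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of an ROI-count table with a ``density`` column."""
    t = table.copy()
    t["density"] = [
        density_per_100um2(r["count"], r.get("roi_width", ROI_WIDTH_UM),
                           r.get("roi_height", ROI_HEIGHT_UM))
        for _, r in t.iterrows()
    ]
    return t


def ml_profile(table: pd.DataFrame, region: str) -> pd.DataFrame:
    """Per-animal maximum density versus mediolateral position for a region.

    Bins are the recorded M/L positions. Returns a tidy frame
    (animal_id, ml_position, density); empty when the region has no ROIs.
    """
    t = add_density_column(table[table["region"] == region])
    if t.empty:
        return pd.DataFrame(columns=["animal_id", "ml_position", "density"])
    prof = (t.groupby(["animal_id", "ml_position"])["density"].max()
            .reset_index())
    return prof


@dataclass
class DensitySummary:
    """Per-animal maximum-density ratios of GP to a reference structure."""

    cortical_source: str
    denominator_region: str
    per_animal: pd.DataFrame  # animal_id, gp_max, denom_max, ratio
    mean_ratio: float
    sd_ratio: float
    percent: int  # mean ratio as integer percent (round half up)
    excluded_animals: tuple = ()


def _round_half_up_percent(x: float) -> int:
    return int(math.floor(100.0 * x + 0.5))


def normalized_ratio_summary(table: pd.DataFrame, source: str,
                             denominator_region: str = "STN",
                             numerator_region: str = "GP") -> DensitySummary:
    """Per-animal max-GP-density over max-reference-density ratios.

    For each animal of the given cortical source, the ratio is the maximum
    density over its GP ROIs divided by the maximum over its ROIs in the
    denominator region; the summary reports the group mean and sample SD
    (n-1) of the ratios, plus the mean as an integer percent. Animals with a
    zero denominator are excluded with a warning.
    """
    t = add_density_column(table[table["cortical_source"] == source])
    if t.empty:
        raise ValueError(f"no ROIs for cortical source {source!r}")
    rows, excluded = [], []
    for animal, sub in t.groupby("animal_id"):
        num = sub[sub["region"] == numerator_region]["density"]
        den = sub[sub["region"] == denominator_region]["density"]
        if num.empty or den.empty:
            raise ValueError(f"animal {animal} lacks ROIs in both regions")
        num_max, den_max = float(num.max()), float(den.max())
        if den_max == 0:
            excluded.append(animal)
            continue
        rows.append(dict(animal_id=animal, gp_max=num_max,
                         denom_max=den_max, ratio=num_max / den_max))
    if excluded:
        warnings.warn(f"excluded animals with zero reference density: {excluded}")
    if not rows:
        raise ValueError("no animal had a non-zero reference density")
    per = pd.DataFrame(rows)
    mean = float(per["ratio"].mean())
    sd = float(per["ratio"].std(ddof=1)) if len(per) > 1 else 0.0
    return DensitySummary(source, denominator_region, per, mean, sd,
                          _round_half_up_percent(mean), tuple(excluded))


def compare_density_groups(groups: dict, exact: bool = False) -> dict:
    """Kruskal-Wallis across the given groups plus pairwise Tukey HSD on the
    same values (both are reported; users may prefer either).

    ``groups`` maps a label to a 1-D array of per-animal values. The grouping
    is an explicit argument because different normalizations (to striatum or
    to STN, per cortical source) define different families.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    kw = _stats.kruskal_wallis(values, labels=labels, exact=exact)
    tukey = _stats.tukey_hsd(values, labels=labels)
    return {"kruskal_wallis": kw, "tukey_hsd": tukey,
            "group_means": {k: float(np.mean(v)) for k, v in zip(labels, values)}}


def load_packaged_bouton_table() -> pd.DataFrame:
    """Packaged per-animal maximum bouton densities (motor-cortex tracing).

    The published quantification reports, per animal and structure, the
    maximum bouton count per 100 x 100 um^2; the packaged table encodes each
    maximum as a single 100 x 100 um pseudo-ROI so that count and density
    coincide and the normalization pipeline runs unchanged.
    """
    ref = importlib.resources.files("optopallidum.data") / "bouton_max_densities.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
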