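"""Anatomical coordinate scaling, region assignment, co-expression rates
and expression-gradient maps.

Cell positions are normalised per animal and hemisphere: the centre of each
hemisphere's cell cloud becomes (0, 0) and coordinates are z-scored (sample
SD, ddof = 1), so positions are comparable across animals and cohorts.  The
lateral sign is normalised so +x points laterally on both hemispheres.  On
this scale the lateral region is defined by scaled x strictly greater than
1.5 units; the corresponding physical distance in um is cohort-dependent
and is reported alongside, never thresholded on.

Along the caudo-rostral axis sections are ordered by bregma (mm), binned as
rostral (-3.1, -2.7], medial (-3.5, -3.1], caudal [-3.9, -3.5].
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "scale_coordinates",
    "assign_regions",
    "coexpression_table",
    "gradient_map",
    "LATERAL_THRESHOLD",
    "BREGMA_BINS",
]

LATERAL_THRESHOLD = 1.5  # scaled x units
BREGMA_BINS = {  # half-open (lo, hi]; caudal edge closed at -3.9
    "rostral": (-3.1, -2.7),
    "medial": (-3.5, -3.1),
    "caudal": (-3.9, -3.5),
}
SECTION_THICKNESS_UM = 30.0


def scale_coordinates(cells: pd.DataFrame,
                      x: str = "x_um", y: str = "y_um",
                      group: tuple[str, str] = ("animal", "hemisphere"),
                      hemisphere_sign: bool = True) -> pd.DataFrame:
    """Per-(animal, hemisphere) z-scoring of cell coordinates.

    Adds ``scaled_x``/``scaled_y``; within each group both have mean 0 and
    sample SD 1.  The x sign is flipped on the left hemisphere so +x points
    laterally everywhere.  Also adds ``um_per_scaled_x``, the group's
    physical equivalent of one scaled unit.  Groups with fewer than two
    cells have an undefined SD and raise an error.

    ``hemisphere_sign=False`` skips the lateral flip, for coordinates that
    are already in the lateral-positive convention (z-scoring such data is
    then idempotent: re-scaling scaled coordinates returns them unchanged).
    """
    out = cells.copy()
    x_src = out[x].copy()
    y_src = out[y].copy()
    out["scaled_x"] = np.nan
    out["scaled_y"] = np.nan
    out["um_per_scaled_x"] = np.nan
    for keys, idx in out.groupby(list(group)).groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {keys} has a single cell: SD undefined")
        sub = out.loc[idx]
        hemi = sub[group[1]].iloc[0] if group[1] in sub else "none"
        sign = -1.0 if hemisphere_sign and str(hemi) == "left" else 1.0
        xv = sign * x_src.loc[idx].to_numpy(dtype=float)
        yv = y_src.loc[idx].to_numpy(dtype=float)
        sx = xv.std(ddof=1)
        sy = yv.std(ddof=1)
        if sx == 0 or sy == 0:
            raise ValueError(f"group {keys} has zero coordinate spread")
        out.loc[idx, "scaled_x"] = (xv - xv.mean()) / sx
        out.loc[idx, "scaled_y"] = (yv - yv.mean()) / sy
        out.loc[idx, "um_per_scaled_x"] = sx
    return out


def assign_regions(cells: pd.DataFrame, bregma: str = "bregma_mm"
                   ) -> pd.DataFrame:
    """Add ``lateral`` (scaled_x > 1.5, strict) and caudo-rostral ``region``.

    Bregma values outside [-3.9, -2.7] get region ``None`` with a warning.
    """
    if "scaled_x" not in cells:
        raise ValueError("run scale_coordinates first")
    out = cells.copy()
    out["lateral"] = out["scaled_x"] > LATERAL_THRESHOLD
    b = out[bregma].to_numpy(dtype=float)
    region = np.full(len(out), None, dtype=object)
    region[(b > -3.1) & (b <= -2.7)] = "rostral"
    region[(b > -3.5) & (b <= -3.1)] = "medial"
    region[(b >= -3.9) & (b <= -3.5)] = "caudal"
    n_out = int(np.sum((b < -3.9) | (b > -2.7)))
    if n_out:
        warnings.warn(f"{n_out} cells with bregma outside [-3.9, -2.7]: "
                      "region set to None")
    out["region"] = region
    return out


def _rate_row(n_pos: int, n: int) -> dict:
    if n == 0:
        return {"n": 0, "n_positive": 0, "percent": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "undefined": True}
    lo, hi = proportion_confint(n_pos, n, alpha=0.05, method="beta")
    return {"n": n, "n_positive": int(n_pos),
            "percent": 100.0 * n_pos / n,
            "ci_low": 100.0 * lo, "ci_high": 100.0 * hi, "undefined": False}


def coexpression_table(cells: pd.DataFrame, primary: str,
                       secondary: list[str] | str,
                       strata: str = "all") -> pd.DataFrame:
    """Positive/negative rates of secondary markers among primary-positive cells.

    ``cells`` carries one boolean column ``<marker>_positive`` per marker and
    a ``qc_included`` column; only QC-included, primary-positive cells enter.
    ``strata``: "all", "lateral" (lateral vs non-lateral) or "region".
    Rates come with Clopper-Pearson 95% confidence intervals; empty strata
    are flagged undefined rather than reported as 0.
    """
    if isinstance(secondary, str):
        secondary = [secondary]
    df = cells
    if "qc_included" in df:
        df = df[df["qc_included"]]
    df = df[df[f"{primary}_positive"]]
    if strata == "all":
        groups = {"all": df}
    elif strata == "lateral":
        groups = {"lateral": df[df["lateral"]],
                  "non_lateral": df[~df["lateral"]]}
    elif strata == "region":
        groups = {r: df[df["region"] == r] for r in
                  ("rostral", "medial", "caudal")}
    else:
        raise ValueError("strata must be 'all', 'lateral' or 'region'")
    rows = []
    for name, sub in groups.items():
        for marker in secondary:
            pos = int(sub[f"{marker}_positive"].sum())
            for call, k in (("positive", pos), ("negative", len(sub) - pos)):
                rows.append({"stratum": name, "marker": marker, "call": call,
                             **_rate_row(k, len(sub))})
    return pd.DataFrame(rows)


def gradient_map(cells: pd.DataFrame, rf_column: str,
                 exclude_top_fraction: float = 0.003,
                 animal: str = "animal",
                 thickness_um: float = SECTION_THICKNESS_UM) -> pd.DataFrame:
    """Plotting-ready table of per-cell scaled RF deviations.

    The RF value is z-scored per animal so 0 is each animal's mean and the
    colour scale shows the deviation from it.  The z coordinate is the
    section's bregma position (mm), sections stacked caudal to rostral at
    ``thickness_um``.  The highest ``exclude_top_fraction`` of values
    (ceil(fraction * n) cells) is excluded from the display scaling via the
    ``display`` flag; no cell is dropped from the table.
    """
    out = cells.copy()
    out["scaled_rf"] = np.nan
    for _, idx in out.groupby(animal).groups.items():
        v = out.loc[idx, rf_column].to_numpy(dtype=float)
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        out.loc[idx, "scaled_rf"] = (v - v.mean()) / sd if sd > 0 else 0.0
    out["z_mm"] = out["bregma_mm"]
    out["section_thickness_um"] = thickness_um
    out["display"] = True
    n_excl = math.ceil(exclude_top_fraction * len(out)) \
        if exclude_top_fraction > 0 else 0
    if n_excl:
        top = out["scaled_rf"].nlargest(n_excl).index
        out.loc[top, "display"] = False
    cols = ["scaled_x", "scaled_y", "z_mm", "scaled_rf", "display"]
    missing = [c for c in cols[:2] if c not in out]
    if missing:
        raise ValueError("run scale_coordinates first")
    return out
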