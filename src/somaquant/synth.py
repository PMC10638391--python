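"""Synthetic fixtures with exact ground truth.

Three generators emulate the data the pipeline consumes, so every stage can
be validated against a planted truth without any microscope data:

* :func:`generate_cell_image` renders a multi-channel field of cell bodies
  with nuclei (and optionally membrane rings), sub-resolution fluorescent
  dots, per-cell brightfield attenuation, and Gaussian background noise.
* :func:`generate_if_cohort` builds a per-cell immunofluorescence cohort
  table across animals, hemispheres and sections, with a planted
  marker-negative subpopulation enriched laterally, smaller somata for the
  negative cells, and a medio-lateral expression gradient;
  :func:`render_if_section` turns one section of it into an image.
* :func:`generate_section_series` produces stereology section series by
  distributing a known total across sections and thinning by the sampling
  fractions.

Every generator is a pure function of its spec and seed: identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import LabelMask, MultiChannelImage
from .stereology import SectionCounts, StereologyParams

__all__ = [
    "ImageSpec",
    "GroundTruth",
    "generate_cell_image",
    "dot_segmentation_dataset",
    "generate_if_cohort",
    "render_if_section",
    "generate_section_series",
]


@dataclass
class ImageSpec:
    """Parameters of one rendered field of cells.

    Intensities are on the [0, 1] scale.  ``dots_per_cell`` is either a fixed
    integer or ``("poisson", mean)``.  ``dot_min_separation`` (px, centre to
    centre) keeps dots resolvable; set it small (or 0) to create deliberately
    fused dots.  ``transmission`` is the per-cell brightfield transmission
    range (None disables the brightfield channel).
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 10
    cell_radius: tuple[float, float] = (10.0, 16.0)
    nucleus_fraction: float = 0.45
    membrane_width: float = 2.0
    include_membrane: bool = False
    dots_per_cell: object = ("poisson", 25)
    dot_radius: float = 2.0
    dot_min_separation: float | None = 6.0
    dot_intensity: float = 0.8
    body_intensity: float = 0.35
    nucleus_intensity: float = 0.45
    membrane_intensity: float = 0.5
    background_level: float = 0.05
    noise_sd: float = 0.02
    transmission: tuple[float, float] | None = None
    incident_intensity: float = 0.9
    overlap_fraction: float = 0.0
    border_margin: int = 4
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_radius[0] <= 0 or self.dot_radius <= 0:
            raise ValueError("radii must be positive")
        for p in (self.nucleus_fraction, self.overlap_fraction):
            if not 0 <= p <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth of a rendered image, pixel-consistent by construction."""

    body_labels: LabelMask
    nucleus_labels: LabelMask
    membrane_labels: LabelMask | None
    cells: list[dict]  # id, center (x, y), radius, T, dot_centers, flags
    dot_mask: np.ndarray  # binary, all dots

    def dot_count(self, cell_id: int) -> int:
        return len(self.cells[cell_id - 1]["dot_centers"])

    def semantic_mask(self, classes: Sequence[str]) -> LabelMask:
        """Compose a semantic mask from the named classes.

        ``classes`` starts with "background"; the remaining names are drawn
        in order (later classes overwrite), from {"body", "nucleus",
        "membrane", "dot"}.
        """
        out = np.zeros(self.body_labels.shape, dtype=np.int32)
        sources = {
            "body": self.body_labels.labels > 0,
            "nucleus": self.nucleus_labels.labels > 0,
            "membrane": (self.membrane_labels.labels > 0
                         if self.membrane_labels else None),
            "dot": self.dot_mask,
        }
        for i, name in enumerate(classes):
            if name == "background":
                continue
            src = sources[name]
            if src is None:
                raise ValueError(f"class {name!r} not rendered")
            out[src] = i
        return LabelMask(out, kind="semantic", class_names=list(classes))


def _disc(shape, center, radius):
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2


def _place_centres(spec: ImageSpec, rng: np.random.Generator):
    """Cell centres and radii; a fraction of cells touch their predecessor."""
    H, W = spec.shape
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centres) < spec.n_cells:
        attempts += 1
        if attempts > 200 * spec.n_cells:
            raise ValueError("infeasible packing: too many cells for the field")
        r = rng.uniform(*spec.cell_radius)
        m = spec.border_margin + r
        touch = centres and rng.random() < spec.overlap_fraction
        if touch:
            cx0, cy0 = centres[-1]
            ang = rng.uniform(0, 2 * np.pi)
            d = 0.85 * (r + radii[-1])  # overlapping pair
            cx, cy = cx0 + d * np.cos(ang), cy0 + d * np.sin(ang)
            if not (m <= cx < W - m and m <= cy < H - m):
                continue
            others = centres[:-1]
        else:
            cx = rng.uniform(m, W - m)
            cy = rng.uniform(m, H - m)
            others = centres
        ok = all((cx - ox) ** 2 + (cy - oy) ** 2 >= (r + orr + 2) ** 2
                 for (ox, oy), orr in zip(others, radii))
        if ok:
            centres.append((cx, cy))
            radii.append(r)
    return centres, radii


def _place_dots(spec: ImageSpec, center, radius, nucleus_r,
                rng: np.random.Generator) -> list[tuple[float, float]]:
    if isinstance(spec.dots_per_cell, tuple):
        kind, mean = spec.dots_per_cell
        if kind != "poisson":
            raise ValueError("dots_per_cell must be int or ('poisson', mean)")
        n = int(rng.poisson(mean))
    else:
        n = int(spec.dots_per_cell)
    pts: list[tuple[float, float]] = []
    sep = spec.dot_min_separation
    tries = 0
    while len(pts) < n and tries < 400 * max(n, 1):
        tries += 1
        rr = radius * 0.92 * np.sqrt(rng.random())
        ang = rng.uniform(0, 2 * np.pi)
        x = center[0] + rr * np.cos(ang)
        y = center[1] + rr * np.sin(ang)
        if sep and any((x - px) ** 2 + (y - py) ** 2 < sep ** 2
                       for px, py in pts):
            continue
        pts.append((x, y))
    return pts


def generate_cell_image(spec: ImageSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one field of cells and its exact ground truth.

    Channels, in order: ``marker`` (cell bodies), ``nuclear``, ``target``
    (dots), then optionally ``membrane`` and/or ``brightfield``.  At most 4
    channels fit a :class:`MultiChannelImage`, so membrane and brightfield
    are mutually exclusive.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    centres, radii = _place_centres(spec, rng)

    body = np.zeros((H, W), dtype=np.int32)
    nucleus = np.zeros((H, W), dtype=np.int32)
    membrane = np.zeros((H, W), dtype=np.int32) if spec.include_membrane else None
    dot_mask = np.zeros((H, W), dtype=bool)
    marker_ch = np.zeros((H, W))
    nuclear_ch = np.zeros((H, W))
    target_ch = np.zeros((H, W))
    bf_ch = (np.full((H, W), spec.incident_intensity)
             if spec.transmission is not None else None)

    cells: list[dict] = []
    yy, xx = np.mgrid[:H, :W]
    for cid, ((cx, cy), r) in enumerate(zip(centres, radii), start=1):
        disc = _disc((H, W), (cx, cy), r)
        body[disc] = cid
        gain = rng.uniform(0.85, 1.15)
        marker_ch[disc] = spec.body_intensity * gain
        nuc_r = spec.nucleus_fraction * r
        off = rng.uniform(-0.15 * r, 0.15 * r, size=2)
        ndisc = _disc((H, W), (cx + off[0], cy + off[1]), nuc_r) & disc
        nucleus[ndisc] = cid
        nuclear_ch[ndisc] = spec.nucleus_intensity * rng.uniform(0.9, 1.1)
        if membrane is not None:
            ring = disc & ~_disc((H, W), (cx, cy), r - spec.membrane_width)
            membrane[ring] = cid

        T = (float(rng.uniform(*spec.transmission))
             if spec.transmission is not None else 1.0)
        if bf_ch is not None:
            bf_ch[disc] = spec.incident_intensity * T

        dots = _place_dots(spec, (cx, cy), r, nuc_r, rng)
        for dx, dy in dots:
            spot = np.exp(-(((xx - dx) ** 2 + (yy - dy) ** 2)
                            / (2 * (spec.dot_radius / 1.6) ** 2)))
            target_ch += spec.dot_intensity * spot
            dot_mask |= (xx - dx) ** 2 + (yy - dy) ** 2 <= spec.dot_radius ** 2
        cells.append({
            "id": cid, "center": (cx, cy), "radius": r, "T": T,
            "dot_centers": dots,
        })

    names = ["marker", "nuclear", "target"]
    planes = [marker_ch, nuclear_ch, target_ch]
    if spec.include_membrane and spec.transmission is not None:
        raise ValueError("membrane and brightfield together exceed 4 channels")
    if spec.include_membrane:
        mem_ch = np.where(membrane > 0, spec.membrane_intensity, 0.0)
        names.append("membrane")
        planes.append(mem_ch)
    if bf_ch is not None:
        names.append("brightfield")
        planes.append(bf_ch)

    img = np.stack(planes, axis=2)
    img += spec.background_level
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    mci = MultiChannelImage(img, names, spec.pixel_size_um,
                            {"synthetic": True, "seed": spec.seed})
    truth = GroundTruth(
        body_labels=LabelMask(body, kind="instance"),
        nucleus_labels=LabelMask(nucleus, kind="instance"),
        membrane_labels=(LabelMask(membrane, kind="instance")
                         if membrane is not None else None),
        cells=cells,
        dot_mask=dot_mask,
    )
    return mci, truth


def dot_segmentation_dataset(n_images: int = 20, shape=(256, 256),
                             seed: int = 0):
    """Two-class (background / dot) training set for the RNAscope dot task.

    Returns a list of ``(MultiChannelImage, LabelMask)`` pairs, dots rendered
    on noisy background within cell bodies, truth from the generator.
    """
    pairs = []
    for i in range(n_images):
        spec = ImageSpec(shape=shape, n_cells=8, dots_per_cell=("poisson", 25),
                         seed=int(np.random.SeedSequence([seed, i])
                                  .generate_state(1)[0] % (2 ** 31)))
        img, truth = generate_cell_image(spec)
        pairs.append((img, truth.semantic_mask(["background", "dot"])))
    return pairs


# ---------------------------------------------------------------------------
# immunofluorescence cohort
# ---------------------------------------------------------------------------

def generate_if_cohort(
    n_animals: int = 3,
    cells_per_animal: int = 600,
    dat_negative_fraction: float = 0.05,
    lateral_enrichment: float = 7.0,
    gradient_slope: float = -0.3,
    soma_area_ratio: float = 0.6,
    n_sections: int = 8,
    rf_positive_mean: float = 3.0,
    rf_noise_sd: float = 0.25,
    area_positive_um2: float = 195.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell cohort table with planted truth flags.

    Cells are scattered per animal/hemisphere/section across bregma
    -3.9..-2.7 mm.  A marker-negative subpopulation of overall frequency
    ``dat_negative_fraction`` is planted with ``lateral_enrichment``-fold
    higher probability in the lateral tail (planted scaled x > 1.5) and with
    soma areas scaled by ``soma_area_ratio``.  Positive-cell relative
    fluorescence carries a medio-lateral linear gradient of
    ``gradient_slope`` per scaled-x unit.

    Columns include raw coordinates (``x_um``, ``y_um``), ``bregma_mm``,
    per-cell areas and RF values, and the planted truth flags
    ``true_negative`` / ``true_lateral``.
    """
    if not 0 <= dat_negative_fraction <= 1:
        raise ValueError("dat_negative_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bregma_edges = np.linspace(-3.9, -2.7, n_sections + 1)
    bregma_mid = 0.5 * (bregma_edges[:-1] + bregma_edges[1:])
    sd_x, sd_y = 60.0, 45.0  # um scatter within a hemisphere

    # planted lateral tail probability under the Gaussian scatter
    from scipy.stats import norm
    p_lat = float(norm.sf(1.5))
    denom = p_lat * lateral_enrichment + (1.0 - p_lat)
    p_neg_nonlat = dat_negative_fraction / denom
    p_neg_lat = min(1.0, lateral_enrichment * p_neg_nonlat)

    rows = []
    for a in range(n_animals):
        for cell in range(cells_per_animal):
            hemi = "left" if rng.random() < 0.5 else "right"
            sec = int(rng.integers(0, n_sections))
            z_lat = rng.normal()          # planted lateral coordinate, scaled
            y_um = rng.normal(0.0, sd_y)
            # +x is lateral on the right hemisphere, -x on the left
            x_um = z_lat * sd_x if hemi == "right" else -z_lat * sd_x
            lateral = z_lat > 1.5
            p_neg = p_neg_lat if lateral else p_neg_nonlat
            negative = rng.random() < p_neg
            area = rng.normal(
                area_positive_um2 * (soma_area_ratio if negative else 1.0),
                0.08 * area_positive_um2)
            area = max(area, 40.0)
            if negative:
                rf_dat = max(1.0 + abs(rng.normal(0.0, 0.08)), 0.2)
            else:
                rf_dat = max(rf_positive_mean + gradient_slope * z_lat
                             + rng.normal(0.0, rf_noise_sd), 1.4)
            rf_th = max(4.0 + 0.3 * gradient_slope * z_lat
                        + rng.normal(0.0, rf_noise_sd), 1.5)
            rows.append({
                "animal": f"A{a}", "hemisphere": hemi,
                "section": sec, "bregma_mm": float(bregma_mid[sec]),
                "x_um": x_um, "y_um": y_um,
                "area_um2": area,
                "rf_DAT": rf_dat, "rf_TH": rf_th,
                "true_negative": bool(negative),
                "true_lateral": bool(lateral),
                "true_scaled_x": z_lat,
            })
    return pd.DataFrame(rows)


def render_if_section(cohort: pd.DataFrame, shape=(256, 256),
                      background_level: float = 0.05, noise_sd: float = 0.015,
                      pixel_size_um: float = 1.0, seed: int = 0):
    """Render the cells of one (animal, section, hemisphere) group.

    Channels: ``marker`` (TH, intensity = background x rf_TH), ``target``
    (DAT, intensity = background x rf_DAT), ``nuclear``.  Cell radii follow
    the tabulated soma areas.  Returns (image, instance truth masks,
    cell-id -> cohort-row-index map).
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    body = np.zeros((H, W), dtype=np.int32)
    nucleus = np.zeros((H, W), dtype=np.int32)
    marker = np.zeros((H, W))
    target = np.zeros((H, W))
    nuclear = np.zeros((H, W))
    id_map: dict[int, int] = {}

    placed: list[tuple[float, float, float]] = []
    cid = 0
    for row_idx, row in cohort.iterrows():
        r = float(np.sqrt(row.area_um2 / np.pi) / pixel_size_um)
        cx = W / 2.0 + row.x_um / pixel_size_um
        cy = H / 2.0 + row.y_um / pixel_size_um
        m = r + 3
        cx = float(np.clip(cx, m, W - m))
        cy = float(np.clip(cy, m, H - m))
        ok = False
        for _ in range(60):
            if all((cx - ox) ** 2 + (cy - oy) ** 2 >= (r + orr + 3) ** 2
                   for ox, oy, orr in placed):
                ok = True
                break
            cx = float(np.clip(cx + rng.normal(0, 14), m, W - m))
            cy = float(np.clip(cy + rng.normal(0, 14), m, H - m))
        if not ok:
            continue
        placed.append((cx, cy, r))
        cid += 1
        disc = _disc((H, W), (cx, cy), r)
        body[disc] = cid
        # the flat background_level is added afterwards, so total body
        # intensity is background * RF exactly
        marker[disc] = background_level * (row.rf_TH - 1.0)
        target[disc] = background_level * (row.rf_DAT - 1.0)
        ndisc = _disc((H, W), (cx, cy), 0.45 * r)
        nucleus[ndisc] = cid
        nuclear[ndisc] = 0.45
        id_map[cid] = int(row_idx)

    img = np.stack([marker, target, nuclear], axis=2)
    img += background_level
    img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    mci = MultiChannelImage(img, ["marker", "target", "nuclear"],
                            pixel_size_um, {"synthetic": True})
    truth = GroundTruth(
        body_labels=LabelMask(body, kind="instance"),
        nucleus_labels=LabelMask(nucleus, kind="instance"),
        membrane_labels=None,
        cells=[{"id": i, "row": id_map[i]} for i in sorted(id_map)],
        dot_mask=np.zeros((H, W), dtype=bool),
    )
    return mci, truth, id_map


# ---------------------------------------------------------------------------
# stereology series
# ---------------------------------------------------------------------------

def generate_section_series(
    true_total: int,
    n_sections: int = 40,
    profile: str = "uniform",
    params: StereologyParams | None = None,
    seed: int = 0,
) -> tuple[SectionCounts, dict]:
    """Distribute ``true_total`` cells over sections, then thin by sampling.

    ``profile`` shapes the caudo-rostral density: "uniform", or "skewed"
    (density rising linearly along the axis, emulating inhomogeneous cell
    distributions).  Each cell is counted with probability
    ``asf * ssf * h / t``, giving the per-section counts Q_i^-.
    Returns the section series and a truth dict with the per-section totals.
    """
    if true_total < 0:
        raise ValueError("true_total must be >= 0")
    params = params or StereologyParams(t=11.0, h=9.0, asf=0.44, ssf=1.0)
    rng = np.random.default_rng(seed)
    if profile == "uniform":
        w = np.ones(n_sections)
    elif profile == "skewed":
        w = np.linspace(0.2, 1.8, n_sections)
    else:
        raise ValueError("profile must be 'uniform' or 'skewed'")
    w = w / w.sum()
    totals = rng.multinomial(true_total, w)
    p = params.asf * params.ssf * params.h / params.t
    Q = rng.binomial(totals, p)
    counts = SectionCounts(Q=[int(q) for q in Q])
    return counts, {"true_total": int(true_total),
                    "section_totals": totals.tolist(),
                    "sampling_probability": float(p)}
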