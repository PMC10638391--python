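"""Per-cell measurement engines.

From a semantic segmentation this module derives individual cells with their
compartments (body, nucleus, optionally membrane), then measures them:

* RNAscope dot counting per cell body (dots are watershed-split because the
  network output tends to fuse neighbouring dots);
* relative brightfield attenuation per cell, a proxy for neuromelanin
  content, stored both as attenuation (blank region = 0) and as the
  transmission T = I_t / I_i consumed by the neuromelanin model;
* relative fluorescence (RF): compartment mean intensity per unit area
  divided by the section background mean, so RF = 1 means
  background-level signal and RF is invariant under global gain changes;
* quality-control filtering (border contact, size bounds, missing nucleus,
  fragmentation) that flags records without deleting them;
* marker-positive/negative calls by thresholding RF at
  ``background mean + k x background SD`` on the RF scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .fcn import TrainedModel, predict
from .imaging import LabelMask, MultiChannelImage, ROIPolygon
from .postprocess import (BackgroundStats, fill_holes, morph_refine,
                          watershed_split)

__all__ = [
    "CellRecord",
    "MarkerThreshold",
    "QCCriteria",
    "segment_cells",
    "count_dots",
    "measure_bf",
    "measure_rf",
    "qc_filter",
    "classify_marker",
    "marker_threshold_from_background",
    "animal_marker_threshold",
    "body_label_image",
    "DEFAULT_MARKER_K",
]

_STRUCT4 = ndi.generate_binary_structure(2, 1)

# Default SD multipliers per marker: the DAT value is the midpoint of the
# cohort-dependent 1.5-2.5 range.
DEFAULT_MARKER_K = {"DAT": 2.0, "D2": 1.0, "CB": 4.0, "Aldh1A1": 5.0}

SATURATION_FRACTION = 0.01  # compartments above this saturated-pixel share
                            # carry unreliable RF


@dataclass
class CellRecord:
    """One segmented cell with its compartment masks and measurements."""

    cell_id: int
    body_mask: np.ndarray
    nucleus_mask: np.ndarray | None = None
    membrane_mask: np.ndarray | None = None
    section_id: str | int | None = None
    pixel_size_um: float = 1.0
    centroid: tuple[float, float] = (0.0, 0.0)  # (x, y) px
    area_um2: dict = field(default_factory=dict)  # per compartment
    rf: dict = field(default_factory=dict)  # rf[channel][compartment]
    rf_unreliable: dict = field(default_factory=dict)
    dot_count: int | None = None
    dot_total_area_um2: float | None = None
    bf_transmission: float | None = None
    bf_intensity: float | None = None  # relative attenuation, blank = 0
    qc_included: bool = True
    exclusion_reasons: list = field(default_factory=list)
    marker_calls: dict = field(default_factory=dict)

    def compartment(self, name: str) -> np.ndarray | None:
        return {"body": self.body_mask, "nucleus": self.nucleus_mask,
                "membrane": self.membrane_mask}[name]


@dataclass
class MarkerThreshold:
    """RF threshold for a marker: positive iff RF > bg_mean + k * bg_sd."""

    marker: str
    k: float
    bg_mean: float
    bg_sd: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")

    @property
    def threshold(self) -> float:
        return self.bg_mean + self.k * self.bg_sd


def marker_threshold_from_background(bg: BackgroundStats, channel: str,
                                     k: float, marker: str | None = None
                                     ) -> MarkerThreshold:
    """Threshold on the RF scale from one section's background statistics.

    On the RF scale the background mean is 1 by construction and its spread
    is the relative pixel SD of the background.
    """
    mean = bg.mean_of(channel)
    if mean <= 0:
        raise ValueError("zero background mean")
    return MarkerThreshold(marker or channel, k, 1.0, bg.sd_of(channel) / mean)


def _tukey_keep(values: np.ndarray, fence: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - fence * iqr) & (values <= q3 + fence * iqr)


def animal_marker_threshold(section_stats: list[BackgroundStats], channel: str,
                            k: float, marker: str | None = None
                            ) -> MarkerThreshold:
    """Per-animal threshold from its sections' backgrounds.

    Section background means are normalised to the animal mean and Tukey
    fences (1.5 x IQR) drop outlier sections before averaging the relative
    spread.
    """
    means = np.array([s.mean_of(channel) for s in section_stats])
    if np.any(means <= 0):
        raise ValueError("zero background mean in a section")
    rel = means / means.mean()
    keep = _tukey_keep(rel) if len(rel) >= 4 else np.ones(len(rel), bool)
    rel_sd = np.array([s.sd_of(channel) / s.mean_of(channel)
                       for s in section_stats])[keep]
    return MarkerThreshold(marker or channel, k,
                           float(rel[keep].mean()), float(rel_sd.mean()))


# ---------------------------------------------------------------------------
# segmentation -> records
# ---------------------------------------------------------------------------

_DEFAULT_STAGES = (
    {"op": "fill_holes"},
    {"op": "morph", "radius": 2, "sequence": ["erode", "dilate"]},
    {"op": "watershed", "min_peak_distance": 12},
)


def _apply_stages(binary: np.ndarray, stages) -> np.ndarray:
    """Run the configured post-processing stages; returns an instance array."""
    labels = None
    for stage in stages:
        op = stage["op"]
        if op == "morph":
            binary = morph_refine(binary, stage.get("radius", 2),
                                  stage.get("sequence", ["erode", "dilate"]))
        elif op == "fill_holes":
            if labels is None:
                binary = fill_holes(binary)
            else:
                labels = fill_holes(LabelMask(labels, kind="instance")).labels
        elif op == "watershed":
            labels = watershed_split(
                binary, stage.get("min_peak_distance", 10)).labels
        else:
            raise ValueError(f"unknown stage {op!r}")
    if labels is None:
        labels, _ = ndi.label(binary, structure=_STRUCT4)
    return labels


def segment_cells(
    image: MultiChannelImage,
    model: TrainedModel,
    stages=_DEFAULT_STAGES,
    body_class: str = "body",
    nucleus_class: str | None = "nucleus",
    membrane_class: str | None = None,
    interior_classes: tuple[str, ...] = ("dot",),
    exclude_channel: str | None = None,
    section_id=None,
) -> list[CellRecord]:
    """Segment one image into per-cell records (geometry only).

    The semantic prediction (optionally with the target channel zeroed so
    detection is independent of the quantified signal) is refined by the
    configured classical stages, instances are separated, and each nucleus
    is assigned to the body instance containing its centroid.  A membrane
    class, when the model was trained with one, is attached to the enclosing
    body; no membrane marker channel is needed at inference.
    """
    sem, _ = predict(model, image, excluded_channel=exclude_channel)
    classes = sem.class_names
    if body_class not in classes:
        raise ValueError(f"model classes {classes} lack {body_class!r}")
    body_bin = sem.labels == classes.index(body_class)
    if nucleus_class and nucleus_class in classes:
        nuc_bin = sem.labels == classes.index(nucleus_class)
        body_bin = body_bin | nuc_bin  # nuclei sit inside bodies
    else:
        nuc_bin = None
    for name in interior_classes:
        # classes rendered inside the cytoplasm (e.g. RNAscope dots) would
        # otherwise punch holes into the body support
        if name in classes:
            body_bin = body_bin | (sem.labels == classes.index(name))
    mem_bin = (sem.labels == classes.index(membrane_class)
               if membrane_class and membrane_class in classes else None)
    if mem_bin is not None:
        body_bin = body_bin | mem_bin

    labels = _apply_stages(body_bin, stages)
    if labels.max() == 0:
        return []

    nuc_labels = None
    if nuc_bin is not None:
        nuc_labels, _ = ndi.label(nuc_bin, structure=_STRUCT4)

    px_area = image.pixel_size_um ** 2
    records: list[CellRecord] = []
    label_to_idx: dict[int, int] = {}
    new_id = 0
    for prop in regionprops(labels):
        new_id += 1
        label_to_idx[prop.label] = new_id - 1
        body = labels == prop.label
        rec = CellRecord(
            cell_id=new_id, body_mask=body, section_id=section_id,
            pixel_size_um=image.pixel_size_um,
            centroid=(float(prop.centroid[1]), float(prop.centroid[0])),
        )
        rec.area_um2["body"] = float(prop.area) * px_area
        records.append(rec)

    if nuc_labels is not None:
        for nprop in regionprops(nuc_labels):
            cy, cx = nprop.centroid
            owner = labels[int(round(cy)), int(round(cx))]
            if owner == 0:
                continue
            rec = records[label_to_idx[owner]]
            nmask = (nuc_labels == nprop.label) & rec.body_mask
            if not nmask.any():
                continue
            if rec.nucleus_mask is None:
                rec.nucleus_mask = nmask
            else:
                rec.nucleus_mask |= nmask
        for rec in records:
            if rec.nucleus_mask is not None:
                rec.area_um2["nucleus"] = float(rec.nucleus_mask.sum()) * px_area

    if mem_bin is not None:
        mem_labels, _ = ndi.label(mem_bin, structure=_STRUCT4)
        for mprop in regionprops(mem_labels):
            frag = mem_labels == mprop.label
            ring = ndi.binary_dilation(frag, structure=_STRUCT4, iterations=2)
            owners, counts = np.unique(labels[ring & (labels > 0)],
                                       return_counts=True)
            if len(owners) == 0:
                continue
            rec = records[label_to_idx[owners[np.argmax(counts)]]]
            frag = frag & ~(rec.nucleus_mask
                            if rec.nucleus_mask is not None else False)
            if rec.membrane_mask is None:
                rec.membrane_mask = frag
            else:
                rec.membrane_mask |= frag
        for rec in records:
            if rec.membrane_mask is not None:
                rec.area_um2["membrane"] = (float(rec.membrane_mask.sum())
                                            * px_area)
    return records




def body_label_image(records: list[CellRecord], shape) -> np.ndarray:
    """Instance label image rebuilt from record body masks."""
    out = np.zeros(shape, dtype=np.int32)
    for rec in records:
        out[rec.body_mask] = rec.cell_id
    return out


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def count_dots(
    image: MultiChannelImage,
    records: list[CellRecord],
    dot_prediction,
    min_dot_area: int = 2,
    use_watershed: bool = True,
    min_peak_distance: int = 2,
) -> list[CellRecord]:
    """Count target dots per cell body (nucleus included).

    ``dot_prediction`` is the dot-class binary or semantic mask.  Connected
    dot components are split by EDT watershed (fused neighbouring dots carry
    two distance peaks), filtered by ``min_dot_area`` pixels, and assigned
    to the cell whose body contains their centroid; dots outside every cell
    are ignored.  Updates ``dot_count`` and ``dot_total_area_um2`` in place.
    """
    if isinstance(dot_prediction, LabelMask):
        if dot_prediction.kind == "semantic" and dot_prediction.class_names \
                and "dot" in dot_prediction.class_names:
            dot_bin = dot_prediction.labels == \
                dot_prediction.class_names.index("dot")
        else:
            dot_bin = dot_prediction.labels > 0
    else:
        dot_bin = np.asarray(dot_prediction) > 0

    if use_watershed:
        dots = watershed_split(dot_bin, min_peak_distance).labels
    else:
        dots, _ = ndi.label(dot_bin, structure=_STRUCT4)

    bodies = body_label_image(records, dot_bin.shape)
    # body masks include nuclei by construction of segment_cells
    px_area = image.pixel_size_um ** 2
    counts = {rec.cell_id: 0 for rec in records}
    areas = {rec.cell_id: 0.0 for rec in records}
    for prop in regionprops(dots):
        if prop.area < min_dot_area:
            continue
        cy, cx = prop.centroid
        owner = bodies[int(round(cy)), int(round(cx))]
        if owner == 0:
            # centroid between pixels of another region: majority vote
            region = dots == prop.label
            owners, n = np.unique(bodies[region & (bodies > 0)],
                                  return_counts=True)
            if len(owners) == 0:
                continue
            owner = owners[np.argmax(n)]
        counts[owner] += 1
        areas[owner] += float(prop.area) * px_area
    for rec in records:
        rec.dot_count = counts[rec.cell_id]
        rec.dot_total_area_um2 = areas[rec.cell_id]
    return records


def measure_bf(
    image: MultiChannelImage,
    records: list[CellRecord],
    bf_channel: str = "brightfield",
    incident_intensity: float | None = None,
) -> list[CellRecord]:
    """Per-cell brightfield transmission and relative attenuation.

    Transmission T = mean(I_t over the body, nucleus included) / I_i, where
    the incident intensity I_i defaults to the median brightfield value
    outside all cell bodies (a blank-region estimate).  The relative
    attenuation 1 - T is 0 over blank background and grows with pigment
    content.
    """
    bf = image.channel(bf_channel)
    if incident_intensity is None:
        outside = body_label_image(records, bf.shape) == 0
        if not outside.any():
            raise ValueError("no blank region to estimate incident intensity")
        incident_intensity = float(np.median(bf[outside]))
    if incident_intensity <= 0:
        raise ValueError("incident intensity must be positive")
    for rec in records:
        t = float(np.mean(bf[rec.body_mask])) / incident_intensity
        t = float(np.clip(t, 1e-6, 1.0))
        rec.bf_transmission = t
        rec.bf_intensity = 1.0 - t
    return records


def measure_rf(
    image: MultiChannelImage,
    records: list[CellRecord],
    background: BackgroundStats,
    channels=None,
) -> list[CellRecord]:
    """Relative fluorescence per compartment and channel.

    RF = (compartment mean intensity per unit area) / (section background
    mean).  A compartment equal to background has RF 1; the ratio is
    invariant under global gain changes.  A fragmented membrane's RF is the
    area-weighted mean over its fragments, which equals the plain mean over
    their union.  Compartments with more than 1% saturated pixels are
    flagged unreliable.
    """
    channels = list(channels) if channels else list(image.channel_names)
    for ch in channels:
        if background.mean_of(ch) <= 0:
            raise ValueError(f"zero background mean for channel {ch!r}")
    for rec in records:
        for ch in channels:
            plane = image.channel(ch)
            bgm = background.mean_of(ch)
            rec.rf.setdefault(ch, {})
            rec.rf_unreliable.setdefault(ch, {})
            for comp in ("body", "nucleus", "membrane"):
                mask = rec.compartment(comp)
                if mask is None or not mask.any():
                    continue
                vals = plane[mask]
                rec.rf[ch][comp] = float(vals.mean() / bgm)
                rec.rf_unreliable[ch][comp] = bool(
                    np.mean(vals >= 1.0) > SATURATION_FRACTION)
    return records


# ---------------------------------------------------------------------------
# QC and classification
# ---------------------------------------------------------------------------

@dataclass
class QCCriteria:
    """Automated proxies for the manual cell-inclusion check.

    A record is excluded if its body touches the image (or ROI) border, its
    body area leaves [min_area_um2, max_area_um2], it has no nucleus or the
    nucleus overlaps the body by less than ``overlap_min`` of the nucleus
    area, or the body is fragmented (solidity below ``solidity_min``).
    """

    min_area_um2: float = 50.0
    max_area_um2: float = 800.0
    overlap_min: float = 0.5
    solidity_min: float = 0.8
    roi: ROIPolygon | None = None


def qc_filter(records: list[CellRecord],
              criteria: QCCriteria | None = None) -> list[CellRecord]:
    """Flag records violating the inclusion criteria; nothing is deleted."""
    criteria = criteria or QCCriteria()
    for rec in records:
        reasons = []
        body = rec.body_mask
        h, w = body.shape
        if body[0, :].any() or body[-1, :].any() or body[:, 0].any() \
                or body[:, -1].any():
            reasons.append("border")
        if criteria.roi is not None:
            from .imaging import point_in_roi
            if not point_in_roi(criteria.roi, rec.centroid):
                reasons.append("outside_roi")
        area = rec.area_um2.get("body", 0.0)
        if not criteria.min_area_um2 <= area <= criteria.max_area_um2:
            reasons.append("size")
        if rec.nucleus_mask is None or not rec.nucleus_mask.any():
            reasons.append("no_nucleus")
        else:
            overlap = np.sum(rec.nucleus_mask & body) / rec.nucleus_mask.sum()
            if overlap < criteria.overlap_min:
                reasons.append("nucleus_overlap")
        props = regionprops(body.astype(np.int32))
        if props and props[0].solidity < criteria.solidity_min:
            reasons.append("fragmented")
        rec.exclusion_reasons = reasons
        rec.qc_included = not reasons
    return records


def classify_marker(
    records: list[CellRecord],
    threshold: MarkerThreshold,
    channel: str | None = None,
    compartment: str = "body",
) -> list[CellRecord]:
    """Call each cell positive/negative for a marker.

    Positive iff the compartment RF strictly exceeds
    ``bg_mean + k * bg_sd``; an RF exactly at the background mean is
    negative.
    """
    channel = channel or threshold.marker
    thr = threshold.threshold
    for rec in records:
        try:
            rf = rec.rf[channel][compartment]
        except KeyError:
            raise ValueError(
                f"RF for channel {channel!r}/{compartment!r} not computed "
                f"for cell {rec.cell_id}")
        rec.marker_calls[threshold.marker] = (
            "positive" if rf > thr else "negative")
    return records
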