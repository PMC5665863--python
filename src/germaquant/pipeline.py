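"""End-to-end orchestration: stack -> per-cell table + stage report.

Stage order is fixed and logged: detect (coarse 2.5 um spots on the
nuclear stain) -> refine (1.75 um cores at masked centroids) -> QC flags ->
optional manual spot edits -> geometry (canonical rotation, AP coordinate,
region labels) -> intensity measurement -> background estimation and
subtraction -> clone assignment -> depth-bias QC -> normalization -> fate
classification.  Every stage writes its parameters into the report, and
the whole run is deterministic given the config seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import detection, geometry, quant, stats
from .config import RunConfig
from .stack import VoxelStack
from .tables import column_order, new_cell_table, validate_cell_table

log = logging.getLogger("germaquant")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_pipeline(stack: VoxelStack, config: RunConfig, sample_id: str = "sample0",
                 truth=None):
    """Run all stages on one stack; returns ``(cell table, report dict)``.

    ``truth`` (a PhantomTruth) may supply the anterior hint and region
    boundaries when the config says so implicitly (empty boundaries with a
    phantom use the phantom's AP axis only for the hint, never for
    measured values).
    """
    report: dict = {"sample_id": sample_id, "stages": []}
    rng = np.random.default_rng(config.seed)

    def stage(name, fn, **params):
        log.info("stage %s: %s", name, params)
        report["stages"].append({"stage": name, **params})
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, exc) from exc

    coarse = stage(
        "detect",
        lambda: detection.detect_spots(stack, config.nuclear_channel,
                                       config.coarse_diameter_um, config.sensitivity),
        channel=config.nuclear_channel, diameter_um=config.coarse_diameter_um,
        sensitivity=config.sensitivity,
    )
    coarse = stage("manual_edit", lambda: _apply_manual_edits(coarse, config),
                   added=len(config.manual_add_spots), removed=len(config.manual_remove_spots))
    cores = stage("refine",
                  lambda: detection.refine_cores(stack, coarse, config.core_diameter_um),
                  core_diameter_um=config.core_diameter_um)
    excluded = stage("qc_flags",
                     lambda: detection.flag_excluded(stack, cores, config.nuclear_channel),
                     cutoff=3.5)

    centers = cores.centers_um
    hint = np.asarray(config.anterior_hint, dtype=float)

    def _geometry():
        plane = geometry.fit_sagittal_plane(centers)
        frame, transformed = geometry.rotate_to_canonical(centers, plane, hint)
        ap = geometry.assign_ap_coordinate(transformed)
        return frame, transformed, ap

    frame, transformed, ap_um = stage("geometry", _geometry, anterior_hint=hint.tolist())
    regions = stage("regions",
                    lambda: geometry.label_regions(ap_um, config.region_boundaries_um),
                    boundaries=list(config.region_boundaries_um))

    raw = stage("measure", lambda: quant.measure_intensities(stack, cores))
    bg = stage(
        "background",
        lambda: quant.estimate_background(
            stack, centers, config.coarse_diameter_um, config.background_spots,
            config.core_diameter_um, rng=rng),
        n_spots=config.background_spots,
    )
    table = stage("subtract", lambda: quant.subtract_background(raw, bg))

    clone = stage("clones", lambda: _assign_clones(table, config), channel=config.clone_channel)

    def _depth_qc():
        ctrl = clone == "control"
        if ctrl.sum() >= 9:
            return quant.depth_bias_qc(centers[ctrl, 0],
                                       table.loc[ctrl, f"{config.nuclear_channel}_bgsub"],
                                       config.depth_qc_tolerance)
        return quant.depth_bias_qc(centers[:, 0],
                                   table[f"{config.nuclear_channel}_bgsub"],
                                   config.depth_qc_tolerance)

    depth_qc = stage("depth_qc", _depth_qc, tolerance=config.depth_qc_tolerance)

    norm_channels = list(config.marker_channels)
    if config.reporter_channel:
        norm_channels.append(config.reporter_channel)

    def _normalize():
        out = {}
        for ch in norm_channels:
            vals = table[f"{ch}_bgsub"].to_numpy()
            if config.normalization == "max":
                out[ch] = quant.normalize_max(vals, exclude=excluded)
            elif config.normalization == "control":
                out[ch] = quant.normalize_to_control_mean(vals, clone == "control")
            else:  # decay: fit on internal-control cells, divide by prediction
                ctrl = (clone == "control") & ~excluded
                fit = quant.fit_one_phase_decay(ap_um[ctrl], vals[ctrl])
                normed, _ = quant.normalize_to_decay_prediction(vals, ap_um, fit)
                report.setdefault("decay_fits", {})[ch] = fit
                out[ch] = normed
        return out

    normalized = stage("normalize", _normalize, mode=config.normalization,
                       channels=norm_channels)

    # assemble the cell table
    out = new_cell_table(stack.channel_names)
    n = len(cores)
    if n >= 3:
        t1, t2 = np.quantile(centers[:, 0], [1 / 3, 2 / 3])
        depth_band = np.where(centers[:, 0] <= t1, "top",
                              np.where(centers[:, 0] <= t2, "middle", "bottom"))
    else:
        depth_band = ["unassigned"] * n
    rows = {
        "cell_id": cores.spots["id"].to_numpy(),
        "z_um": centers[:, 0], "y_um": centers[:, 1], "x_um": centers[:, 2],
        "core_radius_um": config.core_diameter_um / 2.0,
        "ap_um": ap_um, "region": regions, "clone": clone,
        "qc": ["excluded_division_death" if e else "" for e in excluded],
        "depth_band": depth_band,
        "sample_id": sample_id,
    }
    for ch in stack.channel_names:
        rows[f"{ch}_raw"] = table[f"{ch}_raw"].to_numpy()
        rows[f"{ch}_bgsub"] = table[f"{ch}_bgsub"].to_numpy()
        rows[f"{ch}_norm"] = normalized.get(ch, np.full(n, np.nan))
    cells = pd.DataFrame(rows)[column_order(out)]
    validate_cell_table(cells)

    # fate classification on the two marker channels
    if len(config.marker_channels) >= 2 and n > 0:
        eya_ch, cas_ch = config.marker_channels[:2]
        if config.fate_thresholds is not None:
            thr = tuple(config.fate_thresholds)
        else:
            try:
                thr = stats.auto_thresholds(cells[f"{eya_ch}_norm"], cells[f"{cas_ch}_norm"])
            except ValueError:
                thr = (0.5, 0.5)
        cells["fate"] = stats.classify_fate(
            cells[f"{eya_ch}_norm"].to_numpy(), cells[f"{cas_ch}_norm"].to_numpy(), thr
        )
        report["fate_thresholds"] = thr

    report["frame"] = frame
    report["background"] = bg
    report["depth_qc"] = depth_qc
    report["n_cells"] = n
    return cells, report


def _apply_manual_edits(coarse, config: RunConfig):
    """Represent manual spot editing as add/remove lists from the config."""
    spots = coarse.spots
    if config.manual_remove_spots:
        keep = np.ones(len(spots), dtype=bool)
        centers = coarse.centers_um
        for target in np.asarray(config.manual_remove_spots, dtype=float):
            d = np.linalg.norm(centers - target, axis=1)
            if len(d) and d.min() <= config.manual_remove_radius_um:
                keep[int(np.argmin(d))] = False
        spots = spots[keep].reset_index(drop=True)
    if config.manual_add_spots:
        next_id = int(spots["id"].max()) + 1 if len(spots) else 0
        extra = pd.DataFrame(
            [
                {"id": next_id + i, "z_um": z, "y_um": y, "x_um": x,
                 "diameter_um": coarse.diameter_um, "score": np.nan}
                for i, (z, y, x) in enumerate(np.asarray(config.manual_add_spots, float))
            ]
        )
        spots = pd.concat([spots, extra], ignore_index=True)
    return detection.SpotSet(spots, "coarse", coarse.source_channel, coarse.diameter_um)


def _assign_clones(table: pd.DataFrame, config: RunConfig) -> np.ndarray:
    """Label cells mutant/control from the clone-marker channel.

    The clone marker is bimodal (present in clones, or lost from clones
    when the marker is a ubi-RFP/GFP that homozygous mutant cells lack);
    cells are split at the midpoint of the 10th-90th percentile spread,
    with the polarity flag deciding which side is mutant.
    """
    n = len(table)
    if not config.clone_channel or f"{config.clone_channel}_bgsub" not in table:
        return np.array(["unassigned"] * n, dtype=object)
    v = table[f"{config.clone_channel}_bgsub"].to_numpy()
    lo, hi = np.percentile(v, [10, 90])
    if hi - lo < 1e-9:
        return np.array(["control"] * n, dtype=object)
    marked = v > (lo + hi) / 2.0
    mutant = marked if config.clone_polarity == "positive" else ~marked
    return np.where(mutant, "mutant", "control").astype(object)
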