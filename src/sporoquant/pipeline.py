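"""Config-driven pipeline tying simulation and analysis stages together.

Each stage reads/writes files under the run's output directory; the resolved
configuration is written next to the outputs, and every result CSV records
the seed and tool version, so a rerun with the same config and seed produces
byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import logging
import sys
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import foci as foci_mod
from . import morphometry, nucleoid, photokinetics, simulate
from .core import SporoquantError
from .iotools import (
    RunConfig,
    read_image_stack,
    read_traces_csv,
    write_image_stack,
    write_result_csv,
    write_traces_csv,
)

__all__ = ["run_pipeline", "STAGES"]

log = logging.getLogger("sporoquant")


def _imaging(params: dict[str, Any]) -> simulate.ImagingConfig:
    fields = {f.name for f in dataclasses.fields(simulate.ImagingConfig)}
    return simulate.ImagingConfig(**{k: v for k, v in params.items() if k in fields})


def _spec(cls, params: dict[str, Any]):
    fields = {f.name for f in dataclasses.fields(cls)}
    return cls(**{k: v for k, v in params.items() if k in fields})


def _ground_truth_frame(truth) -> pd.DataFrame:
    rows = []
    for s in truth.spores:
        rows.append({"object_id": s.spore_id, "type": "spore", "length_um": s.length_um,
                     "mode": s.nucleoid_mode, "position_um": "", "seed": truth.seed})
    for ch, axial in truth.foci_axial_um.items():
        for i, pos in enumerate(axial):
            rows.append({"object_id": i, "type": f"focus_{ch}", "length_um": "",
                         "mode": "", "position_um": pos, "seed": truth.seed})
    return pd.DataFrame(
        rows, columns=["object_id", "type", "length_um", "mode", "position_um", "seed"]
    )


def stage_simulate_chain(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    spec = _spec(simulate.SporeChainSpec, params)
    stack, truth = simulate.simulate_spore_chain(spec, _imaging(params), seed=cfg.seed)
    write_image_stack(stack, out / "chain.tiff")
    write_result_csv(_ground_truth_frame(truth), out / "chain_ground_truth.csv", seed=cfg.seed)


def stage_simulate_foci(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    spec = _spec(simulate.FociFieldSpec, params)
    n_hyphae = int(params.get("n_hyphae", 1))
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for h in range(n_hyphae):
        stack, truth = simulate.simulate_foci_hypha(
            spec, _imaging(params), seed=int(rng.integers(2**31))
        )
        write_image_stack(stack, out / f"hypha_{h:03d}.tiff")
        df = _ground_truth_frame(truth)
        df.insert(0, "hypha_id", h)
        frames.append(df)
    write_result_csv(pd.concat(frames, ignore_index=True),
                     out / "foci_ground_truth.csv", seed=cfg.seed)


def stage_simulate_fret(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    spec = _spec(simulate.PhotobleachSpec, params)
    n = int(params.get("n_series", 1))
    rng = np.random.default_rng(cfg.seed)
    traces = []
    for i in range(n):
        tr = simulate.simulate_fretap_series(spec, seed=int(rng.integers(2**31)))
        tr.roi_id = f"donor_{i:03d}"
        traces.append(tr)
    write_traces_csv(traces, out / "fret_traces.csv")


def stage_simulate_frap(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    spec = _spec(simulate.PhotobleachSpec, params)
    n = int(params.get("n_series", 1))
    rng = np.random.default_rng(cfg.seed)
    traces = []
    for i in range(n):
        bleached, reference = simulate.simulate_frap_series(spec, seed=int(rng.integers(2**31)))
        bleached.roi_id = f"bleached_{i:03d}"
        reference.roi_id = f"reference_{i:03d}"
        traces += [bleached, reference]
    write_traces_csv(traces, out / "frap_traces.csv")


def _segment(params: dict[str, Any], stack) -> morphometry.LabeledRegions:
    seg = _spec(morphometry.SegmentationParams, params)
    return morphometry.segment_spores(stack.channel("membrane"), seg)


def stage_measure(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    stack = read_image_stack(out / params.get("image", "chain.tiff"))
    regions = _segment(params, stack)
    sample = morphometry.measure_spore_lengths(
        regions, stack.pixel_size_nm, strain_id=params.get("strain", "")
    )
    centroids = regions.centroids_px()
    df = pd.DataFrame({
        "spore_id": regions.labels,
        "length_um": sample.lengths_um,
        "area_px": regions.areas_px(),
        "centroid_row": centroids[:, 0],
        "centroid_col": centroids[:, 1],
    })
    write_result_csv(df, out / "spore_lengths.csv", seed=cfg.seed)
    if sample.n:
        summary = morphometry.summarize_lengths(sample)
        write_result_csv(
            pd.DataFrame([{"strain": sample.strain_id, "n": summary.n,
                           "mean_um": summary.mean, "sd_um": summary.sd,
                           "sem_um": summary.sem}]),
            out / "spore_length_summary.csv", seed=cfg.seed,
        )


def stage_profile(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    stack = read_image_stack(out / params.get("image", "chain.tiff"))
    regions = _segment(params, stack)
    clf = _spec(nucleoid.RimClassifierParams, params)
    profiles, calls = [], []
    for lab in regions.labels:
        try:
            prof = nucleoid.extract_axial_profile(stack.channel("dna"), regions, lab)
        except nucleoid.ProfileError:
            continue
        profiles.append(prof)
        calls.append(nucleoid.classify_rim_localization(prof, clf))
    write_result_csv(
        pd.DataFrame([{"spore_id": c.spore_id, "call": c.call,
                       "dip_depth": c.dip_depth, "n_maxima": c.n_maxima} for c in calls]),
        out / "rim_calls.csv", seed=cfg.seed,
    )
    if profiles:
        mat = pd.DataFrame(
            [p.intensities for p in profiles],
            index=pd.Index([p.spore_id for p in profiles], name="spore_id"),
            columns=[f"x{i:03d}" for i in range(nucleoid.N_PROFILE_POINTS)],
        )
        write_result_csv(mat.reset_index(), out / "profiles.csv", seed=cfg.seed)
        avg = nucleoid.average_profiles(profiles)
        write_result_csv(
            pd.DataFrame({"position": avg.positions, "intensity": avg.intensities}),
            out / "profile_mean.csv", seed=cfg.seed,
        )
        frac = nucleoid.rim_fraction(calls)
        write_result_csv(
            pd.DataFrame([dataclasses.asdict(frac)]), out / "rim_fraction.csv", seed=cfg.seed
        )


def stage_foci(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    det = _spec(foci_mod.FocusDetectionParams, params)
    channel = params.get("channel", "fusion_a")
    images = sorted(out.glob(params.get("pattern", "hypha_*.tiff")))
    sets, rows = [], []
    for h, img in enumerate(images):
        stack = read_image_stack(img)
        fs = foci_mod.detect_foci(stack.channel(channel), stack.pixel_size_nm, det, channel)
        sets.append(fs)
        for i in range(fs.n):
            rows.append({"hypha_id": h, "channel": channel, "focus_index": i,
                         "row": fs.positions_px[i, 0], "col": fs.positions_px[i, 1],
                         "axial_um": fs.axial_um[i], "peak_intensity": fs.peak_intensity[i]})
    write_result_csv(pd.DataFrame(rows, columns=["hypha_id", "channel", "focus_index",
                                                 "row", "col", "axial_um", "peak_intensity"]),
                     out / "foci.csv", seed=cfg.seed)
    if sets:
        st = foci_mod.foci_spacing_stats(sets)
        write_result_csv(pd.DataFrame([dataclasses.asdict(st)]),
                         out / "foci_spacing.csv", seed=cfg.seed)


def stage_coloc(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    det = _spec(foci_mod.FocusDetectionParams, params)
    tol = float(params.get("tolerance_nm", 200.0))
    rows = []
    for h, img in enumerate(sorted(out.glob(params.get("pattern", "hypha_*.tiff")))):
        stack = read_image_stack(img)
        a = foci_mod.detect_foci(stack.channel("fusion_a"), stack.pixel_size_nm, det, "fusion_a")
        b = foci_mod.detect_foci(stack.channel("fusion_b"), stack.pixel_size_nm, det, "fusion_b")
        res = foci_mod.colocalization_overlap(a, b, tolerance_nm=tol)
        rows.append({"frame_id": h, "overlap_percent_a": res.percent_a,
                     "overlap_percent_b": res.percent_b, "tolerance_nm": tol})
    write_result_csv(pd.DataFrame(rows), out / "colocalization.csv", seed=cfg.seed)


def stage_fret(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    traces = read_traces_csv(out / params.get("traces", "fret_traces.csv"))
    results = [photokinetics.fretap_efficiency(t) for t in traces]
    df = pd.DataFrame([{"roi_id": r.roi_id, "i_pre": r.i_pre, "i_post": r.i_post,
                        "ratio": r.ratio, "efficiency": r.efficiency} for r in results])
    write_result_csv(df, out / "fret_results.csv", seed=cfg.seed)
    agg = photokinetics.aggregate_fret(results)
    write_result_csv(
        pd.DataFrame([{"pair": params.get("pair", ""), "average": agg.mean_ratio,
                       "standard_deviation": agg.sd, "n": agg.n,
                       "p_vs_control": agg.p_vs_control}]),
        out / "fret_summary.csv", seed=cfg.seed,
    )


def stage_frap(cfg: RunConfig, params: dict[str, Any], out: Path) -> None:
    traces = {t.roi_id: t for t in read_traces_csv(out / params.get("traces", "frap_traces.csv"))}
    rows = []
    for roi_id, tr in traces.items():
        if not roi_id.startswith("bleached"):
            continue
        ref = traces.get(roi_id.replace("bleached", "reference"))
        corrected = photokinetics.bleach_correct(tr, ref) if ref is not None else tr
        fit = photokinetics.fit_frap(corrected)
        rows.append({"roi_id": roi_id, "k_per_s": fit.k_per_s,
                     "t_half_s": fit.t_half_s if fit.converged else float("nan"),
                     "mobile_fraction": fit.mobile_fraction, "rss": fit.rss,
                     "converged": fit.converged})
    write_result_csv(pd.DataFrame(rows), out / "frap_fits.csv", seed=cfg.seed)


STAGES: dict[str, Callable[[RunConfig, dict[str, Any], Path], None]] = {
    "simulate-chain": stage_simulate_chain,
    "simulate-foci": stage_simulate_foci,
    "simulate-fret": stage_simulate_fret,
    "simulate-frap": stage_simulate_frap,
    "measure": stage_measure,
    "profile": stage_profile,
    "foci": stage_foci,
    "coloc": stage_coloc,
    "fret": stage_fret,
    "frap": stage_frap,
}


def run_pipeline(config: RunConfig) -> int:
    """Execute the configured stages in order; returns a process exit status.

    A stage failure logs the stage name and aborts with status 1.  The
    resolved configuration is written to ``config_resolved.yaml`` in the
    output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "config_resolved.yaml")
    for entry in config.stages:
        name = entry["stage"]
        if name not in STAGES:
            log.error("unknown stage %r (known: %s)", name, ", ".join(STAGES))
            return 1
        params = {k: v for k, v in entry.items() if k != "stage"}
        log.info("running stage %s", name)
        try:
            STAGES[name](config, params, out)
        except (SporoquantError, OSError) as exc:
            log.error("stage %s failed: %s", name, exc)
            return 1
    return 0
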