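"""End-to-end orchestration of the two analysis chains.

``run_demo`` executes both chains on synthetic data with one seed and
writes every intermediate table plus a plain-text report; with a fixed
seed the whole output directory is byte-identical across runs, which is
the package's provenance guarantee.
"""

from __future__ import annotations

import hashlib
import logging
import os

from . import io as _io
from .calcium_events import bin_high_events, detect_events, label_events
from .config import RunConfig, save_config
from .response_analysis import classify_response, extract_features, population_summary
from .synth_calcium import generate_population
from .synth_imaging import simulate_titration
from .uncaging_quant import analyze_titration, quantify_stack

__all__ = ["run_demo", "run_uncaging_chain", "run_calcium_chain"]

logger = logging.getLogger("uncagekit")


def _stage(name: str):
    logger.info("stage=%s", name)


def run_uncaging_chain(config: RunConfig, out_dir: str) -> dict:
    """Simulate a laser titration, quantify every level, pick the optimum.

    Quantification uses the generative label masks (the pass-through path
    of the segmenter), so the demo isolates the photochemistry readout
    from segmentation error; ``segment_compartments`` remains available
    for real data.
    """
    _stage("simulate-titration")
    series = simulate_titration(
        config.scene,
        config.reaction,
        list(config.titration.laser_levels),
        config.titration.dose_per_percent,
        n_scans=config.titration.n_scans,
        n_pre=config.windows.n_pre_frames,
        n_post=config.windows.n_post_frames,
        seed=config.seed,
    )
    _stage("quantify-uncaging")
    results = []
    truths = []
    for i, (stack, masks, truth) in enumerate(series):
        _io.write_stack(
            os.path.join(out_dir, f"stack_level{i}.tif"),
            stack,
            extra_meta={
                "truth_pm_fluorescent": float(truth["pm"].fluorescent),
                "truth_ves_fluorescent": float(truth["vesicle"].fluorescent),
            },
        )
        _io.write_masks(os.path.join(out_dir, f"masks_level{i}.tif"), masks)
        results.append(
            quantify_stack(
                stack,
                masks,
                n_post=config.windows.dF_post_frames,
                completeness_threshold=config.windows.completeness_threshold,
            )
        )
        truths.append(truth)
    _stage("titrate")
    report = analyze_titration(results)
    _io.write_titration_csv(os.path.join(out_dir, "titration.csv"), report)
    return {"report": report, "truths": truths}


def run_calcium_chain(config: RunConfig, out_dir: str) -> dict:
    """Simulate a calcium population, detect/label/bin events, classify cells."""
    _stage("simulate-traces")
    mix = config.calcium_mix.as_mix()
    traces, truths = generate_population(
        mix, config.calcium_mix.n_cells, config.population, seed=config.seed
    )
    _io.write_traces_csv(os.path.join(out_dir, "traces.csv"), traces)

    _stage("detect-events")
    t0 = config.population.base.uncaging_time_s
    events_per_cell = {}
    labelled_per_cell = []
    for trace in traces:
        events = label_events(
            detect_events(trace, config.detection), config.detection.high_threshold
        )
        events_per_cell[trace.cell_id] = events
        labelled_per_cell.append(events)
    _io.write_events_csv(os.path.join(out_dir, "events.csv"), events_per_cell)

    binned = bin_high_events(
        labelled_per_cell,
        t0,
        bin_s=config.windows.bin_s,
        pre_s=config.windows.pre_window_s,
        post_s=config.windows.post_window_s,
    )
    _io.write_binned_csv(os.path.join(out_dir, "binned_counts.csv"), binned)

    _stage("classify-responses")
    classes = []
    for trace in traces:
        features = extract_features(trace, events_per_cell[trace.cell_id], t0)
        classes.append(classify_response(features, config.thresholds))
    summary = population_summary(classes, binned, t0_s=t0)
    _io.dump_yaml(os.path.join(out_dir, "population_summary.yaml"), summary)
    return {
        "traces": traces,
        "truths": truths,
        "events": events_per_cell,
        "binned": binned,
        "classes": classes,
        "summary": summary,
    }


def run_demo(config: RunConfig | None = None, seed: int | None = None, out_dir: str | None = None) -> dict:
    """Run both chains end to end and write a deterministic report bundle."""
    config = config or RunConfig()
    if seed is not None:
        import dataclasses

        config = dataclasses.replace(config, seed=seed)
    out_dir = out_dir or config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    save_config(os.path.join(out_dir, "config.yaml"), config)

    try:
        uncaging = run_uncaging_chain(config, out_dir)
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        raise RuntimeError(f"stage uncaging-chain failed: {exc}") from exc
    try:
        calcium = run_calcium_chain(config, out_dir)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage calcium-chain failed: {exc}") from exc

    report_path = os.path.join(out_dir, "report.txt")
    _write_report(report_path, config, uncaging, calcium)
    return {"uncaging": uncaging, "calcium": calcium, "report_path": report_path}


def _write_report(path: str, config: RunConfig, uncaging: dict, calcium: dict) -> None:
    rep = uncaging["report"]
    lines = [
        "uncagekit demo report",
        f"seed: {config.seed}",
        "",
        "[uncaging titration]",
        "level  dF_pm   dF_ves  ratio   remaining_pm  complete",
    ]
    for r in rep.results:
        lines.append(
            f"{r.laser_level:5.1f}  {r.dF_pm.value:.4f}  {r.dF_ves.value:.4f}  "
            f"{r.efficiency_ratio:6.3f}  {r.remaining_pm:.4f}        {r.complete}"
        )
    lines += [
        f"complete_levels: {list(rep.complete_levels)}",
        f"optimal_level: {rep.optimal_level}",
        "",
        "[calcium population]",
        f"n_cells: {calcium['summary']['n_cells']}",
    ]
    for cls, info in calcium["summary"]["class_fractions"].items():
        lines.append(f"{cls:22s} {info['count']:4d}  ({info['fraction']:.3f})")
    b = calcium["summary"]["binned"]
    lines += [
        f"welch pre-vs-post high counts: t={b['welch_t']:.4f} df={b['welch_df']:.2f} p={b['welch_p']:.4g}",
        "",
    ]
    text = "\n".join(lines)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    logger.info("report sha256=%s", hashlib.sha256(text.encode()).hexdigest())
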