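"""Reproducible end-to-end runs: simulate -> classify -> score -> quantify -> compare.

A single :class:`RunConfig` drives one run; every output (per-cell CSV,
counts CSV, SiSc CSV, ROI-measure CSV, stats JSON) lands in the run
directory together with a manifest echoing the full config, its hash, the
seed and package versions, so identical config+seed reproduces identical
CSV content.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifyParams, classify_stack, tabulate
from .densitometry import calibrate_thresholds, measure_mosaic, map2_area_check
from .io import read_counts, read_rois, read_stack, write_stack, write_truth
from .simulate import (SimConfig, default_roi_layout, render_mosaic, render_stack,
                       simulate_labels, ROI_NAMES)
from .sisc import CellCounts, sisc_table
from .stats import two_way_anova

__all__ = ["RunConfig", "run", "experiment_3x3"]

MODES = ("simulate", "stacks", "counts_csv")


@dataclass
class RunConfig:
    """One run's full parameterization; round-trips through JSON."""

    mode: str = "simulate"
    outdir: str = "arcfish_run"
    seed: int = 0
    # simulate mode
    sim: SimConfig = field(default_factory=SimConfig)
    simulate_mosaic: bool = True
    mosaic_fractions: Optional[dict] = None
    # stacks mode
    stack_paths: tuple[str, ...] = ()
    roi_path: Optional[str] = None
    mosaic_path: Optional[str] = None
    # counts_csv mode
    counts_path: Optional[str] = None
    # analysis knobs
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    enlargement: float = 0.10
    posthoc: str = "bonferroni"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "stacks" and not self.stack_paths:
            raise ValueError("stacks mode requires stack_paths")
        if self.mode == "counts_csv" and not self.counts_path:
            raise ValueError("counts_csv mode requires counts_path")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["sim"] = SimConfig(**{**d["sim"],
                                "stack_shape": tuple(d["sim"]["stack_shape"])})
        d["classify"] = ClassifyParams(**d["classify"])
        d["stack_paths"] = tuple(d.get("stack_paths", ()))
        return cls(**d)


def _records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "cell_id": r.cell_id, "z": r.centroid[0], "y": r.centroid[1],
            "x": r.centroid[2], "volume": r.volume, "is_neuron": r.is_neuron,
            "n_focus_tracks": len(r.focus_spans),
            "max_focus_span": max(r.focus_spans, default=0),
            "max_coverage": float(np.max(r.coverage)) if r.coverage is not None else 0.0,
            "label": r.label,
        })
    return pd.DataFrame(rows)


def run(config: RunConfig) -> Path:
    """Execute one run; returns the run directory path."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exclusions: list[dict] = []

    counts_rows: list[CellCounts] = []
    cells_frames: list[pd.DataFrame] = []

    if config.mode == "simulate":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        truth = simulate_labels(sim)
        write_truth(outdir / "truth.csv", truth)
        stack = render_stack(truth, sim)
        write_stack(outdir / "stack.tif", stack)
        records = classify_stack(stack, config.classify)
        cells_frames.append(_records_frame(records))
        counts_rows.append(tabulate(records, animal_id="sim01", region="CA1",
                                    condition="AA", pretreatment="WM"))
    elif config.mode == "stacks":
        for i, p in enumerate(config.stack_paths):
            stack = read_stack(p)
            records = classify_stack(stack, config.classify)
            df = _records_frame(records)
            df.insert(0, "stack", Path(p).name)
            cells_frames.append(df)
            counts_rows.append(tabulate(records, animal_id=f"stack{i:02d}", region="CA1"))
    else:  # counts_csv
        df = read_counts(config.counts_path)
        for row in df.itertuples(index=False):
            counts_rows.append(CellCounts(
                neg=int(row.neg), nuc=int(row.nuc), cyt=int(row.cyt), dob=int(row.dob),
                animal_id=str(row.animal_id), region=str(row.region),
                condition=str(row.condition), pretreatment=str(row.pretreatment)))

    cells = pd.concat(cells_frames, ignore_index=True) if cells_frames else pd.DataFrame()
    cells.to_csv(outdir / "cells.csv", index=False)
    counts_df = pd.DataFrame([{
        "animal_id": c.animal_id, "region": c.region, "condition": c.condition,
        "pretreatment": c.pretreatment, "neg": c.neg, "nuc": c.nuc,
        "cyt": c.cyt, "dob": c.dob, "total": c.total} for c in counts_rows])
    counts_df.to_csv(outdir / "counts.csv", index=False)

    sisc = sisc_table(counts_rows)
    for row in sisc[~sisc["defined"]].itertuples(index=False):
        exclusions.append({"unit": f"{row.animal_id}/{row.region}",
                           "reason": "undefined SiSc (leastEpoch == p(E1E2))"})
    sisc.to_csv(outdir / "sisc.csv", index=False)

    # densitometry leg
    roi_df = pd.DataFrame()
    if config.mode == "simulate" and config.simulate_mosaic:
        rois = default_roi_layout()
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(3,)))
        fractions = config.mosaic_fractions or {
            name: float(np.round(rng.uniform(5, 40), 1)) for name in ROI_NAMES}
        mosaic, _ = render_mosaic(rois, fractions, seed=config.seed,
                                  enlargement=config.enlargement)
        thr = calibrate_thresholds(mosaic, rois, image_id="sim-control")
        roi_df = measure_mosaic(mosaic, rois, thr, enlargement=config.enlargement,
                                animal_id="sim01", pretreatment="WM")
    elif config.mode == "stacks" and config.mosaic_path and config.roi_path:
        from .densitometry import Mosaic
        import tifffile
        arr = tifffile.imread(config.mosaic_path)
        mosaic = Mosaic(arr)
        rois = read_rois(config.roi_path)
        thr = calibrate_thresholds(mosaic, rois, image_id=Path(config.mosaic_path).name)
        roi_df = measure_mosaic(mosaic, rois, thr, enlargement=config.enlargement)
    roi_df.to_csv(outdir / "roi_measures.csv", index=False)

    stats_out: dict = {"n_units": len(counts_rows),
                       "mean_sisc": float(sisc["sisc"].mean()) if len(sisc) else None}
    if not roi_df.empty and roi_df["pretreatment"].nunique() > 1:
        stats_out["map2_area_check"] = map2_area_check(roi_df).to_dict("records")
    (outdir / "stats.json").write_text(json.dumps(stats_out, indent=1))

    config_json = config.to_json()
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "arcfish_version": __version__,
        "excluded_units": exclusions,
        "outputs": ["cells.csv", "counts.csv", "sisc.csv", "roi_measures.csv", "stats.json"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def experiment_3x3(kappa: dict, n_animals: int = 4, n_cells: int = 1000,
                   p1: float = 0.3, p2: float = 0.3, seed: int = 0,
                   glia_fraction: float = 0.0) -> dict:
    """Simulate the pretreatment x condition design at the label level.

    ``kappa`` maps pretreatment -> {condition -> overlap}; each of the
    ``n_animals`` per cell gets an independent population of ``n_cells``
    neurons, one SiSc per animal.  Returns per-animal rows, the cell
    means +/- s.e.m., and the two-way ANOVA (pretreatment, condition).
    """
    from .simulate import counts_from_truth

    rows = []
    n_sims = sum(len(conds) for conds in kappa.values()) * n_animals
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(4,))
    child_seeds = ss.generate_state(max(1, n_sims))
    i = 0
    for pre, conds in kappa.items():
        for cond, k in conds.items():
            for a in range(n_animals):
                sim = SimConfig(n_cells=n_cells, p1=p1, p2=p2, kappa=float(k),
                                glia_fraction=glia_fraction,
                                seed=int(child_seeds[i] % (2**31 - 1)))
                i += 1
                truth = simulate_labels(sim, place=False)
                counts = counts_from_truth(
                    truth, animal_id=f"{pre}-{cond}-{a}", region="CA1",
                    condition=cond, pretreatment=pre)
                from .sisc import similarity_score
                r = similarity_score(counts)
                rows.append({"pretreatment": pre, "condition": cond,
                             "animal_id": counts.animal_id, "sisc": r.sisc,
                             "defined": r.defined})
    table = pd.DataFrame(rows)
    defined = table[table["defined"]].copy()
    summary = (defined.groupby(["pretreatment", "condition"])["sisc"]
               .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="size")
               .reset_index())
    if len(defined) < len(table):
        anova = None  # undefined-score units dropped -> design no longer balanced
    else:
        anova = two_way_anova(defined.rename(columns={"sisc": "value"}),
                              "pretreatment", "condition")
    return {"table": table, "summary": summary, "anova": anova}
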