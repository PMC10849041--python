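"""End-to-end reproducible pipeline: simulate → assign → distribute →
cluster → ephys → stats, with a run manifest.

The run is driven by a single declarative JSON config (validated with
pydantic).  Analysis constants (edge threshold, cluster threshold, bins,
region bounds) all live in the config with their standard defaults; nothing
numeric is hard-coded in the stages.  Every output directory carries exactly
one ``manifest.json`` recording the config snapshot, input digests, package
version, and seeds, so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .config import AnalysisConfig
from .morphology import CellLabel, read_swc, write_swc
from .puncta import Channel, filter_inputs
from .spatial import cluster_summary, coloc_vs_chance, distribution_summary
from .inference import ComparisonSpec, Design, select_and_run, summarize
from .ephys import classify_cell, extract_features
from .synth import GenerationParams, simulate_cell
from . import io as smio

logger = logging.getLogger(__name__)


class AnalysisSection(BaseModel):
    edge_threshold: float = Field(0.5, gt=0)
    cluster_threshold: float = Field(5.0, gt=0)
    bin_width: float = Field(10.0, gt=0)
    proximal_max: float = Field(30.0, gt=0)
    medial_max: float = Field(100.0, gt=0)
    coloc_threshold_vglut: float = Field(0.5, gt=0)

    @field_validator("medial_max")
    @classmethod
    def _ordered(cls, v, info):
        if "proximal_max" in info.data and v <= info.data["proximal_max"]:
            raise ValueError("medial_max must exceed proximal_max")
        return v

    def to_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            edge_threshold=self.edge_threshold,
            cluster_threshold=self.cluster_threshold,
            bin_width=self.bin_width,
            region_bounds=(self.proximal_max, self.medial_max),
            coloc_threshold_vglut=self.coloc_threshold_vglut,
        )


class RunConfig(BaseModel):
    seed: int = 0
    cell_type: str = "SPN"
    n_cells: int = Field(3, ge=1)
    analysis: AnalysisSection = AnalysisSection()
    generator_overrides: dict = {}

    @field_validator("cell_type")
    @classmethod
    def _cell_type(cls, v):
        if v.upper() not in ("SPN", "FSI"):
            raise ValueError("cell_type must be SPN or FSI")
        return v.upper()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.model_validate(json.loads(Path(path).read_text()))


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> Path:
    """Execute all stages for a simulated cohort; returns the output dir."""
    config_path = Path(config_path)
    rc = load_config(config_path)
    cfg = rc.analysis.to_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_log: dict[str, dict] = {}

    def _stage(name):
        def deco(fn):
            def wrapped(*a, **k):
                t0 = time.time()
                try:
                    r = fn(*a, **k)
                except Exception as err:  # partial outputs stay on disk
                    raise StageError(name, err) from err
                stage_log[name] = {"seconds": round(time.time() - t0, 3)}
                return r

            return wrapped

        return deco

    @_stage("simulate")
    def simulate():
        cells = []
        for i in range(rc.n_cells):
            p = GenerationParams.for_cell_type(rc.cell_type, seed=rc.seed * 1000 + i, **rc.generator_overrides)
            m, puncta, sweeps, gt = simulate_cell(p, cfg)
            cdir = out / "cells" / f"cell_{i:02d}"
            cdir.mkdir(parents=True, exist_ok=True)
            write_swc(m, cdir / "morphology.swc")
            smio.write_puncta_csv(puncta, cdir / "puncta.csv")
            smio.write_sweeps_csv(sweeps, cdir / "sweeps.csv", cdir / "sweeps_meta.csv")
            gt.to_json(cdir / "ground_truth.json")
            cells.append((m, puncta, sweeps, gt, cdir))
        return cells

    cells = simulate()

    @_stage("assign")
    def assign():
        assigned = []
        for m, puncta, _sweeps, _gt, cdir in cells:
            inputs = filter_inputs([p for p in puncta if p.channel is not Channel.VGLUT1], m, cfg)
            smio.write_assignments_tsv(inputs, cdir / "assignments.tsv")
            assigned.append(inputs)
        return assigned

    assigned = assign()

    @_stage("distribute")
    def distribute():
        rows = []
        for i, inputs in enumerate(assigned):
            ds = distribution_summary(inputs, cfg)
            for ch in (Channel.M1, Channel.S1):
                cs = ds.per_channel[ch]
                rows.append(
                    dict(
                        cell=i,
                        channel=ch.value,
                        count=cs.count,
                        proportion_pct=cs.proportion_pct,
                        mean_soma_path_um=cs.mean_soma_path_distance,
                        ratio_m1_s1=ds.ratio_m1_s1,
                    )
                )
        df = pd.DataFrame(rows)
        df.to_csv(out / "distribution.tsv", sep="\t", index=False)
        return df

    dist_df = distribute()

    @_stage("cluster")
    def cluster():
        rows = []
        for i, inputs in enumerate(assigned):
            csum = cluster_summary(inputs, cfg)
            rows.append(
                dict(
                    cell=i,
                    nn_m1_m1_um=csum.nn_same[Channel.M1],
                    nn_s1_s1_um=csum.nn_same[Channel.S1],
                    nn_m1_to_s1_um=csum.nn_cross[(Channel.M1, Channel.S1)],
                    nn_s1_to_m1_um=csum.nn_cross[(Channel.S1, Channel.M1)],
                    s1_coloc_frac=csum.coloc_fraction_at_threshold[Channel.S1],
                    m1_coloc_frac=csum.coloc_fraction_at_threshold[Channel.M1],
                )
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "cluster.tsv", sep="\t", index=False)
        return df

    clus_df = cluster()

    @_stage("ephys")
    def ephys():
        rows = []
        for i, (_m, _p, sweeps, _gt, _cdir) in enumerate(cells):
            fs = extract_features(sweeps)
            rows.append(
                dict(
                    cell=i,
                    mean_hhw_ms=fs.mean_hhw,
                    mean_iff_hz=fs.mean_iff,
                    mff_hz=fs.mff,
                    rmp_mv=fs.rmp,
                    input_resistance_mohm=fs.input_resistance,
                    steady_state=fs.steady_state,
                    classified=classify_cell(fs).value,
                )
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "ephys.tsv", sep="\t", index=False)
        return df

    ephys_df = ephys()

    @_stage("stats")
    def stats_stage():
        results = {}
        m1 = dist_df.query("channel == 'M1'")["count"].to_numpy(dtype=float)
        s1 = dist_df.query("channel == 'S1'")["count"].to_numpy(dtype=float)
        if len(m1) >= 3:
            tr = select_and_run(m1, s1, ComparisonSpec(design=Design.PAIRED))
            results["m1_vs_s1_counts"] = dict(test=tr.test_name, statistic=tr.statistic, p=tr.p_value)
            ratios = dist_df.query("channel == 'M1'")["ratio_m1_s1"].dropna().to_numpy(dtype=float)
            if len(ratios) >= 3:
                tr = select_and_run(ratios, None, ComparisonSpec(design=Design.ONE_SAMPLE, null_value=1.0))
                results["ratio_vs_1"] = dict(test=tr.test_name, statistic=tr.statistic, p=tr.p_value)
            fr = clus_df["s1_coloc_frac"].dropna().to_numpy(dtype=float) * 100.0
            if len(fr) >= 3:
                tr = select_and_run(fr, None, ComparisonSpec(design=Design.ONE_SAMPLE, null_value=50.0))
                results["s1_coloc_vs_chance"] = dict(test=tr.test_name, statistic=tr.statistic, p=tr.p_value)
        for name, col in [("m1_count", m1), ("s1_count", s1)]:
            s = summarize(col)
            results.setdefault("summaries", {})[name] = dict(n=s.n, mean=s.mean, sem=s.sem)
        (out / "stats.json").write_text(json.dumps(results, indent=1))
        return results

    stats = stats_stage()

    report = {
        "n_cells": rc.n_cells,
        "cell_type": rc.cell_type,
        "mean_m1_count": float(dist_df.query("channel == 'M1'")["count"].mean()),
        "mean_s1_count": float(dist_df.query("channel == 'S1'")["count"].mean()),
        "mean_ratio_m1_s1": float(dist_df["ratio_m1_s1"].dropna().mean()),
        "mean_s1_coloc_frac": float(clus_df["s1_coloc_frac"].dropna().mean()),
        "mean_hhw_ms": float(ephys_df["mean_hhw_ms"].dropna().mean()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))

    manifest = {
        "tool": "striamap",
        "version": __version__,
        "seed": rc.seed,
        "config": rc.model_dump(),
        "input_digests": {config_path.name: _sha256(config_path)},
        "stages": stage_log,
        "outputs": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
        ),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "elapsed_seconds": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
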