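"""Dataset I/O, run configuration, and the end-to-end pipeline.

Datasets are long-format delimited text with header columns ``input`` and
``output``, one row per cell — the least-common-denominator export of flow
cytometers, microscopes and simulators alike.  Zero input concentrations
(the uninduced condition of an experiment) cannot enter the log-transformed
design space directly and are remapped to a user-supplied pseudo-value
(typically x_min) before analysis.

A :class:`RunConfig` plus its seed fully reproduces a run: every stochastic
stage (generator sampling, SSA, subsampling) derives its stream from the
single config seed through ``numpy`` seed spawning in a fixed order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_models
from .design_space import InputBounds, make_grid
from .landscape import (
    MILandscape,
    compute_landscape,
    find_optimum,
    near_optimal_region,
    plot_landscape,
    write_landscape,
)
from .mi_core import DEFAULT_FRACTIONS, DEFAULT_REPS, SingleCellDataset
from .srom import SupportSet

log = logging.getLogger("semil")


# ---------------------------------------------------------------------------
# dataset reader / writer
# ---------------------------------------------------------------------------

def read_dataset(
    path,
    discrete_outputs: bool = False,
    zero_input_value: float | None = None,
) -> SingleCellDataset:
    """Read a long-format single-cell table (columns ``input``, ``output``).

    The delimiter is auto-detected among comma and tab.  Rows are grouped by
    exact input value.  Zero inputs are remapped to ``zero_input_value``
    when given (logged), otherwise they are an error since the design space
    requires positive concentrations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"input", "output"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in ("input", "output"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header and 1-based
            raise ValueError(f"{path}: non-numeric {col!r} values at line(s) {lines}")
        if numeric.isna().any():
            lines = [int(i) + 2 for i in df.index[numeric.isna()][:5]]
            raise ValueError(f"{path}: empty {col!r} cells at line(s) {lines}")
        df[col] = numeric.astype(float)
    if (df["input"] == 0).any():
        if zero_input_value is None:
            raise ValueError(
                f"{path}: zero input values present; pass zero_input_value "
                "(e.g. x_min) to remap them"
            )
        n0 = int((df["input"] == 0).sum())
        log.info("remapped %d zero-input rows to %g", n0, zero_input_value)
        df.loc[df["input"] == 0, "input"] = zero_input_value
    groups = {
        float(x): sub["output"].to_numpy(dtype=float)
        for x, sub in df.groupby("input")
    }
    dataset = SingleCellDataset(groups, discrete_outputs=discrete_outputs)
    log.info(
        "read %d cells at %d input values from %s",
        dataset.n_total, len(groups), path,
    )
    return dataset


def write_dataset(dataset: SingleCellDataset, path) -> None:
    """Write the long-format CSV the reader understands."""
    frames = [
        pd.DataFrame({"input": x, "output": dataset.groups[x]})
        for x in dataset.input_values
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a landscape run."""

    design_space: dict
    dataset: str | None = None
    discrete_outputs: bool = False
    zero_input_value: float | None = None
    generator: dict | None = None  # alternative to `dataset`
    srom: dict = field(default_factory=lambda: {"weight": 1.0, "moment_orders": [1, 2]})
    mi: dict = field(
        default_factory=lambda: {
            "n_bins": None,
            "fractions": list(DEFAULT_FRACTIONS),
            "reps": DEFAULT_REPS,
            "bias_correction": True,
        }
    )
    output_dir: str = "semil_out"
    seed: int = 0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _generate_dataset(spec: dict, seed: int) -> SingleCellDataset:
    spec = dict(spec)
    kind = spec.pop("kind")
    sup = spec.pop("support")
    support = SupportSet(
        np.asarray(sup["values"], dtype=float)
        if "values" in sup
        else np.geomspace(sup["lo"], sup["hi"], sup["n"])
    )
    n_cells = int(spec.pop("n_cells"))
    if kind == "gamma":
        model = synthetic_models.GammaResponseModel(**spec)
        return model.sample_dataset(support, n_cells, seed=seed)
    if kind == "ssa":
        t_end = float(spec.pop("t_end"))
        net = synthetic_models.lac_network(**spec)
        return synthetic_models.sample_dataset_ssa(net, support, n_cells, t_end, seed=seed)
    raise ValueError(f"unknown generator kind {kind!r}")


def run_pipeline(config: RunConfig) -> tuple[MILandscape, dict]:
    """Execute the full pipeline: data -> binning -> SROM -> landscape -> optimum.

    Writes ``landscape.csv``, ``summary.json`` (and optionally
    ``landscape.png``) into the configured output directory and returns the
    landscape with a summary dictionary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ds_cfg = config.design_space
    bounds = InputBounds(float(ds_cfg["x_min"]), float(ds_cfg["x_max"]))
    log.info("stage design_space: bounds=%s grid=%dx%d",
             bounds, ds_cfg["n_E"], ds_cfg["n_sigma"])
    grid = make_grid(
        bounds,
        (float(ds_cfg["E_min"]), float(ds_cfg["E_max"])),
        (float(ds_cfg["sigma_min"]), float(ds_cfg["sigma_max"])),
        int(ds_cfg["n_E"]),
        int(ds_cfg["n_sigma"]),
    )

    if (config.dataset is None) == (config.generator is None):
        raise ValueError("config must set exactly one of `dataset` and `generator`")
    if config.dataset is not None:
        dataset = read_dataset(
            config.dataset,
            discrete_outputs=config.discrete_outputs,
            zero_input_value=config.zero_input_value,
        )
    else:
        log.info("stage generate: %s", config.generator.get("kind"))
        dataset = _generate_dataset(config.generator, seed=config.seed)

    log.info("stage landscape: %d feasible cells", int(grid.feasible.sum()))
    ls = compute_landscape(
        grid,
        dataset,
        n_bins=config.mi.get("n_bins"),
        fractions=tuple(config.mi.get("fractions", DEFAULT_FRACTIONS)),
        reps=int(config.mi.get("reps", DEFAULT_REPS)),
        seed=config.seed,
        srom_weight=float(config.srom.get("weight", 1.0)),
        moment_orders=tuple(config.srom.get("moment_orders", (1, 2))),
        bias_correction=bool(config.mi.get("bias_correction", True)),
    )
    opt = find_optimum(ls)
    contour = near_optimal_region(ls)
    summary = {
        "optimum": {
            "E": round(opt.E, 4),
            "sigma": round(opt.sigma, 4),
            "I": round(opt.I, 4),
            "on_boundary": opt.on_boundary,
        },
        "near_optimal_cells": int(contour.sum()),
        "feasible_cells": int(grid.feasible.sum()),
        "support": ls.support.values.tolist(),
        "settings": ls.metadata,
        "seed": config.seed,
    }
    write_landscape(ls, out / "landscape.csv", out / "landscape.json")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    if config.plots:
        plot_landscape(ls, out / "landscape.png")
    log.info("stage optimum: E*=%.4g sigma*=%.4g I*=%.4g boundary=%s",
             opt.E, opt.sigma, opt.I, opt.on_boundary)
    return ls, summary
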