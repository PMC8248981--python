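"""Pipeline runner: chain simulate -> quantify -> gate -> analyse from one
YAML config, with a content-hashed output manifest for reproducibility.

All stage randomness derives from the single root seed via named
substreams, so identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bistability, division, dose_response, synthetic
from .errors import ConfigurationError, PipelineError
from .io import read_records, read_traces, write_image, write_records, write_traces
from .lineage import classify_skipped_divisions
from .quantify import GateParams, gate_records, quantify_images
from .io import read_images

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_rng", "load_config"]


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Named substream of the root seed (stable across runs and platforms)."""
    digest = hashlib.sha256(stage.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence((root_seed, sub)))


@dataclasses.dataclass
class PipelineConfig:
    seed: int
    outdir: Path
    stages: list[dict]  # each: {"name": str, **params}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "stages" not in d or not d["stages"]:
            raise ConfigurationError("config needs a non-empty 'stages' list")
        names = [s.get("name") for s in d["stages"]]
        if any(n is None for n in names):
            raise ConfigurationError("every stage needs a 'name'")
        return cls(
            seed=int(d.get("seed", 0)),
            outdir=Path(d.get("outdir", ".")),
            stages=[dict(s) for s in d["stages"]],
        )

    def to_dict(self) -> dict:
        return {"seed": self.seed, "outdir": str(self.outdir), "stages": self.stages}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(params: dict, seed: int) -> synthetic.SimConfig:
    fields = {f.name for f in dataclasses.fields(synthetic.SimConfig)}
    kwargs = {k: v for k, v in params.items() if k in fields}
    if "genotypes" in kwargs:
        kwargs["genotypes"] = tuple(kwargs["genotypes"])
    if "ploidies" in kwargs:
        kwargs["ploidies"] = tuple(kwargs["ploidies"])
    return synthetic.SimConfig(seed=seed, **kwargs)


def _stage_simulate(params: dict, cfg: PipelineConfig, outputs: list[Path]) -> None:
    rng = stage_rng(cfg.seed, "simulate")
    sim = _sim_config(params, cfg.seed)
    records, truth = synthetic.simulate_population(sim, rng=rng)
    fmt = params.get("format", "csv")
    outputs.append(write_records(records, cfg.outdir / f"records.{fmt}"))
    truth_path = cfg.outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    outputs.append(truth_path)
    n_images = int(params.get("n_images", 0))
    if n_images > 0:
        img_dir = cfg.outdir / "images"
        img_dir.mkdir(exist_ok=True)
        for _, row in truth.head(n_images).iterrows():
            img = synthetic.render_cell_image(row, sim, rng=rng)
            outputs.append(write_image(img, img_dir / f"{row['cell_id']}.tif"))
    if params.get("lineages"):
        lp = params["lineages"]
        traces = synthetic.simulate_lineages(
            sim,
            n_lineages=int(lp.get("n", 100)),
            duration_min=float(lp.get("duration_min", 300.0)),
            genotype=lp.get("genotype", "AF"),
            rng=rng,
        )
        csv_p, ev_p = write_traces(traces, cfg.outdir / "lineages.csv")
        outputs.extend([csv_p, ev_p])


def _stage_quantify(params: dict, cfg: PipelineConfig, outputs: list[Path]) -> None:
    images = read_images(
        Path(params.get("images", cfg.outdir / "images")),
        pixel_size_um=params.get("pixel_size_um"),
    )
    df = quantify_images(images)
    df["sample_id"] = params.get("sample_id", "quantified")
    df["time_s"] = 0.0
    df["genotype"] = params.get("genotype", "WT")
    df["pp2a"] = bool(params.get("pp2a", True))
    df["ploidy"] = int(params.get("ploidy", 1))
    df["gated"] = False
    outputs.append(write_records(df, cfg.outdir / "quantified.csv"))


def _stage_gate(params: dict, cfg: PipelineConfig, outputs: list[Path]) -> None:
    records = read_records(Path(params.get("records", cfg.outdir / "records.csv")))
    gp = GateParams(
        grad_rms_min=float(params.get("grad_rms_min", 65.0)),
        area_range=tuple(params.get("area_range", (-np.inf, np.inf))),
        aspect_range=tuple(params.get("aspect_range", (-np.inf, np.inf))),
    )
    outputs.append(write_records(gate_records(records, gp), cfg.outdir / "gated.csv"))


def _stage_doseresponse(params: dict, cfg: PipelineConfig, outputs: list[Path]) -> None:
    records = read_records(Path(params.get("records", cfg.outdir / "gated.csv")))
    rows = []
    for (genotype, pp2a, ploidy), grp in records.groupby(["genotype", "pp2a", "ploidy"]):
        sel = grp[grp["gated"].astype(bool)] if grp["gated"].any() else grp
        if len(sel) < 4:
            continue
        fit = dose_response.fit_sigmoid(
            sel["cdk_level_au"].to_numpy(float), sel["activity_nc"].to_numpy(float)
        )
        rows.append(
            {
                "genotype": genotype, "pp2a": pp2a, "ploidy": ploidy,
                "ec50": fit.ec50, "slope": fit.slope, "top": fit.top,
                "bottom": fit.bottom, "rss": fit.rss, "converged": fit.converged,
            }
        )
    path = cfg.outdir / "dose_response_fits.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    outputs.append(path)


def _stage_thresholds(params: dict, cfg: PipelineConfig, outputs: list[Path]) -> None:
    records = read_records(Path(params.get("records", cfg.outdir / "gated.csv")))
    curve = division.threshold_level(
        records,
        size_bin_width=float(params.get("size_bin_width", 1.0)),
        activity_cut=float(params.get("activity_cut", 5.0)),
        fraction=float(params.get("fraction", 0.5)),
    )
    path = cfg.outdir / "threshold_curve.csv"
    curve.table.to_csv(path, index=False)
    outputs.append(path)


def _stage_bistability(params: dict, cfg: PipelineConfig, outputs: list[Path]) -> None:
    records = read_records(Path(params.get("records", cfg.outdir / "gated.csv")))
    width = float(params.get("size_bin_width", 1.0))
    level_width = float(params.get("level_bin_width", 100.0))
    sizes = records["length_um"].to_numpy(float)
    edges = np.arange(np.floor(sizes.min()), sizes.max() + width, width)
    rows = []
    for b in range(len(edges) - 1):
        sel = records[(sizes >= edges[b]) & (sizes < edges[b + 1])]
        if len(sel) < 50:
            continue
        try:
            curve = bistability.mean_activity_curve(sel, level_bin_width=level_width)
            grad = bistability.max_gradient(curve)
        except Exception:
            continue
        rows.append(
            {
                "size_bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "max_gradient": grad.value,
                "from_spline": grad.from_spline,
                "n": len(sel),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 4:
        reg = bistability.gradient_residuals(df["size_bin_center"], df["max_gradient"])
        df["residual"] = reg.residuals
        df.attrs["nonlinearity_score"] = reg.nonlinearity_score
    path = cfg.outdir / "bistability.csv"
    df.to_csv(path, index=False)
    outputs.append(path)


def _stage_lineage(params: dict, cfg: PipelineConfig, outputs: list[Path]) -> None:
    traces = read_traces(Path(params.get("traces", cfg.outdir / "lineages.csv")))
    summary = classify_skipped_divisions(traces, lag_max=int(params.get("lag_max", 3)))
    pdiv = division.estimate_pdiv(
        traces, bin_var=params.get("bin_var", "size"),
        bin_width=float(params.get("bin_width", 1.0)),
    )
    path = cfg.outdir / "pdiv_curve.csv"
    pdiv.table.to_csv(path, index=False)
    outputs.append(path)
    summary_path = cfg.outdir / "skip_division.json"
    summary_path.write_text(
        json.dumps(
            {
                "n_degradation": summary.n_degradation,
                "n_skipped": summary.n_skipped,
                "fraction": summary.fraction,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
            },
            indent=1,
        )
    )
    outputs.append(summary_path)


_STAGES = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "gate": _stage_gate,
    "doseresponse": _stage_doseresponse,
    "thresholds": _stage_thresholds,
    "bistability": _stage_bistability,
    "lineage": _stage_lineage,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; return the output manifest.

    The manifest records the config snapshot and, per stage, every output
    file with its SHA-256 hash; identical config + seed gives identical
    hashes.  A stage failure aborts with the stage named.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": []}
    for stage in config.stages:
        name = stage["name"]
        if name not in _STAGES:
            raise PipelineError(f"unknown stage {name!r}")
        params = {k: v for k, v in stage.items() if k != "name"}
        outputs: list[Path] = []
        log.info("stage %s: %s", name, params)
        try:
            _STAGES[name](params, config, outputs)
        except Exception as exc:
            for p in outputs:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {
                "name": name,
                "params": params,
                "outputs": [
                    {"path": str(p.relative_to(config.outdir)), "sha256": _sha256(p)}
                    for p in outputs
                ],
            }
        )
    manifest_path = config.outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
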