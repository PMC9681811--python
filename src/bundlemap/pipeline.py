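"""Config-driven orchestration: simulate -> spatial stats -> distance stats -> allometry.

A :class:`RunConfig` (YAML or JSON) names an ordered list of stages with
per-stage parameters, one seed, and an output directory.  Running it yields
an :class:`AnalysisReport`: per-stage summaries keyed by stage name plus a
provenance block (config hash, seed, package version) so the report alone
suffices to re-run the analysis.  Reports contain no timestamps; identical
config + seed gives byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .allometry import fit_table, load_species_table
from .distance import DistanceSequence, sequential_groups, summarize
from .io import read_point_pattern, write_curve_tsv, write_density_map, write_point_pattern
from .patterns import Window
from .spatial import clark_evans, cv_bandwidth, estimate_G, estimate_K, kernel_intensity
from .synthetic import DistanceGenConfig, GeneratorConfig, gen_distance_sequence, generate

_STAGES = ("simulate", "spatial", "distances", "allometry")


@dataclass
class RunConfig:
    stages: list[dict]
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for st in self.stages:
            if "name" not in st or st["name"] not in _STAGES:
                raise ValueError(
                    f"each stage needs a 'name' from {_STAGES}, got {st!r}"
                )
        for st in self.stages:
            inp = st.get("input")
            if inp and not Path(inp).exists():
                raise ValueError(f"stage {st['name']}: input path {inp!r} not found")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def canonical(self) -> str:
        # out_dir is deliberately excluded: where artifacts land does not
        # change what was computed, and reports must be byte-identical
        # across output locations
        return json.dumps({"stages": self.stages, "seed": self.seed}, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    stages: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "provenance": self.provenance},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(stages=d["stages"], provenance=d["provenance"])


def _window_from(params: dict) -> Window:
    w = params.get("window", {"x_min": 0, "x_max": 2000, "y_min": 0, "y_max": 2000})
    return Window.from_dict(w)


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the configured stages in order; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_stages: dict = {}
    pattern = None
    seq = None
    for st in config.stages:
        name = st["name"]
        marker = out / f"{name}.partial"
        marker.write_text("")
        try:
            if name == "simulate":
                if "distance" in st:
                    d = dict(st["distance"])
                    d.setdefault("seed", config.seed)
                    seq_values = gen_distance_sequence(DistanceGenConfig(**d))
                    seq = DistanceSequence(seq_values, block="synthetic")
                    report_stages[name] = {"kind": "distance_sequence", "n": seq.n}
                else:
                    gc = GeneratorConfig(
                        kind=st["kind"],
                        parameters=st.get("parameters", {}),
                        seed=st.get("seed", config.seed),
                    )
                    pattern = generate(gc, _window_from(st))
                    write_point_pattern(pattern, out / "pattern.tsv")
                    report_stages[name] = {
                        "kind": gc.kind,
                        "n": pattern.n,
                        "intensity_per_mm2": pattern.intensity_per_mm2,
                    }
            elif name == "spatial":
                if st.get("input"):
                    pattern = read_point_pattern(st["input"])
                if pattern is None:
                    raise ValueError("spatial stage has no pattern (input or simulate)")
                kc = estimate_K(pattern, correction=st.get("correction", "translation"))
                gc_curve = estimate_G(pattern)
                ce = clark_evans(pattern)
                write_curve_tsv(
                    out / "kfunc.tsv",
                    {
                        "r_um": kc.radii,
                        "k_hat_um2": kc.k_hat,
                        "scaled_r": kc.scaled_radii,
                        "lambda_k": kc.lambda_k,
                        "poisson_k": kc.poisson_k,
                    },
                )
                write_curve_tsv(
                    out / "gfunc.tsv",
                    {
                        "r_um": gc_curve.radii,
                        "g_hat": gc_curve.g_hat,
                        "poisson_g": gc_curve.poisson_g,
                        "diff": gc_curve.diff,
                    },
                )
                entry = {
                    "clark_evans_R": ce.r_ratio,
                    "clark_evans_p": ce.p_value,
                    "lambda_per_mm2": pattern.intensity_per_mm2,
                    "k_deficit_at_scaled_r1": kc.deficit_at_scaled_radius(1.0),
                }
                if st.get("density", True):
                    sigma = st.get("sigma", "auto")
                    if sigma == "auto":
                        sigma = cv_bandwidth(pattern)
                    dmap = kernel_intensity(pattern, float(sigma))
                    write_density_map(dmap, out / "density")
                    entry["density_sigma_um"] = float(sigma)
                    entry["density_mean_per_mm2"] = float(dmap.values.mean())
                report_stages[name] = entry
            elif name == "distances":
                if st.get("input"):
                    from .io import read_distances

                    seq = read_distances(st["input"], block=st.get("block"))
                if seq is None:
                    raise ValueError("distances stage has no sequence")
                summ = summarize(seq)
                entry = {
                    "n": summ.n,
                    "mean_um": summ.mean,
                    "sd_um": summ.sd,
                    "skewness": summ.skewness,
                    "excess_kurtosis": summ.excess_kurtosis,
                    "ks_p": summ.ks_p,
                }
                gs = st.get("group_size")
                if gs:
                    scan = sequential_groups(seq, group_size=int(gs))
                    entry["group_means_um"] = scan.means.tolist()
                    entry["adjacent_p"] = scan.p_values.tolist()
                report_stages[name] = entry
            elif name == "allometry":
                records = load_species_table()
                fit = fit_table(
                    records,
                    x=st.get("x", "acuity"),
                    y=st.get("y", "total_bundles"),
                    range_policy=st.get("range_policy", "midpoint"),
                )
                report_stages[name] = {
                    "x": st.get("x", "acuity"),
                    "y": st.get("y", "total_bundles"),
                    "exponent": fit.exponent,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                    "excluded": list(fit.excluded),
                }
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        marker.unlink(missing_ok=True)
    report = AnalysisReport(
        stages=report_stages,
        provenance={
            "config_hash": config.config_hash,
            "seed": config.seed,
            "bundlemap_version": __version__,
        },
    )
    (out / "report.json").write_text(report.to_json())
    return report
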