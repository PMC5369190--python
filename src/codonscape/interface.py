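"""Experiment presets, artifact output, and reproducibility plumbing.

Each preset names one experimental condition of the study: a GA ensemble
(model x scheme x sharing radius), a large random-code sample, or a p.d.m.
evaluation.  ``run_experiment`` executes a preset and writes all outputs
(per-run generation CSVs, final populations, best code tables, aggregate
JSON) together with a manifest recording the configuration, seeds and
package version, which suffice to reproduce every file exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import code_model as cm
from . import error_cost as ec
from . import evolution as ev
from . import landscape_analysis as la
from . import niching

__all__ = ["ExperimentSpec", "PRESETS", "run_experiment", "load_config", "score_code"]


@dataclass(frozen=True)
class ExperimentSpec:
    """A named experimental condition."""

    name: str
    kind: str  # "ensemble" | "sample" | "pdm"
    ga: ev.GAConfig | None = None
    sample_model: str | None = None
    sample_scheme: str | None = None
    sample_n: int = 0


def _ga(model: str, scheme: str = "ms", sigma: float | None = None) -> ev.GAConfig:
    sharing = niching.SharingConfig(sigma_share=sigma) if sigma else None
    return ev.GAConfig(model=model, scheme=scheme, sharing=sharing)


PRESETS: dict[str, ExperimentSpec] = {
    "restrictive-nosharing": ExperimentSpec("restrictive-nosharing", "ensemble", ga=_ga("restrictive")),
    "restrictive-sigma001": ExperimentSpec("restrictive-sigma001", "ensemble", ga=_ga("restrictive", sigma=0.01)),
    "restrictive-sigma01": ExperimentSpec("restrictive-sigma01", "ensemble", ga=_ga("restrictive", sigma=0.1)),
    "unrestrictive-nosharing": ExperimentSpec("unrestrictive-nosharing", "ensemble", ga=_ga("unrestrictive")),
    "unrestrictive-sigma001": ExperimentSpec("unrestrictive-sigma001", "ensemble", ga=_ga("unrestrictive", sigma=0.01)),
    "unrestrictive-sigma01": ExperimentSpec("unrestrictive-sigma01", "ensemble", ga=_ga("unrestrictive", sigma=0.1)),
    "tms-restrictive": ExperimentSpec("tms-restrictive", "ensemble", ga=_ga("restrictive", "tms")),
    "tms-unrestrictive": ExperimentSpec("tms-unrestrictive", "ensemble", ga=_ga("unrestrictive", "tms")),
    "statistical-1M": ExperimentSpec(
        "statistical-1M", "sample", sample_model="restrictive", sample_scheme="ms",
        sample_n=1_000_000,
    ),
    "pdm-restrictive": ExperimentSpec(
        "pdm-restrictive", "pdm", ga=_ga("restrictive"),
        sample_model="restrictive", sample_scheme="ms", sample_n=10_000,
    ),
    "pdm-unrestrictive": ExperimentSpec(
        "pdm-unrestrictive", "pdm", ga=_ga("unrestrictive"),
        sample_model="unrestrictive", sample_scheme="ms", sample_n=10_000,
    ),
    "pdm-restrictive-tms": ExperimentSpec(
        "pdm-restrictive-tms", "pdm", ga=_ga("restrictive", "tms"),
        sample_model="restrictive", sample_scheme="tms", sample_n=10_000,
    ),
}


def load_config(path: str | Path) -> ev.GAConfig:
    """Read a flat key:value (YAML) config file into a :class:`GAConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sigma = raw.pop("sharing_radius", None)
    alpha = raw.pop("alpha", 1.0)
    if sigma is not None:
        raw["sharing"] = niching.SharingConfig(sigma_share=float(sigma), alpha=float(alpha))
    fields = {f.name for f in dataclasses.fields(ev.GAConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ev.GAConfig(**raw)


def _config_dict(cfg: ev.GAConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.sharing is not None:
        d["sharing"] = dataclasses.asdict(cfg.sharing)
    return d


def _write_run_outputs(record: ev.RunRecord, out_dir: Path, run_index: int) -> None:
    prefix = out_dir / f"run{run_index:02d}"
    with open(f"{prefix}_generations.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["generation", "best_cost", "mean_cost", "canonical_present"])
        for st in record.stats:
            w.writerow(
                [st.generation, f"{st.best_cost:.6f}", f"{st.mean_cost:.6f}",
                 int(st.canonical_present)]
            )
    with open(f"{prefix}_population.tsv", "w") as fh:
        for row, cost in zip(record.final_population, record.final_costs):
            g = ev._wrap_genotype(row, record.config.model)
            fh.write(f"{cm.to_compact(g)}\t{cost:.6f}\n")
    cm.write_code_table(record.best_genotype, f"{prefix}_best_code.tsv")


def run_experiment(
    preset: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run a named preset (or a GA config file) and write all artifacts.

    Returns the summary dict that is also written as ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(preset, str) and preset in PRESETS:
        spec = PRESETS[preset]
    elif Path(preset).is_file():
        spec = ExperimentSpec(name=str(preset), kind="ensemble", ga=load_config(preset))
    else:
        raise ValueError(
            f"unknown preset {preset!r}; available: {', '.join(sorted(PRESETS))}"
        )

    summary: dict = {"preset": spec.name, "version": __version__}
    if spec.kind in ("ensemble", "pdm"):
        cfg = spec.ga
        if seed is not None:
            cfg = dataclasses.replace(cfg, rng_seed=seed)
        records, agg = ev.multi_run(cfg)
        for i, rec in enumerate(records):
            _write_run_outputs(rec, out, i)
        summary["config"] = _config_dict(cfg)
        summary["aggregate"] = dataclasses.asdict(agg)
        summary["table"] = la.summarize_ensemble(records)
        if spec.kind == "pdm":
            rng = np.random.default_rng(
                ev.run_seed(cfg.rng_seed, 10_007)  # disjoint from the run seeds
            )
            stats = ec.sample_random_statistics(
                spec.sample_model, spec.sample_scheme, spec.sample_n, rng
            )
            summary["random_sample"] = dataclasses.asdict(stats)
            summary["pdm"] = la.pdm_from_ensemble(records, stats)
    elif spec.kind == "sample":
        rng = np.random.default_rng(seed if seed is not None else 0)
        stats = ec.sample_random_statistics(
            spec.sample_model, spec.sample_scheme, spec.sample_n, rng
        )
        summary["config"] = {
            "model": spec.sample_model, "scheme": spec.sample_scheme,
            "n": spec.sample_n, "seed": seed if seed is not None else 0,
        }
        summary["sample"] = dataclasses.asdict(stats)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    manifest = {
        "preset": spec.name,
        "seed": seed,
        "version": __version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def score_code(path: str | Path, scheme: str = "ms") -> float:
    """Score a code-table file; raises ValueError on malformed input."""
    table = cm.read_code_table(path)
    violations = cm.validate(table)
    # user tables may legitimately move stops (unrestrictive model)
    violations = [v for v in violations if v != "stop_codons_not_canonical"]
    if violations:
        raise ValueError(f"invalid code table: {violations}")
    return ec.ms_error(table, weights=scheme)
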