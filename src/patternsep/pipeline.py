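"""End-to-end orchestration: configuration, the full analysis run, and
deterministic result/manifest output.

``run_all`` executes simulate -> (optional GLM) -> decode -> group stats for
every configured ROI and writes the group results CSV, per-participant
confusion matrices (JSON), and a manifest echoing all parameters and
derived seeds.  ROIs are labels on pattern sets: a run typically contains a
signal-bearing "HC"-like ROI and null ROIs with zero signal amplitudes, so
the output table mirrors the contrast between the hippocampus and its
neighbouring regions in one pass.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .design import ExperimentDesign, make_design
from .exceptions import ConfigError
from .glm import HRFParams, SingleTrialGLM, build_design_matrix, trial_tmaps
from .io import save_pattern_set, write_manifest
from .model import MemoryDecodingModel, MemoryDecodingResults
from .roi import subsample_voxels
from .simulate import NoiseModel, SignalSpec, generate_patterns, generate_timeseries
from .util import derive_seed

#: default ROI signal layout: bound + context signal in the hippocampus-like
#: ROI, pure noise in the three neighbouring-region stand-ins
DEFAULT_ROIS = {
    "HC": SignalSpec(),
    "EC": SignalSpec(amp_bound=0.0, amp_context=0.0, amp_event=0.0),
    "PRC": SignalSpec(amp_bound=0.0, amp_context=0.0, amp_event=0.0),
    "PHC": SignalSpec(amp_bound=0.0, amp_context=0.0, amp_event=0.0),
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int | None = None
    n_participants: int = 15
    n_trials_per_condition: int = 20
    recall_duration: float = 12.0
    inter_trial_interval: float = 4.0
    tr: float = 2.0
    rois: dict = field(default_factory=lambda: dict(DEFAULT_ROIS))
    use_timeseries: bool = False
    hrf: HRFParams = field(default_factory=HRFParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    drift_order: int = 1
    cost: float = 1.0
    normalize: str = "none"
    subsample_k: int | None = None
    analyses: tuple = ("fourway", "context_transfer", "content_transfer")
    n_perm: int = 500
    alpha: float = 0.05
    outdir: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("config field 'seed' is mandatory")
        if not (0 < self.alpha < 1):
            raise ConfigError("config field 'alpha' must be in (0, 1)")
        if self.n_participants < 2:
            raise ConfigError("config field 'n_participants' must be >= 2")
        if self.n_trials_per_condition < 2:
            raise ConfigError(
                "config field 'n_trials_per_condition' must be >= 2"
            )
        if self.normalize not in ("none", "zscore"):
            raise ConfigError("config field 'normalize' must be none|zscore")
        for name, spec in self.rois.items():
            if not isinstance(spec, SignalSpec):
                raise ConfigError(
                    f"config field 'rois[{name}]' must be a SignalSpec"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rois" in d:
            d["rois"] = {
                name: SignalSpec(**spec) if isinstance(spec, dict) else spec
                for name, spec in d["rois"].items()
            }
        if isinstance(d.get("hrf"), dict):
            d["hrf"] = HRFParams(**d["hrf"])
        if isinstance(d.get("noise"), dict):
            d["noise"] = NoiseModel(**d["noise"])
        if isinstance(d.get("analyses"), list):
            d["analyses"] = tuple(d["analyses"])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyses"] = list(self.analyses)
        return d


@dataclass
class PipelineResult:
    """Bundle of per-ROI fitted results plus the run manifest."""

    config: RunConfig
    design: ExperimentDesign
    results: dict  # roi -> MemoryDecodingResults
    manifest: dict

    def to_frame(self):
        import pandas as pd

        return pd.concat(
            [r.to_frame() for r in self.results.values()], ignore_index=True
        )


def _patterns_via_glm(design, spec, config, seed, roi_name):
    """Timeseries -> single-trial GLM -> t-map pattern sets."""
    series_list = generate_timeseries(
        design, spec, hrf=config.hrf, noise=config.noise, seed=seed,
        drift_order=config.drift_order,
    )
    X = build_design_matrix(design, config.hrf, drift_order=config.drift_order)
    out = []
    for ts in series_list:
        res = SingleTrialGLM(ts, X).fit()
        out.append(
            trial_tmaps(
                res,
                design.labels(ts.participant_id),
                ts.accurate,
                participant_id=ts.participant_id,
                roi_name=roi_name,
            )
        )
    return out


def run_all(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full pipeline described by ``config``.

    Deterministic: rerunning with an identical config reproduces the result
    tables byte for byte.
    """
    config.validate()
    seed = int(config.seed)
    design = make_design(
        config.n_participants,
        config.n_trials_per_condition,
        recall_duration=config.recall_duration,
        inter_trial_interval=config.inter_trial_interval,
        tr=config.tr,
        seed=derive_seed(seed, "design"),
    )
    results: dict[str, MemoryDecodingResults] = {}
    roi_seeds = {}
    for roi_name, spec in config.rois.items():
        roi_seed = derive_seed(seed, "simulate", roi_name)
        roi_seeds[roi_name] = roi_seed
        if config.use_timeseries:
            psets = _patterns_via_glm(design, spec, config, roi_seed, roi_name)
        else:
            psets = generate_patterns(
                design, spec, seed=roi_seed, roi_name=roi_name
            )
        if config.subsample_k is not None:
            psets = [
                subsample_voxels(
                    p, config.subsample_k,
                    seed=derive_seed(seed, "subsample", roi_name,
                                     p.participant_id),
                )
                for p in psets
            ]
        model = MemoryDecodingModel(psets)
        results[roi_name] = model.fit(
            analyses=config.analyses,
            cost=config.cost,
            normalize=config.normalize,
            n_perm=config.n_perm,
            seed=derive_seed(seed, "perm", roi_name),
        )

    manifest = {
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "derived_seeds": {
            "design": derive_seed(seed, "design"),
            "simulate": roi_seeds,
        },
        "permutation_scheme": (
            "labels permuted over trials independently within participant; "
            "add-one p-value"
        ),
        "normalize": config.normalize,
        "voxel_scan_order": "ascending C-order flat index",
    }
    result = PipelineResult(
        config=config, design=design, results=results, manifest=manifest
    )
    if write and config.outdir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = result.to_frame()
    table.to_csv(outdir / "group_results.csv", index=False,
                 float_format="%.10g")
    confusion = {
        roi: {
            str(d.participant_id): d.confusion.tolist()
            for d in r.decodings
        }
        for roi, r in result.results.items()
    }
    (outdir / "confusion.json").write_text(
        json.dumps(confusion, indent=2, sort_keys=True) + "\n"
    )
    mis = [r.misclass_frame() for r in result.results.values()
           if len(r.misclass)]
    if mis:
        import pandas as pd

        pd.concat(mis, ignore_index=True).to_csv(
            outdir / "misclassification.csv", index=False,
            float_format="%.10g"
        )
    write_manifest(result.manifest, outdir / "manifest.json")


def export_patterns(result: PipelineResult, directory) -> None:
    """Re-generate and export every ROI's pattern sets as TSV (stage
    isolation hook: exported patterns re-imported with
    :func:`patternsep.io.load_pattern_set` reproduce downstream results)."""
    config = result.config
    for roi_name, spec in config.rois.items():
        roi_seed = derive_seed(int(config.seed), "simulate", roi_name)
        for pset in generate_patterns(
            result.design, spec, seed=roi_seed, roi_name=roi_name
        ):
            save_pattern_set(pset, directory)
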