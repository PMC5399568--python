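"""End-to-end pipeline: simulate/load -> detect -> quantify -> compare.

One YAML config and one master seed fully determine a run; re-running
the same config produces byte-identical CSV outputs. Per-lobe synthesis
seeds are derived by hashing (master seed, group label, lobe index), so
they are stable under reordering of groups in the config.

Outputs written to the run directory:

* ``cells.csv``        one row per detected cell
* ``lobes.csv``        one row per lobe (N cells, n positive, % positive)
* ``comparisons.csv``  one row per group pair (KS D, p, summaries)
* ``config_resolved.yaml``  the fully-defaulted configuration
* ``manifest.json``    versions, seed, input hashes, per-stage counts
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import DetectionParams
from .shells import LobeQuantification, ShellParams, quantify_lobe_detailed
from .stackio import ImageStack, read_stack, write_quantification_table
from .stats import comparison_frame, ks_compare
from .synthesis import SynthesisParams, generate_cohort

__all__ = [
    "PipelineConfig",
    "GroupSpec",
    "ConfigError",
    "PipelineError",
    "validate_config",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration document is invalid; the message names the key."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class GroupSpec:
    label: str
    params: SynthesisParams
    n_lobes: int


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    output_dir: Path
    synthesis_groups: tuple[GroupSpec, ...] | None
    input_directory: Path | None
    input_manifest: Path | None
    detection: DetectionParams
    shell: ShellParams
    alpha: float = 0.05
    percentiles: tuple[float, float] = (5.0, 95.0)
    log_level: str = "INFO"


def _check_keys(section: dict, allowed: Sequence[str], context: str) -> None:
    unknown = sorted(set(section) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) {unknown} in {context}")


def _build_dataclass(cls, section: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, sorted(fields), context)
    try:
        obj = cls(**section)
        if hasattr(obj, "validate"):
            obj.validate()
        return obj
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


TOP_LEVEL_KEYS = ("seed", "output_dir", "input", "detection", "shell", "stats", "log_level")


def validate_config(raw: dict) -> PipelineConfig:
    """Resolve a raw YAML document into a fully-defaulted PipelineConfig.

    Unknown keys anywhere are rejected, every nested parameter object is
    validated, and exactly one input source (``input.synthesis`` or
    ``input.directory``) must be present.
    """
    if not isinstance(raw, dict):
        raise ConfigError("config document must be a mapping")
    _check_keys(raw, TOP_LEVEL_KEYS, "top level")
    if "output_dir" not in raw:
        raise ConfigError("missing required key 'output_dir'")
    if "input" not in raw or not isinstance(raw["input"], dict):
        raise ConfigError("missing required mapping 'input'")
    inp = raw["input"]
    _check_keys(inp, ("synthesis", "directory"), "input")
    if ("synthesis" in inp) == ("directory" in inp):
        raise ConfigError("input must contain exactly one of 'synthesis' or 'directory'")

    seed = int(raw.get("seed", 0))
    if not 0 <= seed < 2**31:
        raise ConfigError("seed must lie in [0, 2**31)")

    groups = None
    in_dir = manifest = None
    if "synthesis" in inp:
        synth = inp["synthesis"]
        _check_keys(synth, ("groups",), "input.synthesis")
        raw_groups = synth.get("groups")
        if not raw_groups:
            raise ConfigError("input.synthesis.groups must be a nonempty list")
        specs = []
        seen = set()
        for i, g in enumerate(raw_groups):
            ctx = f"input.synthesis.groups[{i}]"
            _check_keys(g, ("label", "n_lobes", "params"), ctx)
            label = str(g.get("label", ""))
            if not label:
                raise ConfigError(f"{ctx}: missing 'label'")
            if label in seen:
                raise ConfigError(f"{ctx}: duplicate group label {label!r}")
            seen.add(label)
            n_lobes = int(g.get("n_lobes", 0))
            if n_lobes < 1:
                raise ConfigError(f"{ctx}: n_lobes must be >= 1")
            params = _build_dataclass(
                SynthesisParams, dict(g.get("params", {})), f"{ctx}.params"
            )
            specs.append(GroupSpec(label=label, params=params, n_lobes=n_lobes))
        groups = tuple(specs)
    else:
        d = inp["directory"]
        _check_keys(d, ("path", "manifest"), "input.directory")
        if "path" not in d or "manifest" not in d:
            raise ConfigError("input.directory needs 'path' and 'manifest'")
        in_dir = Path(d["path"])
        manifest = Path(d["manifest"])

    detection = _build_dataclass(DetectionParams, dict(raw.get("detection", {})), "detection")
    shell = _build_dataclass(ShellParams, dict(raw.get("shell", {})), "shell")

    stats_raw = dict(raw.get("stats", {}))
    _check_keys(stats_raw, ("alpha", "percentiles"), "stats")
    alpha = float(stats_raw.get("alpha", 0.05))
    if not 0 < alpha < 1:
        raise ConfigError("stats.alpha must lie in (0, 1)")
    pct = tuple(float(p) for p in stats_raw.get("percentiles", (5.0, 95.0)))
    if len(pct) != 2 or not 0 <= pct[0] < pct[1] <= 100:
        raise ConfigError("stats.percentiles must be an increasing pair in [0, 100]")

    return PipelineConfig(
        seed=seed,
        output_dir=Path(raw["output_dir"]),
        synthesis_groups=groups,
        input_directory=in_dir,
        input_manifest=manifest,
        detection=detection,
        shell=shell,
        alpha=alpha,
        percentiles=pct,
        log_level=str(raw.get("log_level", "INFO")).upper(),
    )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _resolved_config_dict(config: PipelineConfig) -> dict:
    d: dict[str, Any] = {
        "seed": config.seed,
        "output_dir": str(config.output_dir),
        "log_level": config.log_level,
        "detection": dataclasses.asdict(config.detection),
        "shell": dataclasses.asdict(config.shell),
        "stats": {"alpha": config.alpha, "percentiles": list(config.percentiles)},
    }
    if config.synthesis_groups is not None:
        d["input"] = {
            "synthesis": {
                "groups": [
                    {
                        "label": g.label,
                        "n_lobes": g.n_lobes,
                        "params": dataclasses.asdict(g.params),
                    }
                    for g in config.synthesis_groups
                ]
            }
        }
    else:
        d["input"] = {
            "directory": {
                "path": str(config.input_directory),
                "manifest": str(config.input_manifest),
            }
        }
    return d


def _load_stacks(config: PipelineConfig) -> list[ImageStack]:
    if config.synthesis_groups is not None:
        cohort = generate_cohort(
            [(g.label, g.params, g.n_lobes) for g in config.synthesis_groups],
            seed=config.seed,
        )
        return [lobe.stack for lobe in cohort]
    mf = pd.read_csv(config.input_manifest)
    for col in ("lobe_id", "path", "group_label"):
        if col not in mf.columns:
            raise ConfigError(f"input manifest lacks column {col!r}")
    if mf["group_label"].nunique() < 1 or mf["lobe_id"].duplicated().any():
        raise ConfigError("input manifest has duplicate lobe_id entries")
    stacks = []
    for row in mf.itertuples(index=False):
        stack = read_stack(Path(config.input_directory) / str(row.path))
        stack.lobe_id = str(row.lobe_id)
        stack.group_label = str(row.group_label)
        stacks.append(stack)
    return stacks


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    Any stage error aborts the run with the failing stage named; partial
    outputs are retained next to a ``FAILED.json`` marker.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lobequant")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level, logging.INFO))

    stage = "configure"
    try:
        (out / "config_resolved.yaml").write_text(
            yaml.safe_dump(_resolved_config_dict(config), sort_keys=True)
        )

        stage = "load-input"
        logger.info("loading input stacks")
        stacks = _load_stacks(config)
        input_hashes = {
            s.lobe_id: hashlib.sha256(np.ascontiguousarray(s.pixels).tobytes()).hexdigest()
            for s in stacks
        }

        stage = "quantify"
        logger.info("quantifying %d lobes", len(stacks))
        cell_rows = []
        lobe_records: list[LobeQuantification] = []
        n_border = 0
        for stack in stacks:
            quant, cells = quantify_lobe_detailed(stack, config.detection, config.shell)
            lobe_records.append(quant)
            for cid, cell in enumerate(cells):
                n_border += cell.border_clipped
                cell_rows.append(
                    {
                        "lobe_id": stack.lobe_id,
                        "group_label": stack.group_label,
                        "cell_id": cid,
                        "row": cell.centre[0],
                        "col": cell.centre[1],
                        "plane": cell.source_plane,
                        "response": cell.peak_response,
                        "shell_value": cell.shell_value,
                        "is_positive": bool(cell.is_positive),
                        "border_clipped": cell.border_clipped,
                    }
                )
        pd.DataFrame(
            cell_rows,
            columns=[
                "lobe_id", "group_label", "cell_id", "row", "col",
                "plane", "response", "shell_value", "is_positive", "border_clipped",
            ],
        ).to_csv(out / "cells.csv", index=False, float_format="%.6g")
        write_quantification_table(lobe_records, out / "lobes.csv")

        stage = "compare"
        labels = list(dict.fromkeys(r.group_label for r in lobe_records))
        by_group = {
            lab: [
                r.percent_positive
                for r in lobe_records
                if r.group_label == lab and r.percent_positive is not None
            ]
            for lab in labels
        }
        comparisons = []
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                if len(by_group[la]) >= 3 and len(by_group[lb]) >= 3:
                    comparisons.append(ks_compare(by_group[la], by_group[lb], la, lb))
                else:
                    logger.warning("skipping %s vs %s: fewer than 3 lobes", la, lb)
        comparison_frame(comparisons).to_csv(
            out / "comparisons.csv", index=False, float_format="%.6g"
        )

        stage = "manifest"
        manifest = {
            "versions": {
                "lobequant": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "seed": config.seed,
            "input_hashes": input_hashes,
            "counts": {
                "lobes_in": len(stacks),
                "lobes_out": len(lobe_records),
                "cells": len(cell_rows),
                "positives": int(sum(r.n_positive for r in lobe_records)),
                "border_clipped_cells": int(n_border),
                "comparisons": len(comparisons),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        logger.info("pipeline complete: %s", manifest["counts"])
        return manifest
    except Exception as exc:
        (out / "FAILED.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)}, indent=1)
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
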