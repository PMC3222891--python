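"""Plain-text serialization: pattern sets, result tables, run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .simulate import TrialPatternSet


def save_pattern_set(pset: TrialPatternSet, directory, stem=None) -> Path:
    """Write a pattern set as ``<stem>_patterns.tsv`` plus a label sidecar.

    The patterns file holds the trials x voxels matrix; the sidecar the
    trial labels and accuracy flags.  Returns the patterns path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"sub-{pset.participant_id:02d}_roi-{pset.roi_name}"
    pat_path = directory / f"{stem}_patterns.tsv"
    # %.17g round-trips float64 exactly, so re-imported patterns reproduce
    # downstream results bit for bit
    np.savetxt(pat_path, pset.patterns, delimiter="\t", fmt="%.17g")
    side = pd.DataFrame(
        {
            "memory_id": pset.memory_ids,
            "accurate": pset.accurate.astype(int),
        }
    )
    side.to_csv(directory / f"{stem}_labels.tsv", sep="\t", index=False)
    return pat_path


def load_pattern_set(patterns_path, participant_id: int | None = None,
                     roi_name: str | None = None) -> TrialPatternSet:
    """Read a pattern set written by :func:`save_pattern_set`."""
    patterns_path = Path(patterns_path)
    if not patterns_path.name.endswith("_patterns.tsv"):
        raise InvalidParameterError(
            "expected a path ending in '_patterns.tsv'"
        )
    stem = patterns_path.name[: -len("_patterns.tsv")]
    side = pd.read_csv(
        patterns_path.with_name(f"{stem}_labels.tsv"), sep="\t"
    )
    patterns = np.loadtxt(patterns_path, delimiter="\t", ndmin=2)
    if participant_id is None or roi_name is None:
        # recover ids from the canonical stem when not supplied
        parts = dict(
            kv.split("-", 1) for kv in stem.split("_") if "-" in kv
        )
        participant_id = (
            participant_id if participant_id is not None
            else int(parts.get("sub", 0))
        )
        roi_name = roi_name or parts.get("roi", "ROI")
    return TrialPatternSet(
        participant_id=participant_id,
        roi_name=roi_name,
        patterns=patterns,
        labels=list(side["memory_id"]),
        accurate=side["accurate"].to_numpy(dtype=bool),
    )


def write_manifest(manifest: dict, path) -> None:
    """Write the run manifest as sorted, indented JSON."""
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
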