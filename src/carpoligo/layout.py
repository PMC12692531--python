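"""Array layout: randomized placement of biological probes and controls.

Emulates an 8 x 60K slide format: each of the 8 subarrays carries 62,976
features, of which 1,319 are controls (spike-in dilution series, stringency
probes and corner markers) and 20 designated biological probes are replicated
10 times each for technical-replicate QC. Remaining positions carry the
biological probe set, each unique probe at least once when capacity allows,
with round-robin duplication filling residual capacity. Placement is a seeded
random permutation, so a layout is reproducible byte-for-byte from its seed.

The split of the control count into classes is a declared configuration
default (the vendor grid composition is not public).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LayoutSpec", "ArrayLayout", "build_layout", "export_design_table", "read_design_table"]

FEATURE_CLASSES = ("biological", "replicate", "spikein", "stringency", "corner")

#: default split of the control features into classes (sums to control_count)
DEFAULT_CONTROL_MANIFEST = {"spikein": 330, "stringency": 289, "corner": 700}

#: number of spike-in dilution levels in the control series
SPIKEIN_LEVELS = 10


@dataclass(frozen=True)
class LayoutSpec:
    subarrays: int = 8
    features_per_subarray: int = 62976
    control_count: int = 1319
    replicate_probe_count: int = 20
    replicate_copies: int = 10
    seed: int = 0
    grid_width: int = 256
    control_manifest: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_MANIFEST))

    def __post_init__(self) -> None:
        if sum(self.control_manifest.values()) != self.control_count:
            raise ValueError("control manifest must sum to control_count")
        if (
            self.control_count + self.replicate_probe_count * self.replicate_copies
            > self.features_per_subarray
        ):
            raise ValueError("controls + replicates exceed subarray capacity")


@dataclass
class ArrayLayout:
    """Per-subarray ordered assignment position -> (feature_class, id)."""

    spec: LayoutSpec
    subarrays: list[pd.DataFrame]  # columns: feature_class, feature_id

    @property
    def n_features(self) -> int:
        return sum(len(s) for s in self.subarrays)

    def class_counts(self, subarray: int) -> dict[str, int]:
        return self.subarrays[subarray]["feature_class"].value_counts().to_dict()


def _control_ids(spec: LayoutSpec) -> tuple[list[str], list[str]]:
    classes, ids = [], []
    for cls, count in spec.control_manifest.items():
        for i in range(count):
            classes.append(cls)
            if cls == "spikein":
                level = i % SPIKEIN_LEVELS + 1
                ids.append(f"E1A_L{level:02d}_{i // SPIKEIN_LEVELS + 1:03d}")
            elif cls == "stringency":
                ids.append(f"DCP_{i + 1:04d}")
            else:
                ids.append(f"{cls.upper()}_{i + 1:04d}")
    return classes, ids


def build_layout(probes, spec: LayoutSpec | None = None) -> ArrayLayout:
    """Assign every position of every subarray exactly once, seeded.

    Replicate probes are the first ``replicate_probe_count`` designed probes
    in probe_id order, each placed ``replicate_copies`` times per subarray.
    """
    spec = spec or LayoutSpec()
    designed = sorted(
        (p for p in probes if p.status == "designed"), key=lambda p: p.probe_id
    )
    if not designed:
        raise ValueError("no designed probes to place")

    n_rep = min(spec.replicate_probe_count, len(designed))
    rep_ids = [p.probe_id for p in designed[:n_rep]]
    # replicate probes occupy their replicate-class positions only
    bio_ids = [p.probe_id for p in designed[n_rep:]] or rep_ids
    n_bio_positions = (
        spec.features_per_subarray - spec.control_count - n_rep * spec.replicate_copies
    )
    if n_bio_positions < 0:
        raise ValueError("controls + replicates exceed subarray capacity")

    ctrl_classes, ctrl_ids = _control_ids(spec)
    rng = np.random.default_rng(spec.seed)
    subarrays = []
    for _ in range(spec.subarrays):
        classes = list(ctrl_classes) + ["replicate"] * (n_rep * spec.replicate_copies)
        ids = list(ctrl_ids) + [r for r in rep_ids for _ in range(spec.replicate_copies)]
        # every unique biological probe at least once, round-robin fill after
        fill = [bio_ids[i % len(bio_ids)] for i in range(n_bio_positions)]
        classes += ["biological"] * n_bio_positions
        ids += fill
        perm = rng.permutation(len(classes))
        subarrays.append(
            pd.DataFrame(
                {
                    "feature_class": np.asarray(classes, dtype=object)[perm],
                    "feature_id": np.asarray(ids, dtype=object)[perm],
                }
            )
        )
    return ArrayLayout(spec, subarrays)


def export_design_table(layout: ArrayLayout, path) -> None:
    """Write the design table TSV: subarray, row, col, feature_class, feature_id."""
    frames = []
    width = layout.spec.grid_width
    for si, sub in enumerate(layout.subarrays, start=1):
        pos = np.arange(len(sub))
        frames.append(
            pd.DataFrame(
                {
                    "subarray": si,
                    "row": pos // width + 1,
                    "col": pos % width + 1,
                    "feature_class": sub["feature_class"].to_numpy(),
                    "feature_id": sub["feature_id"].to_numpy(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_design_table(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    required = {"subarray", "row", "col", "feature_class", "feature_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df
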