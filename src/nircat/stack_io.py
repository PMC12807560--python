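"""Reading, validation and writing of fluorescence stacks and sample tables.

Stacks travel as multi-page single-channel TIFF (16-bit unsigned, one page
per frame); sample manifests and all tabular outputs are plain CSV with a
header row and '.' decimal separator.  Frame indices are 0-based throughout;
the stimulation frame is the first frame at/after stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthetic import AcquisitionProtocol, REGIONS, TREATMENTS

__all__ = [
    "FluorescenceStack",
    "SampleRecord",
    "read_stack",
    "write_stack",
    "quantize_stack",
    "read_manifest",
    "write_table",
    "read_table",
]

MANIFEST_COLUMNS = ("animal_id", "treatment", "region", "slice_id", "replicate_index", "stack_path")

#: CSV float format preserving 15 significant digits for lossless round trips.
_FLOAT_FMT = "%.15g"


@dataclass
class FluorescenceStack:
    """A frames x rows x cols intensity movie with its acquisition protocol."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3-D (frames, rows, cols); got shape {self.data.shape}")
        n_frames, n_rows, n_cols = self.data.shape
        if n_frames != self.protocol.n_frames:
            raise ValueError(
                f"frame count {n_frames} does not match protocol n_frames={self.protocol.n_frames}"
            )
        # spatial extent must agree with FOV / um_per_pixel to within one pixel
        for have, want, axis in (
            (n_rows, self.protocol.n_rows, "rows"),
            (n_cols, self.protocol.n_cols, "cols"),
        ):
            if abs(have - want) > 1:
                raise ValueError(
                    f"{axis}={have} inconsistent with FOV extent / um_per_pixel (expected ~{want})"
                )
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def quantize_stack(stack: FluorescenceStack) -> FluorescenceStack:
    """Round intensities to the 16-bit unsigned grid used on disk."""
    q = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max)
    return FluorescenceStack(data=q, protocol=stack.protocol, source_id=stack.source_id)


def write_stack(stack: FluorescenceStack, path: str | Path) -> None:
    """Write a stack as multi-page uint16 TIFF (values rounded to integers)."""
    q = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), q, photometric="minisblack")


def read_stack(path: str | Path, protocol: AcquisitionProtocol) -> FluorescenceStack:
    """Read and validate a multi-page single-channel TIFF against a protocol.

    A frame-count mismatch is an error, never a silent truncation; RGB or
    other multi-channel input is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    data = tifffile.imread(str(path))
    if data.ndim == 4 or (data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] not in (protocol.n_frames,)):
        raise ValueError(f"{path}: multi-channel stacks are not supported (shape {data.shape})")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page single-channel stack, got shape {data.shape}")
    if data.shape[0] != protocol.n_frames:
        raise ValueError(
            f"{path}: has {data.shape[0]} frames but protocol expects {protocol.n_frames}"
        )
    return FluorescenceStack(data=data.astype(float), protocol=protocol, source_id=str(path))


@dataclass(frozen=True)
class SampleRecord:
    """One imaging trial: design labels plus the path to its stack."""

    animal_id: str
    treatment: str
    region: str
    slice_id: str
    replicate_index: int
    stack_path: str

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}; got {self.treatment!r}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}; got {self.region!r}")
        if self.replicate_index not in (1, 2, 3):
            raise ValueError(f"replicate_index must be 1, 2 or 3; got {self.replicate_index}")

    @property
    def slice_key(self) -> tuple[str, str, str]:
        return (self.animal_id, self.region, self.slice_id)


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a sample manifest CSV into validated records.

    Rejects missing columns, vocabulary violations, and duplicate
    (animal, region, slice, replicate) keys.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "slice_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required columns: {missing}")
    records = [
        SampleRecord(
            animal_id=str(row.animal_id),
            treatment=str(row.treatment),
            region=str(row.region),
            slice_id=str(row.slice_id),
            replicate_index=int(row.replicate_index),
            stack_path=str(row.stack_path),
        )
        for row in df.itertuples(index=False)
    ]
    seen: set[tuple] = set()
    for r in records:
        key = (r.animal_id, r.region, r.slice_id, r.replicate_index)
        if key in seen:
            raise ValueError(f"duplicate manifest key {key}")
        seen.add(key)
    return records


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a metrics/results table as CSV, lossless to 15 significant digits."""
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
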