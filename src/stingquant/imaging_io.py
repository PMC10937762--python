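"""Multi-channel image stack I/O.

A field of view is stored as a multi-page 16-bit TIFF (one page per channel,
or Z consecutive pages per channel for thin z-stacks) together with a YAML
sidecar that maps pages to biological channel roles and records the pixel
size. Roles are fixed strings: ``nucleus_dye`` (DAPI), ``neuron_marker``
(TUJ1/HuC-HuD analog), ``sting``, ``effector`` (p-IRF3 / p-NF-kB / gH2AX
analog) and ``layer_marker`` (CTIP2/CRYM analog).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, FormatError

#: Canonical channel roles, in on-disk page order.
CHANNEL_ROLES = ("nucleus_dye", "neuron_marker", "sting", "effector", "layer_marker")

PROJECTIONS = {"max": np.max, "mean": np.mean, "sum": np.sum}


@dataclass
class ChannelStack:
    """One imaging field: per-role intensity arrays plus acquisition metadata.

    All channels share one shape, either (H, W) or (Z, H, W); intensities are
    non-negative. ``nucleus_dye`` must be present for any quantification run.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.325
    z_step_um: float = 1.6
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigurationError("ChannelStack requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise FormatError(f"channel shapes differ: {sorted(shapes)}")
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ConfigurationError(
                    f"unknown channel role {role!r}; expected one of {CHANNEL_ROLES}"
                )
            arr = np.asarray(arr)
            if arr.ndim not in (2, 3):
                raise FormatError(f"channel {role!r} must be 2D or 3D, got {arr.ndim}D")
            if np.any(arr < 0):
                raise FormatError(f"channel {role!r} has negative intensities")
            self.channels[role] = arr

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def is_3d(self) -> bool:
        return len(self.shape) == 3

    def require(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise ConfigurationError(f"stack has no {role!r} channel")
        return self.channels[role]


def _ordered_roles(channels: Mapping[str, np.ndarray]) -> list[str]:
    return [r for r in CHANNEL_ROLES if r in channels]


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a stack as a multi-page uint16 TIFF plus a YAML sidecar."""
    path = Path(path)
    roles = _ordered_roles(stack.channels)
    pages = []
    for role in roles:
        arr = np.asarray(stack.channels[role])
        planes = arr[None] if arr.ndim == 2 else arr
        for plane in planes:
            pages.append(np.clip(np.rint(plane), 0, 65535).astype(np.uint16))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    n_z = stack.shape[0] if stack.is_3d else 1
    sidecar = {
        "channel_order": roles,
        "n_z": int(n_z),
        "pixel_size_um": float(stack.pixel_size_um),
        "z_step_um": float(stack.z_step_um),
        "acquisition": stack.acquisition,
    }
    sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".yaml")


def read_stack(
    path: str | Path, channel_map: Sequence[str] | None = None
) -> ChannelStack:
    """Read a multi-page TIFF into a ChannelStack.

    ``channel_map`` lists channel roles in page-block order; when omitted it
    is taken from the YAML sidecar written by :func:`write_stack`. The page
    count must equal ``len(channel_map) * n_z`` and a ``nucleus_dye`` role
    must be present.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta: dict = {}
    n_z = 1
    side = sidecar_path(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text()) or {}
        n_z = int(meta.get("n_z", 1))
    if channel_map is None:
        channel_map = meta.get("channel_order")
        if channel_map is None:
            raise ConfigurationError(
                f"no channel_map given and no sidecar found for {path}"
            )
    channel_map = list(channel_map)
    if "nucleus_dye" not in channel_map:
        raise ConfigurationError("channel_map must include the nucleus_dye role")
    if len(pages) != len(channel_map) * n_z:
        raise FormatError(
            f"{path} has {len(pages)} pages but channel_map declares "
            f"{len(channel_map)} roles x {n_z} z-planes"
        )
    channels: dict[str, np.ndarray] = {}
    for i, role in enumerate(channel_map):
        block = pages[i * n_z : (i + 1) * n_z]
        channels[role] = block[0] if n_z == 1 else block
    return ChannelStack(
        channels=channels,
        pixel_size_um=float(meta.get("pixel_size_um", 0.325)),
        z_step_um=float(meta.get("z_step_um", 1.6)),
        acquisition=dict(meta.get("acquisition", {})),
    )


def project_z(stack: ChannelStack, method: str = "max") -> ChannelStack:
    """Project a z-stack to the 2D working plane.

    Maximum-intensity projection is the default, the usual choice for sparse
    punctate signal; ``mean`` and ``sum`` are also available. 2D stacks pass
    through unchanged (apart from metadata recording the method).
    """
    if method not in PROJECTIONS:
        raise ValueError(f"unknown projection {method!r}; use one of {sorted(PROJECTIONS)}")
    reducer = PROJECTIONS[method]
    channels = {
        role: (reducer(arr, axis=0) if arr.ndim == 3 else arr.copy())
        for role, arr in stack.channels.items()
    }
    acq = dict(stack.acquisition)
    acq["z_projection"] = method
    return ChannelStack(
        channels=channels,
        pixel_size_um=stack.pixel_size_um,
        z_step_um=stack.z_step_um,
        acquisition=acq,
    )
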