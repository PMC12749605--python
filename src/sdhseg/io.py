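"""Image, mask, config and manifest input/output.

Masks travel as single-channel 8-bit PNG/TIFF with foreground = 255 and
background = 0, thresholded at >127 on read. Images are 8-bit grayscale
rescaled to [0,1] on read. Every CLI run writes a RunManifest JSON so runs
are auditable and reproducible from the recorded seed and config.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import as_binary_mask

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "RunManifest",
    "package_version",
]


def package_version() -> str:
    from . import __version__

    return __version__


def read_image(path) -> np.ndarray:
    """8-bit grayscale image -> float32 array in [0,1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float32)
    return arr / 255.0


def write_image(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    """8-bit mask file -> {0,1} array (foreground where value > 127)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    arr = as_binary_mask(mask)
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)


@dataclass
class RunManifest:
    command: str
    seed: int
    output_dir: str
    config_path: str | None = None
    config: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    version: str = ""

    def __post_init__(self):
        if not self.started:
            self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        if not self.version:
            self.version = package_version()

    def finalize(self) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")

    def write(self, path=None) -> Path:
        path = Path(path) if path else Path(self.output_dir) / "run_manifest.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return path
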