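"""Gate-stack serialization: multi-page TIFF + JSON metadata sidecar.

The TIFF holds one page per gate in gate order (16-bit unsigned by default,
32-bit on request for bright scenes); the sidecar ``<stem>.json`` carries
the gate timing, detector geometry, optics, scene description and seed so
a loaded stack is analysable without the original configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .detector import DetectorConfig, GateConfig, GateStack

__all__ = ["sidecar_path", "write_gate_stack", "read_gate_stack"]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_gate_stack(
    stack: GateStack, path: str | Path, bitdepth: int = 16
) -> Path:
    """Write ``stack`` as a multi-page TIFF plus JSON sidecar.

    Raises if any pixel/gate count overflows the chosen bit depth; pass
    ``bitdepth=32`` for bright scenes.  Returns the sidecar path.
    """
    path = Path(path)
    if bitdepth == 16:
        dtype = np.uint16
    elif bitdepth == 32:
        dtype = np.uint32
    else:
        raise ValueError("bitdepth must be 16 or 32")
    counts = stack.counts
    if np.any(counts < 0):
        raise ValueError("gate stack contains negative counts")
    maxval = counts.max() if counts.size else 0
    if maxval > np.iinfo(dtype).max:
        raise ValueError(
            f"count {int(maxval)} overflows {bitdepth}-bit storage; "
            "write with bitdepth=32"
        )
    if not np.issubdtype(counts.dtype, np.integer) and not np.allclose(
        counts, np.rint(counts)
    ):
        raise ValueError("cannot serialize a non-integer (analytic) stack losslessly")
    tifffile.imwrite(path, counts.astype(dtype), photometric="minisblack")
    side = {
        "gates": stack.gates.to_dict(),
        "detector": stack.detector.to_dict(),
        "meta": _jsonable(stack.meta),
    }
    sc = sidecar_path(path)
    sc.write_text(json.dumps(side, indent=1, sort_keys=True))
    return sc


def read_gate_stack(path: str | Path) -> GateStack:
    """Load a TIFF + sidecar pair written by :func:`write_gate_stack`."""
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sc} not found; re-export the stack or supply "
            "gate timing via explicit --gates overrides"
        )
    side = json.loads(sc.read_text())
    gates = GateConfig.from_dict(side["gates"])
    det = DetectorConfig.from_dict(side["detector"])
    counts = tifffile.imread(path)
    if counts.ndim == 2:
        counts = counts[None, :, :]
    if counts.shape[0] != gates.num_gates:
        raise ValueError(
            f"TIFF has {counts.shape[0]} pages but sidecar declares "
            f"{gates.num_gates} gates"
        )
    return GateStack(
        counts=np.ascontiguousarray(counts),
        gates=gates,
        detector=det,
        meta=side.get("meta", {}),
    )


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON output."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
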