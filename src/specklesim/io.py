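"""Frame-stack serialization: multi-page TIFF with provenance metadata."""

from __future__ import annotations

import json

import numpy as np
import tifffile

from .copula import FrameStack

__all__ = ["save_stack", "load_stack"]


def save_stack(stack: FrameStack, path) -> None:
    """Write a stack as a multi-page float32 TIFF (one page per frame).

    units/noise tags, t_frame and rho travel in the TIFF image
    description as JSON.
    """
    meta = {
        "units_tag": stack.units_tag,
        "noise_tag": stack.noise_tag,
        "t_frame": stack.t_frame,
        "rho": stack.rho,
    }
    pages = np.moveaxis(stack.data, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack",
                     description=json.dumps(meta))


def load_stack(path) -> FrameStack:
    """Read a stack written by :func:`save_stack`."""
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    if pages.ndim == 2:
        pages = pages[None]
    return FrameStack(
        data=np.moveaxis(pages.astype(float), 0, 2),
        units_tag=meta.get("units_tag", "copula-a.u."),
        noise_tag=meta.get("noise_tag", "~"),
        t_frame=float(meta.get("t_frame", float("nan"))),
        rho=float(meta.get("rho", float("nan"))),
    )
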