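"""Average-brain CT template construction.

One preprocessed control scan is chosen as the fixed reference; every
control — including the reference itself — is registered to it with the
full rigid → affine → B-spline chain, resampled onto the reference grid,
and the template is the voxelwise arithmetic mean.  Because the reference
also participates as a moving image, the template is not biased toward a
bit-identical copy of it.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .registration import (
    RegistrationConfig,
    RegistrationError,
    TransformChain,
    register,
    resample,
)
from .volumes import VolumeHU

log = logging.getLogger(__name__)

TISSUE_BANDS = {
    "csf": (0.0, 20.0),
    "brain": (20.0, 50.0),
    "blood": (50.0, 100.0),
    "bone": (300.0, np.inf),
}


@dataclass
class AverageTemplate:
    """Voxelwise-mean control brain on the fixed reference grid."""

    volume: VolumeHU
    n_controls: int
    provenance: list = field(default_factory=list)  # dicts: id, seed, chain
    failures: list = field(default_factory=list)


def control_seed(master_seed: int, control_id: str) -> int:
    """Stable per-control registration seed: invariant to list order."""
    return (int(master_seed) ^ zlib.crc32(str(control_id).encode())) & 0x7FFFFFFF


def build_average(
    controls: list[VolumeHU],
    fixed_index: int,
    config: RegistrationConfig | None = None,
    master_seed: int = 0,
    ids: list[str] | None = None,
) -> AverageTemplate:
    """Register every control to the one at ``fixed_index`` and average.

    A control whose registration fails is dropped with a warning; fewer
    than two successes abort the build.  Per-control seeds derive from the
    master seed and the control's identifier, and contributions are summed
    in identifier order, so permuting the input list does not change the
    template.
    """
    if len(controls) < 2:
        raise ValueError("need at least two controls to average")
    if not (0 <= fixed_index < len(controls)):
        raise IndexError("fixed_index out of range")
    cfg = config or RegistrationConfig()
    ids = [str(i) for i in (ids if ids is not None else range(len(controls)))]
    if len(ids) != len(controls) or len(set(ids)) != len(ids):
        raise ValueError("ids must be unique and match controls")
    fixed = controls[fixed_index]

    registered: list[tuple[str, int, TransformChain, np.ndarray]] = []
    failures: list[str] = []
    for cid, vol in zip(ids, controls):
        seed = control_seed(master_seed, cid)
        try:
            chain = register(fixed, vol, cfg, seed=seed)
        except RegistrationError as exc:
            log.warning("registration of control %s failed: %s; dropping it", cid, exc)
            failures.append(cid)
            continue
        warped = resample(vol, chain, fixed)
        registered.append((cid, seed, chain, warped.voxels))
    if len(registered) < 2:
        raise RegistrationError(
            f"only {len(registered)} controls registered successfully; cannot average"
        )
    registered.sort(key=lambda r: r[0])
    acc = np.zeros(fixed.shape, dtype=np.float64)
    for _, _, _, vox in registered:
        acc += vox
    mean = acc / len(registered)
    provenance = [{"id": cid, "seed": seed, "chain": chain}
                  for cid, seed, chain, _ in registered]
    return AverageTemplate(
        volume=VolumeHU(mean, fixed.spacing.copy(), fixed.origin.copy()),
        n_controls=len(registered),
        provenance=provenance,
        failures=failures,
    )


def template_summary(t: AverageTemplate) -> dict:
    """Per-tissue-band mean HU plus build bookkeeping (JSON-serializable)."""
    vox = t.volume.voxels
    bands = {}
    for name, (lo, hi) in TISSUE_BANDS.items():
        sel = (vox >= lo) & (vox < hi)
        bands[name] = {
            "n_voxels": int(sel.sum()),
            "mean_hu": float(vox[sel].mean()) if sel.any() else None,
        }
    return {
        "n_controls": t.n_controls,
        "failures": list(t.failures),
        "control_ids": [p["id"] for p in t.provenance],
        "tissue_bands": bands,
        "grid": {
            "shape": list(t.volume.shape),
            "spacing_mm": [float(s) for s in t.volume.spacing],
        },
    }


def template_summary_json(t: AverageTemplate) -> str:
    return json.dumps(template_summary(t), indent=2, sort_keys=True)
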