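"""Serialization of flat parameter vectors, masks, and payloads.

Everything goes through NPZ containers with the layout (or payload) metadata
embedded as a JSON string, so a file is self-describing and portable across
processes: the deterministic parameter ordering recorded in the layout is what
makes payload indices meaningful elsewhere.
"""

from __future__ import annotations

import json

import numpy as np

from .comms import SparsePayload
from .model_core import LayoutEntry, Mask, ParamLayout, ParamVector

__all__ = [
    "save_param_vector",
    "load_param_vector",
    "save_mask",
    "load_mask",
    "save_payload",
    "load_payload",
]


def _layout_to_json(layout: ParamLayout) -> str:
    return json.dumps(
        [[e.name, list(e.shape), e.offset, e.prunable] for e in layout.entries]
    )


def _layout_from_json(s: str) -> ParamLayout:
    return ParamLayout(
        tuple(LayoutEntry(n, tuple(sh), off, pr) for n, sh, off, pr in json.loads(s))
    )


def save_param_vector(params: ParamVector, path) -> None:
    np.savez(path, values=params.values, layout=_layout_to_json(params.layout))


def load_param_vector(path) -> ParamVector:
    with np.load(path, allow_pickle=False) as z:
        return ParamVector(z["values"], _layout_from_json(str(z["layout"])))


def save_mask(mask: Mask, path, seed=None, mode: str = "") -> None:
    header = json.dumps(
        {
            "sparsity": mask.sparsity,
            "seed": seed,
            "mode": mode,
            "layout_hash": mask.layout_hash,
        }
    )
    np.savez(path, bits=mask.bits, header=header)


def load_mask(path) -> tuple[Mask, dict]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        mask = Mask(z["bits"], header["sparsity"], header.get("layout_hash", ""))
    return mask, header


def save_payload(payload: SparsePayload, path) -> None:
    header = json.dumps(
        {
            "mode": payload.mode,
            "round": payload.round,
            "sender": payload.sender,
            "layout_hash": payload.layout_hash,
        }
    )
    arrays = {"values": payload.values, "header": header}
    if payload.indices is not None:
        arrays["indices"] = payload.indices
    np.savez(path, **arrays)


def load_payload(path) -> SparsePayload:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        indices = z["indices"] if "indices" in z.files else None
        return SparsePayload(
            header["mode"],
            z["values"],
            indices,
            header["layout_hash"],
            header["round"],
            header["sender"],
        )
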