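"""Serialized inter-stage alignment state.

The per-section record of the four transform stages is stored in a
versioned, self-describing JSON container.  JSON round-trips Python
floats exactly (repr-based), so coordinate round-trips are bit-exact.
Stage application order is coarse -> rough -> fine -> ultrafine; export
inverts the chain in reverse order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .transforms2d import AffineTransform2D

STATE_FORMAT = "hexalign-chain"
STATE_VERSION = 1

STAGES = ("coarse", "rough", "fine", "ultrafine")


@dataclass
class ElasticField:
    """A resolved per-section warp: deltas sampled on grid points (nm).

    The field is a destination-to-source lookup in the rough-bbox frame:
    output coordinate p samples the previous stage at ``p + delta(p)``.
    """

    grid: np.ndarray    # (N, 2) nm
    deltas: np.ndarray  # (N, 2) nm

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float).reshape(-1, 2)
        self.deltas = np.asarray(self.deltas, float).reshape(self.grid.shape)

    def __eq__(self, other):
        return (isinstance(other, ElasticField)
                and np.array_equal(self.grid, other.grid)
                and np.array_equal(self.deltas, other.deltas))


@dataclass
class TransformChain:
    """Ordered per-section transforms plus the shared rough bounding box.

    Every stage is present for all sections or for none (checked on
    save/load); ``rough_bbox`` is ``(x0, y0, x1, y1)`` nm in the shared
    reference frame.
    """

    n_sections: int
    rough_bbox: np.ndarray | None = None
    coarse: list = field(default_factory=list)      # AffineTransform2D
    rough: list = field(default_factory=list)       # AffineTransform2D
    fine: list = field(default_factory=list)        # ElasticField
    ultrafine: list = field(default_factory=list)   # ElasticField

    def __post_init__(self):
        if self.rough_bbox is not None:
            self.rough_bbox = np.asarray(self.rough_bbox, float).reshape(4)

    def validate(self):
        for name in STAGES:
            stage = getattr(self, name)
            if len(stage) not in (0, self.n_sections):
                raise ValueError(
                    f"stage {name!r} has {len(stage)} entries for "
                    f"{self.n_sections} sections (must be all or none)"
                )

    def __eq__(self, other):
        if not isinstance(other, TransformChain):
            return NotImplemented
        if self.n_sections != other.n_sections:
            return False
        a, b = self.rough_bbox, other.rough_bbox
        if (a is None) != (b is None) or (a is not None and not np.array_equal(a, b)):
            return False
        return all(getattr(self, s) == getattr(other, s) for s in STAGES)


def _encode_affine(t: AffineTransform2D):
    return {"linear": t.linear.tolist(), "translation": t.translation.tolist()}


def _decode_affine(d) -> AffineTransform2D:
    return AffineTransform2D(np.array(d["linear"]), np.array(d["translation"]))


def _encode_field(f: ElasticField):
    return {"grid": f.grid.tolist(), "deltas": f.deltas.tolist()}


def _decode_field(d) -> ElasticField:
    return ElasticField(np.array(d["grid"]), np.array(d["deltas"]))


def save_state(chain: TransformChain, path) -> None:
    chain.validate()
    doc = {
        "format": STATE_FORMAT,
        "version": STATE_VERSION,
        "n_sections": chain.n_sections,
        "rough_bbox": None if chain.rough_bbox is None else chain.rough_bbox.tolist(),
        "coarse": [_encode_affine(t) for t in chain.coarse],
        "rough": [_encode_affine(t) for t in chain.rough],
        "fine": [_encode_field(f) for f in chain.fine],
        "ultrafine": [_encode_field(f) for f in chain.ultrafine],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_state(path) -> TransformChain:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt or truncated state file {path}: {exc}") from exc
    if doc.get("format") != STATE_FORMAT:
        raise ValueError(f"not a {STATE_FORMAT} file: {path}")
    if doc.get("version") != STATE_VERSION:
        raise ValueError(
            f"state version {doc.get('version')} unsupported "
            f"(expected {STATE_VERSION})"
        )
    chain = TransformChain(
        n_sections=doc["n_sections"],
        rough_bbox=None if doc["rough_bbox"] is None else np.array(doc["rough_bbox"]),
        coarse=[_decode_affine(d) for d in doc["coarse"]],
        rough=[_decode_affine(d) for d in doc["rough"]],
        fine=[_decode_field(d) for d in doc["fine"]],
        ultrafine=[_decode_field(d) for d in doc["ultrafine"]],
    )
    chain.validate()
    return chain
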