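"""Boundary enclosing and boundary-target generation.

Nuclei truncated by the image border leave open contours in ground-truth
annotations; open contours are inconsistent supervision and the inconsistency
compounds under geometric augmentation.  ``enclose_boundaries`` closes every
border-touching component by tracing along the image border between its
border contacts and filling the enclosed interior, so that contour extraction
yields only closed curves.  Interior components are left untouched (including
any holes they may have).

``make_boundary_map`` builds the supervision target for the boundary decoder:
the morphological gradient of each instance, unioned over instances, so the
interface between touching nuclei is always marked.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_STRUCT8 = np.ones((3, 3), dtype=bool)


def enclose_boundaries(mask: np.ndarray) -> np.ndarray:
    """Close the contours of border-touching foreground components.

    For every component that touches the image border, foreground runs are
    completed along each touched border edge (and through shared corners when
    a component touches two adjacent edges), then the component's interior is
    filled.  Idempotent; components not touching the border pass through
    bit-identically.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    out = mask.copy()
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & mask])
    touching = touching[touching > 0]
    edges = {
        "top": (labels[0, :], lambda lo, hi: (0, slice(lo, hi + 1))),
        "bottom": (labels[-1, :], lambda lo, hi: (h - 1, slice(lo, hi + 1))),
        "left": (labels[:, 0], lambda lo, hi: (slice(lo, hi + 1), 0)),
        "right": (labels[:, -1], lambda lo, hi: (slice(lo, hi + 1), w - 1)),
    }
    for lab in touching:
        touched_edges = []
        for name, (line, indexer) in edges.items():
            pos = np.flatnonzero(line == lab)
            if pos.size:
                touched_edges.append((name, pos))
                if pos.size >= 2:
                    out[indexer(pos[0], pos[-1])] = True
        # connect contacts on adjacent edges through the shared corner
        touched_names = {nm for nm, _ in touched_edges}
        adjacency = {
            ("top", "left"): (0, 0),
            ("top", "right"): (0, w - 1),
            ("bottom", "left"): (h - 1, 0),
            ("bottom", "right"): (h - 1, w - 1),
        }
        for (ea, eb), (cy, cx) in adjacency.items():
            if ea in touched_names and eb in touched_names:
                pa = dict(touched_edges)[ea]
                pb = dict(touched_edges)[eb]
                # run from the contact nearest the corner up to the corner
                if ea == "top":
                    out[0, min(pa.min(), cx) : max(pa.max(), cx) + 1] = True
                else:
                    out[h - 1, min(pa.min(), cx) : max(pa.max(), cx) + 1] = True
                if eb == "left":
                    out[min(pb.min(), cy) : max(pb.max(), cy) + 1, 0] = True
                else:
                    out[min(pb.min(), cy) : max(pb.max(), cy) + 1, w - 1] = True
        # fill the now-closed interior of this component only
        comp = ndimage.label(out, structure=_STRUCT8)[0]
        comp_ids = np.unique(comp[(labels == lab) & out])
        comp_ids = comp_ids[comp_ids > 0]
        for cid in comp_ids:
            out |= ndimage.binary_fill_holes(comp == cid)
    return out


def make_boundary_map(instance_map: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Union of per-instance morphological gradients.

    Each instance's boundary band is its dilation minus its erosion with a
    disk of radius ceil(thickness / 2); pixels on the interface between two
    touching instances belong to both gradients and are always boundary.
    """
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    instance_map = np.asarray(instance_map)
    out = np.zeros(instance_map.shape, dtype=bool)
    labels = np.unique(instance_map)
    labels = labels[labels > 0]
    if labels.size == 0:
        return out
    radius = int(np.ceil(thickness / 2))
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (yy**2 + xx**2) <= radius**2
    objects = ndimage.find_objects(instance_map)
    for lab in labels:
        sl = objects[lab - 1]
        if sl is None:
            continue
        grown = tuple(
            slice(max(s.start - radius - 1, 0), min(s.stop + radius + 1, dim))
            for s, dim in zip(sl, instance_map.shape)
        )
        inst = instance_map[grown] == lab
        grad = ndimage.binary_dilation(inst, disk) & ~ndimage.binary_erosion(
            inst, disk, border_value=0
        )
        out[grown] |= grad
    return out
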