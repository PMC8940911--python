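"""Persistent cell identities across detection updates.

Every detection update is matched against the current identities by the
area-sum overlap (intersection / sum of areas).  Matched identities
take the coordinates of the new detection and are marked active; detections
overlapping nothing above the new-identity threshold spawn fresh identities;
identities missed this round go inactive but are never deleted — their last
box is carried along, rigid-shifted by the mean displacement of the
identities that did match, so a drifting field of view drags silent cells
with it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import BoundingBox
from .detection import DetectionSet, pair_overlap

__all__ = [
    "Identity",
    "IdentityRegistry",
    "update_tracks",
    "track_statistics",
]


@dataclass
class Identity:
    """One tracked cell: current box, activity flag, and box history."""

    ident: int
    box: BoundingBox
    active: bool
    first_frame: int
    last_active_frame: int
    history: List[BoundingBox] = field(default_factory=list)


@dataclass
class IdentityRegistry:
    """Map of persistent identities; ids are never reused or deleted."""

    fov_shape: Tuple[int, int]
    identities: Dict[int, Identity] = field(default_factory=dict)
    next_id: int = 0
    creation_timeline: List[Tuple[int, int]] = field(default_factory=list)  # (frame, id)

    def add(self, box: BoundingBox, frame_index: int) -> Identity:
        ident = Identity(
            ident=self.next_id,
            box=box,
            active=True,
            first_frame=frame_index,
            last_active_frame=frame_index,
            history=[box],
        )
        self.identities[self.next_id] = ident
        self.creation_timeline.append((frame_index, self.next_id))
        self.next_id += 1
        return ident

    def current_boxes(self) -> List[BoundingBox]:
        """Current box of every identity (active and inactive), tagged with its id."""
        from dataclasses import replace

        return [
            replace(identity.box, identity=ident)
            for ident, identity in sorted(self.identities.items())
        ]

    def active_ids(self) -> List[int]:
        return sorted(i for i, ident in self.identities.items() if ident.active)

    def __len__(self) -> int:
        return len(self.identities)

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        def box_dict(b: BoundingBox) -> dict:
            return {
                "x_min": b.x_min, "y_min": b.y_min,
                "x_max": b.x_max, "y_max": b.y_max, "score": b.score,
            }

        payload = {
            "fov_shape": list(self.fov_shape),
            "next_id": self.next_id,
            "creation_timeline": self.creation_timeline,
            "identities": {
                str(i): {
                    "box": box_dict(ident.box),
                    "active": ident.active,
                    "first_frame": ident.first_frame,
                    "last_active_frame": ident.last_active_frame,
                    "history": [box_dict(b) for b in ident.history],
                }
                for i, ident in self.identities.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IdentityRegistry":
        payload = json.loads(text)

        def box(d: dict) -> BoundingBox:
            return BoundingBox(d["x_min"], d["y_min"], d["x_max"], d["y_max"], d["score"])

        reg = cls(fov_shape=tuple(payload["fov_shape"]))
        reg.next_id = payload["next_id"]
        reg.creation_timeline = [tuple(t) for t in payload["creation_timeline"]]
        for key, data in payload["identities"].items():
            reg.identities[int(key)] = Identity(
                ident=int(key),
                box=box(data["box"]),
                active=data["active"],
                first_frame=data["first_frame"],
                last_active_frame=data["last_active_frame"],
                history=[box(b) for b in data["history"]],
            )
        return reg


def _match_pairs(
    detections: Sequence[BoundingBox],
    identities: Dict[int, Identity],
    method: str = "greedy",
) -> Dict[int, int]:
    """One-to-one matching detection-index -> identity-id by overlap.

    ``greedy`` sorts all candidate pairs by descending area-sum overlap
    and accepts them first-come; ``optimal`` solves the assignment problem
    maximising total overlap.  Pairs with zero overlap are never matched.
    """
    if not detections or not identities:
        return {}
    ids = sorted(identities)
    overlap = np.zeros((len(detections), len(ids)))
    for i, det in enumerate(detections):
        for j, ident_id in enumerate(ids):
            overlap[i, j] = pair_overlap(det, identities[ident_id].box)

    matches: Dict[int, int] = {}
    if method == "optimal":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-overlap)
        for i, j in zip(rows, cols):
            if overlap[i, j] > 0:
                matches[i] = ids[j]
        return matches

    # greedy: candidate pairs by descending overlap, deterministic tie-break
    pairs = [
        (overlap[i, j], i, j)
        for i in range(len(detections))
        for j in range(len(ids))
        if overlap[i, j] > 0
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_dets: set[int] = set()
    used_ids: set[int] = set()
    for _, i, j in pairs:
        if i in used_dets or j in used_ids:
            continue
        matches[i] = ids[j]
        used_dets.add(i)
        used_ids.add(j)
    return matches


def update_tracks(
    registry: IdentityRegistry,
    detections: DetectionSet,
    new_id_threshold: float = 0.2,
    matching: str = "greedy",
) -> IdentityRegistry:
    """Fold one detection update into the registry (in place).

    1. one-to-one matching of detections to identities by descending
       area-sum overlap;
    2. matched identities take the new detection's coordinates and go
       active;
    3. detections whose overlap with *every* identity is below
       ``new_id_threshold`` spawn new identities;
    4. unmatched identities go inactive and their boxes are translated by
       the mean center shift of the identities matched this step (rounded to
       0.1 px, clipped to the FOV); with no matches at all they stay put.

    Detections must already be score-filtered and duplicate-suppressed.
    """
    frame_index = detections.frame_index
    dets = list(detections.boxes)
    matches = _match_pairs(dets, registry.identities, method=matching)

    # reject matches below the association threshold: such a detection is a
    # new identity, and the identity it grazed stays unmatched
    matches = {
        i: ident_id
        for i, ident_id in matches.items()
        if pair_overlap(dets[i], registry.identities[ident_id].box) >= new_id_threshold
    }

    # mean rigid shift of the matched identities (center displacement)
    shifts = []
    for i, ident_id in matches.items():
        old = registry.identities[ident_id].box
        new = dets[i]
        shifts.append(
            (new.center[0] - old.center[0], new.center[1] - old.center[1])
        )
    if shifts:
        mean_shift = np.round(np.mean(np.asarray(shifts), axis=0) * 10) / 10
    else:
        mean_shift = np.zeros(2)

    matched_ids = set(matches.values())

    # update matched identities
    for i, ident_id in matches.items():
        identity = registry.identities[ident_id]
        from dataclasses import replace

        new_box = replace(dets[i], identity=ident_id)
        identity.box = new_box
        identity.active = True
        identity.last_active_frame = frame_index
        identity.history.append(new_box)

    # propagate unmatched identities: inactive, rigid-shifted, clipped
    for ident_id, identity in registry.identities.items():
        if ident_id in matched_ids:
            continue
        identity.active = False
        if shifts and (mean_shift[0] != 0 or mean_shift[1] != 0):
            identity.box = identity.box.translate(
                float(mean_shift[0]), float(mean_shift[1])
            ).clip(registry.fov_shape)

    # spawn identities for unmatched detections below the overlap threshold
    existing_boxes = [idn.box for idn in registry.identities.values()]
    for i, det in enumerate(dets):
        if i in matches:
            continue
        best = max((pair_overlap(det, b) for b in existing_boxes), default=0.0)
        if best < new_id_threshold:
            registry.add(det, frame_index)
            existing_boxes.append(det)
        # a detection overlapping an already-updated identity above the
        # threshold but losing the one-to-one race is dropped: it neither
        # replaces the winner nor creates a duplicate identity

    return registry


def track_statistics(registry: IdentityRegistry) -> dict:
    """Summary counts: totals, activity, lifetimes, creation timeline."""
    total = len(registry)
    active = len(registry.active_ids())
    lifetimes = {
        i: ident.last_active_frame - ident.first_frame
        for i, ident in registry.identities.items()
    }
    return {
        "total": total,
        "active": active,
        "inactive": total - active,
        "lifetimes": lifetimes,
        "creation_timeline": list(registry.creation_timeline),
    }
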