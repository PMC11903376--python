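"""Basket-catheter electrode geometry.

A 64-pole basket mapping catheter carries 8 splines (labeled A–H) of 8
electrodes each (rings 1–8).  For mapping purposes the catheter is unrolled
into an 8 x 8 grid: splines become rows and rings become columns.  The spline
axis is circular (spline A adjoins spline H), and the two poles of the basket
are represented by artificial polar nodes P1 and P8, each defined as the mean
signal of the ring-1 and ring-8 electrodes respectively.  Every physical
electrode therefore has exactly four neighbors: the same-ring electrodes on
the two adjacent splines, and the adjacent-ring electrodes on the same spline
(a polar node standing in at the ring-1 / ring-8 boundary).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

SPLINES = "ABCDEFGH"
N_SPLINES = 8
N_RINGS = 8
N_CHANNELS = N_SPLINES * N_RINGS

#: labels of the two artificial polar nodes
POLAR_1 = "P1"
POLAR_8 = "P8"


def channel_of(spline: str, ring: int) -> int:
    """Map a (spline, ring) pair to the canonical 1-based channel number.

    Convention: channel = 8*(spline_index - 1) + ring, with spline A = index 1,
    so A1 = 1 and H8 = 64.
    """
    s = SPLINES.index(spline.upper())
    if not 1 <= ring <= N_RINGS:
        raise ValueError(f"ring {ring} out of range 1..{N_RINGS}")
    return N_RINGS * s + ring


def unwrap(channel: int) -> tuple[str, int]:
    """Inverse of :func:`channel_of`: channel number -> (spline, ring)."""
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel {channel} out of range 1..{N_CHANNELS}")
    s, r = divmod(channel - 1, N_RINGS)
    return SPLINES[s], r + 1


def label_of(channel: int) -> str:
    """Human label such as 'C5' for a channel number."""
    s, r = unwrap(channel)
    return f"{s}{r}"


def channel_from_label(label: str) -> int:
    return channel_of(label[0], int(label[1:]))


@dataclass(frozen=True)
class BasketGrid:
    """The canonical 8 x 8 basket grid with its neighbor topology.

    ``neighbors`` maps each electrode label (e.g. 'C4') to its four neighbor
    labels; polar nodes appear as 'P1'/'P8'.  ``coords`` gives the 2-D chart
    coordinate of each electrode: x = spline index (0..7, periodic with
    period 8), y = ring (1..8), unit spacing on both axes.
    """

    neighbors: dict[str, tuple[str, ...]] = field(repr=False)
    coords: dict[str, tuple[float, float]] = field(repr=False)

    @property
    def labels(self) -> list[str]:
        return [label_of(c) for c in range(1, N_CHANNELS + 1)]

    def neighbor_channels(self, channel: int) -> list[int | str]:
        """Neighbors of a channel number; physical neighbors as channel
        numbers, polar nodes as their string labels."""
        out: list[int | str] = []
        for lab in self.neighbors[label_of(channel)]:
            out.append(lab if lab.startswith("P") else channel_from_label(lab))
        return out

    def to_json(self) -> str:
        rows = []
        for c in range(1, N_CHANNELS + 1):
            s, r = unwrap(c)
            rows.append(
                {
                    "channel": c,
                    "spline": s,
                    "ring": r,
                    "neighbors": list(self.neighbors[label_of(c)]),
                }
            )
        return json.dumps(rows, indent=1)


def build_grid() -> BasketGrid:
    """Construct the canonical grid with the complete 4-neighbor map.

    Same-ring neighbors on the two adjacent splines (circular: A adjoins H),
    adjacent-ring neighbors on the same spline, and polar nodes P1/P8 as the
    missing ring-neighbor of ring-1/ring-8 electrodes.
    """
    neighbors: dict[str, tuple[str, ...]] = {}
    coords: dict[str, tuple[float, float]] = {}
    for si, s in enumerate(SPLINES):
        for r in range(1, N_RINGS + 1):
            lab = f"{s}{r}"
            left = SPLINES[(si - 1) % N_SPLINES]
            right = SPLINES[(si + 1) % N_SPLINES]
            nb = [f"{left}{r}", f"{right}{r}"]
            nb.append(f"{s}{r - 1}" if r > 1 else POLAR_1)
            nb.append(f"{s}{r + 1}" if r < N_RINGS else POLAR_8)
            neighbors[lab] = tuple(nb)
            coords[lab] = (float(si), float(r))
    return BasketGrid(neighbors=neighbors, coords=coords)
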