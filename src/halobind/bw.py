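"""Ballesteros-Weinstein residue numbering and the TM4 proline motif.

In the Ballesteros-Weinstein (BW) scheme each GPCR transmembrane helix t
carries one maximally conserved anchor residue labelled t.50 (e.g. the
tryptophan of TM4); every other residue in the helix is numbered by its
sequence offset from that anchor, so position anchor+k is t.(50+k).

Serotonin receptors interrupt the TM4 backbone H-bond network with proline
motifs near the extracellular end — a single proline (P4.60), an adjacent
pair (PP4.60) or a proline-x-proline pattern (PxP4.61).  The missing amide
hydrogen leaves the carbonyl four residues N-terminal of each motif proline
exposed, e.g. 4.56 for the lone-proline case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: Window of BW positions scanned for the TM4 proline motif.
MOTIF_WINDOW = (57, 62)

#: Offset of the exposed carbonyl from a motif proline, in BW units.
EXPOSURE_OFFSET = 4


@dataclass(frozen=True)
class AnchorSpec:
    """The x.50 anchor of one TM helix: its sequence position and identity."""

    tm: int
    position: int
    expected_aa: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.tm <= 7:
            raise ValueError(f"TM id must be 1..7, got {self.tm}")
        if self.position < 1:
            raise ValueError("anchor position must be 1-based positive")


@dataclass
class BWMap:
    """Mapping sequence position (1-based) -> BW label 't.nn'."""

    labels: dict[int, str] = field(default_factory=dict)

    def label(self, position: int) -> str | None:
        return self.labels.get(position)

    def position(self, label: str) -> int | None:
        for pos, lab in self.labels.items():
            if lab == label:
                return pos
        return None


@dataclass(frozen=True)
class TM4Motif:
    """TM4 proline motif call with its exposure prediction.

    ``motif`` is one of P / PP / PxP / none; ``proline_positions`` are
    sequence positions; ``exposed_labels`` are the BW labels predicted
    exposed by the i-4 rule, one per motif proline.
    """

    motif: str
    proline_positions: tuple[int, ...]
    exposed_labels: tuple[str, ...]
    convention: str = (
        "window 4.%d-4.%d; PP/PxP anchored at the C-terminal Pro; "
        "exposed = Pro - %d (BW units)" % (*MOTIF_WINDOW, EXPOSURE_OFFSET)
    )


def assign_bw(
    sequence: str,
    anchors: Sequence[AnchorSpec],
    spans: dict[int, tuple[int, int]],
    strict: bool = True,
) -> BWMap:
    """Assign BW labels inside each TM span from its x.50 anchor.

    ``spans`` maps TM id -> inclusive (start, end) sequence positions.  With
    ``strict`` (default) an anchor whose residue differs from
    ``expected_aa`` is an error; otherwise a warning-and-continue.
    """
    seen_positions: set[int] = set()
    seen_tms: set[int] = set()
    labels: dict[int, str] = {}
    for anchor in anchors:
        if anchor.tm in seen_tms:
            raise ValueError(f"duplicate anchor for TM{anchor.tm}")
        if anchor.position in seen_positions:
            raise ValueError(
                f"anchor position {anchor.position} shared by two TMs"
            )
        seen_tms.add(anchor.tm)
        seen_positions.add(anchor.position)
        if anchor.position > len(sequence):
            raise ValueError(
                f"anchor position {anchor.position} beyond sequence "
                f"length {len(sequence)}"
            )
        span = spans.get(anchor.tm)
        if span is None:
            raise ValueError(f"no span for TM{anchor.tm}")
        start, end = span
        if not start <= anchor.position <= end:
            raise ValueError(
                f"TM{anchor.tm} anchor at {anchor.position} outside span "
                f"{start}-{end}"
            )
        found = sequence[anchor.position - 1]
        if anchor.expected_aa and found != anchor.expected_aa:
            msg = (
                f"TM{anchor.tm} anchor at {anchor.position}: expected "
                f"{anchor.expected_aa}, sequence has {found}"
            )
            if strict:
                raise ValueError(msg)
            import logging

            logging.getLogger(__name__).warning(msg)
        for pos in range(start, min(end, len(sequence)) + 1):
            labels[pos] = f"{anchor.tm}.{50 + pos - anchor.position}"
    return BWMap(labels=labels)


def _bw_number(label: str) -> tuple[int, int]:
    t, nn = label.split(".")
    return int(t), int(nn)


def tm4_proline_motif(sequence: str, bw: BWMap) -> TM4Motif:
    """Classify the TM4 proline motif inside the 4.57-4.62 window.

    Decision table: two adjacent prolines -> PP; two prolines separated by
    one non-proline -> PxP; a lone proline -> P; otherwise none.  Each motif
    proline at 4.nn predicts an exposed carbonyl at 4.(nn-4).
    """
    lo, hi = MOTIF_WINDOW
    window_positions = []
    for nn in range(lo, hi + 1):
        pos = bw.position(f"4.{nn}")
        if pos is None:
            raise ValueError(f"BW label 4.{nn} not assigned; cannot scan motif window")
        if pos > len(sequence):
            raise ValueError(f"BW label 4.{nn} maps outside the sequence")
        window_positions.append((nn, pos))
    prolines = [(nn, pos) for nn, pos in window_positions if sequence[pos - 1] == "P"]
    if not prolines:
        return TM4Motif("none", (), ())
    if len(prolines) == 1:
        motif = "P"
    elif len(prolines) == 2:
        gap = prolines[1][0] - prolines[0][0]
        if gap == 1:
            motif = "PP"
        elif gap == 2:
            motif = "PxP"
        else:
            motif = "P"  # two isolated prolines: report the C-terminal one
            prolines = prolines[-1:]
    else:
        # more than two prolines: keep the most C-terminal recognizable pair
        gap = prolines[-1][0] - prolines[-2][0]
        motif = "PP" if gap == 1 else ("PxP" if gap == 2 else "P")
        prolines = prolines[-2:] if motif in ("PP", "PxP") else prolines[-1:]
    exposed = tuple(f"4.{nn - EXPOSURE_OFFSET}" for nn, _ in prolines)
    return TM4Motif(
        motif, tuple(pos for _, pos in prolines), exposed
    )
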