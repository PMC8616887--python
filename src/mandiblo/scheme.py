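"""The canonical 96-point mandible contour scheme.

The contour is a single closed loop through eight anatomical landmarks with
a fixed number of equally spaced semilandmarks on each of the eight segments
between consecutive landmarks.  Landmark names follow craniofacial
convention: RC/LC right and left condyles, RCP/LCP coronoid processes,
RG/LG gonions, SB superior (interdental) border, IB inferior border
(gnathion).  "Right" and "left" are anatomical sides: the patient's right
appears on the image's left in a panoramic radiograph.

Coordinates everywhere are (x, y) floats, origin at the top-left pixel
center, x rightward, y downward, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical landmark names in traversal order of the closed contour.
LANDMARK_ORDER = ("RC", "RG", "IB", "LG", "LC", "LCP", "SB", "RCP")

#: Semilandmark count for each segment (start landmark -> next landmark in
#: LANDMARK_ORDER, the last segment closing RCP -> RC).
SEGMENT_COUNTS = {
    ("RC", "RG"): 8,    # posterior ramus, right
    ("RG", "IB"): 8,    # lower body margin, right
    ("IB", "LG"): 8,    # lower body margin, left
    ("LG", "LC"): 8,    # posterior ramus, left
    ("LC", "LCP"): 10,  # sigmoid notch, left
    ("LCP", "SB"): 18,  # anterior ramus + alveolar margin, left
    ("SB", "RCP"): 18,  # alveolar margin + anterior ramus, right
    ("RCP", "RC"): 10,  # sigmoid notch, right
}


@dataclass(frozen=True)
class ContourScheme:
    """Ordered segment layout of the closed mandible contour.

    ``segments`` is a list of (start_landmark, end_landmark, n_semilandmarks)
    forming a single closed loop: each segment starts where the previous one
    ended and the last segment ends at the first segment's start.
    """

    segments: tuple = field(
        default_factory=lambda: tuple(
            (a, b, SEGMENT_COUNTS[(a, b)])
            for a, b in zip(
                LANDMARK_ORDER, LANDMARK_ORDER[1:] + LANDMARK_ORDER[:1]
            )
        )
    )

    def __post_init__(self):
        names = [s[0] for s in self.segments]
        if sorted(names) != sorted(LANDMARK_ORDER):
            raise ValueError("segments must cover the eight canonical landmarks")
        for (_, end, _), (start, _, _) in zip(
            self.segments, self.segments[1:] + self.segments[:1]
        ):
            if end != start:
                raise ValueError("segments do not form a single closed loop")
        if self.n_semilandmarks != 88:
            raise ValueError(
                f"semilandmark counts sum to {self.n_semilandmarks}, expected 88"
            )

    @property
    def n_semilandmarks(self) -> int:
        return sum(c for _, _, c in self.segments)

    @property
    def n_points(self) -> int:
        return len(self.segments) + self.n_semilandmarks

    @property
    def landmark_indices(self) -> dict:
        """Map landmark name -> index of its point in the 96-point contour."""
        idx, out = 0, {}
        for start, _, count in self.segments:
            out[start] = idx
            idx += 1 + count
        return out

    def segment_slices(self) -> list:
        """Per segment: (start_lm, end_lm, slice of its semilandmark rows)."""
        out, idx = [], 0
        for start, end, count in self.segments:
            out.append((start, end, slice(idx + 1, idx + 1 + count)))
            idx += 1 + count
        return out


DEFAULT_SCHEME = ContourScheme()
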