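"""Superficial U-fiber criteria on analytic curves.

A streamline is U-shaped when its endpoint distance D is below L/pi (L the
arc length) and L lies within 20-80 mm; midline-crossing streamlines are
excluded.  A 3/4 circle passes; a semicircle and a straight line do not.
"""

import numpy as np

from tractreli import arc_length, crosses_midline, endpoint_distance, is_u_shaped


def arc(radius, fraction, n=500, center=(30.0, 0, 0)):
    theta = np.linspace(-np.pi * fraction, np.pi * fraction, n)
    c = np.tile(np.asarray(center), (n, 1))
    c[:, 0] += radius * np.sin(theta)
    c[:, 2] += radius * np.cos(theta)
    return c


curves = {
    "3/4 circle r=10": arc(10.0, 0.75),
    "semicircle r=15": arc(15.0, 0.5),
    "straight 50 mm": np.array([[10.0, 0, 0], [60.0, 0, 0]]),
    "midline 3/4 circle": arc(10.0, 0.75, center=(0.0, 0, 0)),
}
print(f"{'curve':22s} {'L (mm)':>8s} {'D (mm)':>8s} {'L/pi':>7s}  U?   crosses midline?")
for name, c in curves.items():
    L, D = arc_length(c), endpoint_distance(c)
    print(
        f"{name:22s} {L:8.1f} {D:8.1f} {L/np.pi:7.1f}  "
        f"{str(is_u_shaped(c)):5s} {crosses_midline(c)}"
    )
# L is the cumulative polyline length, D the chord between the endpoints;
# only curves bent beyond a semicircle satisfy D < L/pi.
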