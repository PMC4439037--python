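"""Shape complementarity (Sc) on fixtures with a closed-form answer.

Two planar dot grids with opposing normals are a perfectly complementary
interface: at contact Sc = 1, and pulled apart by d the statistic decays as
exp(-w d^2) with the default weight w = 0.5 per square angstrom.
"""

import numpy as np

from ephcompare import sc_statistic, synthetic_data

print(f"{'separation (A)':>15} {'Sc':>8} {'exp(-0.5 d^2)':>14}")
for d in (0.0, 0.5, 1.0, 1.5, 2.0):
    a, b = synthetic_data.make_plane_pair(d)
    report = sc_statistic(a, b, band=5.0)
    print(f"{d:15.1f} {report.sc:8.4f} {np.exp(-0.5 * d * d):14.4f}")
# Sc = 1 means interlocking surfaces at zero gap; values around 0.7-0.8 are
# what tightly packed protein-protein interfaces typically score, and the
# decay with separation shows the statistic's distance weighting at work.
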