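"""Classify bound states and map lipid clustering under the protein.

Uses the published CV boxes for the two bound orientations, counts
lipid-protein contacts with the 0.7 nm cutoff, and builds max-normalised
in-plane density maps from synthetic membrane snapshots with hotspots at
the canonical, noncanonical and third binding sites.
"""

import numpy as np

import lipidpmf as lp
from lipidpmf.workflow import DEFAULT_HOTSPOTS

defs = lp.default_state_definitions()
for frame in [(0.49, 3.94, 0.41), (0.48, 3.48, 0.94), (0.73, 4.30, 0.30)]:
    print(f"  frame {frame} -> {lp.classify_state(frame, defs)}")
# (0.49, 3.94, 0.41) is inside the B_A box, (0.48, 3.48, 0.94) inside
# B_B; the third frame falls in the encounter slab.

frames = lp.generate_membrane_frames(
    "B_A", n_pip3=3, hotspots=list(DEFAULT_HOTSPOTS), n_frames=1000,
    seed=23)
w = np.ones(len(frames))
mask = np.ones(len(frames), bool)

pdf = lp.contact_pdf(frames, w, mask, "B_A")
print("contact-count PDF (3 lipids/leaflet):",
      {int(c): round(float(p), 3)
       for c, p in zip(pdf.counts, pdf.probabilities)})
print(f"mode = {pdf.mode}, mean = {pdf.mean():.2f}")
# Two to three lipids are simultaneously in contact in the three-lipid
# system - binding engages multiple sites at once.

dm = lp.density_map(frames, w, mask, "B_A")
print(f"density map: max = {dm.density.max():.0f} (normalised), "
      f"peaks at {[(round(x, 1), round(y, 1)) for x, y in dm.peak_positions(0.4)]}")
# Peaks recover the three planted binding-site hotspots around the
# protein centre.
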