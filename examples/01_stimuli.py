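"""Build the three stimulus classes and inspect their structure.

A moving Mondrian mask (MMM) is 150 coloured squares drifting along six
directions inside a 7.32 deg bounding square; a regular CFS mask redraws
the same squares at new random positions at 10 Hz; the target is a small
disc crossing the display right-to-left while fading in over 20 frames.
"""

from collections import Counter

import numpy as np

from cfskit.stimulus import (DisplayGeometry, TargetSpec,
                             generate_cfs_sequence, generate_mmm_sequence,
                             generate_target_sequence, init_mmm_elements)

geometry = DisplayGeometry()
print(f"frame: {geometry.frame_side} px "
      f"({geometry.pixels_per_degree:.2f} px/deg), "
      f"element: {geometry.element_px} px")

elements = init_mmm_elements(geometry, speed=3.0, seed=42)
directions = Counter(tuple(np.round(e.direction, 3)) for e in elements)
print(f"{len(elements)} mask elements over {len(directions)} directions "
      f"({sorted(directions.values())} per direction)")

mmm = generate_mmm_sequence(geometry, speed=3.0, duration=1.0, seed=42)
cfs = generate_cfs_sequence(geometry, duration=1.0, refresh_rate=10.0,
                            seed=42)
n_layouts = len({mmm_frame.tobytes() for mmm_frame in cfs.frames})
print(f"MMM: {len(mmm)} frames, all distinct; "
      f"CFS: {len(cfs)} frames holding {n_layouts} layouts (10 Hz refresh)")

target = generate_target_sequence(TargetSpec(speed=3.0, duration=3.6),
                                  geometry)
print(f"target: {len(target)} frames (3.6 s traversal)")

# short traversal keeps the disc on screen from frame 1, showing the ramp
short = generate_target_sequence(TargetSpec(speed=3.0, duration=1.0),
                                 geometry)
dev = np.abs(short.frames - 0.5).reshape(len(short), -1).max(axis=1)
print(f"fade-in: contrast relative to full over the first frames "
      f"{np.round(dev[:5] / dev[20], 2)} ... -> 1.0 at frame 20")
# The ratios show the linear fade-in; frame 21 onward is at full contrast.
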