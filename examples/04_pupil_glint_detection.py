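"""Pupil and glint detection on a painted synthetic IR eye image.

Run:  python examples/04_pupil_glint_detection.py
"""

import numpy as np

from stereogaze.features import DetectionParams, EyeImage, detect_features
from stereogaze.simulator import render_eye_image

# paint a 200x200 ROI: dark pupil ellipse (a=45, b=35 px) at (100, 100),
# two glints below the pupil centre, one distractor reflection above it
img = render_eye_image(
    pupil_center_px=(100.0, 100.0),
    glints_px=[(92.0, 120.0), (112.0, 121.0), (100.0, 80.0)],
    pupil_axes_px=(45.0, 35.0),
)
frame = detect_features(EyeImage(img), DetectionParams(), cam=1, eye="left")

print(f"pupil centre: ({frame.pupil_center[0]:.2f}, {frame.pupil_center[1]:.2f}) px "
      f"(painted at 100, 100)")
print(f"pupil area:   {frame.pupil_area:.0f} px^2 "
      f"(pi*45*35 = {np.pi*45*35:.0f})")
print(f"glint 1:      ({frame.glint1[0]:.2f}, {frame.glint1[1]:.2f}) px")
print(f"glint 2:      ({frame.glint2[0]:.2f}, {frame.glint2[1]:.2f}) px")

# The distractor at (100, 80) sits above the pupil centre, a region where
# real glints cannot appear with the lights mounted below the eyes, so the
# position filter removes it; glints are reported left-to-right.
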