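"""Rotating-wedge geometry: time -> angle -> quadrant, and design accounting.

Builds the default stimulus protocol (48 s revolution, 5 Hz flicker,
8 revolutions) and shows how recording time maps to wedge angle and
visual-field quadrant, then prints the classifier design-matrix geometry
for the reference cohort.
"""

from fosdecode import (
    StimulusProtocol,
    design_geometry,
    label_from_angle,
    quadrant_passes,
    wedge_angle_at,
)

protocol = StimulusProtocol()
print(f"revolution: {protocol.revolution_period} s, flicker {protocol.flicker_rate} Hz,"
      f" {protocol.n_revolutions} revolutions -> {protocol.stimulus_duration:.0f} s")

for t in (0.0, 6.0, 12.0, 24.0, 36.0):
    angle = wedge_angle_at(t, protocol)
    print(f"  t={t:5.1f} s  wedge center {angle:5.1f} deg  -> {label_from_angle(angle).value}")
# The wedge rotates counterclockwise, so the screen angle decreases:
# after a quarter revolution (12 s) the wedge center sits at 270 deg (left).

passes = quadrant_passes(StimulusProtocol(n_revolutions=1))
print(f"\none revolution splits into {len(passes)} constant-quadrant passes:")
for a, b, lab in passes:
    print(f"  [{a:4.1f}, {b:4.1f}) s  {lab.value:6s} ({(b - a):.0f} s = {int((b - a) / 0.4)} trials)")

geom = design_geometry(protocol, n_subjects=41, n_channels=128)
print(f"\nreference cohort: {geom.n_subjects} subjects x {geom.n_revolutions} revolutions"
      f" x {geom.trials_per_quadrant_pass} trials x 2 quadrants"
      f" = {geom.rows} rows x {geom.cols} channels")
# 19,680 x 128 is the input matrix a binary quadrant contrast feeds the SVM.
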