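"""The clockface convention as a lookup table.

Run:  python examples/02_clock_and_grades.py

Prints, for a range of lateralization angles, the clock position on each
side and the severity grade.  This uses only the pure convention functions
(no meshes involved), which is also how a measured angle from another tool
could be mapped onto the clockface.
"""

from trochlemetry import angle_to_clock, classify, clock_to_angle

print(f"{'angle':>7s}  {'left clock':>10s}  {'right clock':>11s}  grade")
for deg in (0, 10, 23, 29.9, 30, 45, 46, 56.6, 60, 75, 90, 120):
    left = angle_to_clock(deg, "left")
    right = angle_to_clock(deg, "right")
    print(f"{deg:7.1f}  {left:10.2f}  {right:11.2f}  {classify(deg)}")

print()
print("inverse mapping (clock position -> angle):")
for hour, side in ((1.0, "left"), (2.0, "left"), (11.0, "right"),
                   (10.0, "right"), (9.0, "right")):
    print(f"  {hour:4.1f} o'clock ({side:5s}) -> "
          f"{clock_to_angle(hour, side):6.1f} deg")
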