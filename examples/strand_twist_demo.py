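"""Cumulative strand twist on constructed backbones.

An ideally repeating extended chain has zero twist; a chain whose carbonyls
advance 20 degrees per two-residue step accumulates 20 degrees per measured
step.  Twist is read from the carbonyl C->O vectors projected perpendicular
to the local CA(i)->CA(i+2) axis, comparing residues two apart so the
beta-pleat's alternation cancels.
"""

from ephcompare import strand_twist, synthetic_data

flat = synthetic_data.make_strand(8, twist_per_step_deg=0.0)
twisted = synthetic_data.make_strand(8, twist_per_step_deg=20.0)

for label, chain in (("ideal strand", flat), ("20 deg/step strand", twisted)):
    report = strand_twist(chain, 1, 8)
    steps = ", ".join(
        "skip" if s is None else f"{s:+.1f}" for s in report.per_step
    )
    print(f"{label:>20}: steps [{steps}] deg -> cumulative {report.cumulative:.1f} deg")
print(f"convention: {strand_twist(flat, 1, 8).convention}")
# Large cumulative values flag strands that corkscrew along their length;
# the stamped convention keeps numbers comparable only to themselves.
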