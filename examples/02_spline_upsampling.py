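"""Comparing CDR3 loops of different lengths via spline up-sampling.

Loops of unequal length have no one-to-one atom pairing, so each backbone
trace is interpolated with a natural cubic spline and both are resampled
at a common number of points. The sampling grid is chosen so the distance
degenerates to the plain RMSD whenever lengths agree.
"""

from tcrloops import (
    GeneratorConfig,
    extract_region,
    generate_repertoire,
    loop_rmsd,
    upsampled_distance,
)

config = GeneratorConfig(n_records=40, seed=3)
records, _ = generate_repertoire(config)
loops = [extract_region(r, "alpha", "CDR3") for r in records]

equal = [(a, b) for a in loops for b in loops
         if a is not b and a.loop_length == b.loop_length][0]
unequal = [(a, b) for a in loops for b in loops
           if a.loop_length < b.loop_length][0]

a, b = equal
print(f"equal lengths {a.loop_length}/{b.loop_length}: "
      f"plain RMSD {loop_rmsd(a, b).value:.4f} A, "
      f"up-sampled {upsampled_distance(a, b).value:.4f} A (identical)")

a, b = unequal
d = upsampled_distance(a, b)
print(f"lengths {a.loop_length} vs {b.loop_length}: "
      f"up-sampled distance {d.value:.3f} A over {d.n_points} sample points")
# The first line shows the calibration property; the second a distance
# that plain RMSD could not produce at all.
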