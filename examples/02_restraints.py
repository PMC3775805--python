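"""Flat-harmonic restraint scoring and ROSETTA constraint emission.

A DSS cross-link tolerates any CB-CB distance up to 30 A without penalty
(x0 = 15, tolerance = 15, sigma = 1); beyond that the penalty grows
quadratically.  The same parameters are written out as AtomPair
FLAT_HARMONIC lines that ROSETTA consumes directly.
"""

from xlmod.restraints import RestraintParams, flat_harmonic, write_rosetta_constraints
from xlmod.sasd import parse_distance_file

params = RestraintParams()  # DSS defaults: x0 15.0, tolerance 15.0, sigma 1.0
for d in (5.0, 15.0, 30.0, 31.0, 32.0, 35.0):
    print(f"penalty({d:5.1f} A) = {flat_harmonic(d, params):6.2f}")

xls = parse_distance_file(
    "1\tmodel.pdb\tLYS-12-A-CB\tLYS-57-A-CB\n"
    "2\tmodel.pdb\tLYS-57-A-CB\tLYS-103-B-CB\n"
)
print("\nROSETTA constraint file:")
print(write_rosetta_constraints(xls, params), end="")
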