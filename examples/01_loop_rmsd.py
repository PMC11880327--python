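"""Anchor-aligned backbone RMSD between two CDR3 loop conformations.

Generates two synthetic TCR records that share the framework scaffold,
displaces one CDR3-beta loop by a known amount, and measures the distance
exactly as the analysis pipeline does: superpose on the anchor backbone
atoms, then RMSD over the loop backbone (N, CA, C, O) with no re-fitting.
"""

from tcrloops import (
    GeneratorConfig,
    extract_region,
    generate_repertoire,
    loop_rmsd,
    perturb_record,
    superpose_by_anchors,
)

records, _ = generate_repertoire(GeneratorConfig(n_records=1, seed=42))
reference = records[0]
# rigidly translate the CDR3-beta loop by 1.5 Angstrom
moved = perturb_record(reference, "beta", "CDR3", displacement=1.5, seed=0)

loop_ref = extract_region(reference, "beta", "CDR3")
loop_mov = extract_region(moved, "beta", "CDR3")

sup = superpose_by_anchors(loop_mov, loop_ref)
dist = loop_rmsd(loop_mov, loop_ref)

print(f"loop sequence:        {loop_ref.sequence} ({loop_ref.loop_length} residues)")
print(f"anchor fit RMSD:      {sup.anchor_rmsd:.3f} A over {sup.n_atoms_used} atoms")
print(f"loop backbone RMSD:   {dist.value:.3f} A ({dist.n_points} atom pairs)")
# The anchors are untouched, so the anchor fit is exact (0 A) and the loop
# RMSD reproduces the planted 1.5 A displacement.
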