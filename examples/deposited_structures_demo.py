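"""Measure deposited crystal structures from a local PDB mirror.

The same ring measurement runs unchanged on real coordinates.  Download the
entries (e.g. 4WD8 for the wild-type pentamer and 6IV0 for its opened
aperture mutant) into data/deposited/ and this script reports the aperture
radii and the backbone RMSD between them.
"""

from bestgate import load_deposited, pore_profile, superpose_rmsd

try:
    wt = load_deposited("4wd8")
    mutant = load_deposited("6iv0")
except FileNotFoundError as exc:
    raise SystemExit(f"skipping: {exc}")

for model in (wt, mutant):
    report = pore_profile(model, [62, 66, 70, 180])
    print(f"{model.identifier}:")
    for rec in report.records:
        if rec.error:
            print(f"  residue {rec.residue_number}: {rec.error}")
        else:
            print(f"  residue {rec.residue_number} ({rec.residue_name}): "
                  f"radius {rec.radius:.2f} A")

print(f"CA RMSD {wt.identifier} vs {mutant.identifier}: "
      f"{superpose_rmsd(wt, mutant):.2f} A")
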