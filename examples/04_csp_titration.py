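"""HSQC titration analysis: minimal-shift CSP profile and response classes.

A synthetic titration (free protein + 1:1, 2:1, 3:1 ligand ratios) is
generated with planted per-residue responses, then analysed exactly as a
real titration would be: combined 1H/15N perturbations, the minimal-shift
profile against the final point, and classification into instant
(strong, sub-uM) vs gradual (weak, >10 uM) responders.
"""

import glycocover as gc

lists, truth = gc.gen_titration_peaks(gc.TitrationScenario(seed=11, noise_sigma=0.0))

profile = gc.minimal_csp_profile(lists["free"], lists["3:1"], w=0.2)
df = profile.as_dataframe()
moved = df[df["csp_ppm"] > 0.02].round(4)
print("residues with minimal combined CSP above the 0.02 ppm floor (3:1 point):")
print(moved.to_string(index=False))

classes = gc.classify_titration(list(lists.values()))
summary = classes.groupby("category")["residue_id"].apply(list)
print("\ntitration response classes:")
for cat, rids in summary.items():
    shown = ", ".join(map(str, rids[:8])) + (" ..." if len(rids) > 8 else "")
    print(f"  {cat:22s} {len(rids):3d} residues  ({shown})")
print("\nInstant responses at 1:1 flag tight (sub-uM) site occupancy; gradual")
print("shifts flag fast-exchange weak binding; the minimal CSP never exceeds")
print("the same-residue (assigned) CSP.")
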