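"""Contrast-ratio extraction for a single subject.

Renders one noise-free phantom subject (a pontine background with two
hyperintense LC tubes), places the 10x10-voxel pontine reference patch
automatically, and extracts mean/median/max contrast ratios for the whole
LC and its rostral/caudal and left/right subdivisions.
"""

from lccr import TrajectoryParams, extract_subject, render_subject_volume

params = TrajectoryParams().noiseless()
volume, lc_mask = render_subject_volume(
    age=45, tr_ms=30, cr_rostral=0.08, cr_caudal=0.05, params=params)

record = extract_subject(volume, lc_mask, subject_id="demo", age_years=45)

print(f"reference mean signal: {record.ref_s_mean:.1f} a.u.")
for region in ("whole", "rostral", "caudal", "left", "right"):
    cr = record.cr[region]
    print(f"{region:>8}: CR mean {cr['mean']:+.3f}  median {cr['median']:+.3f} "
          f" max {cr['max']:+.3f}  ({record.voxel_counts[region]} voxels)")
print()
print("CR = (S_LC - S_ref) / S_ref. The rendered rostral CR was 0.08 and the")
print("caudal CR 0.05; a noise-free extraction returns them exactly, and the")
print("whole-LC value is their voxel-weighted mixture.")
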