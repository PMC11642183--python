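"""Numeric descriptors of a single promoter sequence.

Shows GC content, the dinucleotide Moran's I autocorrelation, the chaos
game representation and its 20x20 occupancy grid, and the CKSNAP / EIIP
feature blocks the random-forest model consumes.
"""

from promdesign.features_numeric import (
    cgr_trajectory,
    cksnap,
    dinucleotide_moran,
    eiip_features,
    gc_content,
    pssm_from_cgr,
)

seq = "TTGACAATTAATCATCGGCTCGTATAATGTGTGGAATTGTGAGCGGATAA"  # 50 bp

print(f"sequence ({len(seq)} bp): {seq}")
print(f"GC content: {gc_content(seq):.1f} %")
moran = dinucleotide_moran(seq)
print(f"dinucleotide Moran's I: {moran.I:+.4f} "
      "(range ~[-1, 1]; positive = neighbouring positions carry similar "
      "dinucleotide frequencies)")

traj = cgr_trajectory(seq)
grid = pssm_from_cgr(traj)
print(f"CGR trajectory: {traj.shape[0]} points in the unit square; "
      f"occupancy grid {grid.shape}, mass {grid.sum():.0f}, "
      f"{int((grid > 0).sum())} occupied cells")

ck = cksnap(seq, K_max=5)
print(f"CKSNAP vector: {len(ck)} features; "
      f"adjacent-pair block head: AA={ck['cksnap_g0_AA']:.3f} AT={ck['cksnap_g0_AT']:.3f}")
ei = eiip_features(seq, (3,))
top = ei.sort_values(ascending=False).head(3)
print("strongest EIIP-weighted 3-mers: "
      + ", ".join(f"{k.split('_')[-1]}={v:.4f}" for k, v in top.items()))
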