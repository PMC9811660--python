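"""From raw peak intensities to a classified PRE profile.

Builds a small duplicate-replicate peak table in memory, computes per-residue
PRE means with sample SDs, classifies them against the standard bins, and
runs the mean-normalized intensity-ratio perturbation analysis used to spot
residues broadened or shifted by complex formation.
"""

from spinpre import (
    PeakRecord,
    compute_pre_profile,
    normalized_ratio_perturbation,
    summed_replicate_profile,
)

records = [
    # residue, label, I_ox, I_red, replicate
    PeakRecord(295, "backbone NH", 72, 100, 1), PeakRecord(295, "backbone NH", 76, 98, 2),
    PeakRecord(305, "backbone NH", 30, 101, 1), PeakRecord(305, "backbone NH", 34, 99, 2),
    PeakRecord(326, "backbone NH", 92, 100, 1), PeakRecord(326, "backbone NH", 97, 103, 2),
    PeakRecord(384, "backbone NH", 99, 100, 1), PeakRecord(384, "backbone NH", 104, 100, 2),
    PeakRecord(404, "W404 side-chain NH", 55, 100, 1), PeakRecord(404, "W404 side-chain NH", 60, 99, 2),
]

profile = compute_pre_profile(records)
print("replicate-mean PRE profile:")
print(profile[["residue_number", "pre_mean", "pre_sd", "class_label", "region_label"]]
      .to_string(index=False))

summed = summed_replicate_profile(records)
print("\nadded-spectra (summed-intensity) PREs:")
print(summed[["residue_number", "pre_mean"]].to_string(index=False))

free = {295: 100.0, 305: 110.0, 326: 95.0, 384: 105.0}
cplx = {295: 60.0, 305: 101.0, 326: 88.0, 384: 99.0}
perturbed, table = normalized_ratio_perturbation(free, cplx, threshold=0.75)
print("\nnormalized bound/free intensity ratios (mean-normalized):")
print(table.to_string(index=False))
print(f"perturbed residues (normalized ratio < 0.75): {sorted(perturbed)}")
print(
    "\nPREs below 0.4 are 'strong' (close, populated contact); the 0.8-1.2 "
    "band is baseline scatter.  Perturbed residues mark the binding surface."
)
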