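"""From a complex structure to the set of residues that should light up.

Generates a small synthetic two-chain structure (stand-in for a real
PDB/mmCIF complex), places the spin-label pseudo-atom at the cysteine site,
derives the per-residue probe-amide distance table, and asks which residues
would show strong PREs if the binding mode were fully populated — then
judges the mode against a simulated profile in which none of them do.
"""

from spinpre import (
    BindingMode,
    PeakRecord,
    ProbeSite,
    SpinSystemParams,
    assess_mode,
    compute_pre_profile,
    distance_table,
    load_structure,
    make_fixture_structure,
    strong_pre_footprint,
)

params = SpinSystemParams()
path = "scratch_fixture.pdb"
make_fixture_structure(6, [9.0, 12.0, 16.0, 20.0, 24.0, 30.0], seed=4, path=path)

structure = load_structure(path)
mode = BindingMode(
    name="candidate",
    structure_source=path,
    probe=ProbeSite("L", 1, placement_rule="cbeta"),
    observed_chain="A",
)
table = distance_table(structure, mode, atom_role="amide_N")
print("probe-amide distance table:")
print(table.data.to_string(index=False))

footprint = strong_pre_footprint(table, params, threshold=0.4, p=1.0)
print(f"\nexpected strong-PRE footprint at full occupancy: {sorted(footprint)}")

# observed profile: everything near baseline -> the mode is not populated
profile = compute_pre_profile(
    [PeakRecord(res, "backbone NH", 95.0, 100.0) for res in range(1, 7)]
)
rows, summary = assess_mode(profile, table, params)
print(f"\nmode '{summary['mode']}' supported: {summary['supported']}")
print(f"expected strong PREs: {summary['expected_strong_pre']}")
print(f"observed strong PREs: {summary['observed_strong_pre']}")
kd = summary["kd_lower_bound_molar"]
print(
    f"K_D lower bound {1e3 * kd:.0f} mM (residue {summary['kd_lower_bound_residue']}): "
    "binding tighter than this would have produced visible attenuation."
)
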