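"""Check the FEM solver against the analytic multilayer-sphere solution.

For point current sources the concentric-sphere problem has an exact
Legendre-series solution; running the voxel FEM on the same geometry
measures its discretization error directly.
"""

from tdcsfield.validation import fem_oracle_comparison

errors = fem_oracle_comparison(voxel_sizes_mm=(4.0, 3.0))
for h, err in errors.items():
    print(f"voxel size {h:g} mm: relative RMS error of |E| on the cortical "
          f"sampling surface = {100 * err:.1f}%")
print("The error shrinks with refinement; it is dominated by the staircase")
print("representation of the curved resistive skull and thin CSF shells")
print("(see docs/methods.md for the measured convergence behaviour).")
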