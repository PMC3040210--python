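"""Chemical-diversity coverage: how much of a reference metabolome's
descriptor-space variance do the detected metabolites span?

Builds a synthetic reference metabolome (18 physicochemical descriptors)
plus a detected subset confined to the reference's first principal plane,
then compares the coverage statistic with the plane's true variance share.
"""

from equiscreen import (
    PropertyMatrix, chemical_coverage, generate_property_tables,
    standardize_properties,
)

reference, subsets, info = generate_property_tables(
    seed=7, n_reference=300,
    subsets={"detected": {"components": (0, 1), "n": 80}})

detected = standardize_properties(subsets["detected"], record=reference.scaling)
coverage = chemical_coverage(reference, detected, n_components=2)
truth = 100 * info["plane_share"]["detected"]
print(f"coverage of the reference metabolome by the detected set: "
      f"{coverage:.1f}% (true plane share {truth:.1f}%)")

full = PropertyMatrix(reference.data, scaling=reference.scaling)
print(f"coverage by the full reference itself at full rank: "
      f"{chemical_coverage(reference, full, 18):.1f}%")
# 100% means the subset's PCA loadings reproduce every descriptor direction
# of the reference; lower values flag chemistry the platforms never saw.
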