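"""Delta-mass arithmetic: from a precursor m/z to a named modification.

The delta mass of an acylcarnitine is its [M+H]+ precursor m/z minus the
[M+H]+ of free carnitine (C7H15NO3); it identifies the conjugated acyl
group independent of structure.
"""

from carnlib import (
    assign_car_nomenclature,
    chain_length_category,
    compute_delta_mass,
    decompose_delta,
    mass_defect,
    monoisotopic_mass,
    parse_formula,
)
from carnlib.curation import CARNITINE_MH, canonical_delta_key, formula_string, ion_mz

print(f"free carnitine [M+H]+      : {CARNITINE_MH:.4f}")
acetylcarnitine = ion_mz(parse_formula("C9H17NO4"))
print(f"acetylcarnitine [M+H]+     : {acetylcarnitine:.4f}")

delta = compute_delta_mass(acetylcarnitine)
print(f"delta mass                 : {delta:.4f} -> canonical key {canonical_delta_key(delta)}")
# 42.01 is an acetylation: the two-decimal key is the library identity.

print(f"mass defect of the delta   : {mass_defect(delta):+.4f}")
# positive defects are typical of hydrogen-rich (CHO) acyl chains.

candidates = decompose_delta(delta, tol_ppm=5.0,
                             element_bounds={"C": (0, 6), "H": (0, 12), "O": (0, 3)})
print(f"formula candidates at 5 ppm: {[formula_string(c) for c in candidates]}")

best = candidates[0]
print(f"CAR name                   : {assign_car_nomenclature(best)}")
print(f"chain-length category (C2) : {chain_length_category(best['C'])}")
# CAR C2:0 = a carnitine carrying a 2-carbon, fully saturated acyl chain.

oleoyl = parse_formula("C18H32O")
print(f"oleoyl delta C18H32O       : {monoisotopic_mass(oleoyl):.4f} "
      f"-> {assign_car_nomenclature(oleoyl)} ({chain_length_category(18)} chain)")
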