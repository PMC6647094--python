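# Reference cofactor species used to balance metabolic reaction steps.
# Symmetry numbers are point-group rotational symmetry numbers for the
# shipped reference records; metabolites default to sigma = 1.
format: cofactor-table/1
cofactors:
  water:
    formula: {H: 2, O: 1}
    charge: 0
    symmetry_number: 2
    standard_concentration_M: 55.34
  methanol:
    formula: {C: 1, H: 4, O: 1}
    charge: 0
    symmetry_number: 1
  glucuronic_acid:
    formula: {C: 6, H: 10, O: 7}
    charge: 0
    symmetry_number: 1
  sulfate:
    formula: {O: 4, S: 1}
    charge: -2
    symmetry_number: 12
  hydronium:
    formula: {H: 3, O: 1}
    charge: 1
    symmetry_number: 3
  nicotinamide_H:
    # protonated nicotinamide cation, oxidized form of the model redox couple
    formula: {C: 6, H: 7, N: 2, O: 1}
    charge: 1
    symmetry_number: 1
  dihydronicotinamide:
    # 1,4-dihydronicotinamide, reduced form of the model redox couple
    formula: {C: 6, H: 8, N: 2, O: 1}
    charge: 0
    symmetry_number: 1
  oxygen:
    formula: {O: 2}
    charge: 0
    symmetry_number: 2
    linear: true
    spin_multiplicity: 3
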