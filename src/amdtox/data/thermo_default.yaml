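# Default aqueous complexation constants for sulfate/chloride-rich acidic waters.
#
# log10_K values are association constants at 25 degC, infinite dilution,
# taken from standard thermodynamic compilations (MINTEQ/WATEQ-family values
# commonly used for acid mine drainage modelling). They are NOT measured or
# reported by any single field study; edit this file to use a different
# database. Stoichiometry is written in terms of the free components below;
# "H" refers to the proton, whose activity is fixed by the input pH.
components:
  Al:       {charge: 3}
  "Fe(II)": {charge: 2}
  "Fe(III)": {charge: 3}
  Cu:       {charge: 2}
  Zn:       {charge: 2}
  Mn:       {charge: 2}
  Co:       {charge: 2}
  Ni:       {charge: 2}
  "As(III)": {charge: 0}   # free form H3AsO3
  "As(V)":  {charge: 0}    # free form H3AsO4
  SO4:      {charge: -2}
  Cl:       {charge: -1}
complexes:
  - {name: HSO4-,       stoichiometry: {H: 1, SO4: 1},        log10_K: 1.99,  charge: -1}
  - {name: AlSO4+,      stoichiometry: {Al: 1, SO4: 1},       log10_K: 3.50,  charge: 1}
  - {name: Al(SO4)2-,   stoichiometry: {Al: 1, SO4: 2},       log10_K: 5.00,  charge: -1}
  - {name: FeSO4,       stoichiometry: {"Fe(II)": 1, SO4: 1}, log10_K: 2.25,  charge: 0}
  - {name: FeCl+,       stoichiometry: {"Fe(II)": 1, Cl: 1},  log10_K: 0.14,  charge: 1}
  - {name: FeSO4+,      stoichiometry: {"Fe(III)": 1, SO4: 1}, log10_K: 4.04, charge: 1}
  - {name: Fe(SO4)2-,   stoichiometry: {"Fe(III)": 1, SO4: 2}, log10_K: 5.38, charge: -1}
  - {name: FeCl+2,      stoichiometry: {"Fe(III)": 1, Cl: 1}, log10_K: 1.48,  charge: 2}
  - {name: CuSO4,       stoichiometry: {Cu: 1, SO4: 1},       log10_K: 2.36,  charge: 0}
  - {name: CuCl+,       stoichiometry: {Cu: 1, Cl: 1},        log10_K: 0.40,  charge: 1}
  - {name: ZnSO4,       stoichiometry: {Zn: 1, SO4: 1},       log10_K: 2.37,  charge: 0}
  - {name: Zn(SO4)2-2,  stoichiometry: {Zn: 1, SO4: 2},       log10_K: 3.28,  charge: -2}
  - {name: ZnCl+,       stoichiometry: {Zn: 1, Cl: 1},        log10_K: 0.43,  charge: 1}
  - {name: MnSO4,       stoichiometry: {Mn: 1, SO4: 1},       log10_K: 2.26,  charge: 0}
  - {name: MnCl+,       stoichiometry: {Mn: 1, Cl: 1},        log10_K: 0.61,  charge: 1}
  - {name: CoSO4,       stoichiometry: {Co: 1, SO4: 1},       log10_K: 2.30,  charge: 0}
  - {name: NiSO4,       stoichiometry: {Ni: 1, SO4: 1},       log10_K: 2.29,  charge: 0}
  - {name: H2AsO3-,     stoichiometry: {"As(III)": 1, H: -1}, log10_K: -9.23, charge: -1}
  - {name: H2AsO4-,     stoichiometry: {"As(V)": 1, H: -1},   log10_K: -2.24, charge: -1}
  - {name: HAsO4-2,     stoichiometry: {"As(V)": 1, H: -2},   log10_K: -9.20, charge: -2}
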