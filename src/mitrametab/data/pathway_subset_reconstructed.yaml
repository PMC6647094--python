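# Curated mitragynine pathway subset: 18 metabolite codes and 21 reaction
# steps per parent, RECONSTRUCTED from the published description of the
# LC-MS-derived rat/human pathway scheme (ester hydrolysis at 16,
# O-demethylation at 9 and 17 with aldehyde intermediates oxidized or
# reduced, glucuronidation at all three positions, sulfation at 9, and
# combinations).  The aldehyde intermediates (*_m?d codes) are the
# compounds not observed directly; evidence flags are approximate.
# Codes are written without the parent tag and apply to both parents.
format: pathway-subset/1
metabolites:
  - {code: mmm, rat: true, human: true, bracketed: false}   # parent compound
  - {code: dmm, rat: true, human: true, bracketed: false}   # 9-O-demethyl
  - {code: mdm, rat: true, human: true, bracketed: false}   # 16-carboxy (ester hydrolysis)
  - {code: mmd, rat: false, human: false, bracketed: true}  # 17-aldehyde intermediate
  - {code: ddm, rat: true, human: true, bracketed: false}   # 9-O-demethyl-16-carboxy
  - {code: dmd, rat: false, human: false, bracketed: true}  # 9-O-demethyl-17-aldehyde
  - {code: mdd, rat: false, human: false, bracketed: true}  # 16-carboxy-17-aldehyde
  - {code: mmo, rat: true, human: false, bracketed: false}  # 17-carboxy
  - {code: mmr, rat: true, human: true, bracketed: false}   # 17-hydroxymethyl
  - {code: dmo, rat: true, human: false, bracketed: false}  # 9-O-demethyl-17-carboxy
  - {code: dmr, rat: true, human: true, bracketed: false}   # 9-O-demethyl-17-hydroxymethyl
  - {code: gmm, rat: true, human: true, bracketed: false}   # 9-O-glucuronide
  - {code: smm, rat: true, human: false, bracketed: false}  # 9-O-sulfate
  - {code: mgm, rat: false, human: true, bracketed: false}  # 16-acyl glucuronide
  - {code: mmG, rat: true, human: true, bracketed: false}   # 17-O-glucuronide
  - {code: gmr, rat: false, human: true, bracketed: false}  # 9-O-glucuronide of 17-alcohol
  - {code: gdm, rat: false, human: true, bracketed: false}  # 9-O-glucuronide of 16-acid
  - {code: dgm, rat: false, human: true, bracketed: false}  # 16-acyl glucuronide of 9-phenol
steps:
  - {from: mmm, to: dmm}
  - {from: mmm, to: mdm}
  - {from: mmm, to: mmd}
  - {from: dmm, to: ddm}
  - {from: mdm, to: ddm}
  - {from: dmm, to: dmd}
  - {from: mmd, to: dmd}
  - {from: mdm, to: mdd}
  - {from: mmd, to: mdd}
  - {from: mmd, to: mmo}
  - {from: mmd, to: mmr}
  - {from: dmd, to: dmo}
  - {from: dmd, to: dmr}
  - {from: mmr, to: dmr}
  - {from: mmr, to: mmG}
  - {from: dmr, to: gmr}
  - {from: dmm, to: gmm}
  - {from: dmm, to: smm}
  - {from: mdm, to: mgm}
  - {from: ddm, to: gdm}
  - {from: ddm, to: dgm}
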