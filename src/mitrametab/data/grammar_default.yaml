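# Positional substitution grammar for mitragynine (M) and 7-hydroxymitragynine (H)
# metabolites.  Three reactive positions carry single-letter substitution states:
#   9  -- aromatic methyl ether:      m (methoxy), d (phenol after O-demethylation),
#         g (glucuronide after d), s (sulfate ester after d, anionic)
#   16 -- methyl ester:               m (ester), d (carboxylic acid after hydrolysis),
#         g (acyl glucuronide after d)
#   17 -- enol methyl ether:          m (enol ether), d (aldehyde after O-demethylation),
#         o (carboxylic acid after oxidation of d), r (primary alcohol after reduction
#         of d), G (ether glucuronide after r)
# Transitions form a DAG rooted at m for each position.  Formula deltas are relative
# to the all-m state of the same parent; `charge` entries are charge deltas.
format: metabolite-grammar/1
positions:
  - position: "9"
    states: [m, d, g, s]
    transitions:
      - {from: m, to: d, reaction: O_demethylation}
      - {from: d, to: g, reaction: glucuronidation}
      - {from: d, to: s, reaction: sulfation}
  - position: "16"
    states: [m, d, g]
    transitions:
      - {from: m, to: d, reaction: ester_hydrolysis}
      - {from: d, to: g, reaction: glucuronidation}
  - position: "17"
    states: [m, d, o, r, G]
    transitions:
      - {from: m, to: d, reaction: O_demethylation}
      - {from: d, to: o, reaction: oxidation}
      - {from: d, to: r, reaction: reduction}
      - {from: r, to: G, reaction: glucuronidation}
formula_deltas:
  "9":
    d: {C: -1, H: -2}
    g: {C: 5, H: 6, O: 6}
    # R-OSO3(-): methyl replaced by SO3 on the anion
    s: {C: -1, H: -3, O: 3, S: 1, charge: -1}
  "16":
    d: {C: -1, H: -2}
    g: {C: 5, H: 6, O: 6}
  "17":
    d: {C: -1, H: -2}
    o: {C: -1, H: -2, O: 1}
    # reduction of the aldehyde: net -CH2 +H2 relative to the enol ether
    r: {C: -1}
    # glucuronide of the position-17 alcohol: r + C6H8O6
    G: {C: 5, H: 8, O: 6}
parents:
  M:
    name: mitragynine
    formula: {C: 23, H: 30, N: 2, O: 4}
    charge: 0
  H:
    name: 7-hydroxymitragynine
    formula: {C: 23, H: 30, N: 2, O: 5}
    charge: 0
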