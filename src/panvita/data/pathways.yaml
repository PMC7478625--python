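# Pathway requirement definitions over canonical gene symbols.
#
# expression: prefix s-expression with AND/OR over function ids.
# category: synthesis | salvage_transport
# vitamin: pairs a synthesis definition with its salvage/transport twin
#          for strategy classification.
# min_tier defaults to MODERATE (family-level calls rescued by genome
# context count as pathway evidence); override per pathway if needed.

pathways:
  # --- central carbon metabolism -------------------------------------
  - id: emp_glycolysis
    category: synthesis
    expression: "(AND pgi pfkA fba tpiA gapA pgk gpmA eno pyk)"
  - id: ppp_oxidative
    category: synthesis
    expression: "(AND zwf pgl gnd)"
  - id: ppp_nonoxidative
    category: synthesis
    expression: "(AND rpe rpiA tktA talA)"
  - id: entner_doudoroff
    category: synthesis
    expression: "(AND edd eda)"

  # --- fermentation / energy conservation ----------------------------
  - id: butyrogenesis
    category: synthesis
    expression: "(AND thl bhbD cro bcd etfA etfB but)"
  - id: lactate_fermentation
    category: synthesis
    expression: "(OR ldhL ldhD)"
  - id: pyruvate_oxidation
    category: synthesis
    expression: "(OR pflD (AND porA porB))"
  - id: rnf_complex
    category: synthesis
    expression: "(AND rnfA rnfB rnfC rnfD rnfE rnfG)"

  # --- amino acids ----------------------------------------------------
  - id: serine_biosynthesis
    category: synthesis
    expression: "(OR (AND serA serC (OR serB thrH)) glyA)"
  - id: histidine_biosynthesis
    category: synthesis
    expression: "(AND hisG hisE hisI hisA hisF hisB hisC hisD)"

  # --- B vitamins: synthesis vs salvage pairs -------------------------
  - id: thiamine_synthesis
    category: synthesis
    vitamin: thiamine
    expression: "(AND (OR thiC cytX) thiD)"
  - id: thiamine_salvage
    category: salvage_transport
    vitamin: thiamine
    expression: "thiT"

  - id: riboflavin_synthesis
    category: synthesis
    vitamin: riboflavin
    expression: "(AND ribBA ribD ribE ribH)"
  - id: riboflavin_salvage
    category: salvage_transport
    vitamin: riboflavin
    expression: "(AND ribU ribF)"

  - id: pantothenate_synthesis
    category: synthesis
    vitamin: pantothenate
    expression: "(AND panB panC panD)"
  - id: pantothenate_salvage
    category: salvage_transport
    vitamin: pantothenate
    expression: "panT"

  - id: pyridoxine_synthesis
    category: synthesis
    vitamin: pyridoxine
    expression: "(AND pdxS pdxT)"
  - id: pyridoxine_salvage
    category: salvage_transport
    vitamin: pyridoxine
    expression: "(OR (AND pdxK pdxY pdxH) pdxU2)"

  - id: biotin_synthesis
    category: synthesis
    vitamin: biotin
    expression: "(AND bioA bioD bioB)"
  - id: biotin_salvage
    category: salvage_transport
    vitamin: biotin
    expression: "bioY"

  - id: folate_synthesis
    category: synthesis
    vitamin: folate
    expression: "(AND folE folK folP folC)"
  - id: folate_salvage
    category: salvage_transport
    vitamin: folate
    expression: "folT"

  # NAD salvage from nicotinate; no dedicated transporter is defined.
  - id: niacin_salvage_pathway
    category: synthesis
    expression: "(AND pncB pncA surE)"

  - id: cobalamin_synthesis
    category: synthesis
    vitamin: cobalamin
    expression: "(AND cbiA cbiC cbiD cbiF cbiG cbiH cbiJ cbiK cbiL cbiT cobS cobU)"
  - id: cobalamin_salvage
    category: salvage_transport
    vitamin: cobalamin
    expression: "(AND btuC btuD btuF)"
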