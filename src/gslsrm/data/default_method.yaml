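# Default wide-targeted acidic-GSL SRM method configuration.
#
# Residue counts per glycan were read from published structures and standard
# antigen definitions; DUPAN-2 and CA19-9 compositions follow the standard
# antigen definitions and are ASSUMPTIONS (no primary numeric source).
# The acyl list and the CE/DP/CXP values are reconstructions/placeholders:
# the original optimized values are not publicly available. Everything in
# this file is overridable by user config.

base: "d18:1"

glycans:
  - {name: GM3,         hex: 2, hexnac: 0, neuac: 1, dhex: 0, series: ganglio}
  - {name: GM2,         hex: 2, hexnac: 1, neuac: 1, dhex: 0, series: ganglio}
  - {name: GM1,         hex: 3, hexnac: 1, neuac: 1, dhex: 0, series: ganglio}
  - {name: GD1a,        hex: 3, hexnac: 1, neuac: 2, dhex: 0, series: ganglio}
  - {name: MSGb5,       hex: 4, hexnac: 1, neuac: 1, dhex: 0, series: globo}
  - {name: DSGb5,       hex: 4, hexnac: 1, neuac: 2, dhex: 0, series: globo}
  - {name: DSLc4,       hex: 3, hexnac: 1, neuac: 2, dhex: 0, series: lacto}
  - {name: GalNAcDSLc4, hex: 3, hexnac: 2, neuac: 2, dhex: 0, series: lacto}
  - {name: DUPAN-2,     hex: 3, hexnac: 1, neuac: 1, dhex: 0, series: lacto}
  - {name: CA19-9,      hex: 3, hexnac: 1, neuac: 1, dhex: 1, series: lacto}

# 24 fatty-acyl chains spanning C14-C30 (reconstruction: even-chain
# saturated 14:0-30:0, odd-chain saturated 15:0-29:0, monounsaturated
# 16:1-28:1 at even carbons).
acyls:
  - "14:0"
  - "15:0"
  - "16:0"
  - "16:1"
  - "17:0"
  - "18:0"
  - "18:1"
  - "19:0"
  - "20:0"
  - "20:1"
  - "21:0"
  - "22:0"
  - "22:1"
  - "23:0"
  - "24:0"
  - "24:1"
  - "25:0"
  - "26:0"
  - "26:1"
  - "27:0"
  - "28:0"
  - "28:1"
  - "29:0"
  - "30:0"

# Collision energy (V) keyed by NeuAc count (charge-dependent); placeholders.
ce_by_neuac:
  1: 60.0
  2: 42.0

# Species-independent sialic-acid product ion.
q3_mz: 290.09

# Source parameters (placeholders, overridable).
declustering_potential: -100.0
cell_exit_potential: -15.0

# Retention-time window defaults to the full gradient span (minutes).
rt_window: [0.0, 45.0]
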