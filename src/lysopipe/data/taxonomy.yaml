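# Default lipid taxonomy: 28 classes in 7 working categories.
#
# The five canonical categories (FA, GL, GPL, SL, St) are used with the
# glycerophospholipids split into diacylGPL (acyl-acyl), etherGPL
# (alkyl/alkenyl-acyl) and lysoGPL (single chain), which is the convention
# for organelle shotgun-lipidomics profiling.
#
# Fields per class:
#   category        one of FA, GL, diacylGPL, etherGPL, lysoGPL, SL, St
#   chains          number of radyl chains summed in the species descriptor
#                   (long-chain base counts as a chain for sphingolipids)
#   ether           class carries the O- (alkyl/alkenyl) designation
#   standard_group  internal-standard group used for absolute quantification
#   marker          optional organelle-marker flag (lysosome | mitochondrion)
#   fixed_composition  carbons:double_bonds for chainless nomenclature
#                      (cholesterol is reported without a chain descriptor)
classes:
  FA:      {category: FA,        chains: 1, ether: false, standard_group: FA}
  DAG:     {category: GL,        chains: 2, ether: false, standard_group: DAG}
  TAG:     {category: GL,        chains: 3, ether: false, standard_group: TAG}
  PC:      {category: diacylGPL, chains: 2, ether: false, standard_group: PC}
  PE:      {category: diacylGPL, chains: 2, ether: false, standard_group: PE}
  PS:      {category: diacylGPL, chains: 2, ether: false, standard_group: PS}
  PI:      {category: diacylGPL, chains: 2, ether: false, standard_group: PI}
  PA:      {category: diacylGPL, chains: 2, ether: false, standard_group: PA}
  BMP/PG:  {category: diacylGPL, chains: 2, ether: false, standard_group: BMP/PG,
            marker: lysosome}
  CL:      {category: diacylGPL, chains: 4, ether: false, standard_group: CL,
            marker: mitochondrion}
  PC O-:   {category: etherGPL,  chains: 2, ether: true,  standard_group: PC O-}
  PE O-:   {category: etherGPL,  chains: 2, ether: true,  standard_group: PE O-}
  LPC:     {category: lysoGPL,   chains: 1, ether: false, standard_group: LPC}
  LPC O-:  {category: lysoGPL,   chains: 1, ether: true,  standard_group: LPC O-}
  LPE:     {category: lysoGPL,   chains: 1, ether: false, standard_group: LPE}
  LPE O-:  {category: lysoGPL,   chains: 1, ether: true,  standard_group: LPE O-}
  LPS:     {category: lysoGPL,   chains: 1, ether: false, standard_group: LPS}
  LPG:     {category: lysoGPL,   chains: 1, ether: false, standard_group: LPG}
  LPI:     {category: lysoGPL,   chains: 1, ether: false, standard_group: LPI}
  LPA:     {category: lysoGPL,   chains: 1, ether: false, standard_group: LPA}
  SM:      {category: SL,        chains: 2, ether: false, standard_group: SM}
  Cer:     {category: SL,        chains: 2, ether: false, standard_group: Cer}
  HexCer:  {category: SL,        chains: 2, ether: false, standard_group: HexCer}
  Hex2Cer: {category: SL,        chains: 2, ether: false, standard_group: Hex2Cer}
  SHexCer: {category: SL,        chains: 2, ether: false, standard_group: SHexCer}
  GM3:     {category: SL,        chains: 2, ether: false, standard_group: GM3}
  Chol:    {category: St,        chains: 0, ether: false, standard_group: Chol,
            fixed_composition: "27:1"}
  CE:      {category: St,        chains: 1, ether: false, standard_group: CE}
aliases:
  # Shotgun MS cannot separate the mass-isomeric BMP and PG; both tokens
  # resolve to the merged class.
  BMP: BMP/PG
  PG: BMP/PG
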