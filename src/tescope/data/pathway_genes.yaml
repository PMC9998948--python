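# Germline TE-silencing pathway gene sets (vertebrate symbols, uppercase).
# pirna: piRNA biogenesis/processing genes; repressive: NuRD-complex and
# associated proteins establishing repressive chromatin; bridge: the
# KRAB-ZFP/NuRD adaptor; mirna: miRNA-processing genes used as the
# normalizing comparison set.
pirna:
  - ASZ1
  - BTBD18
  - DDX4
  - EXD1
  - FKBP6
  - GPAT2
  - HENMT1
  - MAEL
  - MOV10L1
  - PIWIL1
  - PIWIL2
  - PIWIL4
  - PLD6
  - TDRD1
  - TDRD5
  - TDRD6
  - TDRD7
  - TDRD9
  - TDRD12
  - TDRD15
  - TDRKH
repressive:
  - CBX5
  - CHD3
  - CHD4
  - CSNK2A1
  - DNMT1
  - GATAD2A
  - MBD3
  - MTA1
  - MTA2
  - RBBP4
  - RBBP7
  - SALL1
  - SETDB1
  - ZBTB7A
bridge:
  - TRIM28
mirna:
  - ADAR
  - AGO1
  - AGO2
  - AGO3
  - AGO4
  - DICER1
  - NUP155
  - PUM1
  - PUM2
  - SNIP1
  - SPOUT1
  - TARBP2
  - TRIM71
  - ZC3H7B
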