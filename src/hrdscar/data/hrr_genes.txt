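# Provisional 25-gene homologous-recombination-repair (HRR) panel.
# Override with your assay's actual gene list (one symbol per line).
BRCA1
BRCA2
ATM
ATR
BARD1
BLM
BRIP1
CDK12
CHEK1
CHEK2
FANCA
FANCC
FANCD2
FANCE
FANCF
MRE11A
NBN
PALB2
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RAD54L
WRN
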