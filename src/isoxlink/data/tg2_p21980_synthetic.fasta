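>TG2_SYNTHETIC synthetic stand-in for human tissue transglutaminase (UniProtKB P21980); 687 aa; reproduces the seven single-lysine tryptic donor peptides at K205 K265 K429 K468 K590 K600 K677 in tryptic context; filler regions are not the native sequence
ADSGNETVQGSPVSGNETVQGSPVSADSGNETVQGSPADSGNETVQGSPVSGNETVQGSP
VSADSGNETVQGSPADSGNETVQGSPVSGNETVQGSPVSADSGNETVQGSPADSGNETVQ
GSPVSGNETVQGSPVSADSGNETVQGSPADSGNETVQGSPVSGNETVQGSPVSADSGNET
VQGSPADSGNETVQGSPVSGNRFLKNAGRADSGNETVQGSPVSGNETVQGSPVSADSGNE
TVQGSPADSGNETVQGSPVSGNRWKNHGCQRADSGNETVQGSPVSGNETVQGSPVSADSG
NETVQGSPADSGNETVQGSPVSGNETVQGSPVSADSGNETVQGSPADSGNETVQGSPVSG
NETVQGSPVSADSGNETVQGSPADSGNETVQGSPVSGNETVQGSPVSADSGNETVQGSPA
DSGNRISTKSVGRADSGNETVQGSPVSGNETVQGSPVSADSGNRLAEKEETGMAMRADSG
NETVQGSPVSGNETVQGSPVSADSGNETVQGSPADSGNETVQGSPVSGNETVQGSPVSAD
SGNETVQGSPADSGNETVQGSPVSGNETVQGSPVSADSGRDLYLENPEIKIRADSGNRQK
RADSGNETVQGSPVSGNETVQGSPVSADSGNETVQGSPADSGNETVQGSPVSGNETVQGS
PVSADSGNETVQGRAVKGFRADSGNET
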