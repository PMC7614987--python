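# Example showcase input: the 33 Pfam domains annotated to the EFO term
# 'immune system disease' (EFO:0000540) in the dcGO resource.
PF07654
PF00969
PF00605
PF01023
PF01582
PF00017
PF00229
PF00020
PF00048
PF01108
PF00619
PF00008
PF03770
PF01017
PF02864
PF02865
PF09294
PF10401
PF00129
PF00178
PF00993
PF00001
PF00023
PF00656
PF07686
PF02198
PF07714
PF00018
PF07716
PF00170
PF00173
PF00130
PF00169
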