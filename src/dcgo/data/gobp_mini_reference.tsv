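# Miniature GOBP reference for the Pfam example showcase: each term
# annotates exactly the member domains listed for it in the dcGO
# enrichment example.  A small stand-in for the full dcGO Pfam-GOBP
# annotation table, usable only with the packaged example input.
term_id	term_name	domain_id
GO:0002376	immune system process	PF00001
GO:0002376	immune system process	PF00008
GO:0002376	immune system process	PF00017
GO:0002376	immune system process	PF00018
GO:0002376	immune system process	PF00020
GO:0002376	immune system process	PF00048
GO:0002376	immune system process	PF00129
GO:0002376	immune system process	PF00130
GO:0002376	immune system process	PF00169
GO:0002376	immune system process	PF00229
GO:0002376	immune system process	PF00605
GO:0002376	immune system process	PF00619
GO:0002376	immune system process	PF00656
GO:0002376	immune system process	PF00969
GO:0002376	immune system process	PF00993
GO:0002376	immune system process	PF01108
GO:0002376	immune system process	PF01582
GO:0002376	immune system process	PF07654
GO:0002376	immune system process	PF07686
GO:0002376	immune system process	PF07714
GO:0002376	immune system process	PF07716
GO:0002376	immune system process	PF10401
GO:0048522	positive regulation of cellular process	PF00001
GO:0048522	positive regulation of cellular process	PF00008
GO:0048522	positive regulation of cellular process	PF00017
GO:0048522	positive regulation of cellular process	PF00018
GO:0048522	positive regulation of cellular process	PF00020
GO:0048522	positive regulation of cellular process	PF00023
GO:0048522	positive regulation of cellular process	PF00048
GO:0048522	positive regulation of cellular process	PF00129
GO:0048522	positive regulation of cellular process	PF00130
GO:0048522	positive regulation of cellular process	PF00169
GO:0048522	positive regulation of cellular process	PF00170
GO:0048522	positive regulation of cellular process	PF00178
GO:0048522	positive regulation of cellular process	PF00229
GO:0048522	positive regulation of cellular process	PF00605
GO:0048522	positive regulation of cellular process	PF00619
GO:0048522	positive regulation of cellular process	PF00656
GO:0048522	positive regulation of cellular process	PF00969
GO:0048522	positive regulation of cellular process	PF00993
GO:0048522	positive regulation of cellular process	PF01017
GO:0048522	positive regulation of cellular process	PF01023
GO:0048522	positive regulation of cellular process	PF01582
GO:0048522	positive regulation of cellular process	PF02198
GO:0048522	positive regulation of cellular process	PF02864
GO:0048522	positive regulation of cellular process	PF02865
GO:0048522	positive regulation of cellular process	PF07654
GO:0048522	positive regulation of cellular process	PF07686
GO:0048522	positive regulation of cellular process	PF07714
GO:0048522	positive regulation of cellular process	PF07716
GO:0048522	positive regulation of cellular process	PF10401
GO:0002684	positive regulation of immune system process	PF00001
GO:0002684	positive regulation of immune system process	PF00017
GO:0002684	positive regulation of immune system process	PF00018
GO:0002684	positive regulation of immune system process	PF00020
GO:0002684	positive regulation of immune system process	PF00048
GO:0002684	positive regulation of immune system process	PF00129
GO:0002684	positive regulation of immune system process	PF00130
GO:0002684	positive regulation of immune system process	PF00169
GO:0002684	positive regulation of immune system process	PF00229
GO:0002684	positive regulation of immune system process	PF00619
GO:0002684	positive regulation of immune system process	PF00969
GO:0002684	positive regulation of immune system process	PF00993
GO:0002684	positive regulation of immune system process	PF01582
GO:0002684	positive regulation of immune system process	PF07654
GO:0002684	positive regulation of immune system process	PF07686
GO:0002684	positive regulation of immune system process	PF07714
GO:0006952	defense response	PF00001
GO:0006952	defense response	PF00017
GO:0006952	defense response	PF00018
GO:0006952	defense response	PF00020
GO:0006952	defense response	PF00048
GO:0006952	defense response	PF00129
GO:0006952	defense response	PF00605
GO:0006952	defense response	PF00619
GO:0006952	defense response	PF01017
GO:0006952	defense response	PF01023
GO:0006952	defense response	PF01108
GO:0006952	defense response	PF01582
GO:0006952	defense response	PF02864
GO:0006952	defense response	PF02865
GO:0006952	defense response	PF07654
GO:0006952	defense response	PF07714
GO:0006952	defense response	PF09294
GO:0006952	defense response	PF10401
GO:0006950	response to stress	PF00001
GO:0006950	response to stress	PF00008
GO:0006950	response to stress	PF00017
GO:0006950	response to stress	PF00018
GO:0006950	response to stress	PF00020
GO:0006950	response to stress	PF00023
GO:0006950	response to stress	PF00048
GO:0006950	response to stress	PF00129
GO:0006950	response to stress	PF00130
GO:0006950	response to stress	PF00169
GO:0006950	response to stress	PF00170
GO:0006950	response to stress	PF00605
GO:0006950	response to stress	PF00619
GO:0006950	response to stress	PF01017
GO:0006950	response to stress	PF01023
GO:0006950	response to stress	PF01108
GO:0006950	response to stress	PF01582
GO:0006950	response to stress	PF02864
GO:0006950	response to stress	PF02865
GO:0006950	response to stress	PF07654
GO:0006950	response to stress	PF07714
GO:0006950	response to stress	PF07716
GO:0006950	response to stress	PF09294
GO:0006950	response to stress	PF10401
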