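# dataset	J	S	shannon
bci	21058	232	4.275
pasoh	27955	672	5.657
lambir	32918	1007	5.928
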