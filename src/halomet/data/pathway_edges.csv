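parent,child,kind
Cyantraniliprole,IN-J9Z38,ring_closure
IN-J9Z38,IN-MLA84,demethylation
IN-J9Z38,TP633,glycosylation
IN-MLA84,TP619,glycosylation
IN-J9Z38,IN-RNU71,dechlorination
IN-MLA84,TP423,dechlorination
IN-MLA84,TP363,debromination
IN-MLA84,TP405,dechlorination
IN-J9Z38,TP441,demethylation
IN-J9Z38,TP577,amino_acid_conjugation
Cyantraniliprole,IN-MYX98,hydroxylation
IN-MYX98,TP651a,glycosylation
IN-MYX98,TP651b,glycosylation
IN-MYX98,IN-HGW87,dealkylation
Cyantraniliprole,IN-JCZ38,oxidation
IN-JCZ38,IN-JSE76,oxidation
IN-JSE76,TP654,glycosylation
Cyantraniliprole,IN-DBC80,bridge_cleavage
Cyantraniliprole,IN-M2G98,bridge_cleavage
Cyantraniliprole,TP315,bridge_cleavage
Cyantraniliprole,TP316,bridge_cleavage
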