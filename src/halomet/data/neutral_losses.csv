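label,formula
anhydroglucose,C6H10O5
water,H2O
hydrogen chloride,HCl
hydrogen bromide,HBr
carbon monoxide,CO
hydrogen cyanide,HCN
methylamine,CH5N
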