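sample	group
WT1	WT
WT2	WT
WT3	WT
WT4	WT
Het1	Het
Het2	Het
Het3	Het
Hom1	Hom
Hom2	Hom
Hom3	Hom
Hom4	Hom
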