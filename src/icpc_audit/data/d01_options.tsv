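# The 11 Norwegian ICPC-2 diagnosis-text options published for code D01
# ('Abdominal pain/cramps general' in the English single-text version).
# Trailing '*' marks are footnote markers, stripped at parse time.
D01	Abdomen symptomer/plager INA*
D01	Abdominal ømhet
D01	Abdominalsmerte INA*
D01	Abdominalsmerte/krampe generell
D01	Akutt abdomen
D01	Kolikksmerter
D01	Magesmerter akutt
D01	Magesmerter uspesifikke
D01	Smerte abdomen uspesifikk
D01	Spedbarnskolikk
D01	Tremånederskolikk
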