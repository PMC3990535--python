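onco_mirnas	onco-miRNAs	miR-24	miR-27a	miR-146b
muscle_development	muscle development	miR-24	miR-331	miR-503	miR-27a	miR-185	miR-424
cell_cycle	cell cycle-related	miR-24	miR-23a
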