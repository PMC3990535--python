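miR-24
miR-27a
miR-146b
miR-331
miR-503
miR-185
miR-424
miR-23a
miR-1
miR-206
miR-1228
let-7a
miR-21
miR-155
miR-16
miR-31
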