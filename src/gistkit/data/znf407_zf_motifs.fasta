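>znf407_finger_705_728 C2H2 motif around Lys725
CkkCfyktrsstvltrHiklrH
>znf407_finger_1017_1040 C2H2 motif around Leu1020/Arg1038
ClhCefsahssaslelHvkrkH
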