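period,attended,scheduled
2010,200,671
2011-2017,5787,12266
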