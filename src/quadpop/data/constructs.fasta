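>g_core (GGGGA)4 G-core of the non-template strand
GGGGAGGGGAGGGGAGGGGA
>mutant G-to-T mutant lacking consecutive guanines
GTTGATTAGATGTGATTAG
>spacer G-core with an ATTTTA insert between the G-tract pairs
GGGGAGGGGAATTTTAGGGGAGGGGA
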